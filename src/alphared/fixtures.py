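"""Synthetic toy complexes, decoys and confidence profiles.

Every test input the package needs is generated here, deterministically
from a seed: two-partner complexes of ideal-geometry backbone (N, Cα, C, O
plus an explicit Cβ) with a planted native pose, rigid decoys at a
controlled ligand-RMSD, piecewise pLDDT profiles, and a planted funnel
score landscape whose minimum sits at the native pose.

Backbones are built from internal coordinates (bond lengths 1.458 / 1.525
/ 1.329 Å, standard angles) with φ/ψ fixed per geometry: ideal α-helix
(-57°, -47°), extended strand (-120°, 120°), or per-residue random torsions
(random_walk).  Cβ is placed tetrahedrally off Cα.  This is sufficient for
geometric and sampling tests; no side chains beyond Cβ, no sequence design.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from .docking import (
    Pose,
    RigidTransform,
    ScoreModel,
    default_score,
    random_unit_vector,
)
from .structure_io import Atom, ConfidenceProfile, PartnerSplit, Residue, Structure

# ideal backbone internal coordinates
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
ANGLE_N_CA_C = 111.0
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.8
OMEGA = 180.0

GEOMETRIES = ("ideal_helix", "extended", "random_walk")
_PHI_PSI = {"ideal_helix": (-57.0, -47.0), "extended": (-120.0, 120.0)}

MIN_CLASH_DISTANCE = 2.5  # Å, native pose must be clash-free
MIN_NATIVE_CONTACTS = 5  # cross-partner Cβ pairs within 8 Å

# generic 20-letter alphabet for fixture sequences (no glycine by default so
# every residue carries an explicit Cβ)
_FIXTURE_RESNAMES = ("ALA", "LEU", "SER", "VAL", "THR", "ILE", "ASP", "LYS")


@dataclass(frozen=True)
class ToyComplexSpec:
    """Parameters of a generated two-partner toy complex."""

    n_receptor: int = 24
    n_ligand: int = 20
    geometry: str = "ideal_helix"
    native_gap: float = 4.0  # Å closest heavy-atom approach in the native pose
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_receptor < 8 or self.n_ligand < 8:
            raise ValueError("need >= 8 residues per partner")
        if self.geometry not in GEOMETRIES:
            raise ValueError(f"geometry must be one of {GEOMETRIES}")
        if self.native_gap < MIN_CLASH_DISTANCE:
            raise ValueError(
                f"native_gap {self.native_gap} would clash (< {MIN_CLASH_DISTANCE} Å)"
            )


def place_atom(
    a: np.ndarray, b: np.ndarray, c: np.ndarray, bond: float, angle_deg: float,
    torsion_deg: float,
) -> np.ndarray:
    """Place a fourth atom from three predecessors by bond length, bond angle
    (at ``c``) and torsion about the b-c axis (natural extension frame)."""
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    ang = math.radians(angle_deg)
    tor = math.radians(torsion_deg)
    d2 = np.array(
        [
            -bond * math.cos(ang),
            bond * math.sin(ang) * math.cos(tor),
            bond * math.sin(ang) * math.sin(tor),
        ]
    )
    frame = np.stack([bc, m, n], axis=1)
    return c + frame @ d2


def _build_chain(
    n_res: int, chain_id: str, geometry: str, rng: np.random.Generator,
    start_seq: int = 1,
) -> Structure:
    """Ideal-geometry backbone chain with N, CA, C, O, CB per residue."""
    if geometry in _PHI_PSI:
        phi_psi = [(float(_PHI_PSI[geometry][0]), float(_PHI_PSI[geometry][1]))] * n_res
    else:
        phi_psi = [tuple(rng.uniform(-180, 180, size=2)) for _ in range(n_res)]
    # seed the first three backbone atoms
    N0 = np.array([0.0, 0.0, 0.0])
    CA0 = np.array([BOND_N_CA, 0.0, 0.0])
    ang = math.radians(180.0 - ANGLE_N_CA_C)
    C0 = CA0 + BOND_CA_C * np.array([math.cos(ang), math.sin(ang), 0.0])
    backbone: list[tuple[np.ndarray, np.ndarray, np.ndarray]] = [(N0, CA0, C0)]
    for i in range(1, n_res):
        n_prev, ca_prev, c_prev = backbone[-1]
        psi_prev = phi_psi[i - 1][1]
        phi = phi_psi[i][0]
        N = place_atom(n_prev, ca_prev, c_prev, BOND_C_N, ANGLE_CA_C_N, psi_prev)
        CA = place_atom(ca_prev, c_prev, N, BOND_N_CA, ANGLE_C_N_CA, OMEGA)
        C = place_atom(c_prev, N, CA, BOND_CA_C, ANGLE_N_CA_C, phi)
        backbone.append((N, CA, C))
    st = Structure()
    for i, (N, CA, C) in enumerate(backbone):
        if i + 1 < n_res:
            next_n = backbone[i + 1][0]
            O = place_atom(next_n, CA, C, BOND_C_O, ANGLE_CA_C_O, 180.0)
        else:
            O = place_atom(N, CA, C, BOND_C_O, ANGLE_CA_C_O, phi_psi[i][1] - 180.0)
        # tetrahedral CB off CA, bisecting away from N and C
        bis = (N - CA) + (C - CA)
        bis /= np.linalg.norm(bis)
        perp = np.cross(N - CA, C - CA)
        perp /= np.linalg.norm(perp)
        CB = CA + 1.53 * (-bis * math.cos(math.radians(54.75)) + perp * math.sin(math.radians(54.75)))
        res = Residue(
            chain_id=chain_id,
            seq_num=start_seq + i,
            name=_FIXTURE_RESNAMES[i % len(_FIXTURE_RESNAMES)],
            atoms=[
                Atom("N", "N", N, 90.0),
                Atom("CA", "C", CA, 90.0),
                Atom("C", "C", C, 90.0),
                Atom("O", "O", O, 90.0),
                Atom("CB", "C", CB, 90.0),
            ],
        )
        st.residues.append(res)
    return st


def make_toy_complex(
    spec: ToyComplexSpec = ToyComplexSpec(),
) -> tuple[Structure, Pose, PartnerSplit]:
    """Generate a two-partner complex with a planted native pose.

    Returns the native complex structure (chains A and B), the native
    :class:`~alphared.docking.Pose` (identity ligand transform) and the
    partner split ``A_B``.  The native pose is guaranteed clash-free (no
    cross-partner heavy-atom pair below 2.5 Å) with at least 5 cross-partner
    Cβ pairs within 8 Å; deterministic per seed.  The contact guarantee is
    primary: when the requested surface gap would leave fewer contacts (an
    irregular geometry, or a gap close to the 8 Å shell), the ligand is slid
    in further, still respecting the clash limit.
    """
    rng = np.random.default_rng(spec.seed)
    receptor = _build_chain(spec.n_receptor, "A", spec.geometry, rng)
    ligand = _build_chain(spec.n_ligand, "B", spec.geometry, rng)
    # pack the partners side by side: align the ligand's long axis with the
    # receptor's (seed-dependent spin and flip), approach perpendicular to it
    # (seed-dependent azimuth), then slide in until the closest heavy-atom
    # approach equals the requested surface gap.  If a placement cannot meet
    # the contact guarantee (possible for irregular geometries), further
    # seed-deterministic orientations are tried.
    rec_xyz = receptor.heavy_coords()
    lig_template = ligand.heavy_coords()
    rec_com = rec_xyz.mean(axis=0)
    rec_axis = _principal_axis(rec_xyz)
    lig_axis = _principal_axis(lig_template)
    rec_cb = np.array([r.cb_or_ca.coord for r in receptor.residues])
    cb_rows = []
    row = 0
    for res in ligand.residues:
        names = [a.name for a in res.atoms]
        cb_rows.append(row + names.index("CB" if "CB" in names else "CA"))
        row += len(names)
    perp1 = _unit(np.cross(rec_axis, _any_perpendicular(rec_axis)))
    perp2 = np.cross(rec_axis, perp1)

    lig_final = None
    for _attempt in range(64):
        flip = 1.0 if rng.random() < 0.5 else -1.0
        R_align = _rotation_between(lig_axis, flip * rec_axis)
        spin = Rotation.from_rotvec(rec_axis * rng.uniform(0, 2 * math.pi)).as_matrix()
        lig_xyz = (lig_template - lig_template.mean(axis=0)) @ (spin @ R_align).T
        azimuth = rng.uniform(0, 2 * math.pi)
        approach = math.cos(azimuth) * perp1 + math.sin(azimuth) * perp2
        lig_cb = lig_xyz[cb_rows]

        def min_gap(dist_: float) -> float:
            return float(cdist(rec_xyz, lig_xyz + rec_com + approach * dist_).min())

        def contacts_at(dist_: float) -> int:
            return int((cdist(rec_cb, lig_cb + rec_com + approach * dist_) < 8.0).sum())

        lo, hi = 0.0, 60.0
        for _ in range(60):  # bisect the approach distance to the requested gap
            mid = 0.5 * (lo + hi)
            if min_gap(mid) > spec.native_gap:
                hi = mid
            else:
                lo = mid
        dist = hi if min_gap(hi) >= spec.native_gap else lo
        # the contact guarantee is primary: slide in further if needed,
        # never below the clash limit
        while (
            contacts_at(dist) < MIN_NATIVE_CONTACTS
            and min_gap(dist - 0.25) >= MIN_CLASH_DISTANCE
        ):
            dist -= 0.25
        if contacts_at(dist) >= MIN_NATIVE_CONTACTS and min_gap(dist) >= MIN_CLASH_DISTANCE:
            lig_final = lig_xyz + rec_com + approach * dist
            break
    if lig_final is None:
        raise RuntimeError("could not place a clash-free native pose with enough contacts")
    # write ligand coordinates back
    k = 0
    for res in ligand.residues:
        for atom in res.atoms:
            atom.coord = lig_final[k]
            k += 1
    complex_structure = Structure(
        residues=[r for r in receptor.residues] + [r for r in ligand.residues]
    )
    complex_structure.validate()
    _check_native(receptor, ligand)
    native = Pose.from_structures(receptor, ligand)
    return complex_structure, native, PartnerSplit.from_string("A_B")


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _principal_axis(coords: np.ndarray) -> np.ndarray:
    centered = coords - coords.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    return vt[0]


def _any_perpendicular(v: np.ndarray) -> np.ndarray:
    ref = np.array([1.0, 0.0, 0.0]) if abs(v[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    return _unit(np.cross(v, ref))


def _rotation_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Minimal rotation taking unit vector a onto unit vector b."""
    a, b = _unit(a), _unit(b)
    cross = np.cross(a, b)
    dot = float(np.dot(a, b))
    if np.linalg.norm(cross) < 1e-12:
        if dot > 0:
            return np.eye(3)
        perp = _any_perpendicular(a)
        return Rotation.from_rotvec(perp * math.pi).as_matrix()
    angle = math.atan2(float(np.linalg.norm(cross)), dot)
    return Rotation.from_rotvec(_unit(cross) * angle).as_matrix()


def _check_native(receptor: Structure, ligand: Structure) -> None:
    d = cdist(receptor.heavy_coords(), ligand.heavy_coords())
    if d.min() < MIN_CLASH_DISTANCE:
        raise RuntimeError(f"generated native pose clashes: min distance {d.min():.2f} Å")
    rec_cb = np.array([r.cb_or_ca.coord for r in receptor.residues])
    lig_cb = np.array([r.cb_or_ca.coord for r in ligand.residues])
    n_contacts = int((cdist(rec_cb, lig_cb) < 8.0).sum())
    if n_contacts < MIN_NATIVE_CONTACTS:
        raise RuntimeError(
            f"generated native pose has only {n_contacts} Cβ contacts (< {MIN_NATIVE_CONTACTS})"
        )


# ---------------------------------------------------------------------------
# Decoys at controlled deviation
# ---------------------------------------------------------------------------

def make_decoy(
    native: Pose, lrms_target: float, rng: np.random.Generator,
    tolerance: float = 0.10, max_attempts: int = 1000,
) -> Pose:
    """Rigidly perturb the ligand to a requested ligand-RMSD from native.

    Combines a random rotation about the ligand centroid with a translation
    chosen orthogonal to the mean rotational displacement, whose magnitude is
    solved so the total backbone RMSD hits ``lrms_target`` (within
    ``tolerance``, fractional)."""
    if lrms_target < 0:
        raise ValueError("lrms_target must be >= 0")
    if lrms_target == 0:
        return native
    bb0 = native.ligand_backbone()
    pivot = native.ligand_com()
    for _ in range(max_attempts):
        max_angle = math.degrees(lrms_target / max(1.0, _gyration(bb0, pivot)))
        angle = rng.uniform(0.0, max_angle)
        axis = random_unit_vector(rng)
        Rd = Rotation.from_rotvec(axis * math.radians(angle)).as_matrix()
        rotated = native.with_transform(
            native.transform.compose_left(Rd, pivot, np.zeros(3))
        )
        disp = rotated.ligand_backbone() - bb0
        lrms_rot = float(np.sqrt(np.mean(np.sum(disp**2, axis=1))))
        if lrms_rot > lrms_target:
            continue
        mean_disp = disp.mean(axis=0)
        u = random_unit_vector(rng)
        norm = np.linalg.norm(mean_disp)
        if norm > 1e-9:
            u = u - (u @ mean_disp) * mean_disp / norm**2
            un = np.linalg.norm(u)
            if un < 1e-9:
                continue
            u /= un
        d = math.sqrt(max(lrms_target**2 - lrms_rot**2, 0.0))
        decoy = rotated.with_transform(rotated.transform.translated(u * d))
        achieved = float(
            np.sqrt(np.mean(np.sum((decoy.ligand_backbone() - bb0) ** 2, axis=1)))
        )
        if abs(achieved - lrms_target) <= tolerance * lrms_target:
            return decoy
    raise RuntimeError(
        f"could not reach ligand-RMSD {lrms_target} Å in {max_attempts} attempts"
    )


def _gyration(coords: np.ndarray, com: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.sum((coords - com) ** 2, axis=1))))


# ---------------------------------------------------------------------------
# Synthetic confidence profiles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfidenceSpec:
    """Piecewise pLDDT profile: a baseline with planted low-confidence
    segments, optional Gaussian noise, clipped to [0, 100].

    Segments are (start, end, value) with 0-based inclusive positional
    indices into the structure's residue order."""

    baseline: float = 90.0
    segments: tuple[tuple[int, int, float], ...] = ()
    noise_sigma: float = 0.0


def make_confidence(
    structure: Structure, spec: ConfidenceSpec, rng: np.random.Generator | None = None
) -> ConfidenceProfile:
    """Synthetic per-residue pLDDT for ``structure`` per ``spec``."""
    n = len(structure)
    values = np.full(n, spec.baseline, dtype=float)
    for start, end, value in spec.segments:
        if not (0 <= start <= end < n):
            raise ValueError(f"segment ({start}, {end}) out of range for {n} residues")
        values[start : end + 1] = value
    if spec.noise_sigma > 0:
        if rng is None:
            raise ValueError("noise_sigma > 0 requires an rng")
        values = values + rng.normal(0.0, spec.noise_sigma, size=n)
    return ConfidenceProfile(structure.residue_ids, np.clip(values, 0.0, 100.0))


def apply_confidence_to_bfactors(structure: Structure, profile: ConfidenceProfile) -> None:
    """Write a per-residue profile into the B-factor column in place
    (AlphaFold convention), for fixtures exported as PDB."""
    for res in structure.residues:
        v = profile[res.rid]
        for atom in res.atoms:
            atom.bfactor = v


# ---------------------------------------------------------------------------
# Planted funnel landscape
# ---------------------------------------------------------------------------

def funnel_score_factory(
    native: Pose, width: float = 8.0, depth: float = 500.0
) -> ScoreModel:
    """Score model with a planted Gaussian funnel at the native pose:

        score(pose) = default_score(pose) - depth * exp(-Lrms^2 / (2 width^2))

    where Lrms is the ligand backbone RMSD to the native pose.  The Gaussian
    term has its minimum at the native pose by construction; the combined
    minimum stays within a fraction of an ångström of it under the defaults.
    Defaults plant an unambiguous
    single-funnel landscape: a width of the order of a partner's size keeps
    the gradient felt across the accessible pose space, and the depth is
    large relative both to the sampling temperatures and to the spread of
    the coarse contact term among near-native poses (~10 score units), so
    the combined landscape keeps its minimum at the planted pose.
    """
    if width <= 0 or depth <= 0:
        raise ValueError("width and depth must be positive")
    native_bb = native.ligand_backbone().copy()
    inv = 1.0 / (2.0 * width * width)

    def score(pose: Pose) -> float:
        diff = pose.ligand_backbone() - native_bb
        lrms_sq = float(np.mean(np.sum(diff**2, axis=1)))
        return default_score(pose) - depth * math.exp(-lrms_sq * inv)

    return score
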