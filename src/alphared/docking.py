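"""Temperature replica-exchange Monte Carlo rigid-body docking.

The sampler follows the ReplicaDock scheme: several independent
trajectories, each holding one configuration per temperature rung
(default kT = 1.5, 3.0, 5.0 kcal/mol), Metropolis moves within each rung
and periodic configuration swaps between adjacent rungs.  Global mode uses
rigid-body moves only (default 4 Å translations, 8° rotations); local mode
mixes backbone torsion moves on mobile residues with small rigid moves
(1 Å / 3°) at a 3:1 backbone:rigid weighting.

Scoring is pluggable: any deterministic ``pose -> energy`` callable (lower
is better, invariant under a global rigid transform of the whole complex).
The default scorer is a coarse Cβ contact potential: harmonic repulsion
below 4 Å, a flat -1 reward per cross-partner Cβ pair between 4 and 8 Å.

Backbone moves are a simplified torsion operator: Gaussian φ/ψ offsets on
one mobile segment with downstream propagation along the chain and no loop
closure — a deliberate simplification of Backrub/kinematic-closure movers
that preserves the "directed backbone sampling on mobile residues"
contract.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from .flexibility import MobileSelection
from .structure_io import BACKBONE_ATOMS, ResidueId, Structure

# default coarse contact potential
CLASH_DISTANCE = 4.0  # Å
CONTACT_DISTANCE = 8.0  # Å
K_REPULSION = 5.0  # score units / Å^2
CONTACT_ENERGY = 1.0  # score units rewarded per contact pair

SEPARATION_DISTANCE = 500.0  # Å, for interface scores

ScoreModel = Callable[["Pose"], float]


# ---------------------------------------------------------------------------
# Rigid transforms
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RigidTransform:
    """Proper rotation plus translation in Å.

    The rotation is stored as an orthonormal matrix; the equivalent unit
    quaternion is exposed as :attr:`quat`."""

    matrix: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.matrix, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        if R.shape != (3, 3) or t.shape != (3,):
            raise ValueError("expected a 3x3 rotation matrix and 3-vector translation")
        object.__setattr__(self, "matrix", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_quat(cls, quat: np.ndarray, translation: np.ndarray) -> "RigidTransform":
        q = np.asarray(quat, dtype=float)
        return cls(Rotation.from_quat(q / np.linalg.norm(q)).as_matrix(), translation)

    @property
    def quat(self) -> np.ndarray:
        """Equivalent unit quaternion (scalar-last), |q| = 1 to 1e-9."""
        q = Rotation.from_matrix(self.matrix).as_quat()
        return q / np.linalg.norm(q)

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.matrix.T + self.translation

    def compose_left(self, rotation: np.ndarray, pivot: np.ndarray,
                     translation: np.ndarray) -> "RigidTransform":
        """Rotate realized coordinates by ``rotation`` about ``pivot`` and then
        translate; returns the composed transform."""
        R_new = rotation @ self.matrix
        t_new = rotation @ (self.translation - pivot) + pivot + translation
        # re-orthonormalize so numerical drift never accumulates over a run
        u, _, vt = np.linalg.svd(R_new)
        return RigidTransform(u @ vt, t_new)

    def translated(self, delta: np.ndarray) -> "RigidTransform":
        return RigidTransform(self.matrix, self.translation + np.asarray(delta, float))


def uniform_quaternion(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation as a unit quaternion (Gaussian 4-vector
    normalised; uniform on the 3-sphere)."""
    q = rng.normal(size=4)
    return q / np.linalg.norm(q)


def random_unit_vector(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


# ---------------------------------------------------------------------------
# Partner topology and poses
# ---------------------------------------------------------------------------

class PartnerTopology:
    """Immutable flattened-atom view of one docking partner.

    Atom rows follow residue order; precomputes row indices for Cβ (Cα for
    glycine), backbone atoms, and the downstream-in-chain row sets used by
    torsion moves.
    """

    def __init__(self, structure: Structure):
        structure.validate()
        self.structure = structure
        coords: list[np.ndarray] = []
        self.atom_names: list[str] = []
        self.res_of_atom: list[int] = []
        self.residue_ids: list[ResidueId] = list(structure.residue_ids)
        self.res_chain: list[str] = [r.chain_id for r in structure.residues]
        self._row: dict[tuple[int, str], int] = {}
        res_rows: list[list[int]] = []
        for ri, res in enumerate(structure.residues):
            rows: list[int] = []
            for atom in res.atoms:
                row = len(coords)
                coords.append(atom.coord)
                self.atom_names.append(atom.name)
                self.res_of_atom.append(ri)
                self._row[(ri, atom.name)] = row
                rows.append(row)
            res_rows.append(rows)
        self.coords0 = np.array(coords, dtype=float)
        self.res_rows = [np.array(r, dtype=int) for r in res_rows]
        cb = []
        for ri in range(len(res_rows)):
            row = self._row.get((ri, "CB"), self._row.get((ri, "CA")))
            if row is not None:
                cb.append(row)
        self.cb_rows = np.array(cb, dtype=int)
        self.backbone_rows = np.array(
            [
                self._row[(ri, n)]
                for ri in range(len(res_rows))
                for n in BACKBONE_ATOMS
                if (ri, n) in self._row
            ],
            dtype=int,
        )
        # for torsion propagation: rows of residues after ri in the same chain
        self._downstream: list[np.ndarray] = []
        n_res = len(res_rows)
        for ri in range(n_res):
            rows = [
                r
                for rj in range(ri + 1, n_res)
                if self.res_chain[rj] == self.res_chain[ri]
                for r in res_rows[rj]
            ]
            self._downstream.append(np.array(rows, dtype=int))

    def __len__(self) -> int:
        return len(self.coords0)

    @property
    def n_residues(self) -> int:
        return len(self.residue_ids)

    def atom_row(self, res_index: int, name: str) -> int | None:
        return self._row.get((res_index, name))

    def downstream_rows(self, res_index: int) -> np.ndarray:
        return self._downstream[res_index]

    def res_index(self, rid: ResidueId) -> int:
        try:
            return self.residue_ids.index(rid)
        except ValueError:
            raise KeyError(rid) from None


@dataclass
class Pose:
    """Receptor held fixed in the global frame; ligand as base coordinates
    plus a rigid transform; optional torsion-perturbed internal coordinates.

    Coordinate arrays are treated as immutable — moves return new poses
    sharing unchanged arrays."""

    receptor: PartnerTopology
    ligand: PartnerTopology
    receptor_coords: np.ndarray
    ligand_local: np.ndarray
    transform: RigidTransform = field(default_factory=RigidTransform.identity)

    _realized: np.ndarray | None = field(default=None, repr=False, compare=False)

    @classmethod
    def from_structures(cls, receptor: Structure, ligand: Structure) -> "Pose":
        rt, lt = PartnerTopology(receptor), PartnerTopology(ligand)
        return cls(rt, lt, rt.coords0, lt.coords0)

    def ligand_coords(self) -> np.ndarray:
        """Realized (global-frame) ligand coordinates."""
        if self._realized is None:
            self._realized = self.transform.apply(self.ligand_local)
        return self._realized

    def with_transform(self, transform: RigidTransform) -> "Pose":
        return replace(self, transform=transform, _realized=None)

    def receptor_cb(self) -> np.ndarray:
        return self.receptor_coords[self.receptor.cb_rows]

    def ligand_cb(self) -> np.ndarray:
        return self.ligand_coords()[self.ligand.cb_rows]

    def ligand_backbone(self) -> np.ndarray:
        return self.ligand_coords()[self.ligand.backbone_rows]

    def receptor_com(self) -> np.ndarray:
        return self.receptor_coords.mean(axis=0)

    def ligand_com(self) -> np.ndarray:
        return self.ligand_coords().mean(axis=0)

    def to_structure(self) -> Structure:
        """Realize the pose as a single complex Structure (receptor chains
        first, then ligand), with fresh coordinate copies."""
        out = Structure(model_id=1)
        for top, coords in (
            (self.receptor, self.receptor_coords),
            (self.ligand, self.ligand_coords()),
        ):
            from .structure_io import Atom, Residue  # local import avoids cycle at module load

            for ri, res in enumerate(top.structure.residues):
                new = Residue(
                    chain_id=res.chain_id,
                    seq_num=res.seq_num,
                    name=res.name,
                    insertion_code=res.insertion_code,
                )
                for atom in res.atoms:
                    row = top.atom_row(ri, atom.name)
                    new.atoms.append(
                        Atom(atom.name, atom.element, coords[row].copy(), atom.bfactor)
                    )
                out.residues.append(new)
        return out


def pose_ligand_rmsd(a: Pose, b: Pose) -> float:
    """Ligand backbone RMSD between two poses of the same complex.

    The receptor frame is shared and fixed, so no superposition is needed."""
    return float(
        np.sqrt(np.mean(np.sum((a.ligand_backbone() - b.ligand_backbone()) ** 2, axis=1)))
    )


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

def default_score(
    pose: Pose,
    k_rep: float = K_REPULSION,
    epsilon: float = CONTACT_ENERGY,
    d_clash: float = CLASH_DISTANCE,
    d_contact: float = CONTACT_DISTANCE,
) -> float:
    """Coarse cross-partner Cβ contact potential.

    Per pair at distance d: ``k_rep * (d_clash - d)^2`` if d < d_clash;
    ``-epsilon`` if d_clash <= d < d_contact; 0 otherwise.
    """
    d = cdist(pose.receptor_cb(), pose.ligand_cb())
    clash = d < d_clash
    contact = (d >= d_clash) & (d < d_contact)
    e = k_rep * float(np.sum((d_clash - d[clash]) ** 2)) - epsilon * float(contact.sum())
    return e


def separated_pose(pose: Pose, distance: float = SEPARATION_DISTANCE) -> Pose:
    """The same pose with the ligand moved ``distance`` Å further out along
    the receptor-to-ligand centre-of-mass axis."""
    axis = pose.ligand_com() - pose.receptor_com()
    norm = np.linalg.norm(axis)
    axis = axis / norm if norm > 1e-9 else np.array([1.0, 0.0, 0.0])
    return pose.with_transform(pose.transform.translated(axis * distance))


def interface_score(pose: Pose, score: ScoreModel = default_score) -> float:
    """Binding score: E(complex) - E(partners separated by 500 Å)."""
    return score(pose) - score(separated_pose(pose))


# ---------------------------------------------------------------------------
# Moves
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MoveSchedule:
    """Move magnitudes and move-type weights for one docking mode."""

    trans_mag: float  # Å, target mean translation magnitude
    rot_mag: float  # degrees, rotation-angle Gaussian sigma
    backbone_weight: float = 0.0
    rigid_weight: float = 1.0
    torsion_mag: float = 3.0  # degrees, phi/psi offset sigma

    def __post_init__(self) -> None:
        if self.trans_mag < 0 or self.rot_mag < 0 or self.torsion_mag < 0:
            raise ValueError("move magnitudes must be >= 0")
        if self.backbone_weight < 0 or self.rigid_weight < 0:
            raise ValueError("move weights must be >= 0")
        if self.backbone_weight + self.rigid_weight <= 0:
            raise ValueError("at least one move weight must be positive")


#: exhaustive global search moves (4 Å translations, 8° rotations, rigid only)
GLOBAL_SCHEDULE = MoveSchedule(trans_mag=4.0, rot_mag=8.0, backbone_weight=0.0, rigid_weight=1.0)
#: local refinement moves (1 Å, 3°) with 3:1 backbone:rigid weighting
LOCAL_SCHEDULE = MoveSchedule(
    trans_mag=1.0, rot_mag=3.0, backbone_weight=3.0, rigid_weight=1.0, torsion_mag=3.0
)


@dataclass(frozen=True)
class ReplicaLadder:
    """Temperature rungs (kcal/mol) and trajectory count."""

    kT_values: tuple[float, ...] = (1.5, 3.0, 5.0)
    n_trajectories: int = 8

    def __post_init__(self) -> None:
        if len(self.kT_values) < 2:
            raise ValueError("need >= 2 temperature rungs for swaps")
        if any(b <= a for a, b in zip(self.kT_values, self.kT_values[1:])):
            raise ValueError("kT values must be strictly increasing")
        if self.n_trajectories < 1:
            raise ValueError("need >= 1 trajectory")

    @property
    def n_rungs(self) -> int:
        return len(self.kT_values)


def randomize_orientation(
    pose: Pose, rng: np.random.Generator, contact_distance: float = 5.0,
    slide_step: float = 0.5,
) -> Pose:
    """Uniform random ligand orientation, placed along a uniform random
    direction from the receptor centre and slid inward until the first
    cross-partner heavy-atom distance <= ``contact_distance``."""
    R = Rotation.from_quat(uniform_quaternion(rng)).as_matrix()
    direction = random_unit_vector(rng)
    rec_com = pose.receptor_com()
    lig_com_local = pose.ligand_local.mean(axis=0)
    rec_radius = float(np.max(np.linalg.norm(pose.receptor_coords - rec_com, axis=1)))
    lig_radius = float(
        np.max(np.linalg.norm(pose.ligand_local - lig_com_local, axis=1))
    )
    dist = rec_radius + lig_radius + contact_distance
    while dist > 0:
        target = rec_com + direction * dist
        t = target - R @ lig_com_local
        candidate = pose.with_transform(RigidTransform(R, t))
        dmin = float(cdist(pose.receptor_coords, candidate.ligand_coords()).min())
        if dmin <= contact_distance:
            return candidate
        dist -= slide_step
    return candidate  # fully slid in; partners tiny


def perturb_rigid(pose: Pose, schedule: MoveSchedule, rng: np.random.Generator) -> Pose:
    """Gaussian rigid-body move: translation with expected magnitude
    ``trans_mag`` and rotation of Gaussian angle (sigma ``rot_mag``) about a
    random axis through the ligand centroid."""
    # chi-3 mean |t| = sigma * 2*sqrt(2/pi)  =>  sigma = trans_mag * sqrt(pi/8)
    sigma = schedule.trans_mag * math.sqrt(math.pi / 8.0)
    dt = rng.normal(0.0, sigma, size=3) if sigma > 0 else np.zeros(3)
    angle = math.radians(rng.normal(0.0, schedule.rot_mag)) if schedule.rot_mag > 0 else 0.0
    axis = random_unit_vector(rng)
    Rd = Rotation.from_rotvec(axis * angle).as_matrix()
    pivot = pose.ligand_com()
    return pose.with_transform(pose.transform.compose_left(Rd, pivot, dt))


def _rotate_about_axis(
    coords: np.ndarray, rows: np.ndarray, p0: np.ndarray, p1: np.ndarray, angle_rad: float
) -> None:
    axis = p1 - p0
    n = np.linalg.norm(axis)
    if n < 1e-9 or rows.size == 0:
        return
    R = Rotation.from_rotvec(axis / n * angle_rad).as_matrix()
    coords[rows] = (coords[rows] - p0) @ R.T + p0


def perturb_backbone(
    pose: Pose,
    mobile: MobileSelection,
    schedule: MoveSchedule,
    rng: np.random.Generator,
) -> Pose:
    """Torsion move: Gaussian φ/ψ offsets (sigma ``torsion_mag``) on one
    randomly chosen mobile segment, propagated downstream along that chain
    (no loop closure).  Empty selection is a no-op."""
    if not mobile:
        return pose
    seg_start, seg_end = mobile.segments[rng.integers(len(mobile.segments))]
    for which, top, coords in (
        ("receptor", pose.receptor, pose.receptor_coords),
        ("ligand", pose.ligand, pose.ligand_local),
    ):
        ids = set(top.residue_ids)
        if seg_start in ids and seg_end in ids:
            break
    else:
        raise ValueError(f"mobile segment {seg_start}..{seg_end} not within one partner")
    i0, i1 = top.res_index(seg_start), top.res_index(seg_end)
    if top.res_chain[i0] != top.res_chain[i1]:
        raise ValueError(f"mobile segment {seg_start}..{seg_end} spans a chain break")
    new = coords.copy()
    for ri in range(i0, i1 + 1):
        n_row = top.atom_row(ri, "N")
        ca_row = top.atom_row(ri, "CA")
        c_row = top.atom_row(ri, "C")
        down = top.downstream_rows(ri)
        if n_row is not None and ca_row is not None:
            # phi: moves everything bonded past CA (CB, C, O) and downstream
            in_res = np.array(
                [r for r in top.res_rows[ri] if r not in (n_row, ca_row)], dtype=int
            )
            rows = np.concatenate([in_res, down])
            dphi = math.radians(rng.normal(0.0, schedule.torsion_mag))
            if schedule.torsion_mag > 0:
                _rotate_about_axis(new, rows, new[n_row], new[ca_row], dphi)
        if ca_row is not None and c_row is not None:
            # psi: moves the carbonyl O and downstream residues
            o_row = top.atom_row(ri, "O")
            extra = [o_row] if o_row is not None else []
            rows = np.concatenate([np.array(extra, dtype=int), down])
            dpsi = math.radians(rng.normal(0.0, schedule.torsion_mag))
            if schedule.torsion_mag > 0:
                _rotate_about_axis(new, rows, new[ca_row], new[c_row], dpsi)
    if which == "receptor":
        return replace(pose, receptor_coords=new)
    return replace(pose, ligand_local=new, _realized=None)


# ---------------------------------------------------------------------------
# Monte Carlo acceptance
# ---------------------------------------------------------------------------

def metropolis_accept(delta_e: float, kT: float, rng: np.random.Generator) -> bool:
    """Accept with probability min(1, exp(-ΔE/kT))."""
    if kT <= 0:
        raise ValueError("kT must be positive")
    if delta_e <= 0:
        return True
    return bool(rng.random() < math.exp(-delta_e / kT))


@dataclass
class ReplicaState:
    """One configuration bound to a temperature rung."""

    rung: int
    kT: float
    energy: float
    pose: Pose | None = None


def attempt_swap(state_i: ReplicaState, state_j: ReplicaState, rng: np.random.Generator) -> bool:
    """Replica-exchange criterion between adjacent rungs:
    accept with probability min(1, exp((β_i - β_j)(E_i - E_j)))."""
    if abs(state_i.rung - state_j.rung) != 1:
        raise ValueError(f"swap only between adjacent rungs, got {state_i.rung} and {state_j.rung}")
    beta_i, beta_j = 1.0 / state_i.kT, 1.0 / state_j.kT
    arg = (beta_i - beta_j) * (state_i.energy - state_j.energy)
    if arg >= 0:
        return True
    return bool(rng.random() < math.exp(arg))


# ---------------------------------------------------------------------------
# Replica-exchange driver
# ---------------------------------------------------------------------------

@dataclass
class Decoy:
    """A recorded snapshot from the coldest rung."""

    pose: Pose
    energy: float
    interface_score: float
    trajectory: int
    replica: int
    step: int
    seed: int


@dataclass
class DockingResult:
    decoys: list[Decoy]
    mode: str
    seed: int
    n_steps: int
    ladder: ReplicaLadder
    acceptance_rates: list[float]  # per rung, pooled over trajectories
    swap_rate: float

    def best(self) -> Decoy:
        return min(self.decoys, key=lambda d: d.energy)


def run_replica_exchange(
    start: Pose,
    ladder: ReplicaLadder = ReplicaLadder(),
    schedule: MoveSchedule = GLOBAL_SCHEDULE,
    score: ScoreModel = default_score,
    n_steps: int = 5000,
    swap_every: int = 50,
    snapshot_every: int = 10,
    mobile: MobileSelection | None = None,
    mode: str = "global",
    seed: int = 0,
    randomize_start: bool = False,
) -> DockingResult:
    """Run ``ladder.n_trajectories`` independent replica-exchange trajectories.

    Each trajectory holds one configuration per rung; Metropolis moves at each
    rung per step, swap attempts between adjacent rungs (alternating even/odd
    pairs) every ``swap_every`` steps, snapshots of the coldest rung every
    ``snapshot_every`` steps.  Fully reproducible from ``seed``.

    ``mode='global'`` uses rigid moves only; ``mode='local'`` draws backbone
    vs rigid moves by the schedule weights (backbone requires a non-empty
    ``mobile`` selection; otherwise local sampling degrades to rigid moves).
    """
    if mode not in ("global", "local"):
        raise ValueError(f"mode must be 'global' or 'local', got {mode!r}")
    if n_steps <= 0:
        raise ValueError("n_steps must be positive")
    use_backbone = (
        mode == "local" and mobile is not None and bool(mobile) and schedule.backbone_weight > 0
    )
    p_backbone = (
        schedule.backbone_weight / (schedule.backbone_weight + schedule.rigid_weight)
        if use_backbone
        else 0.0
    )
    streams = np.random.SeedSequence(seed).spawn(ladder.n_trajectories)
    decoys: list[Decoy] = []
    n_rungs = ladder.n_rungs
    accept = np.zeros(n_rungs, dtype=int)
    attempts = np.zeros(n_rungs, dtype=int)
    swaps_ok = 0
    swaps_tried = 0
    for traj in range(ladder.n_trajectories):
        rng = np.random.Generator(np.random.PCG64(streams[traj]))
        pose0 = randomize_orientation(start, rng) if randomize_start else start
        poses = [pose0] * n_rungs
        energies = [float(score(pose0))] * n_rungs
        if not math.isfinite(energies[0]):
            raise RuntimeError(f"non-finite starting energy in trajectory {traj}")
        for step in range(1, n_steps + 1):
            for k in range(n_rungs):
                if p_backbone > 0 and rng.random() < p_backbone:
                    proposal = perturb_backbone(poses[k], mobile, schedule, rng)  # type: ignore[arg-type]
                else:
                    proposal = perturb_rigid(poses[k], schedule, rng)
                e_new = float(score(proposal))
                if not math.isfinite(e_new):
                    raise RuntimeError(
                        f"non-finite energy in trajectory {traj}, rung {k}, step {step}"
                    )
                attempts[k] += 1
                if metropolis_accept(e_new - energies[k], ladder.kT_values[k], rng):
                    poses[k], energies[k] = proposal, e_new
                    accept[k] += 1
            if swap_every > 0 and step % swap_every == 0:
                parity = (step // swap_every) % 2
                for k in range(parity, n_rungs - 1, 2):
                    si = ReplicaState(k, ladder.kT_values[k], energies[k])
                    sj = ReplicaState(k + 1, ladder.kT_values[k + 1], energies[k + 1])
                    swaps_tried += 1
                    if attempt_swap(si, sj, rng):
                        poses[k], poses[k + 1] = poses[k + 1], poses[k]
                        energies[k], energies[k + 1] = energies[k + 1], energies[k]
                        swaps_ok += 1
            if step % snapshot_every == 0:
                decoys.append(
                    Decoy(
                        pose=poses[0],
                        energy=energies[0],
                        interface_score=float(interface_score(poses[0], score)),
                        trajectory=traj,
                        replica=0,
                        step=step,
                        seed=seed,
                    )
                )
    return DockingResult(
        decoys=decoys,
        mode=mode,
        seed=seed,
        n_steps=n_steps,
        ladder=ladder,
        acceptance_rates=[
            (accept[k] / attempts[k]) if attempts[k] else float("nan") for k in range(n_rungs)
        ],
        swap_rate=(swaps_ok / swaps_tried) if swaps_tried else float("nan"),
    )


# ---------------------------------------------------------------------------
# Decoy clustering
# ---------------------------------------------------------------------------

def cluster_decoys(
    decoys: Sequence[Decoy],
    energy_keep_fraction: float = 0.2,
    rmsd_threshold: float = 5.0,
    n_clusters: int = 5,
) -> list[Decoy]:
    """Energy-based greedy clustering.

    Keeps the lowest-energy fraction of decoys, then repeatedly takes the
    best-energy remaining decoy as a cluster representative and removes all
    decoys within ``rmsd_threshold`` Å ligand-RMSD of it, up to
    ``n_clusters`` representatives (fewer if the pool empties first).
    Representatives are returned best-energy first.
    """
    if not decoys:
        raise ValueError("no decoys to cluster")
    pool = sorted(decoys, key=lambda d: d.energy)
    n_keep = max(1, math.ceil(len(pool) * energy_keep_fraction))
    pool = pool[:n_keep]
    reps: list[Decoy] = []
    while pool and len(reps) < n_clusters:
        seed_decoy = pool.pop(0)
        reps.append(seed_decoy)
        pool = [d for d in pool if pose_ligand_rmsd(d.pose, seed_decoy.pose) > rmsd_threshold]
    return reps
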