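"""Binding-induced flexibility metrics and mobile-residue selection.

Conformational change between two structures of the same protein (typically
unbound vs. bound) is quantified two ways:

* per-residue Cα RMSD after a single global least-squares superposition
  (sensitive to domain motions);
* LDDT, a superposition-free score counting conserved inter-residue Cα
  distances at tolerances 0.5/1/2/4 Å within a 10 Å inclusion radius
  (insensitive to rigid domain motion, sensitive to local rearrangement).

Residues predicted to move on binding — contiguous runs with pLDDT below 80
— are selected as "mobile" segments for directed backbone sampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import Align
from Bio.SeqUtils import seq1

from .structure_io import ConfidenceProfile, ResidueId, Structure

LDDT_RADIUS = 10.0  # Å inclusion radius: pairs scored iff reference distance < radius
LDDT_TOLERANCES = (0.5, 1.0, 2.0, 4.0)  # Å
MOBILE_PLDDT_THRESHOLD = 80.0
MIN_IDENTITY = 0.30


class MappingError(ValueError):
    """Residue correspondence between two structures could not be built."""


@dataclass
class ResidueMapping:
    """One-to-one, order-preserving residue correspondence A <-> B."""

    pairs: list[tuple[ResidueId, ResidueId]]
    coverage_a: float
    coverage_b: float

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def a_ids(self) -> list[ResidueId]:
        return [a for a, _ in self.pairs]

    @property
    def b_ids(self) -> list[ResidueId]:
        return [b for _, b in self.pairs]

    def b_for_a(self) -> dict[ResidueId, ResidueId]:
        return dict(self.pairs)


def _chain_sequence(structure: Structure, chain: str) -> tuple[str, list[ResidueId]]:
    rids = [r.rid for r in structure.residues if r.chain_id == chain]
    seq = "".join(
        seq1(r.name, undef_code="X")
        for r in structure.residues
        if r.chain_id == chain
    )
    return seq, rids


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -2.0
    aligner.extend_gap_score = -2.0
    return aligner


def map_residues(
    a: Structure,
    b: Structure,
    chain_pairs: list[tuple[str, str]] | None = None,
) -> ResidueMapping:
    """Build a residue correspondence by per-chain global sequence alignment.

    Chains are paired by label when both structures share labels, else in
    order of appearance; an explicit ``chain_pairs`` list overrides both.
    Gapped positions (including unaligned termini) are excluded.  A chain
    aligning below 30% identity raises :class:`MappingError` — almost always
    a wrong chain pairing.
    """
    if chain_pairs is None:
        ca, cb = a.chains, b.chains
        if set(ca) == set(cb):
            chain_pairs = [(c, c) for c in ca]
        elif len(ca) == len(cb):
            chain_pairs = list(zip(ca, cb))
        else:
            raise MappingError(
                f"cannot infer chain correspondence between {ca} and {cb}; "
                "pass chain_pairs explicitly"
            )
    aligner = _make_aligner()
    pairs: list[tuple[ResidueId, ResidueId]] = []
    for chain_a, chain_b in chain_pairs:
        seq_a, rids_a = _chain_sequence(a, chain_a)
        seq_b, rids_b = _chain_sequence(b, chain_b)
        if not seq_a or not seq_b:
            raise MappingError(f"empty chain in pairing {chain_a!r}<->{chain_b!r}")
        aln = aligner.align(seq_a, seq_b)[0]
        n_match = 0
        chain_mapped: list[tuple[ResidueId, ResidueId]] = []
        for (sa, ea), (sb, eb) in zip(*aln.aligned):
            for off in range(ea - sa):
                ia, ib = sa + off, sb + off
                chain_mapped.append((rids_a[ia], rids_b[ib]))
                if seq_a[ia] == seq_b[ib]:
                    n_match += 1
        identity = n_match / max(len(chain_mapped), 1)
        if not chain_mapped or identity < MIN_IDENTITY:
            raise MappingError(
                f"chains {chain_a!r}<->{chain_b!r} align at {identity:.0%} identity "
                f"(< {MIN_IDENTITY:.0%}); wrong pairing?"
            )
        pairs.extend(chain_mapped)
    return ResidueMapping(
        pairs=pairs,
        coverage_a=len(pairs) / len(a),
        coverage_b=len(pairs) / len(b),
    )


# ---------------------------------------------------------------------------
# Superposition
# ---------------------------------------------------------------------------

def kabsch_superpose(
    coords_a: np.ndarray, coords_b: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of ``coords_a`` onto ``coords_b``.

    Returns ``(rotation, translation, rmsd)`` with a proper rotation
    (det = +1) such that ``coords_a @ rotation.T + translation`` best fits
    ``coords_b``.
    """
    A = np.asarray(coords_a, dtype=float)
    B = np.asarray(coords_b, dtype=float)
    if A.shape != B.shape:
        raise ValueError(f"coordinate shapes differ: {A.shape} vs {B.shape}")
    if A.ndim != 2 or A.shape[1] != 3 or A.shape[0] < 3:
        raise ValueError("need >= 3 points of shape (n, 3)")
    ca, cb = A.mean(axis=0), B.mean(axis=0)
    H = (A - ca).T @ (B - cb)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cb - R @ ca
    fitted = A @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - B) ** 2, axis=1))))
    return R, t, rmsd


def superposed_rmsd(coords_a: np.ndarray, coords_b: np.ndarray) -> float:
    return kabsch_superpose(coords_a, coords_b)[2]


def _ca_matrix(structure: Structure, rids: list[ResidueId]) -> np.ndarray:
    by_id = {r.rid: r for r in structure.residues}
    coords, kept = [], []
    for rid in rids:
        ca = by_id[rid].ca
        if ca is not None:
            coords.append(ca.coord)
            kept.append(rid)
    return np.array(coords, dtype=float).reshape(-1, 3), kept  # type: ignore[return-value]


def per_residue_rmsd(
    a: Structure, b: Structure, mapping: ResidueMapping
) -> dict[ResidueId, float]:
    """Per-residue Cα deviation of ``a`` from ``b`` after one global Kabsch
    superposition on all mapped Cα atoms.  Keys are residue identities in
    ``a``; residues missing a Cα in either structure are excluded."""
    ca_a, kept_a = _ca_matrix(a, mapping.a_ids)
    b_for_a = mapping.b_for_a()
    ca_b, kept_b = _ca_matrix(b, [b_for_a[r] for r in kept_a])
    if len(kept_b) != len(kept_a):
        keep = set(kept_b)
        sel = [i for i, r in enumerate(kept_a) if b_for_a[r] in keep]
        ca_a, kept_a = ca_a[sel], [kept_a[i] for i in sel]
    R, t, _ = kabsch_superpose(ca_a, ca_b)
    fitted = ca_a @ R.T + t
    dev = np.linalg.norm(fitted - ca_b, axis=1)
    return {rid: float(d) for rid, d in zip(kept_a, dev)}


# ---------------------------------------------------------------------------
# LDDT
# ---------------------------------------------------------------------------

def lddt(
    model: Structure,
    reference: Structure,
    mapping: ResidueMapping | None = None,
    radius: float = LDDT_RADIUS,
    tolerances: tuple[float, ...] = LDDT_TOLERANCES,
) -> tuple[float, dict[ResidueId, float]]:
    """Cα LDDT of ``model`` against ``reference``.

    A residue pair (i, j), i != j, is scored iff both residues are mapped and
    their reference Cα distance is below ``radius``.  Each scored pair
    contributes the fraction of tolerances its distance deviation
    ``|D_ref - D_model|`` stays within.  The global score averages over all
    scored ordered pairs; the per-residue score for i averages over scored
    pairs involving i.  Keys of the per-residue map are model residue ids.
    """
    if mapping is None:
        mapping = map_residues(model, reference)
    ca_m, kept_m = _ca_matrix(model, mapping.a_ids)
    b_for_a = mapping.b_for_a()
    ca_r, kept_r = _ca_matrix(reference, [b_for_a[r] for r in kept_m])
    if len(kept_r) != len(kept_m):
        keep = set(kept_r)
        sel = [i for i, r in enumerate(kept_m) if b_for_a[r] in keep]
        ca_m, kept_m = ca_m[sel], [kept_m[i] for i in sel]
    n = len(kept_m)
    if n < 2:
        raise ValueError("LDDT undefined: fewer than 2 mapped residues with Cα")
    d_ref = np.linalg.norm(ca_r[:, None, :] - ca_r[None, :, :], axis=-1)
    d_mod = np.linalg.norm(ca_m[:, None, :] - ca_m[None, :, :], axis=-1)
    include = (d_ref < radius) & ~np.eye(n, dtype=bool)
    if not include.any():
        raise ValueError(f"LDDT undefined: no residue pairs within {radius} Å")
    delta = np.abs(d_ref - d_mod)
    tol = np.asarray(tolerances, dtype=float)
    frac = (delta[..., None] < tol).mean(axis=-1)  # score(i, j) in {0, .25, .5, .75, 1}
    global_score = float(frac[include].mean())
    per_residue: dict[ResidueId, float] = {}
    for i, rid in enumerate(kept_m):
        row = include[i]
        if row.any():
            per_residue[rid] = float(frac[i, row].mean())
    return global_score, per_residue


@dataclass
class FlexibilityProfile:
    per_residue_rmsd: dict[ResidueId, float]
    per_residue_lddt: dict[ResidueId, float]
    global_lddt: float


def flexibility_profile(
    model: Structure, reference: Structure, mapping: ResidueMapping | None = None
) -> FlexibilityProfile:
    """Joint per-residue RMSD and LDDT of ``model`` against ``reference``
    on their common mapped residues."""
    if mapping is None:
        mapping = map_residues(model, reference)
    rmsd_map = per_residue_rmsd(model, reference, mapping)
    g, lddt_map = lddt(model, reference, mapping)
    common = set(rmsd_map) & set(lddt_map)
    return FlexibilityProfile(
        per_residue_rmsd={r: rmsd_map[r] for r in common},
        per_residue_lddt={r: lddt_map[r] for r in common},
        global_lddt=g,
    )


# ---------------------------------------------------------------------------
# Mobile residue selection
# ---------------------------------------------------------------------------

@dataclass
class MobileSelection:
    """Contiguous low-confidence segments selected for backbone sampling."""

    segments: list[tuple[ResidueId, ResidueId]] = field(default_factory=list)
    residues: frozenset[ResidueId] = frozenset()

    def __bool__(self) -> bool:
        return bool(self.segments)

    def __len__(self) -> int:
        return len(self.residues)


def select_mobile_residues(
    profile: ConfidenceProfile,
    threshold: float = MOBILE_PLDDT_THRESHOLD,
    min_run: int = 3,
) -> MobileSelection:
    """Maximal runs of consecutive residues with pLDDT strictly below
    ``threshold``; runs shorter than ``min_run`` are discarded.

    Consecutive means same chain and author numbering increasing by one
    (an insertion-code change with equal numbering also counts as adjacent).
    """
    segments: list[list[ResidueId]] = []
    run: list[ResidueId] = []
    prev: ResidueId | None = None
    for rid, val in zip(profile.ids, profile.values):
        low = val < threshold
        adjacent = (
            prev is not None
            and rid[0] == prev[0]
            and (rid[1] - prev[1]) in (0, 1)
        )
        if low and run and adjacent:
            run.append(rid)
        elif low:
            if run:
                segments.append(run)
            run = [rid]
        else:
            if run:
                segments.append(run)
            run = []
        prev = rid
    if run:
        segments.append(run)
    kept = [s for s in segments if len(s) >= min_run]
    return MobileSelection(
        segments=[(s[0], s[-1]) for s in kept],
        residues=frozenset(r for s in kept for r in s),
    )
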