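"""Protein structure and confidence I/O.

Lightweight chain/residue/atom model backed by gemmi for PDB parsing and
writing.  Predicted models carry per-residue confidence (pLDDT, 0-100) in
the B-factor column, following the AlphaFold convention; a ColabFold-style
JSON dialect (``{"plddt": [...]}``) is supported as an alternative source.

Conventions adopted throughout the package:

* hydrogens are ignored everywhere (all distance definitions use heavy atoms);
* glycine has no Cβ, so ``cb`` coordinate selections substitute Cα;
* only the first model of a multi-model file is read;
* for alternate locations the highest-occupancy conformer is kept
  (first on a tie);
* author residue numbering is preserved verbatim; internal indexing is
  0-based positional.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import gemmi
import numpy as np

logger = logging.getLogger("alphared")

BACKBONE_ATOMS = ("N", "CA", "C", "O")

#: residue identity: (chain_id, seq_num, insertion_code)
ResidueId = tuple[str, int, str]


class StructureError(ValueError):
    """Raised for unreadable, empty or inconsistent structure input."""


@dataclass
class Atom:
    """A heavy atom with coordinates in Å and a B-factor.

    For AlphaFold-predicted models the B-factor column carries the
    per-residue pLDDT on the 0-100 scale.
    """

    name: str
    element: str
    coord: np.ndarray
    bfactor: float = 0.0

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if self.coord.shape != (3,) or not np.all(np.isfinite(self.coord)):
            raise StructureError(f"atom {self.name}: coordinates must be a finite 3-vector")
        if self.bfactor < 0:
            raise StructureError(f"atom {self.name}: negative B-factor {self.bfactor}")


@dataclass
class Residue:
    chain_id: str
    seq_num: int
    name: str
    atoms: list[Atom] = field(default_factory=list)
    insertion_code: str = ""

    @property
    def rid(self) -> ResidueId:
        return (self.chain_id, self.seq_num, self.insertion_code)

    def get_atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def ca(self) -> Atom | None:
        return self.get_atom("CA")

    @property
    def cb_or_ca(self) -> Atom | None:
        """Cβ atom, substituting Cα for glycine (or any residue lacking Cβ)."""
        return self.get_atom("CB") or self.get_atom("CA")

    def heavy_coords(self) -> np.ndarray:
        return np.array([a.coord for a in self.atoms], dtype=float).reshape(-1, 3)


@dataclass
class Structure:
    """An ordered collection of residues (file order), one model."""

    residues: list[Residue] = field(default_factory=list)
    model_id: int = 1

    def __len__(self) -> int:
        return len(self.residues)

    def __iter__(self) -> Iterator[Residue]:
        return iter(self.residues)

    @property
    def chains(self) -> list[str]:
        """Chain labels in order of first appearance."""
        seen: dict[str, None] = {}
        for r in self.residues:
            seen.setdefault(r.chain_id, None)
        return list(seen)

    @property
    def residue_ids(self) -> list[ResidueId]:
        return [r.rid for r in self.residues]

    def subset(self, chain_ids: Iterable[str]) -> "Structure":
        wanted = set(chain_ids)
        return Structure(
            residues=[r for r in self.residues if r.chain_id in wanted],
            model_id=self.model_id,
        )

    def heavy_coords(self) -> np.ndarray:
        """All heavy-atom coordinates, (n_atoms, 3), residue order."""
        parts = [r.heavy_coords() for r in self.residues]
        return np.vstack(parts) if parts else np.empty((0, 3))

    def copy(self) -> "Structure":
        return Structure(
            residues=[
                Residue(
                    chain_id=r.chain_id,
                    seq_num=r.seq_num,
                    name=r.name,
                    insertion_code=r.insertion_code,
                    atoms=[Atom(a.name, a.element, a.coord.copy(), a.bfactor) for a in r.atoms],
                )
                for r in self.residues
            ],
            model_id=self.model_id,
        )

    def validate(self) -> None:
        if not self.residues:
            raise StructureError("structure is empty")
        seen: set[ResidueId] = set()
        for r in self.residues:
            if r.rid in seen:
                raise StructureError(f"duplicate residue identity {r.rid}")
            seen.add(r.rid)
            names = [a.name for a in r.atoms]
            if len(names) != len(set(names)):
                raise StructureError(f"duplicate atom names in residue {r.rid}")


@dataclass(frozen=True)
class PartnerSplit:
    """Receptor/ligand chain partition, e.g. parsed from ``"AB_C"``."""

    receptor_chains: frozenset[str]
    ligand_chains: frozenset[str]

    @classmethod
    def from_string(cls, spec: str) -> "PartnerSplit":
        if spec.count("_") != 1:
            raise ValueError(f"partner spec {spec!r}: expected 'RECEPTORCHAINS_LIGANDCHAINS'")
        left, right = spec.split("_")
        rec, lig = frozenset(left), frozenset(right)
        if not rec or not lig:
            raise ValueError(f"partner spec {spec!r}: both sides must name at least one chain")
        overlap = rec & lig
        if overlap:
            raise ValueError(f"partner spec {spec!r}: chains {sorted(overlap)} on both sides")
        return cls(rec, lig)

    def __str__(self) -> str:
        return "".join(sorted(self.receptor_chains)) + "_" + "".join(sorted(self.ligand_chains))


class ConfidenceProfile:
    """Per-residue pLDDT (0-100) keyed by residue identity, ordered."""

    def __init__(self, ids: Sequence[ResidueId], values: Sequence[float]):
        if len(ids) != len(values):
            raise ValueError("ids and values length mismatch")
        vals = np.asarray(values, dtype=float)
        if vals.size and (vals.min() < 0 or vals.max() > 100):
            raise ValueError(
                f"pLDDT values outside [0, 100]: range [{vals.min()}, {vals.max()}]"
            )
        self.ids: list[ResidueId] = list(ids)
        self.values: np.ndarray = vals
        self._by_id = dict(zip(self.ids, vals))
        if len(self._by_id) != len(self.ids):
            raise ValueError("duplicate residue identities in confidence profile")

    def __len__(self) -> int:
        return len(self.ids)

    def __getitem__(self, rid: ResidueId) -> float:
        return self._by_id[rid]

    def __contains__(self, rid: ResidueId) -> bool:
        return rid in self._by_id

    def subset(self, ids: Iterable[ResidueId]) -> np.ndarray:
        return np.array([self._by_id[i] for i in ids], dtype=float)


# ---------------------------------------------------------------------------
# PDB reading / writing (gemmi-backed)
# ---------------------------------------------------------------------------

def _from_gemmi(gst: gemmi.Structure) -> Structure:
    if len(gst) == 0:
        raise StructureError("no models in file")
    model = gst[0]  # first model only
    out = Structure(model_id=1)
    for chain in model:
        for gres in chain:
            if gres.het_flag == "H" or gres.name == "HOH":
                continue  # HETATM and waters skipped
            res = Residue(
                chain_id=chain.name,
                seq_num=gres.seqid.num,
                name=gres.name,
                insertion_code=(gres.seqid.icode or "").strip(),
            )
            best: dict[str, gemmi.Atom] = {}
            for ga in gres:
                if ga.element.is_hydrogen:
                    continue
                prev = best.get(ga.name)
                # keep highest-occupancy altloc, first on tie
                if prev is None or ga.occ > prev.occ:
                    best[ga.name] = ga
            for ga in best.values():
                res.atoms.append(
                    Atom(
                        name=ga.name,
                        element=ga.element.name,
                        coord=np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                        bfactor=max(ga.b_iso, 0.0),
                    )
                )
            if res.atoms:
                out.residues.append(res)
    if not out.residues:
        raise StructureError("zero ATOM records: empty structure")
    out.validate()
    return out


def read_structure(path: str | Path, format: str = "pdb") -> Structure:
    """Read a PDB file into a :class:`Structure`.

    Only the first model is used; HETATM records and waters are skipped;
    hydrogens are dropped.
    """
    if format != "pdb":
        raise ValueError(f"unsupported format {format!r} (only 'pdb')")
    path = Path(path)
    if not path.exists():
        raise StructureError(f"file not found: {path}")
    try:
        gst = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:
        raise StructureError(f"cannot parse PDB {path}: {exc}") from exc
    return _from_gemmi(gst)


def write_structure(structure: Structure, path: str | Path) -> None:
    """Write a structure as a single-model PDB file (ATOM records only)."""
    gst = gemmi.Structure()
    gst.name = "alphared"
    model = gemmi.Model(1)
    chain_map: dict[str, gemmi.Chain] = {}
    serial = 0
    for res in structure.residues:
        chain = chain_map.get(res.chain_id)
        if chain is None:
            chain = gemmi.Chain(res.chain_id)
            chain_map[res.chain_id] = chain
        gres = gemmi.Residue()
        gres.name = res.name
        gres.seqid = gemmi.SeqId(res.seq_num, res.insertion_code or " ")
        for atom in res.atoms:
            serial += 1
            ga = gemmi.Atom()
            ga.name = atom.name
            ga.element = gemmi.Element(atom.element)
            ga.pos = gemmi.Position(*atom.coord)
            ga.b_iso = atom.bfactor
            ga.occ = 1.0
            ga.serial = serial
            gres.add_atom(ga)
        chain.add_residue(gres)
    for chain in chain_map.values():
        model.add_chain(chain)
    gst.add_model(model)
    gst.setup_entities()
    gst.write_pdb(str(path))


# ---------------------------------------------------------------------------
# Confidence sources
# ---------------------------------------------------------------------------

def read_confidence_json(path: str | Path, structure: Structure) -> ConfidenceProfile:
    """Read a ColabFold-style ``{"plddt": [...]}`` JSON confidence file.

    Values are mapped to residues in file order and must match the structure
    length.  Inputs on a 0-1 scale (max <= 1.0) are rescaled to 0-100 with a
    warning; values outside [0, 100] are an error, not clamped.
    """
    with open(path) as fh:
        data = json.load(fh)
    if not isinstance(data, dict) or "plddt" not in data:
        raise ValueError(f"{path}: expected a JSON object with a 'plddt' array")
    values = np.asarray(data["plddt"], dtype=float)
    if values.ndim != 1:
        raise ValueError(f"{path}: 'plddt' must be a flat array")
    if len(values) != len(structure):
        raise ValueError(
            f"{path}: {len(values)} pLDDT values for {len(structure)} residues"
        )
    if values.size and values.max() <= 1.0:
        warnings.warn(
            f"{path}: pLDDT values look 0-1 scaled (max {values.max():.3f}); rescaling x100",
            stacklevel=2,
        )
        values = values * 100.0
    if values.min() < 0 or values.max() > 100:
        raise ValueError(f"{path}: pLDDT values outside [0, 100]")
    return ConfidenceProfile(structure.residue_ids, values)


def confidence_from_bfactor(structure: Structure) -> ConfidenceProfile:
    """Per-residue pLDDT from the B-factor column (AlphaFold convention).

    The per-residue value is the Cα B-factor; residues lacking a Cα fall back
    to the mean over their atoms.
    """
    structure.validate()
    values = []
    for res in structure.residues:
        ca = res.ca
        if ca is not None:
            values.append(ca.bfactor)
        else:
            values.append(float(np.mean([a.bfactor for a in res.atoms])))
    arr = np.asarray(values)
    if arr.size and arr.max() == 0.0:
        warnings.warn(
            "all B-factors are zero: treating as uniformly low confidence", stacklevel=2
        )
    return ConfidenceProfile(structure.residue_ids, arr)


# ---------------------------------------------------------------------------
# Partner splitting and coordinate views
# ---------------------------------------------------------------------------

def split_partners(
    structure: Structure, spec: str | PartnerSplit
) -> tuple[Structure, Structure]:
    """Split a complex into (receptor, ligand) per a ``"AB_C"`` partner spec."""
    if isinstance(spec, str):
        spec = PartnerSplit.from_string(spec)
    present = set(structure.chains)
    missing = (spec.receptor_chains | spec.ligand_chains) - present
    if missing:
        raise ValueError(
            f"partner spec names chains {sorted(missing)} absent from structure "
            f"(present: {sorted(present)})"
        )
    return structure.subset(spec.receptor_chains), structure.subset(spec.ligand_chains)


_SELECTIONS = ("ca", "cb", "backbone", "heavy")


def get_coords(
    structure: Structure, selection: str = "ca"
) -> tuple[np.ndarray, list[ResidueId]]:
    """Ordered coordinate view plus the residue identity of each row.

    ``cb`` substitutes Cα for glycine; ``backbone`` is N, Cα, C, O; residues
    missing every selected atom are skipped (absent from the index map).
    """
    if selection not in _SELECTIONS:
        raise ValueError(f"selection must be one of {_SELECTIONS}, got {selection!r}")
    coords: list[np.ndarray] = []
    index: list[ResidueId] = []
    for res in structure.residues:
        if selection == "ca":
            atoms = [res.ca] if res.ca else []
        elif selection == "cb":
            a = res.cb_or_ca
            atoms = [a] if a else []
        elif selection == "backbone":
            atoms = [a for n in BACKBONE_ATOMS if (a := res.get_atom(n)) is not None]
        else:  # heavy
            atoms = list(res.atoms)
        if not atoms:
            logger.debug("residue %s has no %s atoms; skipped", res.rid, selection)
            continue
        for a in atoms:
            coords.append(a.coord)
            index.append(res.rid)
    arr = np.array(coords, dtype=float).reshape(-1, 3)
    return arr, index
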