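"""Docking model quality against a reference complex.

Implements the standard CAPRI-style quality metrics:

* ``fnat`` — fraction of the reference's cross-partner residue contacts
  (any heavy-atom pair within 5 Å) reproduced by the model;
* ``Irms`` — backbone RMSD over reference-defined interface residues
  (any heavy atom within 10 Å of the partner) after superposing the model
  on those residues;
* ``Lrms`` — backbone RMSD of the ligand partner after superposing on the
  receptor backbone only;
* ``DockQ = [fnat + 1/(1+(Irms/1.5)^2) + 1/(1+(Lrms/8.5)^2)] / 3``;
* CAPRI class from DockQ: incorrect (<= 0.23), acceptable (<= 0.49),
  medium (<= 0.8), high (>= 0.8).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .flexibility import ResidueMapping, kabsch_superpose, map_residues
from .structure_io import (
    BACKBONE_ATOMS,
    PartnerSplit,
    ResidueId,
    Structure,
    get_coords,
    split_partners,
)

NATIVE_CONTACT_CUTOFF = 5.0  # Å heavy-atom, fnat definition
INTERFACE_DEFINITION_CUTOFF = 10.0  # Å heavy-atom, Irms interface definition
DOCKQ_D1 = 1.5  # Å, Irms scaling
DOCKQ_D2 = 8.5  # Å, Lrms scaling
ACCEPTABLE_DOCKQ = 0.23

CAPRI_CLASSES = ("incorrect", "acceptable", "medium", "high")


@dataclass
class QualityMetrics:
    fnat: float
    irms: float
    lrms: float
    dockq: float
    capri_class: str

    @property
    def success(self) -> bool:
        """CAPRI acceptable or better (DockQ > 0.23)."""
        return self.dockq > ACCEPTABLE_DOCKQ

    def to_dict(self) -> dict:
        return {
            "fnat": self.fnat,
            "irms": self.irms,
            "lrms": self.lrms,
            "dockq": self.dockq,
            "capri_class": self.capri_class,
            "success": self.success,
        }


def _cross_pairs(
    receptor: Structure, ligand: Structure, cutoff: float
) -> set[tuple[ResidueId, ResidueId]]:
    rc, rid = get_coords(receptor, "heavy")
    lc, lid = get_coords(ligand, "heavy")
    if len(rc) == 0 or len(lc) == 0:
        return set()
    tree = cKDTree(lc)
    out: set[tuple[ResidueId, ResidueId]] = set()
    for i, hits in enumerate(tree.query_ball_point(rc, r=cutoff)):
        for j in hits:
            out.add((rid[i], lid[j]))
    return out


def native_contacts(
    receptor: Structure, ligand: Structure, cutoff: float = NATIVE_CONTACT_CUTOFF
) -> set[tuple[ResidueId, ResidueId]]:
    """Cross-partner residue pairs with any heavy-atom distance <= cutoff."""
    return _cross_pairs(receptor, ligand, cutoff)


def fnat(
    model_receptor: Structure,
    model_ligand: Structure,
    ref_receptor: Structure,
    ref_ligand: Structure,
    mapping: ResidueMapping,
    cutoff: float = NATIVE_CONTACT_CUTOFF,
) -> float:
    """Fraction of reference contacts present in the model.

    ``mapping`` maps model residues onto reference residues for the whole
    complex; model contacts are translated into reference identities before
    intersecting.
    """
    ref_set = native_contacts(ref_receptor, ref_ligand, cutoff)
    if not ref_set:
        raise ValueError("reference complex has zero native contacts")
    model_set = native_contacts(model_receptor, model_ligand, cutoff)
    m2r = mapping.b_for_a()
    translated = {
        (m2r[a], m2r[b]) for a, b in model_set if a in m2r and b in m2r
    }
    return len(translated & ref_set) / len(ref_set)


def _backbone_pairs(
    model: Structure, reference: Structure, mapping: ResidueMapping,
    restrict_model: set[ResidueId] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Paired backbone coordinate matrices (model, reference) over mapped
    residues, restricted to ``restrict_model`` model residues if given.
    Only atoms present in both partners of a residue pair are used."""
    ref_by_id = {r.rid: r for r in reference.residues}
    mc, rc = [], []
    m2r = mapping.b_for_a()
    for res in model.residues:
        if restrict_model is not None and res.rid not in restrict_model:
            continue
        ref_rid = m2r.get(res.rid)
        if ref_rid is None or ref_rid not in ref_by_id:
            continue
        ref_res = ref_by_id[ref_rid]
        for name in BACKBONE_ATOMS:
            am, ar = res.get_atom(name), ref_res.get_atom(name)
            if am is not None and ar is not None:
                mc.append(am.coord)
                rc.append(ar.coord)
    return (
        np.array(mc, dtype=float).reshape(-1, 3),
        np.array(rc, dtype=float).reshape(-1, 3),
    )


def interface_rmsd(
    model: Structure,
    reference: Structure,
    partners: PartnerSplit,
    mapping: ResidueMapping,
    cutoff: float = INTERFACE_DEFINITION_CUTOFF,
) -> float:
    """Backbone RMSD over reference-defined interface residues.

    Interface residues are reference residues (either partner) with any
    heavy atom within ``cutoff`` of the other partner; the model is
    superposed on the reference using the backbone atoms of those residues
    jointly across both partners.
    """
    ref_rec, ref_lig = split_partners(reference, partners)
    iface_pairs = _cross_pairs(ref_rec, ref_lig, cutoff)
    iface_ref: set[ResidueId] = set()
    for a, b in iface_pairs:
        iface_ref.add(a)
        iface_ref.add(b)
    if len(iface_ref) < 3:
        raise ValueError(f"interface too small: {len(iface_ref)} residues")
    m2r = mapping.b_for_a()
    restrict = {m for m, r in m2r.items() if r in iface_ref}
    mc, rc = _backbone_pairs(model, reference, mapping, restrict_model=restrict)
    if len(mc) < 3:
        raise ValueError("too few mapped interface backbone atoms")
    return kabsch_superpose(mc, rc)[2]


def ligand_rmsd(
    model: Structure,
    reference: Structure,
    partners: PartnerSplit,
    mapping: ResidueMapping,
) -> float:
    """Backbone RMSD of the ligand partner after superposing the model on the
    reference receptor backbone only."""
    model_rec, model_lig = split_partners(model, partners)
    ref_rec, ref_lig = split_partners(reference, partners)
    rec_m, rec_r = _backbone_pairs(model_rec, ref_rec, mapping)
    lig_m, lig_r = _backbone_pairs(model_lig, ref_lig, mapping)
    if len(rec_m) < 3 or len(lig_m) == 0:
        raise ValueError("insufficient mapped backbone atoms for ligand RMSD")
    R, t, _ = kabsch_superpose(rec_m, rec_r)
    lig_fit = lig_m @ R.T + t
    return float(np.sqrt(np.mean(np.sum((lig_fit - lig_r) ** 2, axis=1))))


def dockq(fnat_v: float, irms_v: float, lrms_v: float) -> float:
    """DockQ composite score in [0, 1]."""
    return (
        fnat_v
        + 1.0 / (1.0 + (irms_v / DOCKQ_D1) ** 2)
        + 1.0 / (1.0 + (lrms_v / DOCKQ_D2) ** 2)
    ) / 3.0


def capri_class(dockq_v: float) -> str:
    """CAPRI quality bin: incorrect (<= 0.23), acceptable (0.23, 0.49],
    medium (0.49, 0.8), high (>= 0.8)."""
    if dockq_v >= 0.8:
        return "high"
    if dockq_v > 0.49:
        return "medium"
    if dockq_v > 0.23:
        return "acceptable"
    return "incorrect"


def evaluate(
    model: Structure,
    reference: Structure,
    partners: PartnerSplit | str,
    mapping: ResidueMapping | None = None,
) -> QualityMetrics:
    """Full docking-quality evaluation of ``model`` vs ``reference``."""
    if isinstance(partners, str):
        partners = PartnerSplit.from_string(partners)
    if mapping is None:
        mapping = map_residues(model, reference)
    model_rec, model_lig = split_partners(model, partners)
    ref_rec, ref_lig = split_partners(reference, partners)
    fnat_v = fnat(model_rec, model_lig, ref_rec, ref_lig, mapping)
    irms_v = interface_rmsd(model, reference, partners, mapping)
    lrms_v = ligand_rmsd(model, reference, partners, mapping)
    q = dockq(fnat_v, irms_v, lrms_v)
    return QualityMetrics(
        fnat=fnat_v, irms=irms_v, lrms=lrms_v, dockq=q, capri_class=capri_class(q)
    )
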