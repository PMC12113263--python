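"""AlphaFold-derived docking-confidence metrics.

For a predicted complex the interface is the set of residues (on either
partner) with any heavy atom within 8 Å of the other partner.  Interface
contacts are cross-partner residue pairs whose Cβ atoms (Cα for glycine)
are within 5 Å.  The interface-pLDDT — the mean per-residue pLDDT over
interface residues — discriminates correctly-docked from mis-docked
predictions: at a threshold of 85 a model is confident enough to go
straight to local refinement (LOCAL), below it a global rigid-body search
is required (GLOBAL).

Neighbour searches use a k-d tree; equivalence with brute-force all-pairs
enumeration is part of the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy.spatial import cKDTree

from .structure_io import ConfidenceProfile, ResidueId, Structure, get_coords

INTERFACE_CUTOFF = 8.0  # Å, heavy-atom interface residue definition
CONTACT_CUTOFF = 5.0  # Å, Cβ-Cβ contact definition
GATE_THRESHOLD = 85.0  # interface-pLDDT gate

#: sentinel interface-pLDDT when the predicted interface is empty
NO_INTERFACE_SENTINEL = -1.0


class Gate(str, Enum):
    """Docking-protocol branch selected from the interface-pLDDT."""

    GLOBAL = "GLOBAL"
    LOCAL = "LOCAL"


@dataclass
class InterfaceReport:
    interface_residues: frozenset[ResidueId]
    n_interface_residues: int
    n_interface_contacts: int
    interface_plddt: float
    avg_plddt: float
    gate: Gate

    def to_dict(self) -> dict:
        return {
            "n_interface_residues": self.n_interface_residues,
            "n_interface_contacts": self.n_interface_contacts,
            "interface_plddt": self.interface_plddt,
            "avg_plddt": self.avg_plddt,
            "gate": self.gate.value,
            "interface_residues": sorted(
                [list(r) for r in self.interface_residues]
            ),
        }


def find_interface_residues(
    receptor: Structure, ligand: Structure, cutoff: float = INTERFACE_CUTOFF
) -> frozenset[ResidueId]:
    """Residues on either partner with any heavy atom within ``cutoff`` of the
    other partner (symmetric in partner order)."""
    rc, rid = get_coords(receptor, "heavy")
    lc, lid = get_coords(ligand, "heavy")
    if len(rc) == 0 or len(lc) == 0:
        return frozenset()
    tree = cKDTree(lc)
    pairs = tree.query_ball_point(rc, r=cutoff)
    out: set[ResidueId] = set()
    for i, hits in enumerate(pairs):
        if hits:
            out.add(rid[i])
            for j in hits:
                out.add(lid[j])
    return frozenset(out)


def count_interface_contacts(
    receptor: Structure, ligand: Structure, cutoff: float = CONTACT_CUTOFF
) -> int:
    """Number of cross-partner residue pairs with Cβ-Cβ distance <= cutoff."""
    rc, _ = get_coords(receptor, "cb")
    lc, _ = get_coords(ligand, "cb")
    if len(rc) == 0 or len(lc) == 0:
        return 0
    tree = cKDTree(lc)
    return int(sum(len(h) for h in tree.query_ball_point(rc, r=cutoff)))


def interface_plddt(
    profile: ConfidenceProfile, interface: frozenset[ResidueId] | set[ResidueId]
) -> float:
    """Mean pLDDT over interface residues.

    An empty interface returns the sentinel -1.0: no predicted interface is
    the strongest possible evidence of docking failure, so the caller's gate
    is forced to GLOBAL.
    """
    if not interface:
        return NO_INTERFACE_SENTINEL
    missing = [r for r in interface if r not in profile]
    if missing:
        raise KeyError(f"interface residues missing from confidence profile: {missing[:3]}")
    return float(np.mean(profile.subset(sorted(interface))))


def average_plddt(profile: ConfidenceProfile) -> float:
    """Mean pLDDT over every residue of the complex."""
    if len(profile) == 0:
        raise ValueError("empty confidence profile")
    return float(np.mean(profile.values))


def gate_decision(interface_plddt_value: float, threshold: float = GATE_THRESHOLD) -> Gate:
    """LOCAL iff interface-pLDDT >= threshold (default 85); the empty-interface
    sentinel (negative) always yields GLOBAL."""
    return Gate.LOCAL if interface_plddt_value >= threshold else Gate.GLOBAL


def interface_report(
    receptor: Structure,
    ligand: Structure,
    profile: ConfidenceProfile,
    interface_cutoff: float = INTERFACE_CUTOFF,
    contact_cutoff: float = CONTACT_CUTOFF,
    gate_threshold: float = GATE_THRESHOLD,
) -> InterfaceReport:
    """Full confidence report for one predicted complex."""
    iface = find_interface_residues(receptor, ligand, interface_cutoff)
    ipl = interface_plddt(profile, iface)
    return InterfaceReport(
        interface_residues=iface,
        n_interface_residues=len(iface),
        n_interface_contacts=count_interface_contacts(receptor, ligand, contact_cutoff),
        interface_plddt=ipl,
        avg_plddt=average_plddt(profile),
        gate=gate_decision(ipl, gate_threshold),
    )


# ---------------------------------------------------------------------------
# Dataset-level discrimination analysis
# ---------------------------------------------------------------------------

def roc_curve(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """ROC by full threshold sweep (ties collapse to a single threshold).

    Returns (fpr, tpr, thresholds) with thresholds descending, including the
    (0,0) and (1,1) endpoints.  Higher score is treated as predicting the
    positive label.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC undefined: both classes must be present")
    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], labels[order]
    # cumulative counts at each distinct threshold
    distinct = np.r_[np.nonzero(np.diff(s))[0], len(s) - 1]
    tp = np.cumsum(y)[distinct]
    fp = np.cumsum(~y)[distinct]
    tpr = np.r_[0.0, tp / n_pos]
    fpr = np.r_[0.0, fp / n_neg]
    thresholds = np.r_[np.inf, s[distinct]]
    return fpr, tpr, thresholds


def auc(fpr: np.ndarray, tpr: np.ndarray) -> float:
    """Area under a ROC curve by the trapezoid rule."""
    return float(np.trapezoid(tpr, fpr))


@dataclass
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def accuracy(self) -> float:
        n = self.tp + self.fp + self.tn + self.fn
        return (self.tp + self.tn) / n if n else float("nan")

    @property
    def precision(self) -> float:
        d = self.tp + self.fp
        return self.tp / d if d else float("nan")

    @property
    def recall(self) -> float:
        d = self.tp + self.fn
        return self.tp / d if d else float("nan")


def confusion_at_threshold(
    scores: np.ndarray, labels: np.ndarray, threshold: float
) -> ConfusionMatrix:
    """Confusion matrix predicting positive where score >= threshold."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    pred = scores >= threshold
    return ConfusionMatrix(
        tp=int(np.sum(pred & labels)),
        fp=int(np.sum(pred & ~labels)),
        tn=int(np.sum(~pred & ~labels)),
        fn=int(np.sum(~pred & labels)),
    )


def discrimination_analysis(
    records: list[tuple[dict[str, float], bool]],
    gate_metric: str = "interface_plddt",
    gate_threshold: float = GATE_THRESHOLD,
) -> dict:
    """ROC/AUC per metric plus a confusion matrix for the gate metric.

    ``records`` holds per-target metric dicts with a near-native truth flag
    (interface RMSD <= 4 Å against the bound reference).
    """
    if len(records) < 2:
        raise ValueError("need at least 2 records")
    labels = np.array([flag for _, flag in records], dtype=bool)
    metric_names = sorted(records[0][0])
    out: dict = {"metrics": {}, "n": len(records)}
    for name in metric_names:
        scores = np.array([m[name] for m, _ in records], dtype=float)
        fpr, tpr, thr = roc_curve(scores, labels)
        out["metrics"][name] = {
            "fpr": fpr,
            "tpr": tpr,
            "thresholds": thr,
            "auc": auc(fpr, tpr),
        }
    gate_scores = np.array([m[gate_metric] for m, _ in records], dtype=float)
    out["confusion"] = confusion_at_threshold(gate_scores, labels, gate_threshold)
    return out
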