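"""Confidence-gated docking pipeline.

The full flow: compute the interface-pLDDT of the input predicted complex;
if it is below the gate threshold (85) the predicted orientation is
distrusted, so run a global rigid-body replica-exchange search from
randomized orientations, cluster the decoys to at most five representatives,
and refine each with flexible local docking; if at or above the threshold,
refine the input pose directly with local docking.  Backbone moves in the
local stage are directed at mobile residues (pLDDT < 80).  Final models are
the best-ranked decoys by interface score.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import warnings
from dataclasses import dataclass, field, asdict

import yaml

from .confidence import Gate, InterfaceReport, interface_report
from .docking import (
    Decoy,
    DockingResult,
    GLOBAL_SCHEDULE,
    LOCAL_SCHEDULE,
    MoveSchedule,
    Pose,
    ReplicaLadder,
    ScoreModel,
    cluster_decoys,
    default_score,
    run_replica_exchange,
)
from .flexibility import MobileSelection, select_mobile_residues
from .structure_io import (
    ConfidenceProfile,
    PartnerSplit,
    Structure,
    split_partners,
)

logger = logging.getLogger("alphared")


@dataclass
class PipelineConfig:
    """All tunables of the docking pipeline, with the published defaults."""

    gate_threshold: float = 85.0
    mobile_threshold: float = 80.0
    mobile_min_run: int = 3
    ladder: ReplicaLadder = field(default_factory=ReplicaLadder)
    global_schedule: MoveSchedule = GLOBAL_SCHEDULE
    local_schedule: MoveSchedule = LOCAL_SCHEDULE
    global_steps: int = 5000
    local_steps: int = 2000
    local_trajectories_per_start: int = 2
    swap_every: int = 50
    snapshot_every: int = 10
    cluster_keep_fraction: float = 0.2
    cluster_rmsd_threshold: float = 5.0
    n_clusters: int = 5
    n_final_models: int = 5

    def __post_init__(self) -> None:
        if not (0 <= self.gate_threshold <= 100 and 0 <= self.mobile_threshold <= 100):
            raise ValueError("pLDDT thresholds must lie in [0, 100]")

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = dict(raw)
        if "ladder" in kwargs:
            lad = kwargs["ladder"]
            kwargs["ladder"] = ReplicaLadder(
                kT_values=tuple(lad.get("kT_values", (1.5, 3.0, 5.0))),
                n_trajectories=int(lad.get("n_trajectories", 8)),
            )
        for key in ("global_schedule", "local_schedule"):
            if key in kwargs:
                kwargs[key] = MoveSchedule(**kwargs[key])
        return cls(**kwargs)

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class PipelineReport:
    """Everything a run produced, with full provenance."""

    gate: Gate
    interface: InterfaceReport
    stages: list[str]
    mobile: MobileSelection
    decoy_counts: dict[str, int]
    cluster_representatives: list[Decoy]
    final_models: list[Decoy]
    seed: int
    config_digest: str
    stage_seconds: dict[str, float]
    acceptance: dict[str, list[float]]

    def summary(self) -> dict:
        return {
            "gate": self.gate.value,
            "interface_plddt": self.interface.interface_plddt,
            "avg_plddt": self.interface.avg_plddt,
            "stages": self.stages,
            "n_mobile_residues": len(self.mobile),
            "decoy_counts": self.decoy_counts,
            "n_final_models": len(self.final_models),
            "final_interface_scores": [d.interface_score for d in self.final_models],
            "seed": self.seed,
            "config_digest": self.config_digest,
            "stage_seconds": self.stage_seconds,
            "acceptance": self.acceptance,
        }


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def rank_models(decoys: list[Decoy], n: int) -> list[Decoy]:
    """Best ``n`` decoys by ascending interface score; ties broken by total
    energy, then original (provenance) order."""
    if not decoys:
        raise ValueError("no decoys to rank")
    order = sorted(
        range(len(decoys)),
        key=lambda i: (decoys[i].interface_score, decoys[i].energy, i),
    )
    return [decoys[i] for i in order[:n]]


def run_alphared(
    model: Structure,
    confidence: ConfidenceProfile,
    partners: PartnerSplit | str,
    config: PipelineConfig | None = None,
    score: ScoreModel = default_score,
    seed: int = 0,
) -> PipelineReport:
    """Run the confidence-gated docking pipeline on a predicted complex.

    ``model`` is the predicted complex with partner chains per ``partners``;
    ``confidence`` its per-residue pLDDT.  Deterministic for a fixed seed and
    config (identical decoy coordinates on rerun).
    """
    if config is None:
        config = PipelineConfig()
    if isinstance(partners, str):
        partners = PartnerSplit.from_string(partners)
    stages: list[str] = []
    timings: dict[str, float] = {}
    decoy_counts: dict[str, int] = {}
    acceptance: dict[str, list[float]] = {}

    def timed(stage: str):
        stages.append(stage)
        timings[stage] = time.perf_counter()
        logger.info("stage %s started", stage)

    def done(stage: str):
        timings[stage] = time.perf_counter() - timings[stage]
        logger.info("stage %s finished in %.2fs", stage, timings[stage])

    # --- gate ---------------------------------------------------------------
    timed("gate")
    try:
        receptor, ligand = split_partners(model, partners)
        report = interface_report(
            receptor, ligand, confidence, gate_threshold=config.gate_threshold
        )
        mobile = select_mobile_residues(
            confidence, config.mobile_threshold, config.mobile_min_run
        )
    except Exception as exc:  # noqa: BLE001 - stage name must propagate
        raise StageError("gate", exc) from exc
    done("gate")
    start = Pose.from_structures(receptor, ligand)

    local_starts: list[tuple[Pose, str]]
    cluster_reps: list[Decoy] = []
    if report.gate is Gate.GLOBAL:
        # --- global rigid-body search ----------------------------------------
        timed("global")
        try:
            global_result = run_replica_exchange(
                start,
                ladder=config.ladder,
                schedule=config.global_schedule,
                score=score,
                n_steps=config.global_steps,
                swap_every=config.swap_every,
                snapshot_every=config.snapshot_every,
                mode="global",
                seed=_stage_seed(seed, 1),
                randomize_start=True,
            )
        except Exception as exc:  # noqa: BLE001
            raise StageError("global", exc) from exc
        decoy_counts["global"] = len(global_result.decoys)
        acceptance["global"] = global_result.acceptance_rates
        done("global")

        # --- clustering -------------------------------------------------------
        timed("cluster")
        try:
            cluster_reps = cluster_decoys(
                global_result.decoys,
                energy_keep_fraction=config.cluster_keep_fraction,
                rmsd_threshold=config.cluster_rmsd_threshold,
                n_clusters=config.n_clusters,
            )
        except Exception as exc:  # noqa: BLE001
            raise StageError("cluster", exc) from exc
        decoy_counts["cluster"] = len(cluster_reps)
        done("cluster")
        local_starts = [
            (rep.pose, f"local[{i}]") for i, rep in enumerate(cluster_reps)
        ]
        local_trajectories = config.local_trajectories_per_start
    else:
        local_starts = [(start, "local")]
        local_trajectories = config.ladder.n_trajectories

    # --- flexible local refinement -------------------------------------------
    if not mobile:
        warnings.warn(
            "no mobile residues below the pLDDT threshold: "
            "local stage downgraded to rigid-body refinement",
            stacklevel=2,
        )
    timed("local")
    local_decoys: list[Decoy] = []
    local_rates: list[float] = []
    try:
        local_ladder = ReplicaLadder(
            kT_values=config.ladder.kT_values, n_trajectories=local_trajectories
        )
        for i, (pose0, _tag) in enumerate(local_starts):
            result = run_replica_exchange(
                pose0,
                ladder=local_ladder,
                schedule=config.local_schedule,
                score=score,
                n_steps=config.local_steps,
                swap_every=config.swap_every,
                snapshot_every=config.snapshot_every,
                mobile=mobile,
                mode="local",
                seed=_stage_seed(seed, 2 + i),
            )
            local_decoys.extend(result.decoys)
            local_rates = result.acceptance_rates
    except Exception as exc:  # noqa: BLE001
        raise StageError("local", exc) from exc
    decoy_counts["local"] = len(local_decoys)
    acceptance["local"] = local_rates
    done("local")

    # --- ranking ---------------------------------------------------------------
    timed("rank")
    final = rank_models(local_decoys, config.n_final_models)
    done("rank")

    return PipelineReport(
        gate=report.gate,
        interface=report,
        stages=stages,
        mobile=mobile,
        decoy_counts=decoy_counts,
        cluster_representatives=cluster_reps,
        final_models=final,
        seed=seed,
        config_digest=config.digest(),
        stage_seconds=timings,
        acceptance=acceptance,
    )


def _stage_seed(master: int, stage_index: int) -> int:
    """Independent per-stage seeds derived from the master seed, < 2**31."""
    h = hashlib.sha256(f"{master}:{stage_index}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)
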