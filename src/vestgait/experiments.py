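"""Experiment drivers: sensor sweep, transfer comparison, ablations.

These reproduce the study designs end-to-end on a cohort: one independent
LOOCV per sensor placement; pretraining on a source dataset followed by
frozen-convolution fine-tuning per placement with exact deltas against a
baseline report; and subject- or sample-subsampling ablations repeated over
iterations, where iteration i draws with the derived seed master_seed + i and
reports the mean and sample standard deviation of overall accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ContractError
from .evaluation import EvaluationReport, aggregate_sensor_table, run_loocv
from .io import PLACEMENTS, Cohort
from .model import ModelSpec
from .segmentation import CycleDataset, SegmentationParams, build_cycle_dataset
from .training import Checkpoint, FinetuneConfig, TrainConfig, pretrain


@dataclass
class AblationConfig:
    """Subject- or sample-subsampling ablation settings."""

    mode: str = "subjects"
    fractions: tuple[float, ...] = (0.25, 0.5, 0.75)
    iterations: int = 15
    placement: str = "wrist"
    seed: int = 0

    def validate(self) -> None:
        if self.mode not in ("subjects", "samples"):
            raise ContractError("ablation mode must be 'subjects' or 'samples'")
        if any(not 0 < f <= 1 for f in self.fractions):
            raise ContractError("fractions must lie in (0, 1]")
        if self.iterations < 1:
            raise ContractError("iterations must be >= 1")
        if self.placement not in PLACEMENTS:
            raise ContractError(f"unknown placement {self.placement!r}")


def sensor_sweep(
    cohort: Cohort,
    task: str,
    spec: ModelSpec | None = None,
    config: TrainConfig | None = None,
    seg_params: SegmentationParams | None = None,
    placements: tuple[str, ...] = PLACEMENTS,
) -> tuple[dict[str, EvaluationReport], pd.DataFrame]:
    """One independent LOOCV per placement with identical spec and config."""
    reports: dict[str, EvaluationReport] = {}
    for placement in placements:
        dataset = build_cycle_dataset(cohort, task, placement, seg_params)
        reports[placement] = run_loocv(dataset, spec, config)
    return reports, aggregate_sensor_table(reports, placements)


@dataclass
class TransferResult:
    """Fine-tuned per-sensor accuracies, deltas vs. baseline, source metric."""

    source_validation_accuracy: float
    finetuned: dict[str, EvaluationReport]
    baseline: dict[str, EvaluationReport]
    checkpoint: Checkpoint = field(repr=False, default=None)

    def delta_table(self) -> pd.DataFrame:
        """Per-sensor control/patient accuracies with exact baseline deltas."""
        rows = {}
        for placement, report in self.finetuned.items():
            base = self.baseline[placement]
            rows[placement] = {
                "control": report.control_mean,
                "control_delta": report.control_mean - base.control_mean,
                "patient": report.patient_mean,
                "patient_delta": report.patient_mean - base.patient_mean,
            }
        table = pd.DataFrame.from_dict(rows, orient="index")
        table.loc["Mean"] = table.mean(axis=0)
        return table


def transfer_experiment(
    cohort: Cohort,
    source_X: np.ndarray,
    source_y: np.ndarray,
    baseline_reports: dict[str, EvaluationReport],
    task: str = "level_walk_short",
    spec: ModelSpec | None = None,
    pretrain_config: TrainConfig | None = None,
    finetune_config: FinetuneConfig | None = None,
    source_subject_ids: np.ndarray | None = None,
    pretrain_folds: int = 5,
    seg_params: SegmentationParams | None = None,
    placements: tuple[str, ...] | None = None,
) -> TransferResult:
    """Pretrain once on the source, then fine-tune per placement under LOOCV.

    The source must already be formatted as (n, 6, 512) matrices (activity
    windows resampled to 512 points with cubic interpolation upstream).
    Deltas are exact cell-wise differences against the provided baseline.
    """
    spec = spec or ModelSpec()
    pretrain_config = pretrain_config or TrainConfig()
    finetune_config = finetune_config or FinetuneConfig()
    placements = placements or tuple(baseline_reports)
    checkpoint, source_acc = pretrain(
        spec, source_X, source_y, pretrain_config,
        n_folds=pretrain_folds, subject_ids=source_subject_ids,
    )
    finetuned: dict[str, EvaluationReport] = {}
    for placement in placements:
        dataset = build_cycle_dataset(cohort, task, placement, seg_params)
        finetuned[placement] = run_loocv(
            dataset, spec, finetune_checkpoint=checkpoint,
            finetune_config=finetune_config,
        )
    return TransferResult(
        source_validation_accuracy=source_acc,
        finetuned=finetuned,
        baseline=baseline_reports,
        checkpoint=checkpoint,
    )


# ---------------------------------------------------------------------------
# ablations


def _subsample_subjects(
    dataset: CycleDataset, fraction: float, rng: np.random.Generator
) -> CycleDataset:
    """Label-stratified draw of a subject fraction, without replacement."""
    keep: list[str] = []
    for group in ("control", "patient"):
        members = sorted(
            s for s, g in dataset.subjects_with_cycles().items() if g == group
        )
        n_keep = round(fraction * len(members))
        if n_keep < 2:
            raise ContractError(
                f"fraction {fraction} leaves fewer than 2 {group} subjects"
            )
        keep.extend(rng.choice(members, size=n_keep, replace=False))
    mask = np.isin(dataset.subject_ids, keep)
    return dataset.subset(mask)


def _subsample_cycles(
    dataset: CycleDataset, fraction: float, rng: np.random.Generator
) -> CycleDataset:
    """Keep a fraction of each subject's cycles (>= 1), without replacement."""
    sids = dataset.subject_ids
    mask = np.zeros(len(dataset.samples), dtype=bool)
    for sid in np.unique(sids):
        idx = np.flatnonzero(sids == sid)
        n_keep = max(1, round(fraction * idx.size))
        mask[rng.choice(idx, size=n_keep, replace=False)] = True
    return dataset.subset(mask)


def ablate(
    dataset: CycleDataset,
    ablation: AblationConfig,
    spec: ModelSpec | None = None,
    config: TrainConfig | None = None,
) -> pd.DataFrame:
    """Mean ± sample SD of LOOCV accuracy per subsampling fraction.

    Iteration i (0-based) draws its subset and trains with seed
    ablation.seed + i; fraction 1.0 with mode 'subjects' reproduces the
    unablated LOOCV of iteration seed exactly.
    """
    ablation.validate()
    spec = spec or ModelSpec()
    config = config or TrainConfig()
    rows = []
    for fraction in ablation.fractions:
        overall = []
        for i in range(ablation.iterations):
            it_seed = ablation.seed + i
            rng = np.random.default_rng(np.random.SeedSequence(it_seed))
            if ablation.mode == "subjects":
                subset = (
                    dataset if fraction == 1.0
                    else _subsample_subjects(dataset, fraction, rng)
                )
            else:
                subset = (
                    dataset if fraction == 1.0
                    else _subsample_cycles(dataset, fraction, rng)
                )
            report = run_loocv(
                subset, replace(spec, seed=spec.seed + it_seed),
                replace(config, seed=config.seed + it_seed),
            )
            overall.append(report.overall_mean)
        overall = np.array(overall)
        rows.append(
            {
                "fraction": fraction,
                "mean_accuracy": float(overall.mean()),
                "sd_accuracy": float(overall.std(ddof=1)) if overall.size > 1 else 0.0,
                "iterations": ablation.iterations,
            }
        )
    return pd.DataFrame(rows).set_index("fraction")
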