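"""Metrics, paired leave-one-out cross-validation and report tables.

Accuracy follows the confusion-count definition (TP + TN over all four
counts, positive class = patient) evaluated in exact rational arithmetic
before any rounding.  Evaluation is subject-paired LOOCV: each fold holds out
one control and one patient (paired by rank after sorting subject ids within
each group), trains a fresh model on the remaining subjects' cycles with
normalization fitted on the training cycles only, and scores each held-out
subject as the fraction of their cycles classified with their true label.
Group means are arithmetic means of per-subject accuracies and the overall
mean is the mean of the two group means.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from fractions import Fraction

import numpy as np
import pandas as pd

from .errors import ContractError, UndefinedMetricError
from .model import ModelSpec, build_model
from .normalization import apply_range, fit_range
from .segmentation import CycleDataset
from .training import Checkpoint, FinetuneConfig, TrainConfig, finetune, train


@dataclass
class ConfusionCounts:
    """Cycle-level confusion counts; positive class = patient."""

    true_positive: int = 0
    true_negative: int = 0
    false_positive: int = 0
    false_negative: int = 0

    def __post_init__(self) -> None:
        if min(self.true_positive, self.true_negative,
               self.false_positive, self.false_negative) < 0:
            raise ContractError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return (self.true_positive + self.true_negative
                + self.false_positive + self.false_negative)

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.true_positive + other.true_positive,
            self.true_negative + other.true_negative,
            self.false_positive + other.false_positive,
            self.false_negative + other.false_negative,
        )


def accuracy(counts: ConfusionCounts) -> float:
    """(TP + TN) / (TP + FP + TN + FN), exact before the final float."""
    if counts.total == 0:
        raise UndefinedMetricError("accuracy undefined for zero total count")
    return float(Fraction(counts.true_positive + counts.true_negative, counts.total))


def subject_accuracy(predictions: np.ndarray, true_label: int) -> float:
    """Fraction of one subject's cycles classified with the subject's label."""
    predictions = np.asarray(predictions)
    if predictions.size == 0:
        raise UndefinedMetricError("subject has zero cycles; exclude and flag")
    return float(Fraction(int((predictions == true_label).sum()), predictions.size))


@dataclass
class F1Result:
    f1: float | None
    defined: bool
    counts: ConfusionCounts


def f1_and_confusion(counts: ConfusionCounts) -> F1Result:
    """F1 = 2TP / (2TP + FP + FN) on pooled cycle-level counts.

    Flagged undefined (f1 = None) when no positives are predicted or present.
    """
    denom = 2 * counts.true_positive + counts.false_positive + counts.false_negative
    if denom == 0:
        return F1Result(f1=None, defined=False, counts=counts)
    return F1Result(
        f1=float(Fraction(2 * counts.true_positive, denom)),
        defined=True,
        counts=counts,
    )


# ---------------------------------------------------------------------------
# folds


@dataclass(frozen=True)
class Fold:
    fold_index: int
    held_out_control: str | None
    held_out_patient: str | None

    @property
    def held_out(self) -> tuple[str, ...]:
        return tuple(s for s in (self.held_out_control, self.held_out_patient)
                     if s is not None)


def make_loocv_folds(subjects: dict[str, str]) -> list[Fold]:
    """Paired leave-one-out folds over a subject_id -> group mapping.

    Each group is sorted by subject id and paired by rank, so every subject is
    held out exactly once and the folds are deterministic.  With unequal
    group sizes the leftover subjects of the larger group get singleton folds
    and a warning is emitted.
    """
    controls = sorted(s for s, g in subjects.items() if g == "control")
    patients = sorted(s for s, g in subjects.items() if g == "patient")
    if len(controls) < 2 or len(patients) < 2:
        raise ContractError("paired LOOCV needs at least 2 subjects per group")
    folds = []
    n = min(len(controls), len(patients))
    if len(controls) != len(patients):
        warnings.warn(
            f"unequal group sizes ({len(controls)} controls, {len(patients)} "
            "patients); leftover subjects get singleton folds",
            stacklevel=2,
        )
    for i in range(n):
        folds.append(Fold(i, controls[i], patients[i]))
    for j, sid in enumerate(controls[n:]):
        folds.append(Fold(n + j, sid, None))
    for j, sid in enumerate(patients[n:]):
        folds.append(Fold(n + j, None, sid))
    return folds


@dataclass
class FoldResult:
    fold_index: int
    held_out_control: str | None
    held_out_patient: str | None
    per_cycle_predictions: dict[str, np.ndarray]
    per_subject_accuracy: dict[str, float]
    counts: ConfusionCounts


@dataclass
class EvaluationReport:
    """Per-subject accuracies and group aggregates from one LOOCV run."""

    task: str
    placement: str
    per_subject: dict[str, float]
    groups: dict[str, str]
    counts: ConfusionCounts
    folds: list[FoldResult] = field(default_factory=list)
    excluded_subjects: list[str] = field(default_factory=list)

    def group_accuracies(self, group: str) -> list[float]:
        return [a for s, a in self.per_subject.items() if self.groups[s] == group]

    @property
    def control_mean(self) -> float:
        return float(np.mean(self.group_accuracies("control")))

    @property
    def patient_mean(self) -> float:
        return float(np.mean(self.group_accuracies("patient")))

    @property
    def overall_mean(self) -> float:
        return (self.control_mean + self.patient_mean) / 2.0

    @property
    def f1(self) -> F1Result:
        return f1_and_confusion(self.counts)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": list(self.per_subject),
                "group": [self.groups[s] for s in self.per_subject],
                "accuracy": list(self.per_subject.values()),
            }
        )


def run_loocv(
    dataset: CycleDataset,
    spec: ModelSpec | None = None,
    config: TrainConfig | None = None,
    finetune_checkpoint: Checkpoint | None = None,
    finetune_config: FinetuneConfig | None = None,
) -> EvaluationReport:
    """Paired subject-level LOOCV over a cycle dataset.

    Per fold: normalization fitted on training cycles only, a fresh model
    trained (or fine-tuned from a checkpoint with frozen convolutions), and
    the held-out subjects' cycles scored.  Fold f derives its seeds as
    spec.seed + f and config.seed + f.  A runtime assertion guarantees the
    train and test subject sets never intersect.
    """
    spec = spec or ModelSpec()
    config = config or TrainConfig()
    subjects = dataset.subjects_with_cycles()
    folds = make_loocv_folds(subjects)
    X, y, sids = dataset.X, dataset.y, dataset.subject_ids

    per_subject: dict[str, float] = {}
    fold_results: list[FoldResult] = []
    total = ConfusionCounts()
    for fold in folds:
        held = set(fold.held_out)
        test_mask = np.isin(sids, list(held))
        train_mask = ~test_mask
        train_subjects = set(sids[train_mask])
        if train_subjects & held:  # no-leakage invariant
            raise ContractError("subject leakage: held-out subject in training set")
        norm = fit_range(X[train_mask])
        Xtr = apply_range(norm, X[train_mask]).astype(np.float32)
        ytr = y[train_mask]
        fold_spec = replace(spec, seed=spec.seed + fold.fold_index)
        if finetune_checkpoint is not None:
            cfg = finetune_config or FinetuneConfig()
            cfg = replace(cfg, seed=cfg.seed + fold.fold_index)
            model, _ = finetune(finetune_checkpoint, Xtr, ytr, cfg)
        else:
            cfg = replace(config, seed=config.seed + fold.fold_index)
            model = build_model(fold_spec)
            train(model, Xtr, ytr, cfg)
        predictions: dict[str, np.ndarray] = {}
        fold_counts = ConfusionCounts()
        for sid in fold.held_out:
            mask = sids == sid
            probs = model.predict_proba(apply_range(norm, X[mask]))
            preds = (probs >= spec.decision_threshold).astype(int)
            label = int(y[mask][0])
            predictions[sid] = preds
            per_subject[sid] = subject_accuracy(preds, label)
            tp = int(((preds == 1) & (label == 1)).sum())
            tn = int(((preds == 0) & (label == 0)).sum())
            fp = int(((preds == 1) & (label == 0)).sum())
            fn = int(((preds == 0) & (label == 1)).sum())
            fold_counts = fold_counts + ConfusionCounts(tp, tn, fp, fn)
        total = total + fold_counts
        fold_results.append(
            FoldResult(
                fold_index=fold.fold_index,
                held_out_control=fold.held_out_control,
                held_out_patient=fold.held_out_patient,
                per_cycle_predictions=predictions,
                per_subject_accuracy={s: per_subject[s] for s in fold.held_out},
                counts=fold_counts,
            )
        )
    return EvaluationReport(
        task=dataset.task,
        placement=dataset.placement,
        per_subject=per_subject,
        groups=subjects,
        counts=total,
        folds=fold_results,
        excluded_subjects=list(dataset.flagged_subjects),
    )


# ---------------------------------------------------------------------------
# tables


def aggregate_sensor_table(
    per_sensor: dict[str, tuple[float, float] | EvaluationReport],
    placements: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Per-sensor control/patient/average columns plus an unweighted Mean row.

    Accepts either evaluation reports or plain (control, patient) accuracy
    pairs, so published result tables can be aggregated with the same code
    path as freshly computed ones.
    """
    rows = {}
    for placement, value in per_sensor.items():
        if isinstance(value, EvaluationReport):
            control, patient = value.control_mean, value.patient_mean
        else:
            control, patient = value
        rows[placement] = (control, patient, (control + patient) / 2.0)
    if placements is not None:
        missing = [p for p in placements if p not in rows]
        if missing:
            warnings.warn(f"incomplete sensor table; missing {missing}", stacklevel=2)
    table = pd.DataFrame.from_dict(
        rows, orient="index", columns=["control", "patient", "average"]
    )
    table.loc["Mean"] = table.mean(axis=0)
    return table


@dataclass
class ScoreSummary:
    mean: float
    sd: float

    @property
    def display(self) -> str:
        return f"{self.mean:.2f} ± {self.sd:.2f}"


def clinical_score_summary(score_counts: dict[int, int]) -> ScoreSummary:
    """Mean and sample standard deviation of an integer-score distribution.

    ``score_counts`` maps a clinical score (0-3) to the number of subjects
    with that score; the standard deviation uses the n-1 denominator.
    """
    scores = []
    for score, count in score_counts.items():
        if count < 0 or not 0 <= score <= 3:
            raise ContractError("scores must be 0-3 with non-negative counts")
        scores.extend([score] * count)
    if not scores:
        raise ContractError("clinical score summary needs at least one subject")
    arr = np.array(scores, dtype=float)
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return ScoreSummary(mean=float(arr.mean()), sd=sd)
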