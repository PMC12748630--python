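"""Reference result tables for the clinical cohort this pipeline targets.

The package is designed around a study of 32 vestibular-schwannoma patients
and 32 age-matched controls walking with six body-worn IMUs.  The clinical
recordings themselves are not distributable, but the study's printed summary
tables are, and they serve two purposes here: they exercise the package's
aggregation arithmetic (sensor-table means, transfer deltas, clinical-score
summaries reproduce the printed numbers exactly), and they provide the
benchmark figures a user would compare fresh results against.

All accuracies are on a 0-1 scale; sample counts are gait cycles.
"""

from __future__ import annotations

from .evaluation import ScoreSummary, aggregate_sensor_table, clinical_score_summary

#: Per-sensor LOOCV accuracy (control, patient) per task on the clinical cohort.
LOOCV_ACCURACY = {
    "level_walk_short": {
        "ankle_left": (0.6337, 0.5907),
        "ankle_right": (0.5213, 0.5903),
        "waist": (0.5602, 0.5119),
        "back": (0.6122, 0.6437),
        "head": (0.5860, 0.6215),
        "wrist": (0.6896, 0.7132),
    },
    "slow_blink_walk_long": {
        "ankle_left": (0.6241, 0.6138),
        "ankle_right": (0.6493, 0.6062),
        "waist": (0.5980, 0.6469),
        "back": (0.6577, 0.6711),
        "head": (0.6132, 0.5834),
        "wrist": (0.7369, 0.6868),
    },
}

#: Source-dataset validation accuracy during pretraining: the healthy
#: activity-recognition source (single waist sensor, 10 folds) and the
#: vestibular-pathology source per placement (7 subject-level folds).
PRETRAIN_VALIDATION = {
    "activity": 0.8796,
    "pathology": {
        "ankle_left": 0.7163,
        "ankle_right": 0.6744,
        "waist": 0.6986,
        "back": 0.6967,
        "head": 0.7600,
        "wrist": 0.7618,
    },
}

#: Fine-tuned per-sensor accuracy (control, patient) on the short walking
#: task after pretraining on each source.
TRANSFER_FINETUNED = {
    "activity": {
        "ankle_left": (0.6107, 0.5684),
        "ankle_right": (0.5643, 0.4172),
        "waist": (0.6395, 0.5344),
        "back": (0.7005, 0.5737),
        "head": (0.5506, 0.4472),
        "wrist": (0.7639, 0.6024),
    },
    "pathology": {
        "ankle_left": (0.7604, 0.7118),
        "ankle_right": (0.6427, 0.6422),
        "waist": (0.7080, 0.6376),
        "back": (0.6762, 0.6778),
        "head": (0.6498, 0.6198),
        "wrist": (0.7646, 0.7684),
    },
}

#: Gait-cycle counts per group and task on the clinical cohort.
SAMPLE_COUNTS = {
    "level_walk_short": {"control": 153, "patient": 159},
    "slow_blink_walk_long": {"control": 690, "patient": 703},
}

#: Window counts of the healthy activity-recognition pretraining source.
ACTIVITY_SOURCE_COUNTS = {"walking": 882, "running": 595}

#: Cycle counts of the vestibular-pathology pretraining source.
PATHOLOGY_SOURCE_COUNTS = {"control": 57, "patient": 256}

#: Clinician-scored gait ratings (score -> subject count) on the short task.
CLINICAL_SCORE_COUNTS = {
    "control": {0: 0, 1: 0, 2: 6, 3: 26},
    "patient": {0: 0, 1: 1, 2: 4, 3: 27},
}


def loocv_table(task: str):
    """Sensor table (with Mean row) aggregated from the reference accuracies."""
    return aggregate_sensor_table(LOOCV_ACCURACY[task])


def both_task_overall_mean() -> float:
    """Mean over the two tasks of the Mean-row average column."""
    means = [loocv_table(task).loc["Mean", "average"] for task in LOOCV_ACCURACY]
    return float(sum(means) / len(means))


def pathology_validation_mean() -> float:
    vals = PRETRAIN_VALIDATION["pathology"].values()
    return float(sum(vals) / len(vals))


def transfer_delta(scenario: str, placement: str, group: str) -> float:
    """Fine-tuned minus baseline accuracy for one table cell (exact)."""
    idx = 0 if group == "control" else 1
    fine = TRANSFER_FINETUNED[scenario][placement][idx]
    base = LOOCV_ACCURACY["level_walk_short"][placement][idx]
    return fine - base


def transfer_mean_delta(scenario: str, group: str) -> float:
    """Mean-row delta: mean fine-tuned minus mean baseline accuracy."""
    idx = 0 if group == "control" else 1
    placements = TRANSFER_FINETUNED[scenario]
    fine = sum(v[idx] for v in placements.values()) / len(placements)
    base = sum(
        LOOCV_ACCURACY["level_walk_short"][p][idx] for p in placements
    ) / len(placements)
    return fine - base


def sample_share(task: str, group: str) -> float:
    """Percentage of the task's cycles contributed by one group."""
    counts = SAMPLE_COUNTS[task]
    return 100.0 * counts[group] / sum(counts.values())


def activity_class_share(activity: str) -> float:
    """Percentage of the activity source's windows in one class."""
    return (
        100.0 * ACTIVITY_SOURCE_COUNTS[activity]
        / sum(ACTIVITY_SOURCE_COUNTS.values())
    )


def clinical_summary(group: str) -> ScoreSummary:
    return clinical_score_summary(CLINICAL_SCORE_COUNTS[group])
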