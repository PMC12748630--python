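"""Metrics arithmetic, fold construction and LOOCV bookkeeping."""

import numpy as np
import pytest

from vestgait.errors import ContractError, UndefinedMetricError
from vestgait.evaluation import (
    ConfusionCounts,
    accuracy,
    aggregate_sensor_table,
    clinical_score_summary,
    f1_and_confusion,
    make_loocv_folds,
    run_loocv,
    subject_accuracy,
)
from vestgait.fixtures import fixture_model_spec, fixture_train_config
from vestgait.segmentation import build_cycle_dataset
from vestgait import reference
import dataclasses


@pytest.mark.parametrize(
    "counts,expected",
    [((1, 1, 0, 0), 1.0), ((3, 2, 1, 2), 0.625), ((0, 0, 1, 1), 0.0)],
)
def test_accuracy_formula(counts, expected):
    assert accuracy(ConfusionCounts(*counts)) == expected


def test_accuracy_undefined_for_empty_counts():
    with pytest.raises(UndefinedMetricError):
        accuracy(ConfusionCounts())


def test_negative_counts_rejected():
    with pytest.raises(ContractError):
        ConfusionCounts(-1, 0, 0, 0)


@pytest.mark.parametrize(
    "preds,label,expected",
    [([1, 1, 1, 1, 1], 1, 1.0), ([1, 1, 0, 0, 0], 1, 0.4), ([0], 1, 0.0)],
)
def test_subject_accuracy(preds, label, expected):
    assert subject_accuracy(np.array(preds), label) == expected


def test_subject_with_no_cycles_is_flagged_not_zero():
    with pytest.raises(UndefinedMetricError, match="flag"):
        subject_accuracy(np.array([]), 1)


def test_f1_examples():
    assert f1_and_confusion(ConfusionCounts(3, 2, 1, 2)).f1 == pytest.approx(6 / 9)
    assert f1_and_confusion(ConfusionCounts(5, 5, 0, 0)).f1 == 1.0
    undefined = f1_and_confusion(ConfusionCounts(0, 4, 0, 0))
    assert not undefined.defined and undefined.f1 is None


# -- clinical scores --------------------------------------------------------


def test_clinical_score_summary_control_distribution():
    summary = clinical_score_summary({2: 6, 3: 26})
    assert round(summary.mean, 2) == 2.81
    assert round(summary.sd, 2) == 0.40


def test_clinical_score_summary_patient_distribution():
    summary = clinical_score_summary({1: 1, 2: 4, 3: 27})
    assert round(summary.mean, 2) == 2.81
    assert round(summary.sd, 2) == 0.47


def test_clinical_score_summary_degenerate():
    summary = clinical_score_summary({3: 10})
    assert summary.display == "3.00 ± 0.00"
    with pytest.raises(ContractError):
        clinical_score_summary({3: 0})


# -- folds ------------------------------------------------------------------


def test_paired_folds_partition_subjects():
    subjects = {f"c{i}": "control" for i in range(4)}
    subjects |= {f"p{i}": "patient" for i in range(4)}
    folds = make_loocv_folds(subjects)
    assert len(folds) == 4
    held = [s for f in folds for s in f.held_out]
    assert sorted(held) == sorted(subjects)  # each subject exactly once


def test_two_per_group_gives_two_folds():
    folds = make_loocv_folds(
        {"c0": "control", "c1": "control", "p0": "patient", "p1": "patient"}
    )
    assert len(folds) == 2
    assert all(f.held_out_control and f.held_out_patient for f in folds)


def test_unequal_groups_warn_and_add_singletons():
    subjects = {"c0": "control", "c1": "control", "c2": "control",
                "p0": "patient", "p1": "patient"}
    with pytest.warns(UserWarning, match="unequal"):
        folds = make_loocv_folds(subjects)
    assert len(folds) == 3
    assert folds[-1].held_out_patient is None
    held = [s for f in folds for s in f.held_out]
    assert sorted(held) == sorted(subjects)


def test_too_few_subjects_rejected():
    with pytest.raises(ContractError):
        make_loocv_folds({"c0": "control", "p0": "patient", "p1": "patient"})


# -- LOOCV ------------------------------------------------------------------


@pytest.fixture(scope="module")
def small_report(small_cohort):
    dataset = build_cycle_dataset(small_cohort, "level_walk_short", "head")
    spec = fixture_model_spec(seed=1)
    config = fixture_train_config(seed=1)
    return run_loocv(dataset, spec, config), dataset


def test_loocv_scores_every_subject_once(small_report):
    report, dataset = small_report
    assert sorted(report.per_subject) == sorted(dataset.subjects_with_cycles())
    assert all(0 <= a <= 1 for a in report.per_subject.values())


def test_loocv_aggregation_identity(small_report):
    report, _ = small_report
    control = report.group_accuracies("control")
    patient = report.group_accuracies("patient")
    assert report.control_mean == pytest.approx(np.mean(control))
    assert report.overall_mean == pytest.approx(
        (np.mean(control) + np.mean(patient)) / 2
    )
    assert report.counts.total == sum(f.counts.total for f in report.folds)


def test_loocv_is_seed_deterministic(small_cohort):
    dataset = build_cycle_dataset(small_cohort, "level_walk_short", "wrist")
    spec = fixture_model_spec(seed=3)
    config = dataclasses.replace(fixture_train_config(seed=3), epochs=3)
    r1 = run_loocv(dataset, spec, config)
    r2 = run_loocv(dataset, spec, config)
    assert r1.per_subject == r2.per_subject


def test_strong_effect_is_recovered(small_report):
    report, _ = small_report
    assert report.overall_mean >= 0.8


# -- tables -----------------------------------------------------------------


def test_sensor_table_mean_row_matches_reference():
    table = reference.loocv_table("level_walk_short")
    assert round(table.loc["Mean", "control"], 4) == 0.6005
    assert round(table.loc["Mean", "patient"], 4) == 0.6119
    assert round(table.loc["Mean", "average"], 4) == 0.6062


def test_both_task_overall_mean_matches_reference():
    assert round(reference.both_task_overall_mean(), 4) == 0.6234


def test_single_placement_table_mean_equals_row():
    table = aggregate_sensor_table({"wrist": (0.7, 0.8)})
    assert table.loc["Mean", "control"] == pytest.approx(0.7)
    assert table.loc["Mean", "average"] == pytest.approx(0.75)


def test_missing_placement_warns():
    from vestgait.io import PLACEMENTS

    with pytest.warns(UserWarning, match="missing"):
        aggregate_sensor_table({"wrist": (0.7, 0.8)}, placements=PLACEMENTS)
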