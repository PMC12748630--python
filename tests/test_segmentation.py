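"""Cycle detection, shared-boundary slicing and fixed-length resampling."""

import numpy as np
import pytest

from vestgait.errors import AlignmentError, ContractError
from vestgait.io import PLACEMENTS, TrialRecording
from vestgait.segmentation import (
    CycleBoundaries,
    SegmentationParams,
    build_cycle_dataset,
    detect_cycles,
    resample_cycle,
    slice_all_sensors,
)
from vestgait.synthetic import SyntheticCohortConfig, generate_cohort


def _ankle_trial(signal, fs=500.0):
    channels = np.zeros((6, signal.size))
    channels[3] = signal
    return TrialRecording("s", "level_walk_short", "ankle_right", fs, channels)


def test_zero_jitter_trial_yields_interior_cycles():
    """10 peaks at 1 stride/s over 10 s -> 9 half-open [peak, next) cycles."""
    cohort = generate_cohort(
        SyntheticCohortConfig(
            n_per_group=2, trial_duration_s=10.0, cycle_jitter_sd=0.0,
            noise_sd=0.0, stride_freq_subject_sd=0.0,
            subject_random_effect_sd=0.0, seed=0,
        )
    )
    trial = cohort.trials[("control_00", "level_walk_short", "ankle_right")]
    boundaries = detect_cycles(trial)
    assert len(boundaries) == 9
    starts = [s for s, _ in boundaries.intervals]
    ends = [e for _, e in boundaries.intervals]
    assert starts[1:] == ends[:-1]  # contiguous half-open intervals
    durations = (np.array(ends) - np.array(starts)) / trial.sampling_rate
    np.testing.assert_allclose(durations, 1.0, atol=0.02)


def test_constant_signal_gives_empty_boundaries():
    boundaries = detect_cycles(_ankle_trial(np.zeros(5000)))
    assert len(boundaries) == 0


def test_low_prominence_wiggle_is_ignored():
    """A small bump between true peaks does not split a cycle."""
    fs = 100.0
    t = np.arange(0, 5, 1 / fs)
    clean = np.sin(2 * np.pi * t)
    # localized low bump in the trough midway through the third cycle
    wiggle = clean + 0.08 * np.exp(-((t - 2.75) ** 2) / (2 * 0.03**2))
    params = SegmentationParams(min_peak_prominence=0.3, smoothing_window_s=0.0)
    b_clean = detect_cycles(_ankle_trial(clean, fs), params)
    b_wiggle = detect_cycles(_ankle_trial(wiggle, fs), params)
    assert len(b_clean) == len(b_wiggle) > 0
    assert b_clean.intervals == b_wiggle.intervals


def test_detect_requires_right_ankle():
    trial = _ankle_trial(np.sin(np.linspace(0, 30, 3000)))
    trial.placement = "wrist"
    with pytest.raises(ContractError, match="ankle_right"):
        detect_cycles(trial)


def test_slicing_shares_boundaries_across_placements(tiny_cohort):
    trials = tiny_cohort.trials_for("control_00", "level_walk_short")
    boundaries = detect_cycles(trials["ankle_right"])
    segments = slice_all_sensors(trials, boundaries)
    counts = {p: len(s) for p, s in segments.items()}
    assert len(set(counts.values())) == 1
    assert counts["wrist"] == len(boundaries)
    for (start, end), seg in zip(boundaries.intervals, segments["head"]):
        assert seg.shape == (6, end - start)


def test_empty_boundaries_slice_to_zero_segments(tiny_cohort):
    trials = tiny_cohort.trials_for("control_00", "level_walk_short")
    segments = slice_all_sensors(trials, CycleBoundaries(intervals=[]))
    assert all(len(s) == 0 for s in segments.values())


def test_truncated_trial_raises_alignment_error(tiny_cohort):
    trials = dict(tiny_cohort.trials_for("control_00", "level_walk_short"))
    wrist = trials["wrist"]
    trials["wrist"] = TrialRecording(
        wrist.subject_id, wrist.task, "wrist", wrist.sampling_rate,
        wrist.channels[:, :-100],
    )
    with pytest.raises(AlignmentError, match="lengths differ"):
        slice_all_sensors(trials, CycleBoundaries(intervals=[(0, 500)]))


# -- resampling -------------------------------------------------------------


def test_resample_identity_at_target_length(rng):
    segment = rng.standard_normal((6, 512))
    np.testing.assert_array_equal(resample_cycle(segment), segment)


def test_resample_linear_ramp_exact():
    segment = np.tile(np.linspace(0.0, 3.0, 4), (6, 1))
    out = resample_cycle(segment)
    np.testing.assert_allclose(out, np.tile(np.linspace(0.0, 3.0, 512), (6, 1)),
                               atol=1e-12)
    assert out[0, 255] + out[0, 256] == pytest.approx(3.0)  # symmetric midpoint


def test_resample_sine_close_to_closed_form():
    t = np.linspace(0.0, 1.0, 1000)
    segment = np.tile(np.sin(2 * np.pi * t), (6, 1))
    out = resample_cycle(segment)
    target_t = np.linspace(0.0, 1.0, 512)
    assert np.abs(out[0] - np.sin(2 * np.pi * target_t)).max() < 1e-4


def test_resample_preserves_endpoints_and_monotonicity(rng):
    row = np.sort(rng.standard_normal(37))
    out = resample_cycle(np.tile(row, (6, 1)))
    assert out[0, 0] == row[0] and out[0, -1] == row[-1]
    assert np.all(np.diff(out[0]) >= 0)


def test_resample_degenerate_and_cubic():
    with pytest.raises(ContractError, match="egenerate"):
        resample_cycle(np.zeros((6, 1)))
    t = np.linspace(0.0, 1.0, 300)
    segment = np.tile(np.sin(2 * np.pi * t), (6, 1))
    out = resample_cycle(segment, method="cubic")
    assert np.abs(out[0] - np.sin(2 * np.pi * np.linspace(0, 1, 512))).max() < 1e-5


# -- dataset assembly -------------------------------------------------------


def test_dataset_counts_match_detected_cycles(tiny_cohort):
    expected = {}
    for sid in tiny_cohort.subject_ids():
        trials = tiny_cohort.trials_for(sid, "level_walk_short")
        expected[sid] = len(detect_cycles(trials["ankle_right"]))
    ds = build_cycle_dataset(tiny_cohort, "level_walk_short", "wrist")
    assert ds.per_subject_counts() == expected
    assert all(s.matrix.shape == (6, 512) for s in ds.samples)
    assert all(s.label == ds.groups[s.subject_id] for s in ds.samples)


@pytest.mark.parametrize("placement", ["wrist", "head"])
def test_counts_identical_across_placements(tiny_cohort, placement):
    ref = build_cycle_dataset(tiny_cohort, "level_walk_short", "ankle_left")
    other = build_cycle_dataset(tiny_cohort, "level_walk_short", placement)
    assert ref.per_subject_counts() == other.per_subject_counts()


def test_short_recording_subject_is_flagged():
    cohort = generate_cohort(
        SyntheticCohortConfig(n_per_group=2, trial_duration_s=6.0, seed=2)
    )
    # truncate one subject's trials to 1 s: too short for any full cycle
    for p in PLACEMENTS:
        key = ("control_01", "level_walk_short", p)
        rec = cohort.trials[key]
        cohort.trials[key] = TrialRecording(
            rec.subject_id, rec.task, p, rec.sampling_rate, rec.channels[:, :500]
        )
    ds = build_cycle_dataset(cohort, "level_walk_short", "wrist")
    assert "control_01" in ds.flagged_subjects
    assert "control_01" not in set(ds.subject_ids)
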