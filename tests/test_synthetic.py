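"""Synthetic cohort and activity-window generator behaviour."""

import dataclasses

import numpy as np
import pytest
from scipy.signal import find_peaks

from vestgait.errors import ConfigurationError
from vestgait.io import CHANNELS, GYRO_PITCH, PLACEMENTS
from vestgait.synthetic import (
    ActivityWindowConfig,
    SyntheticCohortConfig,
    generate_activity_windows,
    generate_cohort,
)


def _null_config(**overrides):
    base = dict(
        n_per_group=2,
        trial_duration_s=6.0,
        group_amplitude_effect=0.0,
        group_variability_effect=1.0,
        subject_random_effect_sd=0.0,
        stride_freq_subject_sd=0.0,
        cycle_jitter_sd=0.0,
        noise_sd=0.0,
        seed=3,
    )
    base.update(overrides)
    return SyntheticCohortConfig(**base)


def test_same_seed_is_bit_identical():
    config = SyntheticCohortConfig(n_per_group=2, trial_duration_s=5.0, seed=9)
    a = generate_cohort(config)
    b = generate_cohort(dataclasses.replace(config))
    assert [s.subject_id for s in a.subjects] == [s.subject_id for s in b.subjects]
    for key in a.trials:
        np.testing.assert_array_equal(a.trials[key].channels, b.trials[key].channels)


def test_zero_effect_groups_share_waveforms():
    """With all effects and noise off, patient and control signals coincide."""
    cohort = generate_cohort(_null_config())
    for placement in PLACEMENTS:
        control = cohort.trials[("control_00", "level_walk_short", placement)]
        patient = cohort.trials[("patient_00", "level_walk_short", placement)]
        np.testing.assert_allclose(control.channels, patient.channels, atol=1e-12)


def test_zero_jitter_peak_count_matches_stride_count():
    """10 s at 1 stride/s yields exactly 10 dominant ankle-pitch peaks."""
    cohort = generate_cohort(_null_config(trial_duration_s=10.0))
    trial = cohort.trials[("control_00", "level_walk_short", "ankle_right")]
    signal = trial.channels[GYRO_PITCH]
    peaks, _ = find_peaks(signal, prominence=0.5 * np.ptp(signal))
    assert len(peaks) == 10


def test_amplitude_effect_is_monotone_in_group_difference():
    """Larger group effects widen the between-group per-cycle amplitude gap."""
    diffs = []
    for effect in (0.1, 0.3, 0.5):
        cohort = generate_cohort(_null_config(group_amplitude_effect=effect))
        gaps = []
        for placement, channel in (("head", "gyro_pitch"), ("waist", "acc_ml")):
            c = CHANNELS.index(channel)
            control = cohort.trials[("control_00", "level_walk_short", placement)]
            patient = cohort.trials[("patient_00", "level_walk_short", placement)]
            gaps.append(
                abs(np.ptp(control.channels[c]) - np.ptp(patient.channels[c]))
            )
        diffs.append(np.mean(gaps))
    assert diffs[0] < diffs[1] < diffs[2]


@pytest.mark.parametrize(
    "field,value",
    [
        ("n_per_group", 1),
        ("sampling_rate", 0.0),
        ("noise_sd", -0.1),
        ("trial_duration_s", 1.0),
        ("placements", ("nose",)),
    ],
)
def test_invalid_config_names_field(field, value):
    config = dataclasses.replace(SyntheticCohortConfig(), **{field: value})
    with pytest.raises(ConfigurationError):
        generate_cohort(config)


def test_trials_cover_all_placements(tiny_cohort):
    for sid in tiny_cohort.subject_ids():
        trials = tiny_cohort.trials_for(sid, "level_walk_short")
        assert set(trials) == set(PLACEMENTS)
        lengths = {t.n_samples for t in trials.values()}
        assert len(lengths) == 1


# -- activity windows -------------------------------------------------------


def test_activity_windows_shapes_and_determinism():
    config = ActivityWindowConfig(n_windows_per_class=10, seed=5)
    X, y = generate_activity_windows(config)
    assert X.shape == (20, 6, 300)  # 3 s x 100 Hz
    assert list(np.bincount(y)) == [10, 10]
    X2, y2 = generate_activity_windows(ActivityWindowConfig(n_windows_per_class=10, seed=5))
    np.testing.assert_array_equal(X, X2)
    np.testing.assert_array_equal(y, y2)


def test_activity_classes_differ_in_frequency():
    config = ActivityWindowConfig(n_windows_per_class=4, noise_sd=0.0, seed=1)
    X, y = generate_activity_windows(config)
    def dom_freq(w):
        spectrum = np.abs(np.fft.rfft(w[0]))
        spectrum[0] = 0
        return np.fft.rfftfreq(w.shape[1], d=1 / config.sampling_rate)[spectrum.argmax()]
    walking = np.mean([dom_freq(w) for w in X[y == 0]])
    running = np.mean([dom_freq(w) for w in X[y == 1]])
    assert walking == pytest.approx(config.class_freq[0], abs=0.35)
    assert running == pytest.approx(config.class_freq[1], abs=0.35)


def test_activity_invalid_config():
    with pytest.raises(ConfigurationError):
        generate_activity_windows(ActivityWindowConfig(n_windows_per_class=0))
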