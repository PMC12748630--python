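"""Synthetic multi-sensor IMU gait cohorts and activity windows.

The generator produces the statistical structure the downstream pipeline
assumes rather than a biomechanical simulation: quasi-periodic 6-channel
signals built from a few harmonics of each subject's stride frequency, with

* per-subject random effects (stride frequency and a global amplitude scale),
* per-cycle multiplicative lognormal jitter on cycle duration,
* a configurable group effect that rescales selected channel amplitudes for
  the patient class (by default: head pitch/roll amplitudes reduced,
  mediolateral trunk acceleration increased, and a milder mediolateral
  effect at every other placement so each sensor carries some signal), and
* additive white Gaussian sensor noise scaled to each channel's base
  amplitude.

The right-ankle pitch angular-velocity channel is built with one dominant
positive peak per stride cycle (a dominant first harmonic at fixed phase with
small higher harmonics), so peak-based cycle segmentation is well posed.

A second generator emulates an unsegmented activity-recognition source:
fixed-duration single-sensor windows of two activity classes distinguished by
their base movement frequency, used for pretraining experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigurationError
from .io import CHANNELS, PLACEMENTS, Cohort, Subject, TrialRecording

#: Base channel amplitudes (acc in m/s^2, gyro in deg/s), identical for both
#: groups; group/subject effects act multiplicatively on top.
BASE_AMPLITUDE = {
    "acc_ap": 2.5,
    "acc_ml": 1.5,
    "acc_v": 3.0,
    "gyro_pitch": 120.0,
    "gyro_roll": 60.0,
    "gyro_yaw": 50.0,
}
#: Amplitude of the dedicated right-ankle pitch segmentation waveform.
ANKLE_PITCH_AMPLITUDE = 200.0


def default_group_effect_map() -> dict[str, dict[str, float]]:
    """Signed per-channel weights of the patient-group amplitude effect.

    A weight w on channel c of placement p means the patient class's amplitude
    on that channel is multiplied by (1 + w * group_amplitude_effect).
    Defaults: head pitch/roll restricted (negative weights), mediolateral
    trunk acceleration increased at waist/back, and a milder mediolateral
    effect everywhere else so every sensor carries some group signal.
    """
    mapping: dict[str, dict[str, float]] = {p: {"acc_ml": 0.4} for p in PLACEMENTS}
    mapping["head"].update({"gyro_pitch": -1.0, "gyro_roll": -1.0})
    mapping["waist"]["acc_ml"] = 1.0
    mapping["back"]["acc_ml"] = 1.0
    return mapping


@dataclass
class SyntheticCohortConfig:
    """Generative parameters of a two-group synthetic gait cohort."""

    n_per_group: int = 8
    sampling_rate: float = 500.0
    stride_freq_mean: float = 1.0
    stride_freq_subject_sd: float = 0.05
    n_harmonics: int = 3
    group_amplitude_effect: float = 0.0
    group_variability_effect: float = 1.0
    subject_random_effect_sd: float = 0.1
    cycle_jitter_sd: float = 0.02
    noise_sd: float = 0.05
    trial_duration_s: float = 8.0
    task: str = "level_walk_short"
    placements: tuple[str, ...] = PLACEMENTS
    group_effect_map: dict[str, dict[str, float]] = field(
        default_factory=default_group_effect_map
    )
    seed: int = 0

    def validate(self) -> None:
        if self.n_per_group < 2:
            raise ConfigurationError("n_per_group must be >= 2")
        if self.sampling_rate <= 0:
            raise ConfigurationError("sampling_rate must be > 0")
        if self.stride_freq_mean <= 0:
            raise ConfigurationError("stride_freq_mean must be > 0")
        if self.n_harmonics < 1:
            raise ConfigurationError("n_harmonics must be >= 1")
        for name in (
            "stride_freq_subject_sd",
            "group_amplitude_effect",
            "subject_random_effect_sd",
            "cycle_jitter_sd",
            "noise_sd",
        ):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.group_variability_effect < 0:
            raise ConfigurationError("group_variability_effect must be >= 0")
        if self.trial_duration_s <= 2.0 / self.stride_freq_mean:
            raise ConfigurationError(
                "trial_duration_s must exceed two mean stride periods"
            )
        unknown = [p for p in self.placements if p not in PLACEMENTS]
        if unknown:
            raise ConfigurationError(f"placements contains unknown entries {unknown}")
        if not self.placements:
            raise ConfigurationError("placements must not be empty")


def _cycle_phase(
    duration_s: float, sampling_rate: float, periods: np.ndarray
) -> np.ndarray:
    """Continuous stride-phase phi(t): phi = k + fraction within cycle k.

    ``periods`` are the (jittered) cycle durations; the sequence is extended
    until it covers the trial, and phase grows piecewise-linearly from one
    cycle boundary to the next.  With constant periods 1/f this reduces to
    phi(t) = f * t.
    """
    t = np.arange(round(duration_s * sampling_rate)) / sampling_rate
    boundaries = np.concatenate([[0.0], np.cumsum(periods)])
    k = np.searchsorted(boundaries, t, side="right") - 1
    frac = (t - boundaries[k]) / periods[k]
    return k + frac


def _channel_waveform(
    phase: np.ndarray, channel: str, placement: str, n_harmonics: int
) -> np.ndarray:
    """Unit-amplitude quasi-periodic waveform for one channel.

    Harmonic phases are a fixed deterministic table of the channel/placement
    indices so control and patient cohorts share identical base waveforms.
    The right-ankle pitch channel instead uses a dominant first harmonic
    (peak at phase 0.25 of every cycle) with small higher harmonics, keeping
    exactly one dominant positive peak per stride.
    """
    c = CHANNELS.index(channel)
    p = PLACEMENTS.index(placement)
    if placement == "ankle_right" and channel == "gyro_pitch":
        wave = np.sin(2 * np.pi * phase)
        for h in range(2, n_harmonics + 1):
            wave = wave + (0.1 / h) * np.sin(2 * np.pi * h * phase)
        return wave
    wave = np.zeros_like(phase)
    for h in range(1, n_harmonics + 1):
        offset = 2 * np.pi * ((3 * c + 5 * h + 2 * p) % 7) / 7.0
        wave = wave + (1.0 / h) * np.sin(2 * np.pi * h * phase + offset)
    return wave


def generate_cohort(config: SyntheticCohortConfig) -> Cohort:
    """Generate a two-group cohort of multi-sensor trials; deterministic in seed."""
    config.validate()
    n_subjects = 2 * config.n_per_group
    seq = np.random.SeedSequence(config.seed)
    subject_seeds = seq.spawn(n_subjects + 1)
    demo_rng = np.random.default_rng(subject_seeds[-1])

    subjects: list[Subject] = []
    cohort = Cohort(subjects=subjects)
    idx = 0
    for group in ("control", "patient"):
        for i in range(config.n_per_group):
            sid = f"{group}_{i:02d}"
            age = float(demo_rng.integers(25, 82))
            sex = "male" if demo_rng.random() < 0.5 else "female"
            subjects.append(Subject(sid, group, age, sex))
            rng = np.random.default_rng(subject_seeds[idx])
            _generate_subject_trials(cohort, sid, group, rng, config)
            idx += 1
    return cohort


def _generate_subject_trials(
    cohort: Cohort,
    subject_id: str,
    group: str,
    rng: np.random.Generator,
    config: SyntheticCohortConfig,
) -> None:
    stride = config.stride_freq_mean + config.stride_freq_subject_sd * rng.standard_normal()
    stride = max(stride, 0.2)
    amp_effect = 1.0 + config.subject_random_effect_sd * rng.standard_normal()
    amp_effect = max(amp_effect, 0.1)

    jitter_sd = config.cycle_jitter_sd * (
        config.group_variability_effect if group == "patient" else 1.0
    )
    n_cycles = int(np.ceil(config.trial_duration_s * stride)) + 2
    log_jitter = jitter_sd * rng.standard_normal(n_cycles)
    periods = (1.0 / stride) * np.exp(log_jitter - jitter_sd**2 / 2.0)
    phase = _cycle_phase(config.trial_duration_s, config.sampling_rate, periods)

    for placement in config.placements:
        data = np.empty((6, phase.size))
        weights = config.group_effect_map.get(placement, {})
        for c, channel in enumerate(CHANNELS):
            if placement == "ankle_right" and channel == "gyro_pitch":
                base = ANKLE_PITCH_AMPLITUDE
            else:
                base = BASE_AMPLITUDE[channel]
            scale = base * amp_effect
            if group == "patient":
                w = weights.get(channel, 0.0)
                scale *= max(1.0 + w * config.group_amplitude_effect, 0.05)
            wave = _channel_waveform(phase, channel, placement, config.n_harmonics)
            noise = config.noise_sd * base * rng.standard_normal(phase.size)
            data[c] = scale * wave + noise
        cohort.trials[(subject_id, config.task, placement)] = TrialRecording(
            subject_id=subject_id,
            task=config.task,
            placement=placement,
            sampling_rate=config.sampling_rate,
            channels=data,
            frame="global",
        )


# ---------------------------------------------------------------------------
# fixture presets

#: Amplitude-effect ladder used by the packaged fixture studies.
EFFECT_LADDER = {"none": 0.0, "weak": 0.1, "medium": 0.25, "strong": 0.5}


def fixture_cohort_config(
    effect: str = "strong", n_per_group: int = 8, seed: int = 0, **overrides
) -> SyntheticCohortConfig:
    """Preset cohort configurations for the packaged property studies.

    ``effect`` picks a rung of the amplitude-effect ladder
    (none/weak/medium/strong = 0 / 0.10 / 0.25 / 0.50); other generative
    parameters keep the defaults (8 s trials at 500 Hz, 1 Hz stride, 5%
    channel noise, 10% subject amplitude scatter, 2% cycle jitter).
    """
    if effect not in EFFECT_LADDER:
        raise ConfigurationError(f"effect must be one of {sorted(EFFECT_LADDER)}")
    return replace(
        SyntheticCohortConfig(
            n_per_group=n_per_group,
            group_amplitude_effect=EFFECT_LADDER[effect],
            seed=seed,
        ),
        **overrides,
    )


# ---------------------------------------------------------------------------
# activity windows (pretraining source)

ACTIVITY_CLASSES = ("walking", "running")


@dataclass
class ActivityWindowConfig:
    """Parameters of the unsegmented two-class activity-window generator."""

    n_windows_per_class: int = 50
    window_duration_s: float = 3.0
    sampling_rate: float = 100.0
    class_freq: tuple[float, float] = (1.8, 3.0)
    noise_sd: float = 0.1
    seed: int = 0

    @property
    def window_length(self) -> int:
        return round(self.window_duration_s * self.sampling_rate)

    def validate(self) -> None:
        if self.n_windows_per_class < 1:
            raise ConfigurationError("n_windows_per_class must be >= 1")
        if self.window_duration_s <= 0:
            raise ConfigurationError("window_duration_s must be > 0")
        if self.sampling_rate <= 0:
            raise ConfigurationError("sampling_rate must be > 0")
        if len(self.class_freq) != 2 or any(f <= 0 for f in self.class_freq):
            raise ConfigurationError("class_freq must be two positive frequencies")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")


def generate_activity_windows(
    config: ActivityWindowConfig,
) -> tuple[np.ndarray, np.ndarray]:
    """Generate labelled single-sensor activity windows.

    Returns ``(windows, labels)`` where ``windows`` has shape
    (2 * n_windows_per_class, 6, window_length) and ``labels`` is 0 for the
    first activity class and 1 for the second.  Windows are continuous
    recordings, deliberately NOT segmented into movement cycles.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    length = config.window_length
    t = np.arange(length) / config.sampling_rate
    windows = np.empty((2 * config.n_windows_per_class, 6, length))
    labels = np.empty(2 * config.n_windows_per_class, dtype=int)
    amps = np.array([BASE_AMPLITUDE[c] for c in CHANNELS])
    i = 0
    for cls, freq in enumerate(config.class_freq):
        for _ in range(config.n_windows_per_class):
            t0 = rng.uniform(0.0, 1.0 / freq)
            for c in range(6):
                offset = 2 * np.pi * ((3 * c + 1) % 5) / 5.0
                wave = np.sin(2 * np.pi * freq * (t + t0) + offset)
                wave = wave + 0.3 * np.sin(4 * np.pi * freq * (t + t0))
                noise = config.noise_sd * rng.standard_normal(length)
                windows[i, c] = amps[c] * (wave + noise)
            labels[i] = cls
            i += 1
    return windows, labels
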