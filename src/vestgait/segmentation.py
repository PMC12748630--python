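"""Gait-cycle segmentation and fixed-length cycle matrices.

Cycles are delimited by successive dominant positive peaks of the right-ankle
pitch angular velocity (the standard shank-gyro swing-phase event): each
cycle is the half-open sample interval [peak_i, peak_{i+1}).  The boundaries
detected on the right ankle are reused verbatim for every other sensor of the
same subject x task, and each sliced segment is resampled to a fixed 6 x 512
matrix by piecewise-linear interpolation on a closed endpoint grid (cubic
interpolation is available for the unsegmented activity-window path).

The stored cycle data are the raw signals; smoothing, when enabled, only
affects the detector's working copy of the pitch channel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import find_peaks

from .errors import AlignmentError, ContractError
from .io import GYRO_PITCH, SEGMENTATION_PLACEMENT, Cohort, TrialRecording

TARGET_LENGTH = 512


@dataclass
class SegmentationParams:
    """Peak-detector settings.

    min_peak_prominence is a fraction of the pitch signal's robust range
    (95th minus 5th percentile); the duration window discards physiologically
    implausible cycles rather than merging them.
    """

    min_peak_prominence: float = 0.3
    min_cycle_duration_s: float = 0.6
    max_cycle_duration_s: float = 2.0
    smoothing_window_s: float = 0.05

    def validate(self) -> None:
        if not 0 < self.min_cycle_duration_s < self.max_cycle_duration_s:
            raise ContractError(
                "cycle duration window requires 0 < min < max"
            )
        if not 0 < self.min_peak_prominence:
            raise ContractError("min_peak_prominence must be > 0")
        if self.smoothing_window_s < 0:
            raise ContractError("smoothing_window_s must be >= 0")


@dataclass
class CycleBoundaries:
    """Ordered half-open [start, end) sample intervals of detected cycles."""

    intervals: list[tuple[int, int]]
    source_placement: str = SEGMENTATION_PLACEMENT
    params: SegmentationParams = field(default_factory=SegmentationParams)

    def __len__(self) -> int:
        return len(self.intervals)


@dataclass
class CycleSample:
    """One gait cycle: a 6 x 512 matrix plus its provenance and group label."""

    subject_id: str
    task: str
    placement: str
    cycle_index: int
    matrix: np.ndarray
    label: str

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (6, TARGET_LENGTH):
            raise ContractError(
                f"cycle matrix must be 6x{TARGET_LENGTH}, got {self.matrix.shape}"
            )
        if not np.isfinite(self.matrix).all():
            raise ContractError("cycle matrix contains non-finite values")


def _moving_average(signal: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return signal
    kernel = np.ones(window) / window
    pad = window // 2
    padded = np.pad(signal, pad, mode="edge")
    smoothed = np.convolve(padded, kernel, mode="same")
    return smoothed[pad : pad + signal.size]


def detect_cycles(
    recording: TrialRecording, params: SegmentationParams | None = None
) -> CycleBoundaries:
    """Detect cycle boundaries from the right-ankle pitch angular velocity.

    Returns successive dominant positive peaks filtered by prominence and by
    the cycle-duration window; an empty interval list (not an error) when no
    peaks survive.
    """
    params = params or SegmentationParams()
    params.validate()
    if recording.placement != SEGMENTATION_PLACEMENT:
        raise ContractError(
            f"segmentation requires the {SEGMENTATION_PLACEMENT} recording, "
            f"got {recording.placement}"
        )
    if recording.frame != "global":
        raise ContractError("segment after rotating the recording to the global frame")
    fs = recording.sampling_rate
    signal = recording.channels[GYRO_PITCH].astype(float)
    window = round(params.smoothing_window_s * fs)
    work = _moving_average(signal, window) if window > 1 else signal
    lo, hi = np.percentile(work, [5.0, 95.0])
    robust_range = hi - lo
    if robust_range <= 0:
        return CycleBoundaries(intervals=[], params=params)
    prominence = params.min_peak_prominence * robust_range
    distance = max(round(params.min_cycle_duration_s * fs), 1)
    peaks, _ = find_peaks(work, prominence=prominence, distance=distance)
    intervals: list[tuple[int, int]] = []
    max_len = params.max_cycle_duration_s * fs
    min_len = params.min_cycle_duration_s * fs
    for start, end in zip(peaks[:-1], peaks[1:]):
        length = end - start
        if min_len <= length <= max_len:
            intervals.append((int(start), int(end)))
    return CycleBoundaries(intervals=intervals, params=params)


def slice_all_sensors(
    trials: dict[str, TrialRecording], boundaries: CycleBoundaries
) -> dict[str, list[np.ndarray]]:
    """Slice every placement of one subject x task on the shared boundaries.

    All trials must agree in subject, task, sampling rate and length; the
    segment count is identical across placements by construction.
    """
    if not trials:
        raise ContractError("no trials to slice")
    recs = list(trials.values())
    ref = recs[0]
    for rec in recs[1:]:
        if rec.subject_id != ref.subject_id or rec.task != ref.task:
            raise AlignmentError("trials mix subjects or tasks")
        if rec.sampling_rate != ref.sampling_rate:
            raise AlignmentError("trials differ in sampling rate")
        if rec.n_samples != ref.n_samples:
            raise AlignmentError(
                f"trial lengths differ: {rec.placement} has {rec.n_samples}, "
                f"{ref.placement} has {ref.n_samples}"
            )
    out: dict[str, list[np.ndarray]] = {}
    for placement, rec in trials.items():
        out[placement] = [rec.channels[:, s:e] for s, e in boundaries.intervals]
    return out


def resample_cycle(
    segment: np.ndarray, target_length: int = TARGET_LENGTH, method: str = "linear"
) -> np.ndarray:
    """Resample a 6 x L segment to 6 x target_length.

    Evaluation positions are linearly spaced over the closed interval from
    the first to the last original sample, so endpoints are preserved exactly
    and an L == target_length input is returned unchanged.  ``method`` is
    ``linear`` (cycle path) or ``cubic`` (activity-window path).
    """
    segment = np.asarray(segment, dtype=float)
    if segment.ndim != 2:
        raise ContractError("segment must be a 2-D channels x time matrix")
    n_channels, length = segment.shape
    if length < 2:
        raise ContractError("degenerate cycle: need at least 2 samples")
    positions = np.linspace(0.0, length - 1, target_length)
    xp = np.arange(length)
    out = np.empty((n_channels, target_length))
    if method == "linear":
        for c in range(n_channels):
            out[c] = np.interp(positions, xp, segment[c])
    elif method == "cubic":
        for c in range(n_channels):
            out[c] = CubicSpline(xp, segment[c])(positions)
    else:
        raise ContractError(f"unknown resampling method {method!r}")
    return out


@dataclass
class CycleDataset:
    """A collection of cycle samples for one task x placement."""

    samples: list[CycleSample]
    task: str
    placement: str
    #: subjects that yielded zero cycles (kept for reporting, absent from X/y)
    flagged_subjects: list[str] = field(default_factory=list)
    #: subject_id -> group, including flagged subjects
    groups: dict[str, str] = field(default_factory=dict)

    @property
    def X(self) -> np.ndarray:
        return np.stack([s.matrix for s in self.samples])

    @property
    def y(self) -> np.ndarray:
        return np.array([1 if s.label == "patient" else 0 for s in self.samples])

    @property
    def subject_ids(self) -> np.ndarray:
        return np.array([s.subject_id for s in self.samples])

    def per_subject_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {sid: 0 for sid in self.groups}
        for s in self.samples:
            counts[s.subject_id] = counts.get(s.subject_id, 0) + 1
        return counts

    def subjects_with_cycles(self) -> dict[str, str]:
        present = {s.subject_id for s in self.samples}
        return {sid: g for sid, g in self.groups.items() if sid in present}

    def subset(self, keep: np.ndarray) -> "CycleDataset":
        samples = [self.samples[i] for i in np.flatnonzero(keep)]
        present = {s.subject_id for s in samples}
        return CycleDataset(
            samples=samples,
            task=self.task,
            placement=self.placement,
            flagged_subjects=sorted(set(self.groups) - present),
            groups=dict(self.groups),
        )


def build_cycle_dataset(
    cohort: Cohort,
    task: str,
    placement: str,
    params: SegmentationParams | None = None,
) -> CycleDataset:
    """Segment every subject of a cohort and collect 6 x 512 cycle samples.

    Boundaries are always detected on the right-ankle recording and applied
    to the requested placement; subjects yielding zero cycles are flagged.
    """
    params = params or SegmentationParams()
    samples: list[CycleSample] = []
    flagged: list[str] = []
    groups: dict[str, str] = {}
    for subject in cohort.subjects:
        sid = subject.subject_id
        trials = cohort.trials_for(sid, task)
        if not trials:
            continue
        groups[sid] = subject.group
        if SEGMENTATION_PLACEMENT not in trials or placement not in trials:
            flagged.append(sid)
            continue
        boundaries = detect_cycles(trials[SEGMENTATION_PLACEMENT], params)
        segments = slice_all_sensors(trials, boundaries)[placement]
        if not segments:
            flagged.append(sid)
            continue
        for k, segment in enumerate(segments):
            samples.append(
                CycleSample(
                    subject_id=sid,
                    task=task,
                    placement=placement,
                    cycle_index=k,
                    matrix=resample_cycle(segment),
                    label=subject.group,
                )
            )
    return CycleDataset(
        samples=samples,
        task=task,
        placement=placement,
        flagged_subjects=flagged,
        groups=groups,
    )
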