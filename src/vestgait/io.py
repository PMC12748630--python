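"""Data model and on-disk formats for multi-sensor IMU gait trials.

A cohort is a directory of per-trial text files plus a ``manifest.csv``.
Each trial file holds one subject x task x sensor-placement recording as a
small ``# key: value`` header followed by six named data columns:

    # subject_id: control_00
    # task: level_walk_short
    # placement: wrist
    # sampling_rate: 500.0
    # frame: global
    # units: acc m/s^2, gyro deg/s
    acc_ap,acc_ml,acc_v,gyro_pitch,gyro_roll,gyro_yaw
    ...

Values are written with 17 significant digits so float64 round-trips are
exact.  The channel order is fixed: anterior-posterior, mediolateral and
vertical acceleration, then pitch, roll and yaw angular velocity.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ContractError, FormatError

PLACEMENTS = ("wrist", "ankle_left", "ankle_right", "waist", "back", "head")
#: The sensor whose pitch angular velocity drives gait-cycle segmentation.
SEGMENTATION_PLACEMENT = "ankle_right"
CHANNELS = ("acc_ap", "acc_ml", "acc_v", "gyro_pitch", "gyro_roll", "gyro_yaw")
#: Row index of the pitch angular-velocity channel.
GYRO_PITCH = CHANNELS.index("gyro_pitch")
TASKS = ("level_walk_short", "slow_blink_walk_long")
GROUPS = ("control", "patient")
SEXES = ("male", "female", "unspecified")
FRAMES = ("local", "global")

_HEADER_UNITS = "acc m/s^2, gyro deg/s"


@dataclass(frozen=True)
class Subject:
    """One cohort participant."""

    subject_id: str
    group: str
    age: float = float("nan")
    sex: str = "unspecified"

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ContractError(f"group must be one of {GROUPS}, got {self.group!r}")
        if self.sex not in SEXES:
            raise ContractError(f"sex must be one of {SEXES}, got {self.sex!r}")


@dataclass
class TrialRecording:
    """One continuous 6-channel IMU stream for a subject x task x placement.

    ``channels`` is a (6, T) float array in the fixed order of
    :data:`CHANNELS`; ``frame`` records whether the triads are still in the
    sensor-local coordinate frame or already rotated to the common global one.
    """

    subject_id: str
    task: str
    placement: str
    sampling_rate: float
    channels: np.ndarray
    frame: str = "global"

    def __post_init__(self) -> None:
        self.channels = np.asarray(self.channels, dtype=float)
        if self.task not in TASKS:
            raise ContractError(f"task must be one of {TASKS}, got {self.task!r}")
        if self.placement not in PLACEMENTS:
            raise ContractError(
                f"placement must be one of {PLACEMENTS}, got {self.placement!r}"
            )
        if self.frame not in FRAMES:
            raise ContractError(f"frame must be one of {FRAMES}, got {self.frame!r}")
        if self.sampling_rate <= 0:
            raise ContractError("sampling_rate must be > 0")
        if self.channels.ndim != 2 or self.channels.shape[0] != 6:
            raise ContractError(
                f"channels must be a 6xT matrix, got shape {self.channels.shape}"
            )
        if self.channels.shape[1] < 2:
            raise ContractError("a trial needs at least 2 samples per channel")

    @property
    def n_samples(self) -> int:
        return self.channels.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate


class RotationSpec:
    """Per-placement 3x3 rotation matrices into the global frame.

    The same matrix is applied to the acceleration triad and the
    angular-velocity triad of its placement.  Matrices must be orthonormal
    with determinant +1 (tolerance 1e-6).
    """

    def __init__(self, matrices: dict[str, np.ndarray]):
        self.matrices: dict[str, np.ndarray] = {}
        for placement, mat in matrices.items():
            if placement not in PLACEMENTS:
                raise ContractError(f"unknown placement {placement!r}")
            mat = np.asarray(mat, dtype=float)
            if mat.shape != (3, 3):
                raise ContractError(f"rotation for {placement} must be 3x3")
            if not np.allclose(mat @ mat.T, np.eye(3), atol=1e-6):
                raise ContractError(f"rotation for {placement} is not orthonormal")
            if not np.isclose(np.linalg.det(mat), 1.0, atol=1e-6):
                raise ContractError(
                    f"rotation for {placement} must have determinant +1"
                )
            self.matrices[placement] = mat

    def __contains__(self, placement: str) -> bool:
        return placement in self.matrices

    def __getitem__(self, placement: str) -> np.ndarray:
        return self.matrices[placement]

    @classmethod
    def identity(cls, placements=PLACEMENTS) -> "RotationSpec":
        return cls({p: np.eye(3) for p in placements})


def to_global_frame(recording: TrialRecording, rotation: RotationSpec) -> TrialRecording:
    """Rotate a local-frame recording into the common global frame.

    Left-multiplies the acceleration triad and the angular-velocity triad by
    the placement's rotation matrix at every time point.  Per-sample triad
    norms are preserved (orthonormality).
    """
    if recording.frame != "local":
        raise ContractError(
            f"recording is already in frame {recording.frame!r}; expected 'local'"
        )
    if recording.placement not in rotation:
        raise ContractError(f"rotation spec lacks placement {recording.placement!r}")
    mat = rotation[recording.placement]
    out = np.empty_like(recording.channels)
    out[0:3] = mat @ recording.channels[0:3]
    out[3:6] = mat @ recording.channels[3:6]
    return replace(recording, channels=out, frame="global")


# ---------------------------------------------------------------------------
# trial files


def write_trial(recording: TrialRecording, path: str | Path) -> Path:
    """Write one trial file; creates parent directories as needed."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    buf = _io.StringIO()
    buf.write(f"# subject_id: {recording.subject_id}\n")
    buf.write(f"# task: {recording.task}\n")
    buf.write(f"# placement: {recording.placement}\n")
    buf.write(f"# sampling_rate: {recording.sampling_rate!r}\n")
    buf.write(f"# frame: {recording.frame}\n")
    buf.write(f"# units: {_HEADER_UNITS}\n")
    buf.write(",".join(CHANNELS) + "\n")
    cols = recording.channels.T
    for row in cols:
        buf.write(",".join(format(v, ".17g") for v in row) + "\n")
    path.write_text(buf.getvalue())
    return path


def _parse_header(path: Path) -> dict[str, str]:
    header: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if ":" in body:
                key, _, value = body.partition(":")
                header[key.strip()] = value.strip()
    return header


def read_trial(path: str | Path, manifest: pd.DataFrame | None = None) -> TrialRecording:
    """Read one trial file written by :func:`write_trial`.

    If a cohort ``manifest`` is given, the subject must appear in it.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"trial file {path} does not exist")
    header = _parse_header(path)
    for key in ("subject_id", "task", "placement", "sampling_rate", "frame"):
        if key not in header:
            raise FormatError(f"{path}: missing header key {key!r}")
    try:
        table = pd.read_csv(path, comment="#", float_precision="round_trip")
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise FormatError(f"{path}: unreadable data table ({exc})") from exc
    missing = [c for c in CHANNELS if c not in table.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    extra = [c for c in table.columns if c not in CHANNELS]
    if extra:
        raise FormatError(f"{path}: unexpected column(s) {extra}")
    data = table[list(CHANNELS)]
    bad = [c for c in CHANNELS if not np.issubdtype(data[c].dtype, np.number)]
    if not bad:
        bad = [c for c in CHANNELS if data[c].isna().any()]
    if bad:
        raise FormatError(f"{path}: non-numeric or missing samples in column {bad[0]!r}")
    if manifest is not None and header["subject_id"] not in set(manifest["subject_id"]):
        raise FormatError(
            f"{path}: subject {header['subject_id']!r} absent from manifest"
        )
    try:
        rate = float(header["sampling_rate"])
    except ValueError as exc:
        raise FormatError(f"{path}: bad sampling_rate {header['sampling_rate']!r}") from exc
    return TrialRecording(
        subject_id=header["subject_id"],
        task=header["task"],
        placement=header["placement"],
        sampling_rate=rate,
        channels=data.to_numpy(dtype=float).T,
        frame=header["frame"],
    )


# ---------------------------------------------------------------------------
# cohorts


def trial_filename(subject_id: str, task: str, placement: str) -> str:
    return f"{subject_id}__{task}__{placement}.csv"


@dataclass
class Cohort:
    """Subjects plus their trial recordings, keyed (subject_id, task, placement)."""

    subjects: list[Subject]
    trials: dict[tuple[str, str, str], TrialRecording] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [s.subject_id for s in self.subjects]
        if len(set(ids)) != len(ids):
            raise ContractError("subject_id values must be unique within a cohort")

    def subject(self, subject_id: str) -> Subject:
        for s in self.subjects:
            if s.subject_id == subject_id:
                return s
        raise ContractError(f"unknown subject {subject_id!r}")

    def group_of(self, subject_id: str) -> str:
        return self.subject(subject_id).group

    def subject_ids(self, group: str | None = None) -> list[str]:
        return [s.subject_id for s in self.subjects if group is None or s.group == group]

    def tasks(self) -> list[str]:
        return sorted({key[1] for key in self.trials})

    def trials_for(self, subject_id: str, task: str) -> dict[str, TrialRecording]:
        """All placements of one subject x task, keyed by placement."""
        return {
            placement: rec
            for (sid, tsk, placement), rec in self.trials.items()
            if sid == subject_id and tsk == task
        }

    def manifest_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": [s.subject_id for s in self.subjects],
                "group": [s.group for s in self.subjects],
                "age": [s.age for s in self.subjects],
                "sex": [s.sex for s in self.subjects],
            }
        )

    def write(self, directory: str | Path) -> Path:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.manifest_frame().to_csv(directory / "manifest.csv", index=False)
        for (sid, task, placement), rec in sorted(self.trials.items()):
            write_trial(rec, directory / trial_filename(sid, task, placement))
        return directory

    @classmethod
    def read(cls, directory: str | Path) -> "Cohort":
        directory = Path(directory)
        manifest_path = directory / "manifest.csv"
        if not manifest_path.exists():
            raise FormatError(f"{directory}: missing manifest.csv")
        manifest = pd.read_csv(manifest_path)
        needed = {"subject_id", "group", "age", "sex"}
        if not needed.issubset(manifest.columns):
            raise FormatError(
                f"{manifest_path}: manifest needs columns {sorted(needed)}"
            )
        subjects = [
            Subject(str(r.subject_id), str(r.group), float(r.age), str(r.sex))
            for r in manifest.itertuples()
        ]
        cohort = cls(subjects=subjects)
        for path in sorted(directory.glob("*__*__*.csv")):
            rec = read_trial(path, manifest)
            cohort.trials[(rec.subject_id, rec.task, rec.placement)] = rec
        return cohort


def validate_cohort(directory: str | Path) -> list[str]:
    """Check a cohort directory; returns a list of human-readable problems.

    An empty list means the cohort is internally consistent: manifest present,
    every trial readable, and all placements of one subject x task equal in
    length and sampling rate.
    """
    problems: list[str] = []
    try:
        cohort = Cohort.read(directory)
    except (FormatError, ContractError) as exc:
        return [str(exc)]
    for sid in cohort.subject_ids():
        for task in cohort.tasks():
            trials = cohort.trials_for(sid, task)
            if not trials:
                continue
            lengths = {rec.n_samples for rec in trials.values()}
            if len(lengths) > 1:
                problems.append(
                    f"subject {sid} task {task}: trial lengths differ {sorted(lengths)}"
                )
            rates = {rec.sampling_rate for rec in trials.values()}
            if len(rates) > 1:
                problems.append(
                    f"subject {sid} task {task}: sampling rates differ {sorted(rates)}"
                )
            if SEGMENTATION_PLACEMENT not in trials:
                problems.append(
                    f"subject {sid} task {task}: missing {SEGMENTATION_PLACEMENT} "
                    "(segmentation sensor)"
                )
    return problems
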