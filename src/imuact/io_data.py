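"""Recording I/O, trimming, and the activity-code → class mapping.

A *recording* is one continuous 30 Hz capture of 6-axis motion data
(3-axis user acceleration in g, 3-axis rotation rate in rad/s) for one
participant performing one activity.  Recordings live on disk as plain
comma-separated files with a header row ``t,ax,ay,az,gx,gy,gz``; a
*manifest* (one row per recording: path, participant, activity code,
device placement) assembles a dataset without relying on directory
naming conventions.

Thirteen activity codes (A1–A13) collapse onto nine evaluation classes
(C1–C9): prescribed treadmill and self-paced versions of the same
movement share a class, e.g. 3.0 mph treadmill walking (A2) and 400 m
self-paced normal walking (A11) are both "normal walking" (C2).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("imuact")

__all__ = [
    "ACTIVITY_TO_CLASS",
    "CLASS_ORDER",
    "CLASS_NAMES",
    "JOGGING_CODES",
    "PLACEMENTS",
    "ImuRecording",
    "activity_to_class",
    "read_recording",
    "write_recording",
    "trim_recording",
    "read_manifest",
    "write_manifest",
    "load_recordings",
]

#: Activity code -> evaluation class.  Prescribed treadmill activities
#: A1-A4 and their self-paced counterparts A10-A13 share classes C1-C4;
#: sitting and the four stair activities map one-to-one onto C5-C9.
ACTIVITY_TO_CLASS: dict[str, str] = {
    "A1": "C1",
    "A2": "C2",
    "A3": "C3",
    "A4": "C4",
    "A5": "C5",
    "A6": "C6",
    "A7": "C7",
    "A8": "C8",
    "A9": "C9",
    "A10": "C1",
    "A11": "C2",
    "A12": "C3",
    "A13": "C4",
}

#: Canonical class order used by every confusion matrix and report.
CLASS_ORDER: tuple[str, ...] = (
    "C1", "C2", "C3", "C4", "C5", "C6", "C7", "C8", "C9",
)

CLASS_NAMES: dict[str, str] = {
    "C1": "Slow walking",
    "C2": "Normal walking",
    "C3": "Brisk walking",
    "C4": "Jogging",
    "C5": "Sitting",
    "C6": "Normal upstairs",
    "C7": "Normal downstairs",
    "C8": "Brisk upstairs",
    "C9": "Brisk downstairs",
}

#: Jogging activities are carried in an armband; everything else rides
#: in a front shorts pocket.
JOGGING_CODES: frozenset[str] = frozenset({"A4", "A13"})
PLACEMENTS: tuple[str, str] = ("pocket", "armband")

_COLUMNS = ("t", "ax", "ay", "az", "gx", "gy", "gz")


@dataclass
class ImuRecording:
    """A labeled 6-axis motion recording.

    Channels are stored column-wise: ``accel`` and ``gyro`` are
    ``(n, 3)`` float arrays (g and rad/s respectively), ``t`` the
    per-sample timestamps in seconds from recording start.
    """

    participant_id: str
    activity_code: str
    t: np.ndarray
    accel: np.ndarray
    gyro: np.ndarray
    placement: str = "pocket"
    sample_rate: float = 30.0

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.accel = np.asarray(self.accel, dtype=float)
        self.gyro = np.asarray(self.gyro, dtype=float)
        if self.activity_code not in ACTIVITY_TO_CLASS:
            raise ValueError(f"unknown activity code {self.activity_code!r}")
        if self.placement not in PLACEMENTS:
            raise ValueError(f"placement must be one of {PLACEMENTS}")
        n = len(self.t)
        if self.accel.shape != (n, 3) or self.gyro.shape != (n, 3):
            raise ValueError("accel and gyro must both have shape (n, 3)")
        if n and self.t[0] < 0:
            raise ValueError("timestamps must be non-negative")
        if n > 1 and not np.all(np.diff(self.t) > 0):
            raise ValueError("timestamps must be strictly increasing")
        for name, arr in (("t", self.t), ("accel", self.accel), ("gyro", self.gyro)):
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"non-finite values in {name}")
        if n > 1:
            gaps = np.diff(self.t)
            if np.any(gaps > 2.0 / self.sample_rate):
                logger.warning(
                    "recording %s/%s has %d inter-sample gap(s) > 2 sample periods",
                    self.participant_id,
                    self.activity_code,
                    int(np.sum(gaps > 2.0 / self.sample_rate)),
                )

    @property
    def n_samples(self) -> int:
        return len(self.t)

    @property
    def duration(self) -> float:
        """Elapsed time in seconds between first and last sample."""
        if self.n_samples < 2:
            return 0.0
        return float(self.t[-1] - self.t[0])

    @property
    def class_id(self) -> str:
        return ACTIVITY_TO_CLASS[self.activity_code]


def activity_to_class(activity_code: str) -> str:
    """Map an activity code (A1–A13) to its evaluation class (C1–C9)."""
    try:
        return ACTIVITY_TO_CLASS[activity_code]
    except KeyError:
        raise ValueError(f"unknown activity code {activity_code!r}") from None


def read_recording(
    path: str | Path,
    participant_id: str,
    activity_code: str,
    placement: str = "pocket",
    sample_rate: float = 30.0,
) -> ImuRecording:
    """Read one comma-separated recording file.

    The file must carry the header ``t,ax,ay,az,gx,gy,gz``.  Malformed
    rows (non-numeric or non-finite fields) raise with the offending
    row number rather than being skipped.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frame = pd.read_csv(path, float_precision="round_trip")
    if tuple(frame.columns) != _COLUMNS:
        raise ValueError(
            f"{path}: expected columns {','.join(_COLUMNS)}, got {','.join(frame.columns)}"
        )
    values = frame.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    bad = ~np.all(np.isfinite(values), axis=1)
    if np.any(bad):
        # +2: one for the header line, one for 1-based numbering
        rows = ", ".join(str(i + 2) for i in np.flatnonzero(bad)[:5])
        raise ValueError(f"{path}: non-numeric or non-finite field(s) in row(s) {rows}")
    return ImuRecording(
        participant_id=participant_id,
        activity_code=activity_code,
        t=values[:, 0],
        accel=values[:, 1:4],
        gyro=values[:, 4:7],
        placement=placement,
        sample_rate=sample_rate,
    )


def write_recording(recording: ImuRecording, path: str | Path) -> Path:
    """Write a recording to ``path``; read_recording round-trips it exactly.

    Floats are written with 17 significant digits, enough to reproduce
    every IEEE double bit-for-bit.
    """
    if recording.n_samples == 0:
        raise ValueError("refusing to write a recording with no samples")
    path = Path(path)
    data = np.column_stack([recording.t, recording.accel, recording.gyro])
    frame = pd.DataFrame(data, columns=list(_COLUMNS))
    frame.to_csv(path, index=False, float_format="%.17g")
    return path


def trim_recording(
    recording: ImuRecording, head_s: float = 2.0, tail_s: float = 2.0
) -> ImuRecording:
    """Drop ``head_s`` seconds from the start and ``tail_s`` from the end.

    Emulates the manual removal of handling artifacts (pressing the
    record button, pocketing and retrieving the device) at both ends of
    a capture.  Remaining timestamps are re-zeroed to start at 0.
    """
    if head_s < 0 or tail_s < 0:
        raise ValueError("trim durations must be non-negative")
    dur = recording.duration
    if head_s + tail_s >= dur and (head_s + tail_s) > 0:
        raise ValueError(
            f"cannot trim {head_s}+{tail_s} s from a {dur:.3f} s recording"
        )
    rel = recording.t - recording.t[0]
    keep = (rel >= head_s) & (rel <= dur - tail_s)
    t = recording.t[keep]
    return replace(
        recording,
        t=t - t[0],
        accel=recording.accel[keep],
        gyro=recording.gyro[keep],
    )


def write_manifest(rows: list[dict], path: str | Path) -> Path:
    """Write a dataset manifest (path, participant_id, activity_code, placement)."""
    path = Path(path)
    frame = pd.DataFrame(rows, columns=["path", "participant_id", "activity_code", "placement"])
    frame.to_csv(path, index=False)
    return path


def read_manifest(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frame = pd.read_csv(path, dtype=str)
    expected = ["path", "participant_id", "activity_code", "placement"]
    if list(frame.columns) != expected:
        raise ValueError(f"{path}: manifest needs columns {expected}")
    return frame


def load_recordings(manifest_path: str | Path, sample_rate: float = 30.0) -> list[ImuRecording]:
    """Load every recording listed in a manifest (paths relative to it)."""
    manifest_path = Path(manifest_path)
    frame = read_manifest(manifest_path)
    recs = []
    for row in frame.itertuples(index=False):
        rec_path = Path(row.path)
        if not rec_path.is_absolute():
            rec_path = manifest_path.parent / rec_path
        recs.append(
            read_recording(
                rec_path, row.participant_id, row.activity_code, row.placement, sample_rate
            )
        )
    logger.info("loaded %d recordings from %s", len(recs), manifest_path)
    return recs
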