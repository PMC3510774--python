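"""Sliding-window segmentation and time/frequency feature extraction.

Features are computed per window, not per sample, to suppress noise and
capture the cyclic structure of gait.  The default window is 2 s
(60 samples at 30 Hz) with 50% overlap; 1, 5 and 10 s windows are
supported for the window-size comparison, all at 50% overlap.

Per window the feature vector holds, in fixed order:

* mean of each acceleration axis, each rotation-rate axis, and of the
  acceleration magnitude √(ax²+ay²+az²);
* sample standard deviation of the same seven channels;
* sum of the acceleration magnitude over the window;
* magnitude of the first five discrete-Fourier-transform coefficients
  of each acceleration axis (indices 1–5; the DC term is excluded
  because the window mean is already a feature, switchable via
  ``include_dc``).

In ``accel_gyro`` mode that is 30 features; ``accel_only`` drops the six
gyroscope-derived entries, leaving 24.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io_data import CLASS_ORDER, ImuRecording

logger = logging.getLogger("imuact")

__all__ = [
    "SENSOR_MODES",
    "WindowSpec",
    "Window",
    "LabeledDataset",
    "feature_names",
    "slide_windows",
    "accel_magnitude",
    "fft_magnitudes",
    "window_features",
    "build_dataset",
]

SENSOR_MODES = ("accel_only", "accel_gyro")
_ACCEL_AXES = ("ax", "ay", "az")
_GYRO_AXES = ("gx", "gy", "gz")
N_FFT_COEFFS = 5


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window geometry: size, overlap fraction, and sample rate."""

    size_s: float = 2.0
    overlap_fraction: float = 0.5
    sample_rate: float = 30.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.overlap_fraction < 1.0):
            raise ValueError("overlap_fraction must be in [0, 1)")
        size = self.size_s * self.sample_rate
        if size <= 0 or abs(size - round(size)) > 1e-9:
            raise ValueError(
                f"window of {self.size_s} s at {self.sample_rate} Hz is not a whole "
                "number of samples"
            )
        if self.step_samples < 1:
            raise ValueError("window step must be at least one sample")

    @property
    def size_samples(self) -> int:
        return int(round(self.size_s * self.sample_rate))

    @property
    def step_samples(self) -> int:
        return int(round(self.size_samples * (1.0 - self.overlap_fraction)))

    def n_windows(self, n_samples: int) -> int:
        """⌊(n − size)/step⌋ + 1 full windows fit in ``n_samples``."""
        if n_samples < self.size_samples:
            return 0
        return (n_samples - self.size_samples) // self.step_samples + 1


@dataclass
class Window:
    """One full-length window of contiguous samples from a recording."""

    recording_id: str
    participant_id: str
    class_id: str
    start: int
    accel: np.ndarray  # (size, 3)
    gyro: np.ndarray  # (size, 3)


def slide_windows(recording: ImuRecording, spec: WindowSpec) -> list[Window]:
    """Segment a recording into overlapping full windows.

    Windows start at sample offsets 0, step, 2·step, …; a trailing
    partial window is discarded rather than padded.
    """
    n = recording.n_samples
    size, step = spec.size_samples, spec.step_samples
    if n < size:
        raise ValueError(
            f"recording {recording.participant_id}/{recording.activity_code} has "
            f"{n} samples, shorter than one {size}-sample window"
        )
    rec_id = f"{recording.participant_id}/{recording.activity_code}"
    windows = []
    for start in range(0, n - size + 1, step):
        windows.append(
            Window(
                recording_id=rec_id,
                participant_id=recording.participant_id,
                class_id=recording.class_id,
                start=start,
                accel=recording.accel[start : start + size],
                gyro=recording.gyro[start : start + size],
            )
        )
    return windows


def accel_magnitude(accel: Sequence[float] | np.ndarray) -> float | np.ndarray:
    """Euclidean norm √(ax²+ay²+az²) of one sample or of each row of (n, 3)."""
    arr = np.asarray(accel, dtype=float)
    return np.sqrt(np.sum(arr**2, axis=-1))


def fft_magnitudes(
    signal: np.ndarray, n_coeffs: int = N_FFT_COEFFS, include_dc: bool = False
) -> np.ndarray:
    """Magnitude of the first ``n_coeffs`` DFT power-spectrum coefficients.

    Returns |X_k| for k = 1…n_coeffs (or 0…n_coeffs−1 with
    ``include_dc``), where X_k = Σ_t x_t e^(−2πi·k·t/N).  No detrending,
    taper, or zero-padding is applied.
    """
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1:
        raise ValueError("signal must be one-dimensional")
    if len(x) < 2 * n_coeffs:
        raise ValueError(f"need at least {2 * n_coeffs} samples, got {len(x)}")
    spectrum = np.abs(np.fft.rfft(x))
    start = 0 if include_dc else 1
    return spectrum[start : start + n_coeffs]


def feature_names(mode: str = "accel_gyro", include_dc: bool = False) -> list[str]:
    """Ordered feature names for a sensor mode."""
    if mode not in SENSOR_MODES:
        raise ValueError(f"mode must be one of {SENSOR_MODES}")
    chans = _ACCEL_AXES + (_GYRO_AXES if mode == "accel_gyro" else ()) + ("mag",)
    names = [f"mean_{c}" for c in chans]
    names += [f"sd_{c}" for c in chans]
    names += ["sum_mag"]
    k0 = 0 if include_dc else 1
    for axis in _ACCEL_AXES:
        names += [f"fftmag_{axis}_{k}" for k in range(k0, k0 + N_FFT_COEFFS)]
    return names


def _feature_block(
    accel: np.ndarray, gyro: np.ndarray, mode: str, include_dc: bool
) -> np.ndarray:
    """Feature matrix for a batch of windows: accel/gyro are (w, size, 3)."""
    mag = np.sqrt(np.sum(accel**2, axis=2))  # (w, size)
    if mode == "accel_gyro":
        chans = np.concatenate([accel, gyro, mag[:, :, None]], axis=2)
    else:
        chans = np.concatenate([accel, mag[:, :, None]], axis=2)
    means = chans.mean(axis=1)
    sds = chans.std(axis=1, ddof=1)
    sum_mag = mag.sum(axis=1)[:, None]
    spectra = np.abs(np.fft.rfft(accel, axis=1))  # (w, size//2+1, 3)
    start = 0 if include_dc else 1
    ffts = spectra[:, start : start + N_FFT_COEFFS, :]  # (w, 5, 3)
    ffts = np.transpose(ffts, (0, 2, 1)).reshape(len(accel), 3 * N_FFT_COEFFS)
    return np.hstack([means, sds, sum_mag, ffts])


def window_features(
    window: Window, mode: str = "accel_gyro", include_dc: bool = False
) -> np.ndarray:
    """Feature vector for one window, in the fixed `feature_names` order."""
    if mode not in SENSOR_MODES:
        raise ValueError(f"mode must be one of {SENSOR_MODES}")
    return _feature_block(
        window.accel[None, :, :], window.gyro[None, :, :], mode, include_dc
    )[0]


@dataclass
class LabeledDataset:
    """Feature matrix with class labels and participant group ids.

    ``X`` is (n_windows, n_features); ``y`` holds class ids C1–C9 and
    ``groups`` the participant each window came from.
    """

    X: np.ndarray
    y: np.ndarray
    groups: np.ndarray
    feature_names: list[str]
    sensor_mode: str
    window: WindowSpec

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=object)
        self.groups = np.asarray(self.groups, dtype=object)
        if not (len(self.X) == len(self.y) == len(self.groups)):
            raise ValueError("X, y and groups must align")
        if self.X.shape[1] != len(self.feature_names):
            raise ValueError("feature_names must match X's columns")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("feature matrix contains non-finite values")

    def __len__(self) -> int:
        return len(self.X)

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def restrict_to_accel_only(self) -> "LabeledDataset":
        """Project an accel_gyro dataset onto the accel_only feature set."""
        if self.sensor_mode == "accel_only":
            return self
        keep_names = feature_names("accel_only")
        idx = [self.feature_names.index(name) for name in keep_names]
        return LabeledDataset(
            X=self.X[:, idx],
            y=self.y.copy(),
            groups=self.groups.copy(),
            feature_names=keep_names,
            sensor_mode="accel_only",
            window=self.window,
        )

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.X, columns=self.feature_names)
        frame["label"] = self.y
        frame["group"] = self.groups
        return frame

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_frame().to_csv(path, index=False, float_format="%.17g")
        return path

    @classmethod
    def from_csv(
        cls, path: str | Path, window: WindowSpec | None = None
    ) -> "LabeledDataset":
        frame = pd.read_csv(path, float_precision="round_trip")
        if "label" not in frame.columns or "group" not in frame.columns:
            raise ValueError(f"{path}: feature table needs 'label' and 'group' columns")
        names = [c for c in frame.columns if c not in ("label", "group")]
        mode = "accel_gyro" if "mean_gx" in names else "accel_only"
        return cls(
            X=frame[names].to_numpy(dtype=float),
            y=frame["label"].to_numpy(),
            groups=frame["group"].to_numpy(),
            feature_names=names,
            sensor_mode=mode,
            window=window or WindowSpec(),
        )


def build_dataset(
    recordings: Iterable[ImuRecording],
    spec: WindowSpec | None = None,
    mode: str = "accel_gyro",
    include_dc: bool = False,
) -> LabeledDataset:
    """Window every recording and stack the per-window feature vectors."""
    recordings = list(recordings)
    if not recordings:
        raise ValueError("no recordings given")
    rates = {rec.sample_rate for rec in recordings}
    if len(rates) > 1:
        raise ValueError(f"mixed sample rates: {sorted(rates)}")
    spec = spec or WindowSpec(sample_rate=recordings[0].sample_rate)
    if spec.sample_rate != recordings[0].sample_rate:
        raise ValueError("window spec sample rate does not match the recordings")

    blocks, labels, groups = [], [], []
    size, step = spec.size_samples, spec.step_samples
    for rec in recordings:
        n_win = spec.n_windows(rec.n_samples)
        if n_win == 0:
            raise ValueError(
                f"recording {rec.participant_id}/{rec.activity_code} is shorter "
                f"than one {spec.size_s} s window"
            )
        starts = np.arange(n_win) * step
        accel = np.stack([rec.accel[s : s + size] for s in starts])
        gyro = np.stack([rec.gyro[s : s + size] for s in starts])
        blocks.append(_feature_block(accel, gyro, mode, include_dc))
        labels.extend([rec.class_id] * n_win)
        groups.extend([rec.participant_id] * n_win)

    dataset = LabeledDataset(
        X=np.vstack(blocks),
        y=np.array(labels, dtype=object),
        groups=np.array(groups, dtype=object),
        feature_names=feature_names(mode, include_dc),
        sensor_mode=mode,
        window=spec,
    )
    logger.info(
        "built dataset: %d windows x %d features from %d recordings (%s)",
        len(dataset), dataset.n_features, len(recordings), mode,
    )
    return dataset
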