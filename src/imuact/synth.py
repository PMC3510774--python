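"""Synthetic 6-axis gait signal generator.

Emulates the statistical structure of pocket-carried smartphone motion
data across the nine activity classes: each cyclic activity is a sum of
per-axis sinusoids at a class-specific stride cadence plus two weaker
harmonics, with independent Gaussian sensor noise; sitting is noise
only.  Subject-to-subject variability enters through per-subject
amplitude and cadence multipliers and per-axis phase offsets; the
armband placement used for jogging is modeled as a fixed axis
permutation plus a small amplitude rescale relative to the pocket.

Two structural choices make the generator exercise the downstream
analysis the way real data would:

* walking-speed classes (slow/normal/brisk walk, jog) are ordered in
  both cadence and amplitude, so signal energy tracks activity
  intensity;
* each stair class shares its acceleration parameters exactly with its
  paired stair class (up vs down at the same pace) and sits close to a
  level-walking class, while its rotation-rate signature is
  distinctive — accelerometer-only features therefore confuse stairs
  with level walking and up with down, and adding the gyroscope
  recovers them.

The generator makes no claim to biomechanical realism; see the methods
note for what it does and does not emulate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io_data import CLASS_ORDER, ImuRecording, JOGGING_CODES, write_manifest, write_recording

__all__ = [
    "ActivityClassSpec",
    "SubjectProfile",
    "SynthConfig",
    "DEFAULT_CLASS_SPECS",
    "default_class_specs",
    "make_subject_profiles",
    "generate_recording",
    "generate_dataset",
    "write_dataset",
]

#: Canonical activity code used when synthesizing one recording per class.
CLASS_TO_CODE = {f"C{i}": f"A{i}" for i in range(1, 10)}

#: Fixed per-axis phase offsets (rad) so the three axes are not collinear.
_AXIS_PHASES = np.array([0.0, 2.0 * np.pi / 3.0, 4.0 * np.pi / 3.0])

#: Armband placement: fixed axis permutation and amplitude rescale
#: applied to both sensors, relative to the pocket orientation.
_ARMBAND_PERM = (1, 2, 0)
_ARMBAND_SCALE = 1.1


@dataclass(frozen=True)
class ActivityClassSpec:
    """Parametric description of one simulated activity class.

    Parameters
    ----------
    cadence_hz
        Fundamental stride frequency in Hz (0 for sitting).  Must lie
        below the Nyquist frequency of the target sample rate.
    accel_amp
        Per-axis fundamental acceleration amplitude, g.
    harmonic_amps
        Amplitudes of harmonics 2 and 3 as fractions of the fundamental.
    gyro_amp
        Per-axis fundamental rotation-rate amplitude, rad/s.
    noise_sd_accel, noise_sd_gyro
        Standard deviation of the additive white Gaussian sensor noise.
    vertical_bias
        Extra fundamental amplitude on the gravity-aligned axis (az),
        g; nonzero for stair classes, where vertical excursion exceeds
        that of level walking at a comparable cadence.
    """

    class_id: str
    cadence_hz: float
    accel_amp: tuple[float, float, float]
    harmonic_amps: tuple[float, float] = (0.5, 0.25)
    gyro_amp: tuple[float, float, float] = (0.0, 0.0, 0.0)
    noise_sd_accel: float = 0.04
    noise_sd_gyro: float = 0.08
    vertical_bias: float = 0.0

    def __post_init__(self) -> None:
        if self.class_id not in CLASS_ORDER:
            raise ValueError(f"unknown class {self.class_id!r}")
        if self.cadence_hz < 0:
            raise ValueError("cadence_hz must be >= 0")
        if min(self.accel_amp) < 0 or min(self.gyro_amp) < 0:
            raise ValueError("amplitudes must be non-negative")
        if self.noise_sd_accel < 0 or self.noise_sd_gyro < 0:
            raise ValueError("noise SDs must be non-negative")


def default_class_specs(
    noise_sd_accel: float = 0.04, noise_sd_gyro: float = 0.08
) -> dict[str, ActivityClassSpec]:
    """Default parametric specs for the nine classes.

    Cadences (1.4 / 1.9 / 2.3 / 2.7 Hz for slow walk → jog, 1.6 / 2.0 Hz
    for normal / brisk stairs) are plausible stride rates, strictly
    ordered by pace and all well below the 15 Hz Nyquist limit of 30 Hz
    sampling.  Acceleration amplitudes rise with intensity so that
    acceleration-magnitude RMS orders sitting < slow < normal < brisk
    walking < jogging.  The up/down stair pairs (C6/C7, C8/C9) share
    identical acceleration parameters and differ only in rotation-rate
    signature.
    """

    def spec(cid, f, aamp, gamp, vbias=0.0, nsa=None, nsg=None):
        return ActivityClassSpec(
            class_id=cid,
            cadence_hz=f,
            accel_amp=aamp,
            gyro_amp=gamp,
            vertical_bias=vbias,
            noise_sd_accel=noise_sd_accel if nsa is None else nsa,
            noise_sd_gyro=noise_sd_gyro if nsg is None else nsg,
        )

    return {
        "C1": spec("C1", 1.4, (0.10, 0.12, 0.18), (0.50, 0.40, 0.30)),
        "C2": spec("C2", 1.9, (0.16, 0.18, 0.30), (0.70, 0.55, 0.40)),
        "C3": spec("C3", 2.3, (0.24, 0.26, 0.45), (0.90, 0.70, 0.50)),
        "C4": spec("C4", 2.7, (0.38, 0.40, 0.70), (1.30, 1.00, 0.70)),
        "C5": spec("C5", 0.0, (0.0, 0.0, 0.0), (0.0, 0.0, 0.0),
                   nsa=0.01, nsg=0.02),
        "C6": spec("C6", 1.6, (0.12, 0.14, 0.20), (1.10, 0.30, 0.60), vbias=0.06),
        "C7": spec("C7", 1.6, (0.12, 0.14, 0.20), (0.30, 1.10, 0.90), vbias=0.06),
        "C8": spec("C8", 2.0, (0.18, 0.20, 0.30), (1.50, 0.40, 0.80), vbias=0.08),
        "C9": spec("C9", 2.0, (0.18, 0.20, 0.30), (0.40, 1.50, 1.20), vbias=0.08),
    }


DEFAULT_CLASS_SPECS = default_class_specs()


@dataclass(frozen=True)
class SubjectProfile:
    """Per-subject gait idiosyncrasy: amplitude/cadence scaling and phase."""

    subject_id: str
    amp_multiplier: float = 1.0
    cadence_multiplier: float = 1.0
    phase_offsets: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.amp_multiplier <= 0 or self.cadence_multiplier <= 0:
            raise ValueError("subject multipliers must be positive")


@dataclass
class SynthConfig:
    """Configuration for a full synthetic data collection.

    Defaults mirror the emulated study: 16 subjects, one recording per
    class per subject, sampled at 30 Hz.  60 s per recording keeps every
    window size in the 1–10 s comparison well represented while staying
    far smaller than the multi-minute originals.
    """

    sample_rate: float = 30.0
    duration_s: float = 60.0
    n_subjects: int = 16
    n_repeats: int = 1
    seed: int = 0
    subject_range: tuple[float, float] = (0.8, 1.2)
    class_specs: dict[str, ActivityClassSpec] = field(
        default_factory=default_class_specs
    )

    def __post_init__(self) -> None:
        if set(self.class_specs) != set(CLASS_ORDER):
            raise ValueError("class_specs must cover exactly C1..C9")
        if self.duration_s * self.sample_rate < 30:
            raise ValueError("recordings must cover at least one 1 s window")
        if self.n_subjects < 1 or self.n_repeats < 1:
            raise ValueError("n_subjects and n_repeats must be >= 1")


def make_subject_profiles(config: SynthConfig) -> list[SubjectProfile]:
    """Draw per-subject multipliers and phases from the master seed."""
    rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(0,)))
    lo, hi = config.subject_range
    profiles = []
    for i in range(config.n_subjects):
        profiles.append(
            SubjectProfile(
                subject_id=f"S{i + 1:02d}",
                amp_multiplier=float(rng.uniform(lo, hi)),
                cadence_multiplier=float(rng.uniform(lo, hi)),
                phase_offsets=tuple(rng.uniform(0.0, 2.0 * np.pi, size=3)),
            )
        )
    return profiles


def _cyclic_channels(
    t: np.ndarray,
    amps: np.ndarray,
    harmonics: tuple[float, ...],
    freq: float,
    phases: np.ndarray,
) -> np.ndarray:
    """Sum of harmonics h=1..H per axis: amp_ax * frac_h * sin(2π h f t + φ_ax)."""
    out = np.zeros((len(t), 3))
    if freq <= 0:
        return out
    fracs = (1.0,) + tuple(harmonics)
    for h, frac in enumerate(fracs, start=1):
        phase = phases[None, :] + (h - 1) * 0.4  # de-align harmonics slightly
        out += (amps[None, :] * frac) * np.sin(
            2.0 * np.pi * h * freq * t[:, None] + phase
        )
    return out


def generate_recording(
    spec: ActivityClassSpec,
    subject: SubjectProfile,
    duration_s: float,
    seed: int | np.random.SeedSequence = 0,
    sample_rate: float = 30.0,
    placement: str | None = None,
) -> ImuRecording:
    """Generate one labeled recording for (class spec, subject).

    Deterministic given ``(spec, subject, seed)``.  The activity code is
    the canonical prescribed code for the class (C4 → A4), so jogging
    recordings default to the armband placement.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    freq = spec.cadence_hz * subject.cadence_multiplier
    if freq >= sample_rate / 2.0:
        raise ValueError(
            f"cadence {freq:.2f} Hz is at or above Nyquist ({sample_rate / 2:.1f} Hz)"
        )
    n = int(np.floor(duration_s * sample_rate))
    t = np.arange(n) / sample_rate
    rng = np.random.default_rng(seed)

    accel_amp = np.array(spec.accel_amp) * subject.amp_multiplier
    accel_amp[2] += spec.vertical_bias * subject.amp_multiplier
    gyro_amp = np.array(spec.gyro_amp) * subject.amp_multiplier
    phases = _AXIS_PHASES + np.array(subject.phase_offsets)

    accel = _cyclic_channels(t, accel_amp, spec.harmonic_amps, freq, phases)
    # rotation lags acceleration by a quarter cycle
    gyro = _cyclic_channels(t, gyro_amp, spec.harmonic_amps, freq, phases + np.pi / 2)
    accel += rng.normal(0.0, spec.noise_sd_accel, size=accel.shape)
    gyro += rng.normal(0.0, spec.noise_sd_gyro, size=gyro.shape)

    code = CLASS_TO_CODE[spec.class_id]
    if placement is None:
        placement = "armband" if code in JOGGING_CODES else "pocket"
    if placement == "armband":
        accel = accel[:, _ARMBAND_PERM] * _ARMBAND_SCALE
        gyro = gyro[:, _ARMBAND_PERM] * _ARMBAND_SCALE

    return ImuRecording(
        participant_id=subject.subject_id,
        activity_code=code,
        t=t,
        accel=accel,
        gyro=gyro,
        placement=placement,
        sample_rate=sample_rate,
    )


def generate_dataset(config: SynthConfig) -> list[ImuRecording]:
    """Generate ``n_subjects × 9 classes × n_repeats`` recordings.

    Each recording's noise stream is seeded from the master seed via
    ``SeedSequence(seed, spawn_key=(1, subject, class, repeat))``, so any
    single recording can be regenerated in isolation and generation
    order is immaterial.
    """
    profiles = make_subject_profiles(config)
    recordings = []
    for si, subject in enumerate(profiles):
        for ci, class_id in enumerate(CLASS_ORDER):
            for ri in range(config.n_repeats):
                seed = np.random.SeedSequence(config.seed, spawn_key=(1, si, ci, ri))
                recordings.append(
                    generate_recording(
                        config.class_specs[class_id],
                        subject,
                        config.duration_s,
                        seed=seed,
                        sample_rate=config.sample_rate,
                    )
                )
    return recordings


def write_dataset(config: SynthConfig, out_dir: str | Path) -> Path:
    """Generate a dataset and write recordings + manifest under ``out_dir``.

    Returns the manifest path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, rec in enumerate(generate_dataset(config)):
        name = f"{rec.participant_id}_{rec.activity_code}_{i:03d}.csv"
        write_recording(rec, out_dir / name)
        rows.append(
            {
                "path": name,
                "participant_id": rec.participant_id,
                "activity_code": rec.activity_code,
                "placement": rec.placement,
            }
        )
    return write_manifest(rows, out_dir / "manifest.csv")
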