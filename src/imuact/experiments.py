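"""End-to-end experiment drivers: classifier evaluation, window-size
comparison, and the gyroscope ablation, on synthetic or manifest data.

Each run is driven by a single :class:`ExperimentConfig` (loadable from
YAML), writes its artifacts under an output directory, and leaves a run
manifest (config hash, master seed, package version) sufficient to
reproduce it exactly.  Partial outputs are removed if a run fails.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from dataclasses import replace as dataclasses_replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .evaluate import (
    CVConfig,
    MetricsReport,
    ablation_delta,
    assign_folds,
    cross_validate,
    load_reference_confusion,
    round_half_up,
    weighted_average_accuracy,
)
from .features import WindowSpec, build_dataset
from .io_data import CLASS_ORDER, load_recordings
from .synth import ActivityClassSpec, SynthConfig, default_class_specs, generate_dataset

logger = logging.getLogger("imuact")

__all__ = [
    "ExperimentConfig",
    "run_classifier_eval",
    "run_window_size_experiment",
    "run_sensor_ablation",
    "replay_reference",
]


@dataclass
class ExperimentConfig:
    """Everything one experiment needs, including its random seed."""

    synth: SynthConfig = field(default_factory=SynthConfig)
    manifest: str | None = None  # when set, real recordings replace synthesis
    window_size_s: float = 2.0
    overlap_fraction: float = 0.5
    window_sizes_s: tuple[float, ...] = (1.0, 2.0, 5.0, 10.0)
    sensor_modes: tuple[str, ...] = ("accel_only", "accel_gyro")
    knn_k: int = 1
    cv: CVConfig = field(default_factory=CVConfig)
    out_dir: str = "imuact_out"
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.sensor_modes:
            raise ValueError("need at least one sensor mode")
        if len(self.window_sizes_s) < 1:
            raise ValueError("need at least one window size")
        # the master seed flows into sub-configs left at their default
        if self.seed != 0:
            if self.synth.seed == 0:
                self.synth.seed = self.seed
            if self.cv.seed == 0:
                self.cv = dataclasses_replace(self.cv, seed=self.seed)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "ExperimentConfig":
        raw = dict(raw)
        seed = int(raw.get("seed", 0))
        synth_raw = dict(raw.pop("synth", {}))
        specs_raw = synth_raw.pop("class_specs", None)
        synth_raw.setdefault("seed", seed)
        synth = SynthConfig(**synth_raw)
        if specs_raw:
            specs = dict(synth.class_specs)
            for cid, spec_kw in specs_raw.items():
                kw = dict(spec_kw)
                for key in ("accel_amp", "gyro_amp", "harmonic_amps"):
                    if key in kw:
                        kw[key] = tuple(kw[key])
                specs[cid] = ActivityClassSpec(class_id=cid, **kw)
            synth.class_specs = specs
        cv = CVConfig(**{**{"seed": seed}, **raw.pop("cv", {})})
        known = {
            "manifest", "window_size_s", "overlap_fraction", "window_sizes_s",
            "sensor_modes", "knn_k", "out_dir", "seed",
        }
        kwargs = {k: v for k, v in raw.items() if k in known}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "window_sizes_s" in kwargs:
            kwargs["window_sizes_s"] = tuple(float(v) for v in kwargs["window_sizes_s"])
        if "sensor_modes" in kwargs:
            kwargs["sensor_modes"] = tuple(kwargs["sensor_modes"])
        return cls(synth=synth, cv=cv, **kwargs)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["synth"]["class_specs"] = {
            cid: asdict(s) for cid, s in self.synth.class_specs.items()
        }
        return d

    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _load_dataset(config: ExperimentConfig, size_s: float, mode: str):
    spec = WindowSpec(
        size_s=size_s,
        overlap_fraction=config.overlap_fraction,
        sample_rate=config.synth.sample_rate,
    )
    if config.manifest:
        recordings = load_recordings(config.manifest, config.synth.sample_rate)
    else:
        recordings = generate_dataset(config.synth)
    return build_dataset(recordings, spec, mode)


def _write_run_manifest(config: ExperimentConfig, out_dir: Path, experiment: str) -> None:
    manifest = {
        "experiment": experiment,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "package_version": __version__,
        "config": config.to_dict(),
    }
    (out_dir / "run_manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n"
    )


def _run_to_dir(config: ExperimentConfig, experiment: str, worker):
    """Run ``worker(out_dir)``, removing partial outputs on failure."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        result = worker(out_dir, written)
        _write_run_manifest(config, out_dir, experiment)
        return result
    except Exception:
        for path in written:
            path.unlink(missing_ok=True)
        raise


def run_classifier_eval(config: ExperimentConfig, mode: str = "accel_gyro") -> MetricsReport:
    """Build the dataset, run cross-validated kNN, write report + matrix."""

    def worker(out_dir: Path, written: list[Path]) -> MetricsReport:
        dataset = _load_dataset(config, config.window_size_s, mode)
        matrix = cross_validate(dataset, "knn", k=config.knn_k, config=config.cv)
        report = MetricsReport.from_matrix(
            matrix,
            config={
                "experiment": "classifier_eval",
                "sensor_mode": mode,
                "window_size_s": config.window_size_s,
                "knn_k": config.knn_k,
                "n_folds": config.cv.n_folds,
                "seed": config.seed,
                "n_windows": len(dataset),
            },
        )
        for name, writer in (
            ("report.json", lambda p: report.to_json(p)),
            ("report.txt", lambda p: p.write_text(report.to_text() + "\n")),
            ("confusion.csv", lambda p: matrix.to_csv(p)),
        ):
            path = out_dir / name
            written.append(path)
            writer(path)
        return report

    return _run_to_dir(config, "classifier_eval", worker)


def run_window_size_experiment(config: ExperimentConfig, mode: str = "accel_gyro") -> pd.DataFrame:
    """Cross-validated weighted accuracy per window size, same source data.

    The recordings (and hence the random seed) are identical across
    sizes; the window sets necessarily differ, so folds are re-drawn
    per size with the same CV seed.
    """
    if len(config.window_sizes_s) < 2:
        raise ValueError("window-size comparison needs at least 2 sizes")
    max_size = max(config.window_sizes_s)
    if not config.manifest and max_size > config.synth.duration_s:
        raise ValueError(
            f"window size {max_size} s exceeds the {config.synth.duration_s} s recordings"
        )

    def worker(out_dir: Path, written: list[Path]) -> pd.DataFrame:
        rows = []
        for size in config.window_sizes_s:
            dataset = _load_dataset(config, size, mode)
            matrix = cross_validate(dataset, "knn", k=config.knn_k, config=config.cv)
            rows.append(
                {
                    "window_size_s": size,
                    "n_windows": len(dataset),
                    "weighted_accuracy_pct": round_half_up(
                        weighted_average_accuracy(matrix)
                    ),
                }
            )
            logger.info("window size %s s: %.1f%%", size, rows[-1]["weighted_accuracy_pct"])
        table = pd.DataFrame(rows)
        path = out_dir / "window_sizes.csv"
        written.append(path)
        table.to_csv(path, index=False)
        return table

    return _run_to_dir(config, "window_size", worker)


def run_sensor_ablation(config: ExperimentConfig) -> pd.DataFrame:
    """Paired accelerometer-only vs accelerometer+gyroscope comparison.

    Both runs use the identical window set and the identical fold
    assignment; only the feature columns differ, so every accuracy
    difference is attributable to the gyroscope features.
    """
    if not {"accel_only", "accel_gyro"} <= set(config.sensor_modes):
        raise ValueError("ablation needs both sensor modes enabled")

    def worker(out_dir: Path, written: list[Path]) -> pd.DataFrame:
        full = _load_dataset(config, config.window_size_s, "accel_gyro")
        reduced = full.restrict_to_accel_only()
        folds = assign_folds(full.y, full.groups, config.cv)
        reports = {}
        for mode, dataset in (("accel_only", reduced), ("accel_gyro", full)):
            matrix = cross_validate(
                dataset, "knn", k=config.knn_k, config=config.cv, folds=folds
            )
            reports[mode] = MetricsReport.from_matrix(matrix)
        acc_a = reports["accel_only"].accuracy_table()
        acc_b = reports["accel_gyro"].accuracy_table()
        deltas = ablation_delta(acc_a, acc_b)
        order = list(CLASS_ORDER) + ["weighted_average"]
        table = pd.DataFrame(
            {
                "class": order,
                "accel_only_pct": [acc_a[c] for c in order],
                "accel_gyro_pct": [acc_b[c] for c in order],
                "delta_pct": [deltas[c] for c in order],
            }
        )
        path = out_dir / "ablation.csv"
        written.append(path)
        table.to_csv(path, index=False)
        return table

    return _run_to_dir(config, "sensor_ablation", worker)


def replay_reference() -> MetricsReport:
    """Recompute the metric suite from the packaged reference matrix."""
    matrix = load_reference_confusion()
    return MetricsReport.from_matrix(
        matrix, config={"experiment": "replay_reference", "source": "packaged fixture"}
    )
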