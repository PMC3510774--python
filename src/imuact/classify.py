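"""From-scratch k-nearest-neighbor classifier with range normalization.

The classifier mirrors the long-standing defaults of instance-based
learners in classic machine-learning toolkits: k = 1, Euclidean
distance, and per-attribute min–max normalization fitted on the
training rows only.  Every rule that a toolkit leaves implicit is fixed
here deterministically:

* features with zero training range contribute 0 to the distance;
* values outside the training range are not clipped;
* among equidistant neighbors the lower training-row index wins;
* among tied vote counts the class earliest in C1…C9 order wins.

A Gaussian naive-Bayes classifier is included as an internal baseline
comparator only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .io_data import CLASS_ORDER

__all__ = [
    "NormalizationParams",
    "KnnModel",
    "GnbModel",
    "fit_normalizer",
    "normalize",
    "knn_fit",
    "knn_predict",
    "gnb_fit",
    "gnb_predict",
    "save_model",
    "load_model",
]

_MODEL_FORMAT_VERSION = 1

#: Classes outside C1..C9 sort after them, alphabetically.
def _class_rank(label: str) -> tuple[int, str]:
    try:
        return (CLASS_ORDER.index(label), "")
    except ValueError:
        return (len(CLASS_ORDER), str(label))


@dataclass(frozen=True)
class NormalizationParams:
    """Per-feature min/max observed in the training rows."""

    mins: np.ndarray
    maxs: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "mins", np.asarray(self.mins, dtype=float))
        object.__setattr__(self, "maxs", np.asarray(self.maxs, dtype=float))
        if self.mins.shape != self.maxs.shape or self.mins.ndim != 1:
            raise ValueError("mins and maxs must be 1-d arrays of equal length")
        if np.any(self.maxs < self.mins):
            raise ValueError("max must be >= min per feature")

    @property
    def n_features(self) -> int:
        return len(self.mins)


def fit_normalizer(X: np.ndarray) -> NormalizationParams:
    """Per-feature min/max from the training rows only."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or len(X) == 0:
        raise ValueError("need a non-empty 2-d training matrix")
    return NormalizationParams(mins=X.min(axis=0), maxs=X.max(axis=0))


def normalize(X: np.ndarray, params: NormalizationParams) -> np.ndarray:
    """(x − min)/(max − min) per feature.

    Zero-range features map to 0 (they carry no information, so they
    must not contribute to distances); out-of-range values are NOT
    clipped, so a query may legitimately fall outside [0, 1].
    """
    X = np.asarray(X, dtype=float)
    if X.shape[-1] != params.n_features:
        raise ValueError(
            f"row length {X.shape[-1]} does not match {params.n_features} features"
        )
    span = params.maxs - params.mins
    out = np.zeros_like(X, dtype=float)
    nz = span > 0
    out[..., nz] = (X[..., nz] - params.mins[nz]) / span[nz]
    return out


@dataclass
class KnnModel:
    """Stored (normalized) training matrix, labels, k, and normalization."""

    X: np.ndarray  # normalized training rows
    y: np.ndarray
    k: int
    normalization: NormalizationParams

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=object)
        if len(self.X) != len(self.y):
            raise ValueError("training matrix and labels must align")
        if not (1 <= self.k <= len(self.X)):
            raise ValueError(f"k={self.k} out of range for {len(self.X)} training rows")


def knn_fit(X: np.ndarray, y: np.ndarray, k: int = 1) -> KnnModel:
    """'Fit' a kNN model: fit the range normalizer and store the rows."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=object)
    if X.ndim != 2 or len(X) == 0:
        raise ValueError("need a non-empty 2-d training matrix")
    if len(X) != len(y):
        raise ValueError("X and y must align")
    params = fit_normalizer(X)
    return KnnModel(X=normalize(X, params), y=y, k=k, normalization=params)


def _vote(labels: np.ndarray) -> str:
    """Majority vote; ties go to the class earliest in C1…C9 order."""
    uniq, counts = np.unique(labels.astype(str), return_counts=True)
    best = counts.max()
    tied = [u for u, c in zip(uniq, counts) if c == best]
    return min(tied, key=_class_rank)


def knn_predict(
    model: KnnModel, queries: np.ndarray, chunk_size: int = 2048
) -> np.ndarray:
    """Predict labels for query rows (raw scale; normalization is applied).

    Distances are squared Euclidean on normalized features, computed in
    chunks to bound memory.  A stable sort on distance makes the
    lower-index rule for equidistant neighbors automatic.
    """
    Q = np.asarray(queries, dtype=float)
    if Q.ndim == 1:
        Q = Q[None, :]
    if Q.shape[1] != model.X.shape[1]:
        raise ValueError(
            f"query dimensionality {Q.shape[1]} != training {model.X.shape[1]}"
        )
    Qn = normalize(Q, model.normalization)
    T = model.X
    t_sq = np.einsum("ij,ij->i", T, T)
    out = np.empty(len(Qn), dtype=object)
    for lo in range(0, len(Qn), chunk_size):
        q = Qn[lo : lo + chunk_size]
        d2 = np.maximum(
            np.einsum("ij,ij->i", q, q)[:, None] + t_sq[None, :] - 2.0 * (q @ T.T),
            0.0,
        )
        # round distances so that float jitter does not break declared ties
        d2 = np.round(d2, 12)
        if model.k == 1:
            nearest = np.argmin(d2, axis=1)  # argmin returns the first (lowest) index
            out[lo : lo + len(q)] = model.y[nearest]
        else:
            order = np.argsort(d2, axis=1, kind="stable")[:, : model.k]
            for i, idx in enumerate(order):
                out[lo + i] = _vote(model.y[idx])
    return out


@dataclass
class GnbModel:
    """Per-class Gaussian likelihood parameters with a variance floor."""

    classes: list[str]
    means: np.ndarray  # (n_classes, n_features)
    variances: np.ndarray  # (n_classes, n_features), floored
    log_priors: np.ndarray  # (n_classes,)


def gnb_fit(X: np.ndarray, y: np.ndarray) -> GnbModel:
    """Gaussian naive Bayes with uniform-smoothed priors.

    Per-class variances are floored at 1e−9 × (global feature range)²
    so constant synthetic features cannot produce singular likelihoods.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=object)
    classes = sorted(set(y.astype(str)), key=_class_rank)
    span = X.max(axis=0) - X.min(axis=0)
    floor = 1e-9 * np.maximum(span, 1e-12) ** 2
    means, variances, priors = [], [], []
    for c in classes:
        rows = X[y.astype(str) == c]
        if len(rows) < 2:
            raise ValueError(f"class {c} has fewer than 2 training rows")
        means.append(rows.mean(axis=0))
        variances.append(np.maximum(rows.var(axis=0, ddof=1), floor))
        priors.append(len(rows))
    counts = np.array(priors, dtype=float)
    log_priors = np.log((counts + 1.0) / (counts.sum() + len(classes)))
    return GnbModel(
        classes=classes,
        means=np.array(means),
        variances=np.array(variances),
        log_priors=log_priors,
    )


def gnb_predict(model: GnbModel, queries: np.ndarray) -> np.ndarray:
    """Argmax over classes of the Gaussian log-posterior."""
    Q = np.asarray(queries, dtype=float)
    if Q.ndim == 1:
        Q = Q[None, :]
    # (n_queries, n_classes): sum over features of log N(q | mu, var)
    diff = Q[:, None, :] - model.means[None, :, :]
    log_lik = -0.5 * np.sum(
        diff**2 / model.variances[None, :, :]
        + np.log(2.0 * np.pi * model.variances)[None, :, :],
        axis=2,
    )
    scores = log_lik + model.log_priors[None, :]
    idx = np.argmax(scores, axis=1)  # first index wins ties = C-order (classes sorted)
    return np.array([model.classes[i] for i in idx], dtype=object)


def save_model(model: KnnModel, path: str | Path) -> Path:
    """Serialize a kNN model to a versioned JSON container."""
    path = Path(path)
    payload = {
        "format_version": _MODEL_FORMAT_VERSION,
        "model_type": "knn",
        "k": model.k,
        "X": model.X.tolist(),
        "y": [str(v) for v in model.y],
        "normalization": {
            "mins": model.normalization.mins.tolist(),
            "maxs": model.normalization.maxs.tolist(),
        },
    }
    path.write_text(json.dumps(payload))
    return path


def load_model(path: str | Path) -> KnnModel:
    payload = json.loads(Path(path).read_text())
    if payload.get("format_version") != _MODEL_FORMAT_VERSION:
        raise ValueError(f"unsupported model format: {payload.get('format_version')}")
    if payload.get("model_type") != "knn":
        raise ValueError(f"not a knn model file: {payload.get('model_type')}")
    return KnnModel(
        X=np.array(payload["X"], dtype=float),
        y=np.array(payload["y"], dtype=object),
        k=int(payload["k"]),
        normalization=NormalizationParams(
            mins=np.array(payload["normalization"]["mins"], dtype=float),
            maxs=np.array(payload["normalization"]["maxs"], dtype=float),
        ),
    )
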