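"""Gaussian-kernel soft-margin SVM over eigen-feature vectors.

The kernel is ``k(u, v) = exp(-||u - v||² / γ)`` — the squared Euclidean
distance divided by γ directly, *not* multiplied by it as in the common
library convention (``γ_lib = 1/γ``).  Training is delegated to libsvm via
scikit-learn; the decision function is re-evaluated from the stored support
vectors, dual coefficients and bias with this module's own kernel, so a
serialized model reproduces its predictions exactly.

Hyperparameters (C, γ) are selected by leave-one-out cross-validated grid
search, with folds grouped by provenance so that samples originating from
the same seizure never straddle the train/test split.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.svm import SVC

from .errors import ParameterError

PREICTAL = "preictal"
INTERICTAL = "interictal"

#: default log2 grids; γ values are multiples of the median pairwise
#: squared distance so the divide-by-γ kernel is scale-matched to the data.
DEFAULT_C_GRID = tuple(2.0**k for k in range(-5, 16, 2))
DEFAULT_GAMMA_MULTIPLIERS = tuple(2.0**k for k in range(-9, 10, 2))


@dataclass
class TrainingSet:
    """Λ vectors with class labels and per-sample provenance ids."""

    features: np.ndarray
    labels: np.ndarray
    provenance: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        if self.features.ndim != 2:
            raise ParameterError("features must be a 2-D (n_samples, p) array")
        if self.labels.shape[0] != self.features.shape[0]:
            raise ParameterError("one label per feature vector required")
        if self.provenance is None:
            self.provenance = np.array(
                [f"sample-{i}" for i in range(self.features.shape[0])], dtype=object
            )
        else:
            self.provenance = np.asarray(self.provenance, dtype=object)
            if self.provenance.shape[0] != self.features.shape[0]:
                raise ParameterError("one provenance id per sample required")
        if len(set(self.labels)) < 2:
            raise ParameterError("training set must contain both classes")


@dataclass
class SVMModel:
    """Trained SVM in self-contained form (Eq.-style divide-by-γ kernel)."""

    support_vectors: np.ndarray
    dual_coef: np.ndarray
    bias: float
    c: float
    gamma: float
    classes: tuple[str, str]  # (negative, positive) per decision-function sign
    metadata: dict = field(default_factory=dict)


def gaussian_kernel(u: np.ndarray, v: np.ndarray, gamma: float) -> float:
    """k(u, v) = exp(-||u - v||² / γ); symmetric, in (0, 1]."""
    if gamma <= 0:
        raise ParameterError("gamma must be positive")
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ParameterError("kernel arguments must have equal length")
    d2 = float(np.sum((u - v) ** 2))
    return float(np.exp(-d2 / gamma))


def kernel_matrix(a: np.ndarray, b: np.ndarray, gamma: float) -> np.ndarray:
    """Gram matrix of the Gaussian kernel between two sample sets."""
    if gamma <= 0:
        raise ParameterError("gamma must be positive")
    d2 = cdist(np.atleast_2d(a), np.atleast_2d(b), metric="sqeuclidean")
    return np.exp(-d2 / gamma)


def train(train_set: TrainingSet, c: float, gamma: float, tol: float = 1e-3) -> SVMModel:
    """Fit the soft-margin dual SVM at fixed (C, γ).

    Eigen-feature components are used as-is (no scaling of the eigenvalue
    coordinate).  Deterministic for identical inputs.
    """
    if c <= 0 or gamma <= 0:
        raise ParameterError("C and gamma must be positive")
    labels = train_set.labels
    if len(set(labels)) < 2:
        raise ParameterError("training requires both classes")
    svc = SVC(kernel="rbf", C=c, gamma=1.0 / gamma, tol=tol)
    svc.fit(train_set.features, labels.astype(str))
    return SVMModel(
        support_vectors=svc.support_vectors_.copy(),
        dual_coef=svc.dual_coef_[0].copy(),
        bias=float(svc.intercept_[0]),
        c=float(c),
        gamma=float(gamma),
        classes=(str(svc.classes_[0]), str(svc.classes_[1])),
    )


def decision_value(model: SVMModel, feature: np.ndarray) -> float:
    """Σ αᵢyᵢ k(svᵢ, Λ) + b, evaluated with the module's own kernel."""
    feature = np.asarray(feature, dtype=float)
    if feature.shape[0] != model.support_vectors.shape[1]:
        raise ParameterError(
            f"feature length {feature.shape[0]} does not match model "
            f"dimension {model.support_vectors.shape[1]}"
        )
    k = kernel_matrix(model.support_vectors, feature[None, :], model.gamma)[:, 0]
    return float(np.dot(model.dual_coef, k) + model.bias)


def predict(model: SVMModel, feature: np.ndarray) -> tuple[str, float]:
    """Label plus raw decision value for one Λ vector."""
    dec = decision_value(model, feature)
    label = model.classes[1] if dec > 0 else model.classes[0]
    return label, dec


def predict_many(model: SVMModel, features: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized :func:`predict` over an (n, p) array."""
    features = np.atleast_2d(np.asarray(features, dtype=float))
    k = kernel_matrix(model.support_vectors, features, model.gamma)
    dec = model.dual_coef @ k + model.bias
    labels = np.where(dec > 0, model.classes[1], model.classes[0]).astype(object)
    return labels, dec


def _loocv_accuracy(train_set: TrainingSet, c: float, gamma: float) -> float:
    """Leave-one-group-out accuracy at one grid point."""
    groups = train_set.provenance
    unique_groups = list(dict.fromkeys(groups))
    correct = 0
    total = 0
    for g in unique_groups:
        test_mask = groups == g
        train_mask = ~test_mask
        train_labels = train_set.labels[train_mask]
        if len(set(train_labels)) < 2:
            raise ParameterError(
                "a LOOCV fold removed an entire class; need >= 2 samples per class"
            )
        fold = TrainingSet(
            train_set.features[train_mask],
            train_labels,
            train_set.provenance[train_mask],
        )
        model = train(fold, c, gamma)
        pred, _ = predict_many(model, train_set.features[test_mask])
        correct += int(np.sum(pred == train_set.labels[test_mask]))
        total += int(np.sum(test_mask))
    return correct / total


def default_gamma_grid(features: np.ndarray) -> tuple[float, ...]:
    """γ grid centred on the median pairwise squared distance.

    Because the kernel divides by γ, useful γ values live on the scale of
    the squared distances between samples; a fixed numeric grid would be
    blind to the (unnormalized) eigenvalue units.
    """
    d2 = cdist(features, features, metric="sqeuclidean")
    iu = np.triu_indices(features.shape[0], k=1)
    med = float(np.median(d2[iu]))
    if med <= 0:
        med = 1.0
    return tuple(med * m for m in DEFAULT_GAMMA_MULTIPLIERS)


def grid_search_loocv(
    train_set: TrainingSet,
    c_grid: tuple[float, ...] | None = None,
    gamma_grid: tuple[float, ...] | None = None,
) -> tuple[float, float, float]:
    """Pick (C, γ) maximizing grouped-LOOCV accuracy.

    Ties are broken toward the simpler model: smaller C, then the smoother
    kernel — which under the divide-by-γ convention means *larger* γ.
    Returns ``(best_c, best_gamma, best_accuracy)``.
    """
    c_grid = tuple(c_grid) if c_grid else DEFAULT_C_GRID
    gamma_grid = (
        tuple(gamma_grid) if gamma_grid else default_gamma_grid(train_set.features)
    )
    if not c_grid or not gamma_grid:
        raise ParameterError("grids must be non-empty")
    labels = train_set.labels
    for cls in set(labels):
        if np.sum(labels == cls) < 2:
            raise ParameterError("need at least 2 samples per class for LOOCV")

    best = (None, None, -1.0)
    for c in sorted(c_grid):
        for gamma in sorted(gamma_grid, reverse=True):
            acc = _loocv_accuracy(train_set, c, gamma)
            if acc > best[2]:
                best = (c, gamma, acc)
    return best


def save_model(model: SVMModel, path: str | Path) -> None:
    """Serialize a model to JSON (fully self-contained)."""
    payload = {
        "support_vectors": model.support_vectors.tolist(),
        "dual_coef": model.dual_coef.tolist(),
        "bias": model.bias,
        "c": model.c,
        "gamma": model.gamma,
        "classes": list(model.classes),
        "metadata": model.metadata,
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def load_model(path: str | Path) -> SVMModel:
    """Load a model serialized by :func:`save_model`."""
    payload = json.loads(Path(path).read_text())
    return SVMModel(
        support_vectors=np.array(payload["support_vectors"], dtype=float),
        dual_coef=np.array(payload["dual_coef"], dtype=float),
        bias=float(payload["bias"]),
        c=float(payload["c"]),
        gamma=float(payload["gamma"]),
        classes=tuple(payload["classes"]),
        metadata=payload.get("metadata", {}),
    )
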