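"""RBF-kernel support-vector classification of feature vectors.

Wraps a standard quadratic-program SVM solver behind a small, deterministic
interface: continuous decision values plus thresholded +1/-1 labels. The
decision threshold is a prediction-time parameter (default 0, the SVM-light
convention); a tie at the threshold resolves to the positive class.

Default hyperparameters per scheme: the dipeptide model uses gamma=3 and
C=375, the width/cost pair found best for dipeptide composition; the other
schemes default to gamma=1, C=100 and are meant to be tuned per dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
from sklearn.svm import SVC

from .features import FeatureVector, Scheme, feature_matrix

PERSISTENCE_FORMAT_VERSION = 1


@dataclass(frozen=True)
class SVMConfig:
    """Kernel and regularisation settings for one SVM model."""

    kernel: str = "rbf"  # rbf | linear | polynomial
    gamma: float = 1.0
    cost: float = 100.0
    threshold: float = 0.0

    def __post_init__(self) -> None:
        if self.kernel not in ("rbf", "linear", "polynomial"):
            raise ValueError(f"unknown kernel {self.kernel!r}")
        if self.gamma <= 0:
            raise ValueError("gamma must be > 0")
        if self.cost <= 0:
            raise ValueError("cost must be > 0")


#: per-scheme defaults; DPC's gamma/C pair is the published optimum
DEFAULT_CONFIGS = {
    Scheme.AAC: SVMConfig(gamma=1.0, cost=100.0),
    Scheme.DPC: SVMConfig(gamma=3.0, cost=375.0),
    Scheme.HYBRID: SVMConfig(gamma=1.0, cost=100.0),
    Scheme.PSSM: SVMConfig(gamma=1.0, cost=100.0),
}


def default_config(scheme: Scheme | str) -> SVMConfig:
    return DEFAULT_CONFIGS[Scheme(scheme)]


@dataclass(frozen=True)
class ScoreRecord:
    """Decision value and thresholded label for one scored sequence."""

    source_id: str
    decision_value: float
    predicted_label: int
    true_label: int | None = None


@dataclass
class TrainedModel:
    """Opaque handle around a fitted SVM (scheme-aware, persistable)."""

    estimator: SVC
    scheme: Scheme
    dimension: int
    config: SVMConfig
    format_version: int = field(default=PERSISTENCE_FORMAT_VERSION)


def _kernel_name(kernel: str) -> str:
    return {"rbf": "rbf", "linear": "linear", "polynomial": "poly"}[kernel]


def train(
    vectors: Sequence[FeatureVector],
    labels: Sequence[int],
    config: SVMConfig | None = None,
) -> TrainedModel:
    """Fit an SVM on labelled feature vectors.

    Requires at least one example of each class and a consistent scheme
    across vectors. Training is deterministic for identical inputs.
    """
    X = feature_matrix(vectors)
    y = np.asarray(labels, dtype=int)
    if len(y) != X.shape[0]:
        raise ValueError(f"{X.shape[0]} vectors but {len(y)} labels")
    if set(np.unique(y)) != {-1, 1}:
        raise ValueError("training needs both classes: at least one +1 and one -1 example")
    if config is None:
        config = default_config(vectors[0].scheme)
    # tight solver tolerance so the fit is, to numerical precision,
    # independent of example ordering
    est = SVC(
        kernel=_kernel_name(config.kernel),
        gamma=config.gamma,
        C=config.cost,
        shrinking=True,
        tol=1e-8,
    )
    est.fit(X, y)
    return TrainedModel(est, vectors[0].scheme, X.shape[1], config)


def decision_values(model: TrainedModel, vectors: Sequence[FeatureVector]) -> np.ndarray:
    """Raw signed distances to the separating surface (+ side = positive class)."""
    X = feature_matrix(vectors)
    if X.shape[1] != model.dimension:
        raise ValueError(
            f"vectors have dimension {X.shape[1]}, model expects {model.dimension}"
        )
    return model.estimator.decision_function(X)


def predict(
    model: TrainedModel,
    vectors: Sequence[FeatureVector],
    threshold: float = 0.0,
    true_labels: Sequence[int] | None = None,
) -> list[ScoreRecord]:
    """Score vectors and threshold into +1/-1 labels.

    A decision value >= threshold (ties included) predicts the positive
    class.
    """
    scores = decision_values(model, vectors)
    if true_labels is not None and len(true_labels) != len(vectors):
        raise ValueError("true_labels length mismatch")
    out = []
    for i, (vec, s) in enumerate(zip(vectors, scores)):
        out.append(
            ScoreRecord(
                source_id=vec.source_id,
                decision_value=float(s),
                predicted_label=1 if s >= threshold else -1,
                true_label=None if true_labels is None else int(true_labels[i]),
            )
        )
    return out


def save_model(model: TrainedModel, path: str | Path) -> Path:
    """Persist a trained model (joblib archive, versioned)."""
    path = Path(path)
    payload = {
        "format_version": PERSISTENCE_FORMAT_VERSION,
        "scheme": model.scheme.value,
        "dimension": model.dimension,
        "config": model.config,
        "estimator": model.estimator,
    }
    joblib.dump(payload, path)
    return path


def load_model(path: str | Path, expected_scheme: Scheme | str | None = None) -> TrainedModel:
    """Load a persisted model; optionally check it matches an expected scheme."""
    path = Path(path)
    try:
        payload = joblib.load(path)
        version = payload["format_version"]
        scheme = Scheme(payload["scheme"])
        model = TrainedModel(
            payload["estimator"], scheme, payload["dimension"], payload["config"],
            format_version=version,
        )
    except Exception as exc:
        raise ValueError(f"cannot load model from {path}: {exc}") from exc
    if version != PERSISTENCE_FORMAT_VERSION:
        raise ValueError(f"unsupported model format version {version}")
    if expected_scheme is not None and model.scheme is not Scheme(expected_scheme):
        raise ValueError(
            f"model was trained on scheme {model.scheme.value!r}, "
            f"expected {Scheme(expected_scheme).value!r}"
        )
    return model
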