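"""Random-Forest training and prediction on labeled feature matrices.

The ensemble itself is scikit-learn's ``RandomForestClassifier`` (bootstrap
resampling per tree, ``max_features`` candidate features per split, seeded).
The positive-class *score* is defined here as the fraction of trees whose
predicted class is +1 — computed from per-tree predictions so that every
score is an exact multiple of 1/n_trees — and the predicted label is +1 iff
score ≥ 0.5 (ties go to the positive class).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import joblib
import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .dataset import LabeledDataset
from .feature_encoding import FeatureVector

_PERSIST_FORMAT = 1


@dataclass
class ForestConfig:
    n_trees: int = 100
    max_features: str | int = "sqrt"
    min_leaf: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError(f"n_trees must be >= 1, got {self.n_trees}")
        if self.min_leaf < 1:
            raise ValueError(f"min_leaf must be >= 1, got {self.min_leaf}")


@dataclass
class TrainedModel:
    """A fitted ensemble plus the metadata needed to apply it safely."""

    estimator: RandomForestClassifier
    config: ForestConfig
    n_features: int
    class_labels: tuple[int, int]
    training_fingerprint: str
    extra: dict[str, Any] = field(default_factory=dict)


def _fingerprint(X: np.ndarray, y: np.ndarray) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(X).tobytes())
    h.update(np.ascontiguousarray(y).tobytes())
    return h.hexdigest()[:16]


def train(data: LabeledDataset, config: ForestConfig | None = None,
          extra: dict[str, Any] | None = None) -> TrainedModel:
    """Fit a Random Forest on the dataset; deterministic given config.seed."""
    if config is None:
        config = ForestConfig()
    X, y = data.X(), data.y()
    classes = set(y.tolist())
    if classes != {+1, -1}:
        raise ValueError(f"training data must contain both classes, got {classes}")
    if len(y) < 2:
        raise ValueError("need at least 2 training samples")
    est = RandomForestClassifier(
        n_estimators=config.n_trees,
        max_features=config.max_features,
        min_samples_leaf=config.min_leaf,
        bootstrap=True,
        random_state=config.seed,
        n_jobs=1,
    )
    est.fit(X, y)
    return TrainedModel(
        estimator=est,
        config=config,
        n_features=X.shape[1],
        class_labels=(+1, -1),
        training_fingerprint=_fingerprint(X, y),
        extra=extra or {},
    )


def predict(model: TrainedModel,
            vectors: list[FeatureVector]) -> list[tuple[int, float]]:
    """Per-vector (label ±1, positive-vote fraction), order-preserving.

    score = (trees voting +1)/n_trees; label = +1 iff score ≥ 0.5.
    """
    if not vectors:
        return []
    X = np.vstack([v.values for v in vectors])
    if X.shape[1] != model.n_features:
        raise ValueError(
            f"dimension mismatch: model expects {model.n_features} features, "
            f"got {X.shape[1]}"
        )
    votes = np.zeros(len(vectors))
    for tree in model.estimator.estimators_:
        votes += tree.predict(X) == 1
    scores = votes / len(model.estimator.estimators_)
    return [(+1 if s >= 0.5 else -1, float(s)) for s in scores]


def save_model(model: TrainedModel, path: str | Path) -> Path:
    """Persist the model to a single versioned file."""
    path = Path(path)
    joblib.dump({
        "format": _PERSIST_FORMAT,
        "estimator": model.estimator,
        "config": model.config,
        "n_features": model.n_features,
        "class_labels": model.class_labels,
        "training_fingerprint": model.training_fingerprint,
        "extra": model.extra,
    }, path)
    return path


def load_model(path: str | Path) -> TrainedModel:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"model file not found: {path}")
    blob = joblib.load(path)
    if blob.get("format") != _PERSIST_FORMAT:
        raise ValueError(f"unsupported model file format: {blob.get('format')!r}")
    return TrainedModel(
        estimator=blob["estimator"],
        config=blob["config"],
        n_features=blob["n_features"],
        class_labels=tuple(blob["class_labels"]),
        training_fingerprint=blob["training_fingerprint"],
        extra=blob.get("extra", {}),
    )
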