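"""SMOTE oversampling of the minority class.

SMOTE (synthetic minority oversampling) generates new minority samples by
linear interpolation: for each original minority point x, a synthetic point
is ``x + u·(x_nn − x)`` with x_nn one of x's k nearest minority neighbours
(Euclidean) and u ~ Uniform(0, 1).  ``percent`` follows the classic
convention: a multiple of 100, giving percent/100 synthetic points per
original — percent=300 turns every minority sample into itself plus three
synthetics, quadrupling the minority class.

Rebalancing is applied to *training* partitions only; synthetic points
never enter a test set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataset import FoldSplit, LabeledDataset
from .feature_encoding import FeatureVector


@dataclass
class SmoteConfig:
    """percent must be a non-negative multiple of 100 (published setting:
    300); k_neighbors defaults to the conventional 5."""

    percent: int = 300
    k_neighbors: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.percent < 0 or self.percent % 100 != 0:
            raise ValueError(f"percent must be a non-negative multiple of 100, "
                             f"got {self.percent}")
        if self.k_neighbors < 1:
            raise ValueError(f"k_neighbors must be >= 1, got {self.k_neighbors}")


def smote(minority: list[FeatureVector], config: SmoteConfig) -> list[FeatureVector]:
    """Generate percent/100 synthetic vectors per original minority vector.

    Returns only the synthetic vectors, in deterministic seeded order
    (original order × generation index).  Each synthetic coordinate lies in
    the closed interval spanned by its two parents; synthetic vectors carry
    the minority label and a ``synthetic:`` source id.
    """
    g = config.percent // 100
    if g == 0:
        return []
    if len(minority) <= config.k_neighbors:
        raise ValueError(
            f"need more than k_neighbors={config.k_neighbors} minority samples, "
            f"got {len(minority)}"
        )
    dims = {len(v) for v in minority}
    if len(dims) != 1:
        raise ValueError(f"minority vectors have mixed dimensions: {sorted(dims)}")
    labels = {v.label for v in minority}
    if len(labels) != 1:
        raise ValueError(f"minority vectors have mixed labels: {labels}")
    label = labels.pop()

    X = np.vstack([v.values for v in minority])
    n = len(minority)
    # pairwise Euclidean distances; ties on distance break toward the lower
    # input index via stable argsort on (distance, index)
    sq = np.sum(X**2, axis=1)
    d2 = np.maximum(sq[:, None] + sq[None, :] - 2 * (X @ X.T), 0.0)
    rng = np.random.default_rng(config.seed)
    out: list[FeatureVector] = []
    for i in range(n):
        row = d2[i].copy()
        row[i] = np.inf  # a point is not its own neighbour
        nn = np.argsort(row, kind="stable")[: config.k_neighbors]
        for j in range(g):
            pick = nn[rng.integers(0, len(nn))]
            u = rng.random()
            values = X[i] + u * (X[pick] - X[i])
            out.append(
                FeatureVector(
                    values=values,
                    label=label,
                    source_id=f"synthetic:{minority[i].source_id}:{j + 1}",
                )
            )
    return out


def rebalance_training(split: FoldSplit, config: SmoteConfig) -> FoldSplit:
    """Return a split whose training set is augmented with SMOTE synthetics
    for its minority class; the test set is passed through untouched."""
    n_pos, n_neg = split.train.class_counts()
    if n_pos == 0 or n_neg == 0:
        raise ValueError(f"fold {split.fold_index}: training set lacks a class "
                         f"(pos={n_pos}, neg={n_neg})")
    if config.percent == 0:
        return split
    minority_label = +1 if n_pos <= n_neg else -1
    minority = [v for v in split.train.vectors if v.label == minority_label]
    synthetic = smote(minority, config)
    train = LabeledDataset(split.train.vectors + synthetic,
                           split.train.attribute_names)
    return FoldSplit(split.fold_index, train, split.test)
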