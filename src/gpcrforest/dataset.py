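"""Labeled datasets, stratified k-fold partitioning, ARFF I/O, and a greedy
redundancy filter.

The fold scheme reproduces the published experimental design: positives and
negatives are shuffled and partitioned *separately* into k near-equal parts
(floor(n/k) each, with the remainder going to the highest-indexed parts), and
fold *i* tests on part *i* while training on the rest.  Separate stratified
splitting is forced by the published per-fold counts, where 2495 positives
split 5-fold give exactly 499 test positives per fold and 10386 negatives
give 2077 per fold with a single extra negative landing in the last fold.

ARFF support covers the narrow dialect the pipeline emits: numeric feature
attributes followed by one nominal class attribute with values {1, -1}.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .feature_encoding import FeatureVector, feature_names
from .seqio import ProteinRecord

logger = logging.getLogger(__name__)


@dataclass
class LabeledDataset:
    """An ordered list of labeled feature vectors with attribute names."""

    vectors: list[FeatureVector]
    attribute_names: list[str]

    def __post_init__(self) -> None:
        if not self.vectors:
            raise ValueError("dataset must contain at least one vector")
        dims = {len(v) for v in self.vectors}
        if len(dims) != 1:
            raise ValueError(f"inconsistent vector dimensions: {sorted(dims)}")
        dim = dims.pop()
        if len(self.attribute_names) != dim:
            raise ValueError(
                f"{len(self.attribute_names)} attribute names for dimension {dim}"
            )

    @property
    def n_features(self) -> int:
        return len(self.attribute_names)

    def X(self) -> np.ndarray:
        """(n_samples, n_features) feature matrix."""
        return np.vstack([v.values for v in self.vectors])

    def y(self) -> np.ndarray:
        """Label vector; raises if any vector is unlabeled."""
        labels = [v.label for v in self.vectors]
        if any(l is None for l in labels):
            raise ValueError("dataset contains unlabeled vectors")
        return np.array(labels, dtype=int)

    def class_counts(self) -> tuple[int, int]:
        """(n_positive, n_negative)."""
        labels = [v.label for v in self.vectors]
        return labels.count(+1), labels.count(-1)

    def subset(self, indices: Sequence[int]) -> "LabeledDataset":
        return LabeledDataset([self.vectors[i] for i in indices],
                              self.attribute_names)


def combine(vectors: Iterable[FeatureVector],
            attribute_names: list[str] | None = None) -> LabeledDataset:
    """Build a LabeledDataset; default names are the 188D feature names."""
    vectors = list(vectors)
    if attribute_names is None:
        attribute_names = feature_names()
    return LabeledDataset(vectors, attribute_names)


@dataclass
class FoldSplit:
    """One train/test partition; fold_index is 1-based."""

    fold_index: int
    train: LabeledDataset
    test: LabeledDataset


def _part_sizes(n: int, k: int) -> list[int]:
    """k near-equal part sizes; the remainder goes to the last parts."""
    base, rem = divmod(n, k)
    return [base + (1 if i >= k - rem else 0) for i in range(k)]


def make_folds(data: LabeledDataset, k: int = 5, seed: int = 0) -> list[FoldSplit]:
    """Stratified k-fold partition with per-class shuffling.

    Each class is independently shuffled (seeded) and cut into k parts of
    size floor(n/k), the remainder parts (one extra each) being the
    highest-indexed ones; fold i's test set is part i of each class, its
    training set everything else.  Deterministic given ``seed``.
    """
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    rng = np.random.default_rng(seed)
    pos_idx = [i for i, v in enumerate(data.vectors) if v.label == +1]
    neg_idx = [i for i, v in enumerate(data.vectors) if v.label == -1]
    for name, idx in (("positive", pos_idx), ("negative", neg_idx)):
        if len(idx) < k:
            raise ValueError(
                f"{name} class has {len(idx)} members; need at least k={k}"
            )
    pos_perm = [pos_idx[i] for i in rng.permutation(len(pos_idx))]
    neg_perm = [neg_idx[i] for i in rng.permutation(len(neg_idx))]

    def cut(perm: list[int]) -> list[list[int]]:
        sizes = _part_sizes(len(perm), k)
        parts, start = [], 0
        for s in sizes:
            parts.append(perm[start:start + s])
            start += s
        return parts

    pos_parts, neg_parts = cut(pos_perm), cut(neg_perm)
    folds: list[FoldSplit] = []
    for i in range(k):
        test_idx = sorted(pos_parts[i] + neg_parts[i])
        train_idx = sorted(
            j for p in range(k) if p != i for j in pos_parts[p] + neg_parts[p]
        )
        folds.append(FoldSplit(i + 1, data.subset(train_idx), data.subset(test_idx)))
    return folds


# --- ARFF -----------------------------------------------------------------

def _fmt(x: float) -> str:
    return format(x, ".6g")


def write_arff(data: LabeledDataset, relation: str, path: str | Path) -> Path:
    """Write the dataset as ARFF: numeric attributes, nominal class {1,-1},
    label last on each data row.  Values carry 6 significant digits."""
    path = Path(path)
    lines = [f"@relation {relation}", ""]
    lines.extend(f"@attribute {name} numeric" for name in data.attribute_names)
    lines.append("@attribute class {1,-1}")
    lines.append("")
    lines.append("@data")
    for v in data.vectors:
        if v.label is None:
            label = "?"
        else:
            label = "1" if v.label == +1 else "-1"
        lines.append(",".join([_fmt(x) for x in v.values] + [label]))
    path.write_text("\n".join(lines) + "\n")
    return path


def read_arff(path: str | Path) -> LabeledDataset:
    """Read an ARFF file with numeric attributes and a final nominal class.

    Class values "1"/"-1" map to ±1; "?" yields an unlabeled vector; any
    other class value is an error naming the value.
    """
    path = Path(path)
    attr_names: list[str] = []
    attr_kinds: list[str] = []
    vectors: list[FeatureVector] = []
    in_data = False
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("%"):
            continue
        low = line.lower()
        if not in_data:
            if low.startswith("@relation"):
                continue
            if low.startswith("@attribute"):
                rest = line.split(None, 2)
                if len(rest) < 3:
                    raise ValueError(f"{path}:{lineno}: malformed @attribute line")
                attr_names.append(rest[1])
                attr_kinds.append(rest[2].strip())
                continue
            if low.startswith("@data"):
                if not attr_names:
                    raise ValueError(f"{path}: @data before any @attribute")
                for name, kind in zip(attr_names[:-1], attr_kinds[:-1]):
                    if kind.lower() not in ("numeric", "real", "integer"):
                        raise ValueError(
                            f"{path}: feature attribute {name!r} is not numeric "
                            f"(declared {kind!r})"
                        )
                in_data = True
                continue
            continue
        fields = [f.strip() for f in line.split(",")]
        if len(fields) != len(attr_names):
            raise ValueError(
                f"{path}:{lineno}: {len(fields)} fields for "
                f"{len(attr_names)} attributes"
            )
        values = np.array([float(f) for f in fields[:-1]])
        cls = fields[-1].strip("'\"")
        if cls == "?":
            label = None
        elif cls == "1":
            label = +1
        elif cls == "-1":
            label = -1
        else:
            raise ValueError(f"{path}:{lineno}: unknown class value {cls!r}")
        vectors.append(FeatureVector(values, label=label,
                                     source_id=f"row{len(vectors) + 1}"))
    if not in_data:
        raise ValueError(f"{path}: no @data section found")
    return LabeledDataset(vectors, attr_names[:-1])


def write_tsv(data: LabeledDataset, path: str | Path) -> Path:
    """Plain tab-separated export: id, feature values, label."""
    path = Path(path)
    header = "\t".join(["id"] + data.attribute_names + ["label"])
    lines = [header]
    for v in data.vectors:
        label = "" if v.label is None else str(v.label)
        lines.append("\t".join([v.source_id] + [_fmt(x) for x in v.values] + [label]))
    path.write_text("\n".join(lines) + "\n")
    return path


# --- redundancy filter ----------------------------------------------------

def _kmers(seq: str, k: int) -> set[str]:
    return {seq[i:i + k] for i in range(len(seq) - k + 1)}


def greedy_redundancy_filter(records: list[ProteinRecord],
                             identity_threshold: float = 0.80,
                             k: int = 5) -> list[ProteinRecord]:
    """Greedy longest-first redundancy reduction via shared-k-mer identity.

    An *estimator*, not an aligner: identity between two sequences is the
    fraction of the shorter sequence's distinct k-mers (k=5) present in the
    longer one.  Records are processed by decreasing length (ties keep input
    order); each either joins the first retained representative it matches
    at or above ``identity_threshold`` or becomes a new representative.
    Returns representatives in processing order.  Deterministic.
    """
    if not 0 < identity_threshold <= 1:
        raise ValueError(f"identity_threshold must be in (0, 1], got {identity_threshold}")
    order = sorted(range(len(records)), key=lambda i: -len(records[i]))
    reps: list[ProteinRecord] = []
    rep_kmers: list[set[str]] = []
    n_removed = 0
    for i in order:
        rec = records[i]
        mers = _kmers(rec.sequence, k)
        matched = False
        for rk in rep_kmers:
            if not mers:
                # sequences shorter than k have no k-mers; identity 1 only
                # against an identical-sequence representative is unknowable,
                # so keep them as their own representatives
                break
            identity = len(mers & rk) / len(mers)
            if identity >= identity_threshold:
                matched = True
                break
        if matched:
            n_removed += 1
        else:
            reps.append(rec)
            rep_kmers.append(mers)
    if n_removed:
        logger.info("redundancy filter removed %d of %d records", n_removed, len(records))
    return reps
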