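"""The 188-dimensional SVM-Prot feature encoding.

A protein sequence of any length is mapped to a fixed 188-value vector:

* positions 1–20: amino-acid composition (AAC), alphabetical by one-letter
  code (A, C, D, …, Y);
* then, for each of the eight physicochemical properties in the fixed
  property-table order, a 21-value CTD block laid out
  ``C1, C2, C3, T12, T13, T23, D1(5 values), D2(5), D3(5)``:

  - **Composition** ``Cj``: fraction of residues in class *j*;
  - **Transition** ``Tjk``: frequency of adjacent residue pairs that cross
    between classes *j* and *k* (either direction), over the L−1 pairs;
  - **Distribution** ``Dj``: the sequence positions (as percent of length)
    at which the first, 25%, 50%, 75% and 100% of class *j*'s occurrences
    have been seen.

20 + 8×(3+3+15) = 188.

The distribution anchor index uses ``m(q) = max(1, ceil(q·n/100))`` — this
guarantees ``m(100%) = n`` and ``m(q) ≥ 1`` with no special cases; published
CTD implementations differ on floor/round/ceil here, and the choice is
isolated in :func:`_anchor_index`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .property_tables import PropertyGrouping, class_string, default_groupings
from .seqio import STANDARD_AA, ProteinRecord

N_FEATURES = 188

#: Distribution anchors, in percent of class occurrences.
_ANCHORS = (0, 25, 50, 75, 100)  # 0 denotes "first occurrence"


@dataclass
class FeatureVector:
    """The ordered 188-value encoding of one sequence, plus its label.

    ``label`` is +1 (GPCR), −1 (non-GPCR) or ``None`` (unlabeled).
    """

    values: np.ndarray
    label: int | None = None
    source_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("FeatureVector values must be 1-D")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"FeatureVector {self.source_id!r}: non-finite values")
        if self.label is not None and self.label not in (+1, -1):
            raise ValueError(f"label must be +1, -1 or None, got {self.label!r}")

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class CTDBlock:
    """Composition (3), transition (3) and distribution (15) values for one
    property grouping."""

    composition: np.ndarray
    transition: np.ndarray
    distribution: np.ndarray

    def concat(self) -> np.ndarray:
        return np.concatenate([self.composition, self.transition, self.distribution])


def aac(sequence: str) -> np.ndarray:
    """20 amino-acid composition values, alphabetical by one-letter code."""
    if not sequence:
        raise ValueError("cannot encode an empty sequence")
    counts = np.array([sequence.count(a) for a in STANDARD_AA], dtype=float)
    total = counts.sum()
    if total != len(sequence):
        bad = set(sequence) - set(STANDARD_AA)
        raise ValueError(f"sequence contains nonstandard residues {sorted(bad)}")
    return counts / total


def ctd_composition(cls: str) -> np.ndarray:
    """Class fractions C1, C2, C3 of a class string over {1,2,3}."""
    if not cls:
        raise ValueError("empty class string")
    L = len(cls)
    return np.array([cls.count("1"), cls.count("2"), cls.count("3")], dtype=float) / L


def ctd_transition(cls: str) -> np.ndarray:
    """Cross-class adjacent-pair frequencies T12, T13, T23.

    A length-1 string has no pairs and returns (0, 0, 0) so degenerate
    inputs survive batch encoding.
    """
    if not cls:
        raise ValueError("empty class string")
    L = len(cls)
    if L == 1:
        return np.zeros(3)
    counts = {frozenset("12"): 0, frozenset("13"): 0, frozenset("23"): 0}
    for a, b in zip(cls, cls[1:]):
        if a != b:
            counts[frozenset((a, b))] += 1
    return np.array([counts[frozenset("12")],
                     counts[frozenset("13")],
                     counts[frozenset("23")]], dtype=float) / (L - 1)


def _anchor_index(q: int, n: int) -> int:
    """1-based occurrence index for anchor ``q`` percent of ``n`` occurrences."""
    if q == 0:  # first occurrence
        return 1
    return max(1, math.ceil(q * n / 100))


def ctd_distribution(cls: str) -> np.ndarray:
    """Distribution values: for each class, the positions (percent of L) of
    the first/25%/50%/75%/100% occurrences; all-zero for an absent class."""
    if not cls:
        raise ValueError("empty class string")
    L = len(cls)
    out = np.zeros(15)
    for j, label in enumerate("123"):
        positions = [i + 1 for i, c in enumerate(cls) if c == label]
        n = len(positions)
        if n == 0:
            continue
        for a, q in enumerate(_ANCHORS):
            out[5 * j + a] = 100.0 * positions[_anchor_index(q, n) - 1] / L
    return out


def ctd_block(sequence: str, grouping: PropertyGrouping) -> CTDBlock:
    """The full 21-value CTD block of a sequence under one grouping."""
    cls = class_string(sequence, grouping)
    return CTDBlock(ctd_composition(cls), ctd_transition(cls), ctd_distribution(cls))


def encode_188(record: ProteinRecord,
               groupings: list[PropertyGrouping] | None = None,
               label: int | None = None) -> FeatureVector:
    """Encode one record into the 188D feature vector."""
    if groupings is None:
        groupings = default_groupings()
    if len(groupings) != 8:
        raise ValueError(f"expected 8 property groupings, got {len(groupings)}")
    parts = [aac(record.sequence)]
    parts.extend(ctd_block(record.sequence, g).concat() for g in groupings)
    values = np.concatenate(parts)
    assert values.shape == (N_FEATURES,)
    return FeatureVector(values=values, label=label, source_id=record.id)


def encode_many(records: list[ProteinRecord],
                groupings: list[PropertyGrouping] | None = None,
                label: int | None = None) -> list[FeatureVector]:
    """Encode a batch, order-preserving; any failure names the record."""
    if not records:
        raise ValueError("no records to encode")
    if groupings is None:
        groupings = default_groupings()
    out: list[FeatureVector] = []
    for rec in records:
        try:
            out.append(encode_188(rec, groupings, label=label))
        except ValueError as exc:
            raise ValueError(f"encoding failed for record {rec.id!r}: {exc}") from exc
    return out


def feature_names(groupings: list[PropertyGrouping] | None = None) -> list[str]:
    """The 188 attribute names, in vector order."""
    if groupings is None:
        groupings = default_groupings()
    names = [f"AAC_{a}" for a in STANDARD_AA]
    anchors = ("first", "p25", "p50", "p75", "p100")
    for g in groupings:
        names.extend(f"{g.name}_C{j}" for j in (1, 2, 3))
        names.extend(f"{g.name}_T{jk}" for jk in ("12", "13", "23"))
        for j in (1, 2, 3):
            names.extend(f"{g.name}_D{j}_{a}" for a in anchors)
    return names
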