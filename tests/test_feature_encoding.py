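"""CTD encoder tests, including exhaustive brute-force oracles.

The oracles below re-derive composition/transition/distribution values by
direct enumeration, independently of the implementation's vectorised paths.
"""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gpcrforest import (N_FEATURES, ProteinRecord, aac, ctd_composition,
                        ctd_distribution, ctd_transition, default_groupings,
                        encode_188, encode_many, feature_names)
from gpcrforest.feature_encoding import ctd_block
from gpcrforest.property_tables import class_string
from gpcrforest.seqio import STANDARD_AA


# --- independent oracles ---------------------------------------------------

def oracle_transition(cls):
    pairs = list(zip(cls, cls[1:]))
    if not pairs:
        return (0.0, 0.0, 0.0)
    out = []
    for j, k in (("1", "2"), ("1", "3"), ("2", "3")):
        n = sum(1 for a, b in pairs if (a, b) in ((j, k), (k, j)))
        out.append(n / len(pairs))
    return tuple(out)


def oracle_distribution(cls):
    L = len(cls)
    out = []
    for label in "123":
        positions = [i + 1 for i, c in enumerate(cls) if c == label]
        n = len(positions)
        if n == 0:
            out.extend([0.0] * 5)
            continue
        anchors = [1] + [max(1, math.ceil(q * n / 100)) for q in (25, 50, 75, 100)]
        out.extend(100.0 * positions[m - 1] / L for m in anchors)
    return tuple(out)


# --- AAC -------------------------------------------------------------------

class TestAAC:
    def test_homopolymer(self):
        v = aac("AAAA")
        assert v[0] == 1.0 and v[1:].sum() == 0.0

    def test_uniform_four_residues(self):
        v = aac("ACDE")
        assert list(v[:4]) == [0.25] * 4 and v[4:].sum() == 0.0

    def test_hand_tally(self):
        # MKTAYIAKQR: A×2, K×2, I/M/Q/R/T/Y ×1 each, over L=10
        v = dict(zip(STANDARD_AA, aac("MKTAYIAKQR")))
        expected = {"A": 0.2, "K": 0.2, "I": 0.1, "M": 0.1, "Q": 0.1,
                    "R": 0.1, "T": 0.1, "Y": 0.1}
        for a in STANDARD_AA:
            assert v[a] == pytest.approx(expected.get(a, 0.0))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            aac("")

    @settings(deadline=None, derandomize=True)
    @given(st.text(alphabet=STANDARD_AA, min_size=1, max_size=60))
    def test_sums_to_one_and_permutation_invariant(self, seq):
        v = aac(seq)
        assert v.sum() == pytest.approx(1.0)
        assert np.allclose(aac(seq[::-1]), v)


# --- CTD sub-operations ----------------------------------------------------

class TestComposition:
    @pytest.mark.parametrize("cls,expected", [
        ("1111", (1.0, 0.0, 0.0)),
        ("123123", (1 / 3, 1 / 3, 1 / 3)),
        ("1133", (0.5, 0.0, 0.5)),
    ])
    def test_hand_counts(self, cls, expected):
        assert ctd_composition(cls) == pytest.approx(expected)

    def test_sums_to_one(self):
        for cls in ("1", "12", "332211", "2" * 9):
            assert ctd_composition(cls).sum() == pytest.approx(1.0)


class TestTransition:
    @pytest.mark.parametrize("cls,expected", [
        ("1111", (0.0, 0.0, 0.0)),
        ("12", (1.0, 0.0, 0.0)),
        ("121332", (0.4, 0.2, 0.2)),  # pairs 12,21,13,33,32
        ("1", (0.0, 0.0, 0.0)),       # length-1 convention
    ])
    def test_hand_enumeration(self, cls, expected):
        assert ctd_transition(cls) == pytest.approx(expected)


class TestDistribution:
    @pytest.mark.parametrize("cls,block,expected", [
        ("1111", 0, (25, 25, 50, 75, 100)),
        ("2222222222", 1, (10, 30, 50, 80, 100)),  # anchors m = 1,3,5,8,10
        ("1111", 1, (0, 0, 0, 0, 0)),              # absent class
    ])
    def test_hand_anchors(self, cls, block, expected):
        vals = ctd_distribution(cls)[5 * block:5 * block + 5]
        assert vals == pytest.approx(expected)

    def test_present_class_values_nondecreasing_in_0_100(self):
        vals = ctd_distribution("321123213")
        for j in range(3):
            block = vals[5 * j:5 * j + 5]
            assert all(0 < v <= 100 for v in block)
            assert all(a <= b for a, b in zip(block, block[1:]))


@pytest.mark.parametrize("length", range(1, 7))
def test_exhaustive_oracle_equivalence(length):
    """Transition and distribution match brute-force enumeration over every
    class string of the given length."""
    for tup in itertools.product("123", repeat=length):
        cls = "".join(tup)
        assert ctd_transition(cls) == pytest.approx(oracle_transition(cls))
        assert ctd_distribution(cls) == pytest.approx(oracle_distribution(cls))


# --- full 188D vector ------------------------------------------------------

class TestEncode188:
    def test_dimension_law(self):
        fv = encode_188(ProteinRecord("p", "", "MKTAYIAKQR"))
        assert len(fv) == N_FEATURES == 20 + 8 * (3 + 3 + 15)

    def test_polyA(self):
        fv = encode_188(ProteinRecord("p", "", "A" * 30))
        assert fv.values[0] == 1.0            # AAC A-slot
        assert fv.values[1:20].sum() == 0.0
        names = feature_names()
        for i, name in enumerate(names):
            if "_T" in name:
                assert fv.values[i] == 0.0    # homopolymer: no transitions
        # each property's C-block concentrates in exactly one class
        for g_idx in range(8):
            c_block = fv.values[20 + 21 * g_idx: 20 + 21 * g_idx + 3]
            assert sorted(c_block) == [0.0, 0.0, 1.0]

    def test_matches_sub_block_assembly(self):
        """The 188 vector is exactly AAC ++ the 8 independently computed
        21-value CTD blocks, in property order."""
        rec = ProteinRecord("p", "", "MKTAYIAKQR")
        groupings = default_groupings()
        expected = np.concatenate(
            [aac(rec.sequence)]
            + [ctd_block(rec.sequence, g).concat() for g in groupings])
        fv = encode_188(rec, groupings)
        assert np.array_equal(fv.values, expected)

    def test_value_ranges(self, synthetic_dataset):
        X = synthetic_dataset.X()
        names = feature_names()
        for i, name in enumerate(names):
            col = X[:, i]
            if "_D" in name:
                assert col.min() >= 0 and col.max() <= 100
            else:
                assert col.min() >= 0 and col.max() <= 1

    def test_deterministic(self):
        rec = ProteinRecord("p", "", "MKTAYIAKQRWLVNDS")
        a = encode_188(rec).values
        b = encode_188(rec).values
        assert np.array_equal(a, b)

    def test_wrong_grouping_count(self):
        with pytest.raises(ValueError):
            encode_188(ProteinRecord("p", "", "MK"), default_groupings()[:5])


class TestEncodeMany:
    def test_labels_and_order(self, records):
        vecs = encode_many(records, label=+1)
        assert [v.source_id for v in vecs] == ["p1", "p2", "p3"]
        assert all(v.label == +1 for v in vecs)

    def test_unlabeled(self, records):
        assert all(v.label is None for v in encode_many(records))

    def test_count_preserving(self, records):
        assert len(encode_many(records * 10)) == 30

    def test_empty_batch_rejected(self):
        with pytest.raises(ValueError):
            encode_many([])
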