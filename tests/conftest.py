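import numpy as np
import pytest

from gpcrforest import (FeatureVector, GeneratorConfig, ProteinRecord, combine,
                        encode_many, generate_both)


@pytest.fixture
def fasta_file(tmp_path):
    """Factory writing raw FASTA text to a temp file."""
    def _write(text, name="input.fasta"):
        path = tmp_path / name
        path.write_text(text)
        return path
    return _write


@pytest.fixture
def records():
    return [
        ProteinRecord("p1", "p1 first", "MKTAYIAKQR"),
        ProteinRecord("p2", "", "ACDEFGHIKLMNPQRSTVWY"),
        ProteinRecord("p3", "", "WWWWCCCC"),
    ]


def make_dataset(n_pos=10, n_neg=20, dim=4, seed=0):
    """Small random labeled dataset with generic (non-188D) dimension."""
    rng = np.random.default_rng(seed)
    vectors = [
        FeatureVector(rng.random(dim), label=+1, source_id=f"pos{i}")
        for i in range(n_pos)
    ] + [
        FeatureVector(rng.random(dim) + 2.0, label=-1, source_id=f"neg{i}")
        for i in range(n_neg)
    ]
    return combine(vectors, [f"f{j}" for j in range(dim)])


@pytest.fixture(scope="session")
def synthetic_dataset():
    """Encoded synthetic two-class dataset (100 pos / 400 neg, seed 1)."""
    pos, neg = generate_both(GeneratorConfig(n_pos=100, n_neg=400, seed=1))
    vecs = encode_many(pos, label=+1) + encode_many(neg, label=-1)
    return combine(vecs)
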