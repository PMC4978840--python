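"""Synthetic receptor-like and background sequence generation.

The pipeline needs two distinguishable sequence populations to exercise and
validate every stage offline:

* **positives** imitate the compositional signature of seven-transmembrane
  receptors: ``n_helices`` (default 7) stretches strongly enriched in
  hydrophobic residues {C,L,V,I,M,F,W}, separated by loop segments of
  uniform residue composition (plus N- and C-terminal tails);
* **negatives** imitate globular proteins: residues drawn i.i.d. from a
  near-uniform frequency table with a mild bias toward the abundant
  residues A, G, L, S, E, K.

Only compositional structure is imitated — no real transmembrane topology,
signal peptides or sequence motifs — which is sufficient to give the
feature encoding a strong, honest class signal.  The default 1:4
positive:negative imbalance mirrors the class ratio of the curated
receptor/non-receptor data the pipeline targets, so SMOTE behaviour is
exercised realistically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .seqio import STANDARD_AA, ProteinRecord

#: Hydrophobic residue set enriched inside helices (hydrophobicity class 3).
HYDROPHOBIC = "CLVIMFW"
_NON_HYDROPHOBIC = "".join(a for a in STANDARD_AA if a not in set(HYDROPHOBIC))

#: Mild globular-protein bias: extra weight on A, G, L, S, E, K.
_GLOBULAR_FAVORED = "AGLSEK"


@dataclass
class GeneratorConfig:
    n_pos: int = 100
    n_neg: int = 400
    length_range: tuple[int, int] = (280, 520)
    n_helices: int = 7
    helix_length_range: tuple[int, int] = (18, 25)
    hydrophobic_bias: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pos < 1 or self.n_neg < 1:
            raise ValueError("n_pos and n_neg must be positive")
        for name in ("length_range", "helix_length_range"):
            lo, hi = getattr(self, name)
            if lo > hi or lo < 1:
                raise ValueError(f"invalid {name}: ({lo}, {hi})")
        if not 0 < self.hydrophobic_bias < 1:
            raise ValueError(f"hydrophobic_bias must be in (0, 1), "
                             f"got {self.hydrophobic_bias}")
        min_core = self.n_helices * self.helix_length_range[1]
        if min_core > self.length_range[1]:
            raise ValueError(
                f"{self.n_helices} helices of up to {self.helix_length_range[1]} "
                f"residues cannot fit in max length {self.length_range[1]}"
            )


def _globular_freqs() -> np.ndarray:
    weights = np.array([1.8 if a in _GLOBULAR_FAVORED else 1.0
                        for a in STANDARD_AA])
    return weights / weights.sum()


def _helix_freqs(bias: float) -> np.ndarray:
    freqs = np.empty(20)
    for i, a in enumerate(STANDARD_AA):
        if a in set(HYDROPHOBIC):
            freqs[i] = bias / len(HYDROPHOBIC)
        else:
            freqs[i] = (1 - bias) / len(_NON_HYDROPHOBIC)
    return freqs


_AA_ARRAY = np.array(list(STANDARD_AA))


def _draw(rng: np.random.Generator, n: int, freqs: np.ndarray) -> str:
    return "".join(_AA_ARRAY[rng.choice(20, size=n, p=freqs)])


def generate_positive(config: GeneratorConfig) -> list[ProteinRecord]:
    """Receptor-like sequences: alternating hydrophobic helices and uniform
    loops, total length within ``length_range``.  Seeded and deterministic."""
    rng = np.random.default_rng(config.seed)
    helix_freqs = _helix_freqs(config.hydrophobic_bias)
    uniform = np.full(20, 1 / 20)
    records = []
    h_lo, h_hi = config.helix_length_range
    for i in range(config.n_pos):
        helix_lens = rng.integers(h_lo, h_hi + 1, size=config.n_helices)
        core = int(helix_lens.sum())
        lo = max(config.length_range[0], core)
        total = int(rng.integers(lo, config.length_range[1] + 1))
        # split the remaining residues over n_helices+1 loop slots
        # (N-terminus, inter-helix loops, C-terminus)
        slack = total - core
        cuts = np.sort(rng.integers(0, slack + 1, size=config.n_helices))
        loop_lens = np.diff(np.concatenate([[0], cuts, [slack]]))
        parts = [_draw(rng, int(loop_lens[0]), uniform)]
        for h in range(config.n_helices):
            parts.append(_draw(rng, int(helix_lens[h]), helix_freqs))
            parts.append(_draw(rng, int(loop_lens[h + 1]), uniform))
        seq = "".join(parts)
        records.append(ProteinRecord(id=f"pos_{i + 1}",
                                     description=f"pos_{i + 1} synthetic receptor-like",
                                     sequence=seq))
    return records


def generate_negative(config: GeneratorConfig) -> list[ProteinRecord]:
    """Background sequences from the globular-like frequency table."""
    rng = np.random.default_rng(config.seed + 1_000_003)
    freqs = _globular_freqs()
    records = []
    for i in range(config.n_neg):
        total = int(rng.integers(config.length_range[0],
                                 config.length_range[1] + 1))
        records.append(ProteinRecord(id=f"neg_{i + 1}",
                                     description=f"neg_{i + 1} synthetic background",
                                     sequence=_draw(rng, total, freqs)))
    return records


def generate_both(config: GeneratorConfig) -> tuple[list[ProteinRecord],
                                                    list[ProteinRecord]]:
    """(positives, negatives) under one config; the two streams use
    decoupled seeds so changing n_pos never perturbs the negatives."""
    return generate_positive(config), generate_negative(config)
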