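"""Three-class amino-acid partitions for the eight physicochemical properties.

Each CTD (composition/transition/distribution) encoder works on a sequence
re-written over the alphabet {1,2,3}, where the digit is the class of the
residue under one physicochemical property.  This module freezes the eight
default partitions from the SVM-Prot/PROFEAT lineage — hydrophobicity,
normalized van der Waals volume, polarity, polarizability, charge, surface
tension, secondary-structure propensity and solvent accessibility — and
fixes their order, because feature positions in the 188D vector depend on
both the property order and the class order within each property.

The defaults can be exported to, and replaced from, a plain-text table file
(one property per line: ``name: class1 | class2 | class3``), so an alternate
residue assignment is a one-file change rather than a code change.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from .seqio import STANDARD_AA

_AA_SET = frozenset(STANDARD_AA)


@dataclass(frozen=True)
class PropertyGrouping:
    """A named 3-way partition of the 20 standard amino acids.

    ``classes`` is an ordered triple of residue strings; class order is part
    of the public feature-ordering contract (class 1 fills the first slot of
    each C/T/D block).
    """

    name: str
    classes: tuple[str, str, str]
    class_labels: tuple[str, str, str]

    def __post_init__(self) -> None:
        sets = [frozenset(c) for c in self.classes]
        union = sets[0] | sets[1] | sets[2]
        if union != _AA_SET:
            missing = _AA_SET - union
            extra = union - _AA_SET
            raise ValueError(
                f"grouping {self.name!r}: classes must cover the 20 standard "
                f"residues exactly (missing={sorted(missing)}, extra={sorted(extra)})"
            )
        if len(sets[0]) + len(sets[1]) + len(sets[2]) != 20:
            raise ValueError(f"grouping {self.name!r}: classes overlap")

    def residue_class(self, residue: str) -> int:
        """1-based class index of a residue."""
        for j, cls in enumerate(self.classes, start=1):
            if residue in cls:
                return j
        raise ValueError(f"residue {residue!r} not in grouping {self.name!r}")


# Default partitions, in the fixed property order.  Class semantics follow
# the conventional low/neutral/high (or polar/neutral/hydrophobic) reading
# of each scale.
_DEFAULTS: list[tuple[str, tuple[str, str, str], tuple[str, str, str]]] = [
    ("hydrophobicity",
     ("RKEDQN", "GASTPHY", "CLVIMFW"),
     ("polar", "neutral", "hydrophobic")),
    ("normalized_vdw_volume",
     ("GASTPDC", "NVEQIL", "MHKFRYW"),
     ("small", "medium", "large")),
    ("polarity",
     ("LIFWCMVY", "PATGS", "HQRKNED"),
     ("low", "medium", "high")),
    ("polarizability",
     ("GASDT", "CPNVEQIL", "KMHFRYW"),
     ("low", "medium", "high")),
    ("charge",
     ("KR", "ANCQGHILMFPSTWYV", "DE"),
     ("positive", "neutral", "negative")),
    ("surface_tension",
     ("GQDNAHR", "KTSEC", "ILMFPWYV"),
     ("low", "medium", "high")),
    ("secondary_structure",
     ("EALMQKRH", "VIYCWFT", "GNPSD"),
     ("helix", "strand", "coil")),
    ("solvent_accessibility",
     ("ALFCGIVW", "RKQEND", "MSPTHY"),
     ("buried", "exposed", "intermediate")),
]


def default_groupings() -> list[PropertyGrouping]:
    """The eight default property groupings, in fixed feature order."""
    return [PropertyGrouping(name, classes, labels)
            for name, classes, labels in _DEFAULTS]


def class_string(sequence: str, grouping: PropertyGrouping) -> str:
    """Rewrite ``sequence`` over {1,2,3} by class membership.

    Length-preserving and total for any sequence over the 20-letter
    alphabet; permutation-equivariant by construction.
    """
    table = _class_table(grouping)
    try:
        return sequence.translate(table)
    except KeyError:  # pragma: no cover - unreachable if invariants hold
        raise ValueError(f"sequence contains residue outside grouping {grouping.name!r}")


def _class_table(grouping: PropertyGrouping) -> dict[int, str]:
    table: dict[int, str] = {}
    for j, cls in enumerate(grouping.classes, start=1):
        for aa in cls:
            table[ord(aa)] = str(j)
    return table


def save_groupings(groupings: list[PropertyGrouping], path: str | Path) -> Path:
    """Export groupings to the plain-text table format."""
    path = Path(path)
    lines = ["# property groupings: name: class1 | class2 | class3",
             "# class order is part of the feature-ordering contract"]
    for g in groupings:
        lines.append(f"{g.name}: {g.classes[0]} | {g.classes[1]} | {g.classes[2]}")
    path.write_text("\n".join(lines) + "\n")
    return path


def load_groupings(path: str | Path) -> list[PropertyGrouping]:
    """Load groupings from the plain-text table format.

    Expects exactly eight properties, one per non-comment line, each a valid
    3-way partition of the 20 standard residues.
    """
    path = Path(path)
    groupings: list[PropertyGrouping] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if ":" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'name: c1 | c2 | c3'")
        name, _, rest = line.partition(":")
        parts = [p.strip().upper() for p in rest.split("|")]
        if len(parts) != 3:
            raise ValueError(f"{path}:{lineno}: expected 3 classes, got {len(parts)}")
        groupings.append(
            PropertyGrouping(name.strip(), (parts[0], parts[1], parts[2]),
                             ("class1", "class2", "class3"))
        )
    if len(groupings) != 8:
        raise ValueError(f"{path}: expected 8 property groupings, found {len(groupings)}")
    return groupings
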