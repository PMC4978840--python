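"""Protein FASTA input/output with an explicit nonstandard-residue policy.

Every downstream encoder assumes the 20-letter amino-acid alphabet, so all
sequences pass through :func:`clean_sequence` on the way in.  Three policies
are offered:

``strict``
    any character outside the 20 standard one-letter codes is an error;
``drop``
    nonstandard characters are silently removed;
``map`` (default)
    ambiguity codes are resolved to a representative residue
    (B→D, Z→E, U→C, O→K, J→L) and X / gap / stop characters are removed.

Records whose cleaned sequence is empty are omitted with a logged warning
rather than propagated, so a stray empty entry cannot poison a batch encode.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: The 20 standard one-letter amino-acid codes, alphabetical.
STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
_STANDARD_SET = frozenset(STANDARD_AA)

#: Ambiguity-code resolution used by the ``map`` policy.
AMBIGUITY_MAP = {"B": "D", "Z": "E", "U": "C", "O": "K", "J": "L"}

#: Characters removed (not mapped) under ``map``: unknown residue, stop, gaps.
_REMOVE_UNDER_MAP = frozenset("X*-.")

POLICIES = ("strict", "drop", "map")


class ResiduePolicyError(ValueError):
    """A sequence violates the residue policy (raised under ``strict``)."""


@dataclass
class ProteinRecord:
    """One identified, validated amino-acid sequence.

    ``sequence`` is guaranteed to be over the 20 standard codes after
    cleaning; ``raw_length`` preserves the residue count before cleaning.
    """

    id: str
    description: str
    sequence: str
    raw_length: int = field(default=0)

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("ProteinRecord id must be non-empty")
        if not self.sequence:
            raise ValueError(f"ProteinRecord {self.id!r}: empty sequence")
        bad = set(self.sequence) - _STANDARD_SET
        if bad:
            raise ValueError(
                f"ProteinRecord {self.id!r}: nonstandard residues {sorted(bad)}"
            )
        if self.raw_length == 0:
            self.raw_length = len(self.sequence)

    def __len__(self) -> int:
        return len(self.sequence)


def clean_sequence(seq: str, policy: str = "map", record_id: str = "?") -> str:
    """Uppercase ``seq`` and apply the residue policy.

    Returns the cleaned sequence (possibly empty).  Idempotent: cleaning a
    cleaned sequence is the identity.
    """
    if policy not in POLICIES:
        raise ValueError(f"unknown residue policy {policy!r}; choose from {POLICIES}")
    seq = seq.upper()
    out: list[str] = []
    for ch in seq:
        if ch in _STANDARD_SET:
            out.append(ch)
        elif policy == "strict":
            raise ResiduePolicyError(
                f"record {record_id!r}: nonstandard residue {ch!r} under strict policy"
            )
        elif policy == "drop":
            continue
        else:  # map
            if ch in AMBIGUITY_MAP:
                out.append(AMBIGUITY_MAP[ch])
            elif ch in _REMOVE_UNDER_MAP or ch.isspace():
                continue
            else:
                raise ResiduePolicyError(
                    f"record {record_id!r}: unmappable character {ch!r}"
                )
    return "".join(out)


def read_fasta(path: str | Path, policy: str = "map") -> list[ProteinRecord]:
    """Read a FASTA file into validated :class:`ProteinRecord` objects.

    Records appear in file order.  Duplicate ids are permitted (logged);
    records whose cleaned sequence is empty are omitted with a warning.
    Raises ``FileNotFoundError`` for a missing file and ``ValueError`` for
    malformed FASTA (e.g. sequence data before any ``>`` header).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"FASTA file not found: {path}")
    records: list[ProteinRecord] = []
    seen_ids: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        raw = str(entry.seq)
        cleaned = clean_sequence(raw, policy=policy, record_id=entry.id)
        if not cleaned:
            logger.warning(
                "record %r: empty sequence after cleaning (policy=%s); omitted",
                entry.id, policy,
            )
            continue
        if entry.id in seen_ids:
            logger.warning("duplicate FASTA id %r (kept; downstream keys on position)",
                           entry.id)
        seen_ids.add(entry.id)
        records.append(
            ProteinRecord(
                id=entry.id,
                description=entry.description,
                sequence=cleaned,
                raw_length=len(raw),
            )
        )
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path,
                width: int = 60) -> Path:
    """Write records as FASTA wrapped at ``width`` columns.

    Round-trips with ``read_fasta(path, policy="strict")`` on ids and
    sequences.
    """
    if width < 1:
        raise ValueError(f"width must be >= 1, got {width}")
    records = list(records)
    if not records:
        raise ValueError("no records to write")
    path = Path(path)
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seq_records)
    return path
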