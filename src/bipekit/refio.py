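"""Reference-sequence handling, coordinates and FASTA I/O.

Conventions used throughout the package:

* All genomic coordinates are 0-based, half-open, on the top (given) strand.
* Nick positions are inter-base coordinates: an integer ``c`` denotes the
  phosphodiester bond between bases ``c - 1`` and ``c``.
* Sequences are uppercase DNA over the alphabet ``{A, C, G, T, N}``;
  lowercase input is normalised on construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

DNA_ALPHABET = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _validate_dna(seq: str, what: str = "sequence") -> str:
    seq = seq.upper()
    for i, base in enumerate(seq):
        if base not in DNA_ALPHABET:
            raise ValueError(
                f"{what} contains non-DNA character {base!r} at position {i}"
            )
    return seq


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N maps to N).

    Raises ``ValueError`` naming the offending position for non-DNA input.
    """
    seq = _validate_dna(seq)
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomicInterval:
    """Contiguous reference span, 0-based half-open, with strand."""

    seq_id: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start < 0 or self.start > self.end:
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}): "
                "need 0 <= start <= end"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.seq_id == other.seq_id
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass(frozen=True)
class ReferenceSeq:
    """A named reference sequence (uppercase DNA over A/C/G/T/N)."""

    seq_id: str
    sequence: str = field(repr=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "sequence", _validate_dna(self.sequence, f"reference {self.seq_id!r}")
        )

    def __len__(self) -> int:
        return len(self.sequence)

    def interval(self, start: int, end: int, strand: str = "+") -> GenomicInterval:
        iv = GenomicInterval(self.seq_id, start, end, strand)
        if end > len(self):
            raise ValueError(
                f"interval [{start}, {end}) exceeds reference length {len(self)}"
            )
        return iv

    def slice(self, interval: GenomicInterval) -> str:
        """Sequence of ``interval`` read 5'->3' on its own strand."""
        if interval.seq_id != self.seq_id:
            raise ValueError(
                f"interval seq_id {interval.seq_id!r} != reference {self.seq_id!r}"
            )
        if interval.end > len(self):
            raise ValueError(
                f"interval [{interval.start}, {interval.end}) exceeds "
                f"reference length {len(self)}"
            )
        s = self.sequence[interval.start : interval.end]
        return revcomp(s) if interval.strand == "-" else s


def load_fasta(path: str | Path) -> list[ReferenceSeq]:
    """Read a FASTA file into a list of :class:`ReferenceSeq`, in file order.

    Rejects empty files and duplicate record IDs; sequences are normalised
    to uppercase.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    seen: set[str] = set()
    refs: list[ReferenceSeq] = []
    for rec in records:
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA record ID {rec.id!r} in {path}")
        seen.add(rec.id)
        refs.append(ReferenceSeq(rec.id, str(rec.seq)))
    return refs


def write_fasta(refs: Iterable[ReferenceSeq], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(ref.sequence), id=ref.seq_id, description="") for ref in refs
    ]
    SeqIO.write(records, str(path), "fasta")
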