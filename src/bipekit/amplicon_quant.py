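"""Amplicon-read classification and outcome-frequency tables.

Each read is aligned glocally (read end to end, allele overhangs free;
affine gaps, see :mod:`bipekit._align`) against every expected allele; the
best-scoring allele wins. Reads whose best alignment needs an indel are
labelled ``indel``; otherwise the read inherits the allele's label unless
its mismatch rate exceeds ``max_mm_rate`` (``other``). For multi-base
conversion designs a read carrying some but not all target substitutions is
an ``imperfect_conversion``.

Frequencies are percentages of total classified reads; an outcome counts as
*detected* only when its percentage strictly exceeds 0.01%.

The production classifier takes exact-substring and unit-cost (edlib)
shortcuts that are label-equivalent to the declared affine rule: a
substitutions-only unit-cost optimum is also affine-optimal, and any
alignment containing an indel has affine cost at least its unit cost. The
full affine computation runs only when the unit-cost path contains an indel.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import edlib
import pandas as pd

from ._align import affine_score, best_substitution_only
from .allele_model import Allele

#: Outcomes below this percentage of total reads are not called detected.
DETECTION_THRESHOLD_PCT = 0.01

DEFAULT_MAX_MM_RATE = 0.05
DEFAULT_JUNCTION_FLANK = 10

LABELS = ("desired", "wt", "indel", "imperfect_conversion", "single_side", "other")

_ALLELE_LABEL = {
    "desired": "desired",
    "WT": "wt",
    "left_only": "single_side",
    "right_only": "single_side",
}


@dataclass(frozen=True)
class ReadLabel:
    label: str
    n_mismatches: int = 0
    indel_ops: int = 0
    allele: str | None = None


def _cigar_ops(cigar: str) -> Counter:
    ops: Counter = Counter()
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            ops[ch] += int(num)
            num = ""
    return ops


def _label_no_indel(
    read: str,
    allele: Allele,
    offset: int,
    n_mm: int,
    max_mm_rate: float,
    conversion_design: bool,
) -> ReadLabel:
    if conversion_design:
        # recompute placement deterministically (smallest best offset)
        n_mm, offset = best_substitution_only(read, allele.sequence)
        covered = [
            (p, rb, ab)
            for p, rb, ab in allele.conversions
            if offset <= p < offset + len(read)
        ]
        n_alt = sum(read[p - offset] == ab for p, _, ab in covered)
        target_mm = sum(
            read[p - offset] != allele.sequence[p] for p, _, _ in covered
        )
        non_target_mm = n_mm - target_mm
        if non_target_mm / len(read) > max_mm_rate:
            return ReadLabel("other", n_mm, 0, allele.name)
        if covered:
            if n_alt == len(covered):
                return ReadLabel("desired", non_target_mm, 0, "desired")
            if n_alt == 0:
                return ReadLabel("wt", non_target_mm, 0, "WT")
            return ReadLabel("imperfect_conversion", non_target_mm, 0, allele.name)
    if n_mm / len(read) > max_mm_rate:
        return ReadLabel("other", n_mm, 0, allele.name)
    return ReadLabel(_ALLELE_LABEL.get(allele.name, "other"), n_mm, 0, allele.name)


def _classify_affine(
    read: str, alleles: list[Allele], max_mm_rate: float, conversion_design: bool
) -> ReadLabel:
    """Full affine-model decision, used when the unit-cost screen finds an
    indel in the best path."""
    results = []
    for al in alleles:
        score = affine_score(read, al.sequence)
        if len(read) <= len(al.sequence):
            mm, off = best_substitution_only(read, al.sequence)
            subs_score = -mm
        else:
            mm, off, subs_score = 0, 0, -math.inf
        results.append((score, subs_score, mm, off, al))
    best_score = max(r[0] for r in results)
    # tie-break: prefer an indel-free optimum, then allele list order
    for score, subs_score, mm, off, al in results:
        if score == best_score and subs_score == score:
            return _label_no_indel(read, al, off, mm, max_mm_rate, conversion_design)
    for score, _, _, _, al in results:
        if score == best_score:
            aln = edlib.align(read, al.sequence, mode="HW", task="path")
            ops = _cigar_ops(aln.get("cigar") or "")
            return ReadLabel(
                "indel", ops.get("X", 0), ops.get("I", 0) + ops.get("D", 0), al.name
            )
    raise AssertionError("unreachable")


def classify_read(
    read: str,
    alleles: list[Allele],
    *,
    max_mm_rate: float = DEFAULT_MAX_MM_RATE,
    junction_flank: int = DEFAULT_JUNCTION_FLANK,
) -> ReadLabel:
    """Classify one read against the expected alleles (see module docs)."""
    if not alleles:
        raise ValueError("empty allele list")
    read = read.upper()
    if len(read) < 2 * junction_flank:
        raise ValueError(
            f"read of {len(read)} nt shorter than 2 x junction_flank "
            f"({2 * junction_flank} nt)"
        )
    conversion_design = any(al.conversions for al in alleles)
    for al in alleles:
        off = al.sequence.find(read)
        if off >= 0:
            return _label_no_indel(read, al, off, 0, max_mm_rate, conversion_design)
    best_al: Allele | None = None
    best_res: dict | None = None
    for al in alleles:
        res = edlib.align(read, al.sequence, mode="HW", task="path")
        if res["editDistance"] < 0:
            continue
        if best_res is None or res["editDistance"] < best_res["editDistance"]:
            best_al, best_res = al, res
    if best_res is None:
        return ReadLabel("other", 0, 0, None)
    ops = _cigar_ops(best_res.get("cigar") or "")
    if ops.get("I", 0) == 0 and ops.get("D", 0) == 0:
        offset = best_res["locations"][0][0]
        return _label_no_indel(
            read, best_al, offset, best_res["editDistance"], max_mm_rate,
            conversion_design,
        )
    return _classify_affine(read, alleles, max_mm_rate, conversion_design)


@dataclass
class FrequencyTable:
    """Per-label and per-(allele, label) read counts with percentages and
    the >0.01% detection flag."""

    pair_counts: dict[tuple[str, str], int]
    total_reads: int
    skipped_records: int = 0
    threshold_pct: float = DETECTION_THRESHOLD_PCT

    @property
    def label_counts(self) -> dict[str, int]:
        counts = dict.fromkeys(LABELS, 0)
        for (_, label), n in self.pair_counts.items():
            counts[label] = counts.get(label, 0) + n
        return counts

    def count(self, label: str) -> int:
        return self.label_counts.get(label, 0)

    def percent(self, label: str) -> float:
        return 100.0 * self.count(label) / self.total_reads

    def detected(self, label: str) -> bool:
        return self.percent(label) > self.threshold_pct

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "label": label,
                "count": n,
                "percent": 100.0 * n / self.total_reads,
                "detected": 100.0 * n / self.total_reads > self.threshold_pct,
            }
            for label, n in self.label_counts.items()
        ]
        return pd.DataFrame(rows)

    def allele_frame(self) -> pd.DataFrame:
        rows = [
            {
                "allele": allele,
                "label": label,
                "count": n,
                "percent": 100.0 * n / self.total_reads,
                "detected": 100.0 * n / self.total_reads > self.threshold_pct,
            }
            for (allele, label), n in sorted(self.pair_counts.items())
        ]
        return pd.DataFrame(rows)


def _iter_fastq_text(handle) -> Iterator[tuple[str | None, str | None]]:
    """Tolerant 4-line FASTQ iteration: malformed records yield
    ``(None, None)`` so callers can count and skip them, rather than
    aborting the whole stream."""
    while True:
        header = handle.readline()
        if not header:
            return
        seq = handle.readline().strip().upper()
        plus = handle.readline()
        qual = handle.readline().strip()
        header = header.strip()
        ok = (
            header.startswith("@")
            and bool(seq)
            and plus.startswith("+")
            and len(qual) == len(seq)
            and all(c in "ACGTN" for c in seq)
        )
        if ok:
            yield header[1:].split()[0], seq
        else:
            yield None, None


def _iter_reads(reads) -> Iterator[tuple[str | None, str | None]]:
    if isinstance(reads, (str, Path)):
        with open(reads) as fh:
            yield from _iter_fastq_text(fh)
        return
    for i, item in enumerate(reads):
        if isinstance(item, str):
            yield f"read{i}", item.upper()
        elif hasattr(item, "seq"):  # Bio.SeqRecord
            yield item.id, str(item.seq).upper()
        else:
            name, seq = item[0], item[1]
            yield name, seq.upper()


def quantify(
    reads: str | Path | Iterable,
    alleles: list[Allele],
    *,
    max_mm_rate: float = DEFAULT_MAX_MM_RATE,
    junction_flank: int = DEFAULT_JUNCTION_FLANK,
) -> FrequencyTable:
    """Classify every read (FASTQ path, SeqRecords, ``(name, seq)`` pairs or
    bare strings) and tabulate outcome frequencies."""
    if not alleles:
        raise ValueError("empty allele list")
    cache: dict[str, ReadLabel] = {}
    pair_counts: Counter = Counter()
    total = skipped = 0
    for _, seq in _iter_reads(reads):
        if seq is None:
            skipped += 1
            continue
        rl = cache.get(seq)
        if rl is None:
            rl = classify_read(
                seq, alleles, max_mm_rate=max_mm_rate, junction_flank=junction_flank
            )
            cache[seq] = rl
        pair_counts[(rl.allele or "-", rl.label)] += 1
        total += 1
    if total == 0:
        raise ValueError("no classifiable reads in input")
    return FrequencyTable(dict(pair_counts), total, skipped)


def indel_among_edited(table: FrequencyTable) -> float | None:
    """Percentage of deletion-junction-bearing reads (best allele =
    desired) that carry additional indels; ``None`` when no junction-bearing
    reads exist."""
    exact = sum(
        n for (al, lab), n in table.pair_counts.items()
        if al == "desired" and lab == "desired"
    )
    with_indel = sum(
        n for (al, lab), n in table.pair_counts.items()
        if al == "desired" and lab == "indel"
    )
    junction = exact + with_indel
    if junction == 0:
        return None
    return 100.0 * with_indel / junction
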