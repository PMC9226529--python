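"""Seeded synthetic data: toy references with planted PAMs, amplicon read
sets drawn from expected-allele mixtures, and electrophoresis band tables.

The read simulator emulates single-end (or pre-merged paired-end) amplicon
sequencing: each read is drawn from an allele according to the requested
mixture, positioned to cover the edited span, and corrupted with i.i.d.
per-base substitution errors. Read headers record the true source allele so
tests can compute exact confusion matrices. Band tables optionally include
the small-fragment PCR amplification bias that inflates gel-based
efficiency estimates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .gel_quant import BandMeasurement
from .refio import ReferenceSeq
from .allele_model import Allele
from .guide_design import SPACER_LEN, NICK_OFFSET

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_PLACEHOLDER_QUAL = "I"  # uniform Q40 placeholder


@dataclass(frozen=True)
class SimulationSpec:
    """Mixture and error model for one simulated read set."""

    allele_freqs: dict[str, float]
    n_reads: int
    read_len: int
    error_rate: float = 0.001
    seed: int = 0
    indel_error_rate: float = 0.0

    def __post_init__(self) -> None:
        total = sum(self.allele_freqs.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"allele frequencies must sum to 1, got {total}")
        if any(not 0 <= f <= 1 for f in self.allele_freqs.values()):
            raise ValueError("allele frequencies must lie in [0, 1]")
        if self.n_reads < 1:
            raise ValueError("n_reads must be >= 1")
        if not 0 <= self.error_rate < 0.25:
            raise ValueError("error_rate must lie in [0, 0.25)")
        if not 0 <= self.indel_error_rate < 0.25:
            raise ValueError("indel_error_rate must lie in [0, 0.25)")


@dataclass(frozen=True)
class SimulatedRead:
    name: str
    sequence: str
    true_allele: str
    start: int

    @property
    def fastq(self) -> str:
        return (
            f"@{self.name} allele={self.true_allele} start={self.start}\n"
            f"{self.sequence}\n+\n{_PLACEHOLDER_QUAL * len(self.sequence)}\n"
        )


def make_reference(
    length: int, seed: int, pam_anchors: tuple[tuple[int, str], ...] = ()
) -> ReferenceSeq:
    """Uniform random A/C/G/T reference with PAM dinucleotides planted so
    each ``(nick position, strand)`` anchor yields a valid spacer site.
    Deterministic per seed."""
    rng = np.random.default_rng(seed)
    arr = _BASES[rng.integers(0, 4, size=length)].copy()
    planted: dict[int, int] = {}
    for pos, strand in pam_anchors:
        if strand == "+":
            # nick at pos: protospacer [pos-17, pos+3), PAM [pos+3, pos+6)
            if pos - (SPACER_LEN - NICK_OFFSET) < 0 or pos + NICK_OFFSET + 3 > length:
                raise ValueError(
                    f"anchor at ({pos}, +) leaves no room for a 20-nt "
                    "protospacer and PAM"
                )
            want = {pos + NICK_OFFSET + 1: ord("G"), pos + NICK_OFFSET + 2: ord("G")}
        elif strand == "-":
            if pos + (SPACER_LEN - NICK_OFFSET) > length or pos - NICK_OFFSET - 3 < 0:
                raise ValueError(
                    f"anchor at ({pos}, -) leaves no room for a 20-nt "
                    "protospacer and PAM"
                )
            want = {pos - NICK_OFFSET - 3: ord("C"), pos - NICK_OFFSET - 2: ord("C")}
        else:
            raise ValueError(f"anchor strand must be '+' or '-', got {strand!r}")
        for i, base in want.items():
            if planted.get(i, base) != base:
                raise ValueError(
                    f"conflicting PAM anchors: position {i} required to be "
                    f"both {chr(planted[i])} and {chr(base)}"
                )
            planted[i] = base
            arr[i] = base
    return ReferenceSeq(f"synth_{seed}", arr.tobytes().decode())


def _read_start_range(allele: Allele, read_len: int) -> tuple[int, int]:
    """Inclusive range of valid read start positions: the read covers the
    edited span when it fits, otherwise lies within it."""
    n = len(allele.sequence)
    lo_span, hi_span = allele.edited_span or (0, 0)
    if lo_span < 0 or hi_span > n:
        raise ValueError(
            f"allele {allele.name!r} ({n} bp) cannot position a read over its "
            f"edited span [{lo_span}, {hi_span}): span exceeds the allele"
        )
    if read_len >= n:
        return 0, 0
    span_len = hi_span - lo_span
    if span_len <= read_len:
        lo = max(0, hi_span - read_len)
        hi = min(lo_span, n - read_len)
    else:
        lo, hi = lo_span, hi_span - read_len
    if lo > hi:
        raise ValueError(
            f"allele {allele.name!r} ({n} bp) cannot position a {read_len} nt "
            "read to cover its edited span"
        )
    return lo, hi


def simulate_reads(alleles: list[Allele], spec: SimulationSpec) -> list[SimulatedRead]:
    """Draw ``spec.n_reads`` reads from the allele mixture (seeded, single
    RNG stream, emitted in generation order)."""
    amap = {al.name: al for al in alleles}
    missing = set(spec.allele_freqs) - set(amap)
    if missing:
        raise ValueError(f"allele_freqs name(s) not in allele list: {sorted(missing)}")
    names = sorted(spec.allele_freqs)
    probs = np.array([spec.allele_freqs[n] for n in names])
    probs = probs / probs.sum()
    rng = np.random.default_rng(spec.seed)
    # pre-validate positioning for every allele that can be drawn
    ranges = {
        name: _read_start_range(amap[name], spec.read_len)
        for name in names
        if spec.allele_freqs[name] > 0
    }
    choice = rng.choice(len(names), size=spec.n_reads, p=probs)
    encoded = {name: np.frombuffer(amap[name].sequence.encode(), np.uint8)
               for name in names}
    reads: list[SimulatedRead] = []
    for i in range(spec.n_reads):
        name = names[int(choice[i])]
        seq_arr = encoded[name]
        lo, hi = ranges[name]
        start = int(rng.integers(lo, hi + 1))
        rl = min(spec.read_len, len(seq_arr))
        read = seq_arr[start : start + rl].copy()
        err = rng.random(rl) < spec.error_rate
        if err.any():
            idx = np.nonzero(err)[0]
            # shift each errored base by 1-3 in A/C/G/T order: never a no-op
            cur = np.searchsorted(_BASES, read[idx])
            shift = rng.integers(1, 4, size=idx.size)
            read[idx] = _BASES[(cur + shift) % 4]
        seq = read.tobytes().decode()
        if spec.indel_error_rate > 0:
            seq = _apply_indel_errors(seq, spec.indel_error_rate, rng)
        reads.append(SimulatedRead(f"read{i}", seq, name, start))
    return reads


def _apply_indel_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    out = []
    for ch in seq:
        r = rng.random()
        if r < rate / 2:
            continue  # deletion
        if r < rate:
            out.append(chr(_BASES[rng.integers(0, 4)]))  # insertion before base
        out.append(ch)
    return "".join(out)


def write_fastq(reads: list[SimulatedRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        for read in reads:
            fh.write(read.fastq)


def true_frequency_table(reads: list[SimulatedRead]) -> dict[str, float]:
    counts: dict[str, int] = {}
    for read in reads:
        counts[read.true_allele] = counts.get(read.true_allele, 0) + 1
    return {name: 100.0 * n / len(reads) for name, n in sorted(counts.items())}


def simulate_bands(
    true_edited_fraction: float,
    length_edited: float,
    length_non_edited: float,
    bias_per_kb: float = 0.0,
    scale: float = 1000.0,
) -> tuple[BandMeasurement, BandMeasurement]:
    """Band signals for a true edited-allele fraction.

    With ``bias_per_kb = 0`` the gel-efficiency formula recovers the true
    fraction exactly; positive bias with a shorter edited fragment models
    the PCR preference for small amplicons and inflates the estimate.
    """
    if not 0 <= true_edited_fraction <= 1:
        raise ValueError("true_edited_fraction must lie in [0, 1]")
    if length_edited <= 0 or length_non_edited <= 0:
        raise ValueError("fragment lengths must be positive")
    bias = math.exp(bias_per_kb * (length_non_edited - length_edited) / 1000.0)
    signal_e = true_edited_fraction * length_edited * bias * scale
    signal_n = (1.0 - true_edited_fraction) * length_non_edited * scale
    return (
        BandMeasurement("edited", signal_e, length_edited),
        BandMeasurement("non_edited", signal_n, length_non_edited),
    )
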