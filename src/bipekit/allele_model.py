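"""Expected amplicon alleles, restriction-digest fragments, and colony
classification for paired-insertion designs.

For an amplicon of length X spanning a designed deletion of N bp with an
insertion of I bp, the desired allele has length X - N + I (the gel-sizing
identity Y = X - N for pure deletions). Double-insertion designs
additionally produce ``left_only`` / ``right_only`` single-insertion
intermediates visible on gels.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import edlib

from .refio import GenomicInterval, revcomp
from .guide_design import PegRNA, SpacerSite, StrategyDesign

#: Flanking bases (each side) of the edited span used when matching a cloned
#: colony sequence against the desired allele.
COLONY_FLANK = 20


@dataclass(frozen=True)
class Allele:
    """An expected amplicon sequence.

    ``edited_span`` is the half-open interval, in allele coordinates, of the
    rewritten region (used to position simulated reads and to score
    classification windows). ``conversions`` carries the design's target
    base conversions in allele coordinates, for conversion designs only.
    """

    name: str
    sequence: str
    edited_span: tuple[int, int] | None = None
    conversions: tuple[tuple[int, str, str], ...] = ()

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class DigestResult:
    enzyme_site: str
    cut_offset: int
    fragments: tuple[int, ...]

    @property
    def n_fragments(self) -> int:
        return len(self.fragments)


def _pbs_len(design: StrategyDesign) -> int:
    pegs = design.pegrnas
    return max(len(p.pbs) for p in pegs) if pegs else 0


def _required_span(design: StrategyDesign) -> tuple[int, int]:
    """Top-strand span the amplicon must cover: edited region plus the PBS
    footprint of every pegRNA (primers must sit outside the PBS)."""
    edit = design.achieved_edit
    if edit.kind in ("deletion", "replacement"):
        lo, hi = edit.deletion.start, edit.deletion.end
    elif edit.kind == "conversions":
        positions = [p for p, _, _ in edit.conversions]
        lo, hi = min(positions), max(positions) + 1
    else:
        inner = edit.pair_insert[2]
        lo, hi = inner.start, inner.end
    for guide in (design.left_guide, design.right_guide):
        if isinstance(guide, PegRNA):
            nick = guide.site.nick_pos
            if guide.site.strand == "+":
                lo = min(lo, nick - len(guide.pbs))
            else:
                hi = max(hi, nick + len(guide.pbs))
        elif isinstance(guide, SpacerSite):
            lo = min(lo, guide.proto_interval.start)
            hi = max(hi, guide.proto_interval.end)
    return lo, hi


def expected_alleles(
    design: StrategyDesign, amplicon: GenomicInterval
) -> list[Allele]:
    """Expected alleles for ``design`` within ``amplicon``: always WT and
    desired; for double insertions also the single-insertion intermediates.
    """
    ref = design.ref
    if amplicon.end > len(ref):
        raise ValueError("amplicon exceeds reference length")
    lo, hi = _required_span(design)
    if not (amplicon.start <= lo and hi <= amplicon.end):
        raise ValueError(
            f"amplicon [{amplicon.start}, {amplicon.end}) does not cover the "
            f"edited region and PBS footprints [{lo}, {hi})"
        )
    seq = ref.sequence
    a, b = amplicon.start, amplicon.end
    edit = design.achieved_edit

    if edit.kind in ("deletion", "replacement"):
        s, e = edit.deletion.start, edit.deletion.end
        ins = edit.insertion
        wt = Allele("WT", seq[a:b], edited_span=(s - a, e - a))
        desired = Allele(
            "desired",
            seq[a:s] + ins + seq[e:b],
            edited_span=(s - a, s - a + len(ins)),
        )
        return [wt, desired]

    if edit.kind == "conversions":
        positions = sorted(p for p, _, _ in edit.conversions)
        span = (positions[0] - a, positions[-1] + 1 - a)
        conv_local = tuple(
            (p - a, rb, ab) for p, rb, ab in sorted(edit.conversions)
        )
        desired_seq = list(seq[a:b])
        for p, _, alt in edit.conversions:
            desired_seq[p - a] = alt
        wt = Allele("WT", seq[a:b], edited_span=span, conversions=conv_local)
        desired = Allele(
            "desired", "".join(desired_seq), edited_span=span, conversions=conv_local
        )
        return [wt, desired]

    # double insertion
    ins_l, ins_r, inner = edit.pair_insert
    l, r = inner.start, inner.end
    t = len(ins_l)
    wt = Allele("WT", seq[a:b], edited_span=(l - a, r - a))
    desired = Allele(
        "desired",
        seq[a:l] + ins_l + seq[l:r] + ins_r + seq[r:b],
        edited_span=(l - a, r - a + 2 * t),
    )
    # intermediate spans cover BOTH insertion points: a read over a single
    # junction cannot distinguish an intermediate from the desired allele
    left_only = Allele(
        "left_only", seq[a:l] + ins_l + seq[l:b], edited_span=(l - a, r - a + t)
    )
    right_only = Allele(
        "right_only", seq[a:r] + ins_r + seq[r:b], edited_span=(l - a, r - a + t)
    )
    return [wt, desired, left_only, right_only]


def digest(allele: Allele, site: str, cut_offset: int) -> DigestResult:
    """Cut ``allele`` at every occurrence of ``site``; fragments are
    returned left to right and always sum to the parent length.

    For palindromic sites (e.g. EcoRV GATATC) only the top strand is
    scanned; otherwise occurrences on both strands cut.
    """
    if not site:
        raise ValueError("recognition site must be non-empty")
    if not 0 <= cut_offset <= len(site):
        raise ValueError("cut_offset must lie within the recognition site")
    seq = allele.sequence
    cuts: set[int] = set()
    for m in re.finditer(f"(?={re.escape(site)})", seq):
        cuts.add(m.start() + cut_offset)
    rc = revcomp(site)
    if rc != site:
        for m in re.finditer(f"(?={re.escape(rc)})", seq):
            cuts.add(m.start() + len(site) - cut_offset)
    ordered = sorted(c for c in cuts if 0 < c < len(seq))
    bounds = [0, *ordered, len(seq)]
    fragments = tuple(bounds[i + 1] - bounds[i] for i in range(len(bounds) - 1))
    return DigestResult(enzyme_site=site, cut_offset=cut_offset, fragments=fragments)


def _count_occurrences(haystack: str, needle: str) -> int:
    count = start = 0
    while True:
        idx = haystack.find(needle, start)
        if idx < 0:
            return count
        count += 1
        start = idx + len(needle)


def classify_colony(seq: str, design: StrategyDesign) -> str:
    """Classify a cloned (Sanger-length) amplicon from a double-insertion
    design.

    ``accurate``: the sequence matches the desired allele exactly over the
    edited span (inserts plus COLONY_FLANK bp flanks). ``inaccurate``: both
    inserts are present but the alignment to the desired allele contains at
    least one indel. ``no_double_insert`` otherwise.
    """
    if not seq:
        raise ValueError("empty colony sequence")
    edit = design.achieved_edit
    if edit.kind != "double_insertion":
        raise ValueError("colony classification applies to double-insertion designs")
    seq = seq.upper()
    ref = design.ref
    full = GenomicInterval(ref.seq_id, 0, len(ref))
    desired = next(
        al for al in expected_alleles(design, full) if al.name == "desired"
    )
    span_lo, span_hi = desired.edited_span
    lo = max(0, span_lo - COLONY_FLANK)
    hi = min(len(desired.sequence), span_hi + COLONY_FLANK)
    window = desired.sequence[lo:hi]
    if window in seq:
        return "accurate"
    insert = edit.pair_insert[0]
    if _count_occurrences(seq, insert) >= 2:
        aln = edlib.align(window, seq, mode="HW", task="path")
        cigar = aln.get("cigar") or ""
        if "I" in cigar or "D" in cigar:
            return "inaccurate"
    return "no_double_insert"
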