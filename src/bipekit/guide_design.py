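"""pegRNA and nick-sgRNA design for PE3 and bi-directional prime editing.

A pegRNA is a guide RNA carrying, 3' of its scaffold, an RT template and a
primer binding site (PBS). At the nick the reverse transcriptase copies the
RT template into a 3' flap whose sequence is ``edit_content + HA``: the new
bases to be written, followed by a homology arm matching the reference
beyond the rewritten region. Bi-directional designs (Bi-PE) make *both*
guides pegRNAs, priming in opposite directions; Bi-PE-2 flaps carry only the
edit, Bi-PE-3 flaps carry edit + HA. PE3 designs (L-PE3 / R-PE3) carry one
pegRNA and one plain nick sgRNA on the other strand.

Nick sgRNAs for a top-strand pegRNA are classified relative to the fragment
to be deleted: Type I nicks fall inside it, Type II within the HA-pairing
window just beyond its 3' end, Type III further downstream. Only Type II
nicks support large-fragment deletion, so candidates are ranked
Type II < Type III < Type I.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum

from .refio import GenomicInterval, ReferenceSeq, revcomp, _validate_dna

SPACER_LEN = 20
#: Distance of the SpCas9 nick 5' of the PAM, on the PAM-containing strand.
NICK_OFFSET = 3
#: Canonical SpCas9 sgRNA scaffold (DNA form); overridable on every builder.
SPCAS9_SCAFFOLD = (
    "GTTTTAGAGCTAGAAATAGCAAGTTAAAATAAGGCTAGTCCGTTATCAACTTGAAAAAGTGGCACCGAGTCGGTGC"
)

DEFAULT_PBS_LEN = 13
DEFAULT_HA_LEN = 25
DEFAULT_SNAP_WINDOW = 10


class NickType(Enum):
    TYPE_I = "TypeI"
    TYPE_II = "TypeII"
    TYPE_III = "TypeIII"
    OUT_OF_RANGE = "out_of_range"


@dataclass(frozen=True)
class SpacerSite:
    """A 20-nt protospacer with NGG PAM and its derived nick coordinate.

    ``protospacer`` and ``pam`` are given 5'->3' on the protospacer strand;
    ``proto_interval`` is in top-strand coordinates; ``nick_pos`` is the
    inter-base coordinate of the nick on the protospacer strand.
    """

    protospacer: str
    strand: str
    pam: str
    proto_interval: GenomicInterval
    nick_pos: int

    def __post_init__(self) -> None:
        if len(self.protospacer) != SPACER_LEN:
            raise ValueError("protospacer must be 20 nt")
        if self.pam[1:3] != "GG":
            raise ValueError(f"PAM {self.pam!r} does not match NGG")
        if self.proto_interval.length != SPACER_LEN:
            raise ValueError("proto_interval must span 20 nt")
        expected = (
            self.proto_interval.end - NICK_OFFSET
            if self.strand == "+"
            else self.proto_interval.start + NICK_OFFSET
        )
        if self.nick_pos != expected:
            raise ValueError(
                f"nick_pos {self.nick_pos} inconsistent with {self.strand} "
                f"protospacer at [{self.proto_interval.start}, "
                f"{self.proto_interval.end}) (expected {expected})"
            )


@dataclass(frozen=True)
class PegRNA:
    """pegRNA = spacer + scaffold + RT template + PBS (5'->3').

    ``flap`` is the 3' flap written at the nick, read 5'->3' on the nicked
    strand; it equals ``edit_content + HA`` and is the reverse complement of
    ``rt_template``.
    """

    site: SpacerSite
    scaffold: str
    pbs: str
    rt_template: str
    ha_len: int
    edit_content: str = ""

    @property
    def flap(self) -> str:
        return revcomp(self.rt_template)

    @property
    def full_sequence(self) -> str:
        return self.site.protospacer + self.scaffold + self.rt_template + self.pbs


@dataclass(frozen=True)
class EditSpec:
    """A requested edit: deletion, replacement, base conversions, or a
    paired (double) insertion flanking an inner segment.

    ``conversions`` entries are ``(top-strand position, ref_base, alt_base)``.
    ``pair_insert`` is ``(left insert, right insert, inner interval)`` with
    both inserts given 5'->3' on the top strand.
    """

    kind: str
    deletion: GenomicInterval | None = None
    insertion: str = ""
    conversions: tuple[tuple[int, str, str], ...] = ()
    pair_insert: tuple[str, str, GenomicInterval] | None = None

    def __post_init__(self) -> None:
        kinds = ("deletion", "replacement", "conversions", "double_insertion")
        if self.kind not in kinds:
            raise ValueError(f"kind must be one of {kinds}, got {self.kind!r}")
        if self.insertion:
            _validate_dna(self.insertion, "insertion")
        if self.kind == "deletion":
            if self.deletion is None:
                raise ValueError("deletion edit requires a deletion interval")
            if self.insertion:
                raise ValueError("deletion edit must have empty insertion")
        elif self.kind == "replacement":
            if self.deletion is None or not self.insertion:
                raise ValueError(
                    "replacement requires a deletion interval and a "
                    "non-empty insertion"
                )
        elif self.kind == "conversions":
            if not self.conversions:
                raise ValueError("conversions edit requires >=1 conversion")
            for pos, ref_b, alt_b in self.conversions:
                if ref_b == alt_b:
                    raise ValueError(
                        f"conversion at {pos}: alt base equals ref base {ref_b!r}"
                    )
        elif self.kind == "double_insertion":
            if self.pair_insert is None:
                raise ValueError("double_insertion requires pair_insert")

    def validate_against(self, ref: ReferenceSeq) -> None:
        for pos, ref_b, _ in self.conversions:
            if ref.sequence[pos] != ref_b:
                raise ValueError(
                    f"conversion ref base {ref_b!r} does not match reference "
                    f"base {ref.sequence[pos]!r} at position {pos}"
                )


@dataclass
class StrategyDesign:
    """A realised guide set: strategy label, left/right guides, the edit
    actually achieved after snapping boundaries to nicks, and warnings."""

    strategy: str
    left_guide: PegRNA | SpacerSite
    right_guide: PegRNA | SpacerSite
    achieved_edit: EditSpec
    ref: ReferenceSeq
    warnings: list[str] = field(default_factory=list)

    def _nick(self, guide: PegRNA | SpacerSite) -> int:
        return guide.site.nick_pos if isinstance(guide, PegRNA) else guide.nick_pos

    @property
    def nick_left(self) -> int:
        return self._nick(self.left_guide)

    @property
    def nick_right(self) -> int:
        return self._nick(self.right_guide)

    @property
    def pegrnas(self) -> list[PegRNA]:
        return [g for g in (self.left_guide, self.right_guide) if isinstance(g, PegRNA)]


def find_spacers(
    ref: ReferenceSeq, region: GenomicInterval | None = None
) -> list[SpacerSite]:
    """Enumerate every NGG site on both strands whose 20-nt protospacer and
    PAM fit inside ``region``; sorted by nick position, then strand."""
    if region is None:
        region = GenomicInterval(ref.seq_id, 0, len(ref))
    if region.end > len(ref):
        raise ValueError("region exceeds reference length")
    seq = ref.sequence
    sites: list[SpacerSite] = []
    for p in range(region.start, region.end - 2):
        # top strand: PAM at [p, p+3), protospacer at [p-20, p)
        if seq[p + 1] == "G" and seq[p + 2] == "G" and p - SPACER_LEN >= region.start:
            sites.append(
                SpacerSite(
                    protospacer=seq[p - SPACER_LEN : p],
                    strand="+",
                    pam=seq[p : p + 3],
                    proto_interval=GenomicInterval(ref.seq_id, p - SPACER_LEN, p, "+"),
                    nick_pos=p - NICK_OFFSET,
                )
            )
        # bottom strand: PAM (NGG on bottom) shows as CCN on top at [p, p+3),
        # protospacer at [p+3, p+23)
        if seq[p] == "C" and seq[p + 1] == "C" and p + 3 + SPACER_LEN <= region.end:
            sites.append(
                SpacerSite(
                    protospacer=revcomp(seq[p + 3 : p + 3 + SPACER_LEN]),
                    strand="-",
                    pam=revcomp(seq[p : p + 3]),
                    proto_interval=GenomicInterval(
                        ref.seq_id, p + 3, p + 3 + SPACER_LEN, "-"
                    ),
                    nick_pos=p + 3 + NICK_OFFSET,
                )
            )
    sites.sort(key=lambda s: (s.nick_pos, s.strand))
    return sites


def classify_nick(
    nick: SpacerSite | int,
    deletion: GenomicInterval,
    ha_len: int,
    pegrna_strand: str = "+",
) -> NickType:
    """Classify a nick on the non-edited strand relative to the fragment to
    be deleted.

    For a top-strand pegRNA (``pegrna_strand='+'``): Type I iff
    ``deletion.start < nick_pos <= deletion.end``; Type II iff
    ``deletion.end < nick_pos <= deletion.end + ha_len``; Type III iff
    ``nick_pos > deletion.end + ha_len``; nicks at or before
    ``deletion.start`` are out of range. ``pegrna_strand='-'`` applies the
    strand-mirrored rule.
    """
    if ha_len < 1:
        raise ValueError("ha_len must be >= 1")
    if deletion.length <= 0:
        raise ValueError("deletion interval must be non-empty")
    pos = nick.nick_pos if isinstance(nick, SpacerSite) else int(nick)
    if pegrna_strand == "+":
        if pos <= deletion.start:
            return NickType.OUT_OF_RANGE
        if pos <= deletion.end:
            return NickType.TYPE_I
        if pos <= deletion.end + ha_len:
            return NickType.TYPE_II
        return NickType.TYPE_III
    # mirrored rule for a bottom-strand pegRNA
    if pos >= deletion.end:
        return NickType.OUT_OF_RANGE
    if pos >= deletion.start:
        return NickType.TYPE_I
    if pos >= deletion.start - ha_len:
        return NickType.TYPE_II
    return NickType.TYPE_III


_RANK = {
    NickType.TYPE_II: 0,
    NickType.TYPE_III: 1,
    NickType.TYPE_I: 2,
    NickType.OUT_OF_RANGE: 3,
}


def rank_nick_candidates(
    cands: list[SpacerSite],
    deletion: GenomicInterval,
    ha_len: int,
    pegrna_strand: str = "+",
) -> list[SpacerSite]:
    """Stable ordering Type II < Type III < Type I; within a class,
    ascending distance from the HA-proximal deletion boundary."""
    if not cands:
        raise ValueError("no nick candidates to rank")
    anchor = deletion.end if pegrna_strand == "+" else deletion.start
    ranked = sorted(
        cands,
        key=lambda s: (
            _RANK[classify_nick(s, deletion, ha_len, pegrna_strand)],
            abs(s.nick_pos - anchor),
        ),
    )
    if all(
        classify_nick(s, deletion, ha_len, pegrna_strand) is not NickType.TYPE_II
        for s in cands
    ):
        warnings.warn(
            "no Type II nick candidate available; large-fragment deletion "
            "is unlikely to be detectable",
            stacklevel=2,
        )
    return ranked


def build_pegrna(
    site: SpacerSite,
    edit_content: str,
    ha_len: int,
    pbs_len: int,
    ref: ReferenceSeq,
    ha_start: int | None = None,
    scaffold: str = SPCAS9_SCAFFOLD,
) -> PegRNA:
    """Assemble a pegRNA for ``site``.

    ``ha_start`` is the inter-base top-strand coordinate where the homology
    arm begins, i.e. the far end of the region being rewritten (defaults to
    the nick itself: pure insertion). The flap is ``edit_content + HA`` read
    5'->3' on the nicked strand, and ``rt_template = revcomp(flap)``.
    """
    if pbs_len < 1:
        raise ValueError("pbs_len must be >= 1")
    if ha_len < 0:
        raise ValueError("ha_len must be >= 0")
    edit_content = _validate_dna(edit_content, "edit_content") if edit_content else ""
    seq = ref.sequence
    nick = site.nick_pos
    if ha_start is None:
        ha_start = nick
    if site.strand == "+":
        if nick - pbs_len < 0:
            raise ValueError(
                f"PBS runs off the reference 5' end; extend by {pbs_len - nick} nt"
            )
        pbs = revcomp(seq[nick - pbs_len : nick])
        if ha_start + ha_len > len(seq):
            raise ValueError(
                "HA runs off the reference 3' end; extend by "
                f"{ha_start + ha_len - len(seq)} nt"
            )
        ha = seq[ha_start : ha_start + ha_len]
    else:
        if nick + pbs_len > len(seq):
            raise ValueError(
                "PBS runs off the reference 3' end; extend by "
                f"{nick + pbs_len - len(seq)} nt"
            )
        pbs = seq[nick : nick + pbs_len]
        if ha_start - ha_len < 0:
            raise ValueError(
                f"HA runs off the reference 5' end; extend by {ha_len - ha_start} nt"
            )
        ha = revcomp(seq[ha_start - ha_len : ha_start])
    flap = edit_content + ha
    if not flap:
        warnings.warn(
            "pegRNA with empty 3' flap (no edit content and ha_len 0)",
            stacklevel=2,
        )
    return PegRNA(
        site=site,
        scaffold=scaffold,
        pbs=pbs,
        rt_template=revcomp(flap),
        ha_len=ha_len,
        edit_content=edit_content,
    )


def _nearest(
    cands: list[SpacerSite], target: int, snap_window: int, side: str
) -> SpacerSite:
    if not cands:
        raise ValueError(f"no {side} spacer sites found on the reference")
    best = min(cands, key=lambda s: (abs(s.nick_pos - target), s.nick_pos))
    if abs(best.nick_pos - target) > snap_window:
        nearest = sorted(cands, key=lambda s: abs(s.nick_pos - target))[:3]
        raise ValueError(
            f"no {side} spacer with nick within {snap_window} nt of position "
            f"{target}; nearest available nicks: "
            f"{[s.nick_pos for s in nearest]}"
        )
    return best


def _apply_conversions(
    seq: str, conversions: tuple[tuple[int, str, str], ...]
) -> str:
    out = list(seq)
    for pos, _, alt in conversions:
        out[pos] = alt
    return "".join(out)


def design_bipe(
    ref: ReferenceSeq,
    edit: EditSpec,
    mode: str = "BiPE3",
    *,
    pbs_len: int = DEFAULT_PBS_LEN,
    ha_len: int = DEFAULT_HA_LEN,
    snap_window: int = DEFAULT_SNAP_WINDOW,
    scaffold: str = SPCAS9_SCAFFOLD,
) -> StrategyDesign:
    """Design a bi-directional pegRNA pair (both guides are pegRNAs).

    Bi-PE-2 flaps carry only the edit; Bi-PE-3 flaps additionally carry a
    homology arm matching the retained sequence beyond the far nick. For
    deletions/replacements the achieved deletion snaps to ``[nick_L, nick_R)``;
    for conversions both flaps encode every converted position.
    """
    if mode not in ("BiPE2", "BiPE3"):
        raise ValueError("mode must be 'BiPE2' or 'BiPE3'")
    if edit.kind not in ("deletion", "replacement", "conversions"):
        raise ValueError(f"design_bipe does not handle kind {edit.kind!r}")
    edit.validate_against(ref)
    eff_ha = ha_len if mode == "BiPE3" else 0
    sites = find_spacers(ref)
    plus = [s for s in sites if s.strand == "+"]
    minus = [s for s in sites if s.strand == "-"]
    notes: list[str] = []

    if edit.kind in ("deletion", "replacement"):
        s, e = edit.deletion.start, edit.deletion.end
        left_site = _nearest(plus, s, snap_window, "+ strand")
        right_site = _nearest(minus, e, snap_window, "- strand")
        nick_l, nick_r = left_site.nick_pos, right_site.nick_pos
        if nick_l >= nick_r:
            raise ValueError(
                f"left nick {nick_l} is not left of right nick {nick_r}"
            )
        if (nick_l, nick_r) != (s, e):
            notes.append(
                f"deletion snapped from [{s}, {e}) to nicks [{nick_l}, {nick_r})"
            )
        ins = edit.insertion
        with warnings.catch_warnings():
            if not ins and eff_ha == 0:
                warnings.simplefilter("always")
            left = build_pegrna(
                left_site, ins, eff_ha, pbs_len, ref, ha_start=nick_r, scaffold=scaffold
            )
            right = build_pegrna(
                right_site,
                revcomp(ins) if ins else "",
                eff_ha,
                pbs_len,
                ref,
                ha_start=nick_l,
                scaffold=scaffold,
            )
        if not ins and eff_ha == 0:
            notes.append("BiPE2 deletion yields empty flaps; use BiPE3 for deletions")
        achieved = EditSpec(
            kind=edit.kind,
            deletion=GenomicInterval(ref.seq_id, nick_l, nick_r),
            insertion=ins,
        )
    else:  # conversions
        positions = sorted(p for p, _, _ in edit.conversions)
        cov_start, cov_end = positions[0], positions[-1] + 1
        left_cands = [s for s in plus if s.nick_pos <= cov_start]
        right_cands = [s for s in minus if s.nick_pos >= cov_end]
        left_site = _nearest(left_cands, cov_start, snap_window, "+ strand")
        right_site = _nearest(right_cands, cov_end, snap_window, "- strand")
        nick_l, nick_r = left_site.nick_pos, right_site.nick_pos
        edited = _apply_conversions(ref.sequence, edit.conversions)
        left = build_pegrna(
            left_site,
            edited[nick_l:cov_end],
            eff_ha,
            pbs_len,
            ref,
            ha_start=cov_end,
            scaffold=scaffold,
        )
        right = build_pegrna(
            right_site,
            revcomp(edited[cov_start:nick_r]),
            eff_ha,
            pbs_len,
            ref,
            ha_start=cov_start,
            scaffold=scaffold,
        )
        notes.append(
            "the two flap homology footprints overlap across the converted "
            "region (expected for conversion designs)"
        )
        achieved = edit
    return StrategyDesign(
        strategy=mode,
        left_guide=left,
        right_guide=right,
        achieved_edit=achieved,
        ref=ref,
        warnings=notes,
    )


def design_pe3(
    ref: ReferenceSeq,
    edit: EditSpec,
    side: str = "L",
    *,
    pbs_len: int = DEFAULT_PBS_LEN,
    ha_len: int = DEFAULT_HA_LEN,
    snap_window: int = DEFAULT_SNAP_WINDOW,
    scaffold: str = SPCAS9_SCAFFOLD,
) -> StrategyDesign:
    """Design a PE3 strategy: one pegRNA on the stated side, plus a plain
    nick sgRNA on the other strand chosen by :func:`rank_nick_candidates`
    (Type II first)."""
    if side not in ("L", "R"):
        raise ValueError("side must be 'L' or 'R'")
    if edit.kind not in ("deletion", "replacement", "conversions"):
        raise ValueError(f"design_pe3 does not handle kind {edit.kind!r}")
    edit.validate_against(ref)
    sites = find_spacers(ref)
    plus = [s for s in sites if s.strand == "+"]
    minus = [s for s in sites if s.strand == "-"]
    notes: list[str] = []

    if edit.kind in ("deletion", "replacement"):
        s, e = edit.deletion.start, edit.deletion.end
        ins = edit.insertion
        if side == "L":
            peg_site = _nearest(plus, s, snap_window, "+ strand")
            nick_l = peg_site.nick_pos
            if nick_l != s:
                notes.append(f"deletion start snapped from {s} to nick {nick_l}")
            peg = build_pegrna(
                peg_site, ins, ha_len, pbs_len, ref, ha_start=e, scaffold=scaffold
            )
            ach_del = GenomicInterval(ref.seq_id, nick_l, e)
            ranked = rank_nick_candidates(minus, ach_del, ha_len, "+")
            left_guide, right_guide = peg, ranked[0]
        else:
            peg_site = _nearest(minus, e, snap_window, "- strand")
            nick_r = peg_site.nick_pos
            if nick_r != e:
                notes.append(f"deletion end snapped from {e} to nick {nick_r}")
            peg = build_pegrna(
                peg_site,
                revcomp(ins) if ins else "",
                ha_len,
                pbs_len,
                ref,
                ha_start=s,
                scaffold=scaffold,
            )
            ach_del = GenomicInterval(ref.seq_id, s, nick_r)
            ranked = rank_nick_candidates(plus, ach_del, ha_len, "-")
            left_guide, right_guide = ranked[0], peg
        achieved = EditSpec(kind=edit.kind, deletion=ach_del, insertion=ins)
    else:  # conversions
        positions = sorted(p for p, _, _ in edit.conversions)
        cov_start, cov_end = positions[0], positions[-1] + 1
        edited = _apply_conversions(ref.sequence, edit.conversions)
        if side == "L":
            cands = [x for x in plus if x.nick_pos <= cov_start]
            peg_site = _nearest(cands, cov_start, snap_window, "+ strand")
            nick_l = peg_site.nick_pos
            peg = build_pegrna(
                peg_site,
                edited[nick_l:cov_end],
                ha_len,
                pbs_len,
                ref,
                ha_start=cov_end,
                scaffold=scaffold,
            )
            span = GenomicInterval(ref.seq_id, nick_l, cov_end)
            ranked = rank_nick_candidates(minus, span, ha_len, "+")
            left_guide, right_guide = peg, ranked[0]
        else:
            cands = [x for x in minus if x.nick_pos >= cov_end]
            peg_site = _nearest(cands, cov_end, snap_window, "- strand")
            nick_r = peg_site.nick_pos
            peg = build_pegrna(
                peg_site,
                revcomp(edited[cov_start:nick_r]),
                ha_len,
                pbs_len,
                ref,
                ha_start=cov_start,
                scaffold=scaffold,
            )
            span = GenomicInterval(ref.seq_id, cov_start, nick_r)
            ranked = rank_nick_candidates(plus, span, ha_len, "-")
            left_guide, right_guide = ranked[0], peg
        achieved = edit
    return StrategyDesign(
        strategy=f"{side}-PE3",
        left_guide=left_guide,
        right_guide=right_guide,
        achieved_edit=achieved,
        ref=ref,
        warnings=notes,
    )


#: Inner-segment length beyond which paired-insertion efficiency is expected
#: to attenuate markedly (90 bp segments insert well; ~200 bp poorly).
INNER_SEGMENT_WARN_BP = 150


def design_double_insertion(
    ref: ReferenceSeq,
    spec: EditSpec,
    *,
    pbs_len: int = DEFAULT_PBS_LEN,
    ha_len: int = DEFAULT_HA_LEN,
    snap_window: int = DEFAULT_SNAP_WINDOW,
    tag: str | None = None,
    scaffold: str = SPCAS9_SCAFFOLD,
) -> StrategyDesign:
    """Design a same-orientation paired insertion (e.g. double LoxP)
    flanking an inner segment; each flap is the (tag-augmented) insert plus
    a homology arm pointing into the inner segment."""
    if spec.kind != "double_insertion":
        raise ValueError("spec.kind must be 'double_insertion'")
    left_ins, right_ins, inner = spec.pair_insert
    if left_ins != right_ins:
        raise ValueError(
            "paired insertion requires both inserts identical on the top "
            "strand (same orientation); got differing sequences"
        )
    insert = _validate_dna(left_ins, "insert")
    if tag:
        insert = insert + _validate_dna(tag, "tag")
    sites = find_spacers(ref)
    plus = [s for s in sites if s.strand == "+"]
    minus = [s for s in sites if s.strand == "-"]
    left_site = _nearest(plus, inner.start, snap_window, "+ strand")
    right_site = _nearest(minus, inner.end, snap_window, "- strand")
    nick_l, nick_r = left_site.nick_pos, right_site.nick_pos
    if nick_r - nick_l < 2 * ha_len:
        raise ValueError(
            f"inner segment [{nick_l}, {nick_r}) is shorter than the "
            f"combined homology-arm lengths ({2 * ha_len} nt)"
        )
    notes: list[str] = []
    if (nick_l, nick_r) != (inner.start, inner.end):
        notes.append(
            f"inner segment snapped from [{inner.start}, {inner.end}) to "
            f"nicks [{nick_l}, {nick_r})"
        )
    inner_len = nick_r - nick_l
    notes.append(f"inner segment length: {inner_len} bp")
    if inner_len > INNER_SEGMENT_WARN_BP:
        notes.append(
            f"inner segment of {inner_len} bp: double-insertion efficiency "
            "attenuates as the segment between the inserts lengthens"
        )
    left = build_pegrna(
        left_site, insert, ha_len, pbs_len, ref, ha_start=nick_l, scaffold=scaffold
    )
    right = build_pegrna(
        right_site,
        revcomp(insert),
        ha_len,
        pbs_len,
        ref,
        ha_start=nick_r,
        scaffold=scaffold,
    )
    achieved = EditSpec(
        kind="double_insertion",
        pair_insert=(insert, insert, GenomicInterval(ref.seq_id, nick_l, nick_r)),
    )
    return StrategyDesign(
        strategy="BiPE3",
        left_guide=left,
        right_guide=right,
        achieved_edit=achieved,
        ref=ref,
        warnings=notes,
    )
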