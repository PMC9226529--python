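import pytest

import bipekit as bk
from bipekit.guide_design import (
    NickType,
    SPCAS9_SCAFFOLD,
    _nearest,
)
from bipekit.refio import GenomicInterval, ReferenceSeq, revcomp
from conftest import LOXP, ECORV


def _site(nick: int, strand: str, seq_id: str = "r") -> bk.SpacerSite:
    """Fabricate a geometry-consistent SpacerSite for classification tests."""
    if strand == "+":
        iv = GenomicInterval(seq_id, nick - 17, nick + 3, "+")
    else:
        iv = GenomicInterval(seq_id, nick - 3, nick + 17, "-")
    return bk.SpacerSite("A" * 20, strand, "AGG", iv, nick)


class TestFindSpacers:
    def test_no_pam_no_sites(self):
        assert bk.find_spacers(ReferenceSeq("r", "A" * 30)) == []

    def test_plus_site_geometry(self):
        ref = ReferenceSeq("r", "A" * 21 + "AGG" + "A" * 6)
        sites = bk.find_spacers(ref)
        assert len(sites) == 1
        (s,) = sites
        assert s.strand == "+"
        assert s.protospacer == ref.sequence[1:21]
        assert s.pam == "AGG"
        assert (s.proto_interval.start, s.proto_interval.end) == (1, 21)
        assert s.nick_pos == 18

    def test_minus_site_geometry(self):
        ref = ReferenceSeq("r", "CCT" + "A" * 22)
        sites = bk.find_spacers(ref)
        assert len(sites) == 1
        (s,) = sites
        assert s.strand == "-"
        assert s.nick_pos == 6
        assert s.pam == "AGG"  # bottom-strand PAM opposite CCT
        assert s.protospacer == revcomp(ref.sequence[3:23])

    def test_short_region_returns_empty(self):
        ref = ReferenceSeq("r", "CCTGGAGGAGGACC" + "A" * 30)
        assert bk.find_spacers(ref, GenomicInterval("r", 0, 10)) == []

    def test_sorted_by_nick_pos(self, ref400):
        sites = bk.find_spacers(ref400)
        nicks = [s.nick_pos for s in sites]
        assert nicks == sorted(nicks)
        assert any(s.nick_pos == 100 and s.strand == "+" for s in sites)
        assert any(s.nick_pos == 254 and s.strand == "-" for s in sites)


class TestClassifyNick:
    DELETION = GenomicInterval("r", 100, 754)

    @pytest.mark.parametrize(
        "pos,ha,expected",
        [
            (400, 30, NickType.TYPE_I),
            (760, 30, NickType.TYPE_II),
            (1500, 30, NickType.TYPE_III),
            (100, 30, NickType.OUT_OF_RANGE),
            (50, 30, NickType.OUT_OF_RANGE),
            (101, 30, NickType.TYPE_I),
            (754, 30, NickType.TYPE_I),
            (755, 30, NickType.TYPE_II),
            (784, 30, NickType.TYPE_II),  # closed upper bound at end + ha_len
            (785, 30, NickType.TYPE_III),
        ],
    )
    def test_examples_and_boundaries(self, pos, ha, expected):
        assert bk.classify_nick(pos, self.DELETION, ha) is expected

    def test_partition_sweep(self):
        for ha in (8, 30, 50):
            for pos in range(0, 1200):
                labels = [
                    bk.classify_nick(pos, self.DELETION, ha) is t for t in NickType
                ]
                assert sum(labels) == 1

    def test_mirrored_rule_matches_reflected_coordinates(self):
        total = 1200
        mirrored = GenomicInterval("r", total - 754, total - 100)
        for pos in range(0, total):
            assert bk.classify_nick(
                pos, self.DELETION, 30, pegrna_strand="+"
            ) is bk.classify_nick(total - pos, mirrored, 30, pegrna_strand="-")

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            bk.classify_nick(400, self.DELETION, 0)
        with pytest.raises(ValueError):
            bk.classify_nick(400, GenomicInterval("r", 100, 100), 30)


class TestRankNickCandidates:
    DELETION = GenomicInterval("r", 100, 754)

    def test_type_order(self):
        cands = [_site(400, "-"), _site(760, "-"), _site(1500, "-")]
        ranked = bk.rank_nick_candidates(cands, self.DELETION, 30)
        assert [bk.classify_nick(s, self.DELETION, 30) for s in ranked] == [
            NickType.TYPE_II,
            NickType.TYPE_III,
            NickType.TYPE_I,
        ]

    def test_distance_tiebreak_within_class(self):
        near, far = _site(759, "-"), _site(784, "-")
        ranked = bk.rank_nick_candidates([far, near], self.DELETION, 30)
        assert ranked[0] is near

    def test_all_type_i_warns_and_orders_by_distance(self):
        cands = [_site(200, "-"), _site(700, "-")]
        with pytest.warns(UserWarning, match="no Type II"):
            ranked = bk.rank_nick_candidates(cands, self.DELETION, 30)
        assert [s.nick_pos for s in ranked] == [700, 200]

    def test_empty_candidates_rejected(self):
        with pytest.raises(ValueError):
            bk.rank_nick_candidates([], self.DELETION, 30)


class TestBuildPegrna:
    def test_plus_site_pbs_and_concatenation(self):
        # + site nicking at 20: protospacer [3, 23), PAM at [23, 26)
        seq = "TTT" + "ACGTACGTACGTAC" + "ACG" + "TACA" + "GG" + "TTTT"
        ref = ReferenceSeq("r", seq)
        site = next(
            s for s in bk.find_spacers(ref) if s.strand == "+" and s.nick_pos == 20
        )
        assert ref.sequence[17:20] == "ACG"
        with pytest.warns(UserWarning, match="empty 3' flap"):
            peg = bk.build_pegrna(site, "", ha_len=0, pbs_len=3, ref=ref)
        assert peg.pbs == "CGT"
        assert peg.rt_template == ""
        assert peg.full_sequence == site.protospacer + SPCAS9_SCAFFOLD + "CGT"

    def test_minus_site_pbs_is_top_strand_right_of_nick(self, ref400):
        site = next(
            s for s in bk.find_spacers(ref400)
            if s.strand == "-" and s.nick_pos == 254
        )
        peg = bk.build_pegrna(site, "TTAA", ha_len=5, pbs_len=6, ref=ref400)
        assert peg.pbs == ref400.sequence[254:260]
        assert peg.flap == "TTAA" + revcomp(ref400.sequence[249:254])
        assert peg.rt_template == revcomp(peg.flap)

    def test_pbs_or_ha_off_reference_rejected_with_extension(self, ref400):
        site = next(s for s in bk.find_spacers(ref400) if s.strand == "+")
        with pytest.raises(ValueError, match="extend by"):
            bk.build_pegrna(site, "", ha_len=0, pbs_len=site.nick_pos + 5, ref=ref400)
        with pytest.raises(ValueError, match="extend by"):
            bk.build_pegrna(site, "", ha_len=999, pbs_len=3, ref=ref400)


class TestDesignBipe:
    def _edit(self, ref, kind="replacement", ins="GAATTC"):
        return bk.EditSpec(
            kind=kind,
            deletion=GenomicInterval(ref.seq_id, 100, 254),
            insertion=ins if kind == "replacement" else "",
        )

    def test_bipe2_replacement_flaps_are_mutual_revcomp(self, ref400):
        d = bk.design_bipe(ref400, self._edit(ref400), "BiPE2", snap_window=0)
        left, right = d.left_guide, d.right_guide
        assert left.flap == "GAATTC"
        assert right.flap == revcomp(left.flap)

    def test_bipe3_flaps_extend_bipe2_flaps_by_ha(self, ref400):
        edit = self._edit(ref400)
        d2 = bk.design_bipe(ref400, edit, "BiPE2", snap_window=0)
        d3 = bk.design_bipe(ref400, edit, "BiPE3", ha_len=9, snap_window=0)
        seq = ref400.sequence
        assert d3.left_guide.flap == d2.left_guide.flap + seq[254 : 254 + 9]
        assert d3.right_guide.flap == d2.right_guide.flap + revcomp(seq[91:100])

    def test_bipe3_deletion_flaps_on_toy(self, ref400):
        d = bk.design_bipe(
            ref400, self._edit(ref400, "deletion", ""), "BiPE3",
            ha_len=5, snap_window=0,
        )
        seq = ref400.sequence
        assert d.left_guide.flap == seq[254:259]
        assert d.right_guide.flap == revcomp(seq[95:100])
        assert d.achieved_edit.deletion.start == 100
        assert d.achieved_edit.deletion.end == 254

    def test_snap_window_zero_without_exact_nick_rejected(self, ref400):
        edit = bk.EditSpec(
            kind="deletion", deletion=GenomicInterval(ref400.seq_id, 103, 254)
        )
        with pytest.raises(ValueError, match="nearest available nicks"):
            bk.design_bipe(ref400, edit, "BiPE3", snap_window=0)

    def test_snapping_is_recorded(self, ref400):
        edit = bk.EditSpec(
            kind="deletion", deletion=GenomicInterval(ref400.seq_id, 103, 254)
        )
        d = bk.design_bipe(ref400, edit, "BiPE3", snap_window=5)
        # snaps to the nearest available nick, not the requested coordinate
        assert d.achieved_edit.deletion.start == d.nick_left != 103
        assert abs(d.nick_left - 103) <= 5
        assert any("snapped" in w for w in d.warnings)

    def test_conversion_flaps_encode_all_targets(self):
        ref = bk.make_reference(300, seed=5, pam_anchors=((120, "+"), (160, "-")))
        seq = ref.sequence
        conv = tuple(
            (pos, seq[pos], "A" if seq[pos] != "A" else "C")
            for pos in (125, 140, 155)
        )
        edit = bk.EditSpec(kind="conversions", conversions=conv)
        d = bk.design_bipe(ref, edit, "BiPE3", ha_len=10, snap_window=10)
        edited = list(seq)
        for pos, _, alt in conv:
            edited[pos] = alt
        edited = "".join(edited)
        nick_l, nick_r = d.nick_left, d.nick_right
        assert d.left_guide.flap == edited[nick_l:156] + seq[156:166]
        assert d.right_guide.flap == revcomp(edited[125:nick_r]) + revcomp(
            seq[115:125]
        )

    def test_conversion_ref_base_mismatch_rejected(self, ref400):
        seq = ref400.sequence
        wrong = "A" if seq[120] != "A" else "C"
        other = "G" if wrong != "G" else "T"
        edit = bk.EditSpec(kind="conversions", conversions=((120, wrong, other),))
        with pytest.raises(ValueError, match="does not match reference"):
            bk.design_bipe(ref400, edit, "BiPE3")


def _mirror_edit(edit: bk.EditSpec, length: int, seq_id: str) -> bk.EditSpec:
    s, e = edit.deletion.start, edit.deletion.end
    return bk.EditSpec(
        kind=edit.kind,
        deletion=GenomicInterval(seq_id, length - e, length - s),
        insertion=revcomp(edit.insertion) if edit.insertion else "",
    )


class TestStrandMirrorSymmetry:
    @pytest.mark.parametrize("seed", range(5))
    def test_bipe_design_mirrors(self, seed):
        length = 500
        ref = bk.make_reference(
            length, seed=seed, pam_anchors=((150, "+"), (330, "-"))
        )
        mref = ReferenceSeq(ref.seq_id, revcomp(ref.sequence))
        edit = bk.EditSpec(
            kind="replacement",
            deletion=GenomicInterval(ref.seq_id, 150, 330),
            insertion="GAATTCAA",
        )
        d = bk.design_bipe(ref, edit, "BiPE3", ha_len=8, snap_window=0)
        md = bk.design_bipe(
            mref, _mirror_edit(edit, length, ref.seq_id), "BiPE3",
            ha_len=8, snap_window=0,
        )
        # mirrored left guide is the original right guide (and vice versa)
        for mine, theirs in (
            (md.left_guide, d.right_guide),
            (md.right_guide, d.left_guide),
        ):
            assert mine.site.protospacer == theirs.site.protospacer
            assert mine.pbs == theirs.pbs
            assert mine.rt_template == theirs.rt_template
        assert md.nick_left == length - d.nick_right
        assert md.nick_right == length - d.nick_left

    def test_rpe3_is_mirror_of_lpe3(self):
        length = 500
        ref = bk.make_reference(
            length, seed=3, pam_anchors=((150, "+"), (330, "-"), (350, "+"))
        )
        mref = ReferenceSeq(ref.seq_id, revcomp(ref.sequence))
        edit = bk.EditSpec(
            kind="deletion", deletion=GenomicInterval(ref.seq_id, 150, 330)
        )
        left = bk.design_pe3(ref, edit, "L", ha_len=8, snap_window=0)
        right = bk.design_pe3(
            mref, _mirror_edit(edit, length, ref.seq_id), "R",
            ha_len=8, snap_window=0,
        )
        assert isinstance(right.right_guide, bk.PegRNA)
        assert right.right_guide.pbs == left.left_guide.pbs
        assert right.right_guide.rt_template == left.left_guide.rt_template
        assert (
            right.left_guide.protospacer == left.right_guide.protospacer
        )  # nick sgRNAs swap sides


class TestDesignPe3:
    def test_lpe3_pegrna_on_plus_and_type_ii_nick_first(self):
        # plant a Type II bottom-strand nick (window (254, 279] for ha 25)
        ref = bk.make_reference(
            500, seed=9,
            pam_anchors=((100, "+"), (260, "-"), (200, "-"), (380, "-")),
        )
        edit = bk.EditSpec(
            kind="deletion", deletion=GenomicInterval(ref.seq_id, 100, 254)
        )
        d = bk.design_pe3(ref, edit, "L", ha_len=25, snap_window=0)
        assert d.strategy == "L-PE3"
        assert isinstance(d.left_guide, bk.PegRNA)
        assert not isinstance(d.right_guide, bk.PegRNA)
        assert d.left_guide.site.strand == "+"
        assert (
            bk.classify_nick(d.right_guide, d.achieved_edit.deletion, 25)
            is NickType.TYPE_II
        )

    def test_pe3_carries_exactly_one_pegrna(self, ref400):
        edit = bk.EditSpec(
            kind="deletion", deletion=GenomicInterval(ref400.seq_id, 100, 254)
        )
        for side in ("L", "R"):
            d = bk.design_pe3(ref400, edit, side, ha_len=12, snap_window=0)
            assert len(d.pegrnas) == 1

    def test_lpe3_conversions_flap_is_edits_plus_ha(self):
        ref = bk.make_reference(300, seed=5, pam_anchors=((120, "+"), (160, "-")))
        seq = ref.sequence
        conv = ((130, seq[130], "A" if seq[130] != "A" else "C"),)
        edit = bk.EditSpec(kind="conversions", conversions=conv)
        d = bk.design_pe3(ref, edit, "L", ha_len=10, snap_window=15)
        edited = seq[:130] + conv[0][2] + seq[131:]
        nick = d.left_guide.site.nick_pos
        assert d.left_guide.flap == edited[nick:131] + seq[131:141]


class TestDoubleInsertion:
    def _spec(self, ref, start=150, end=240, left=LOXP, right=LOXP):
        return bk.EditSpec(
            kind="double_insertion",
            pair_insert=(left, right, GenomicInterval(ref.seq_id, start, end)),
        )

    def test_tagged_flaps_and_inner_segment(self):
        ref = bk.make_reference(500, seed=2, pam_anchors=((150, "+"), (240, "-")))
        d = bk.design_double_insertion(
            ref, self._spec(ref), ha_len=20, snap_window=0, tag=ECORV
        )
        tagged = LOXP + ECORV
        assert d.left_guide.flap.startswith(tagged)
        assert d.right_guide.flap.startswith(revcomp(tagged))
        assert d.left_guide.flap == tagged + ref.sequence[150:170]
        assert d.right_guide.flap == revcomp(tagged) + revcomp(
            ref.sequence[220:240]
        )
        assert any("inner segment length: 90" in w for w in d.warnings)

    def test_long_inner_segment_warns_about_attenuation(self):
        ref = bk.make_reference(600, seed=2, pam_anchors=((150, "+"), (348, "-")))
        d = bk.design_double_insertion(
            ref, self._spec(ref, 150, 348), ha_len=20, snap_window=0
        )
        assert any("attenuates" in w for w in d.warnings)

    def test_opposite_orientation_rejected(self, ref400):
        spec = self._spec(ref400, 100, 254, left=LOXP, right=revcomp(LOXP))
        with pytest.raises(ValueError, match="same orientation"):
            bk.design_double_insertion(ref400, spec, snap_window=0)

    def test_inner_segment_shorter_than_has_rejected(self):
        ref = bk.make_reference(500, seed=2, pam_anchors=((150, "+"), (240, "-")))
        with pytest.raises(ValueError, match="shorter than the combined"):
            bk.design_double_insertion(
                ref, self._spec(ref), ha_len=50, snap_window=0
            )


class TestPegRNAInvariants:
    """Independent string reconstruction of every pegRNA invariant."""

    @pytest.mark.parametrize("seed", range(8))
    @pytest.mark.parametrize("mode", ["BiPE2", "BiPE3"])
    def test_reconstruction_on_seeded_designs(self, seed, mode):
        ref = bk.make_reference(
            420, seed=seed, pam_anchors=((120, "+"), (290, "-"))
        )
        edit = bk.EditSpec(
            kind="replacement",
            deletion=GenomicInterval(ref.seq_id, 120, 290),
            insertion="TTGACGTCAA",
        )
        d = bk.design_bipe(ref, edit, mode, ha_len=11, pbs_len=9, snap_window=0)
        seq = ref.sequence
        for guide in d.pegrnas:
            nick = guide.site.nick_pos
            if guide.site.strand == "+":
                assert guide.pbs == revcomp(seq[nick - 9 : nick])
            else:
                assert guide.pbs == seq[nick : nick + 9]
            assert guide.flap == revcomp(guide.rt_template)
            assert (
                guide.full_sequence
                == guide.site.protospacer
                + guide.scaffold
                + guide.rt_template
                + guide.pbs
            )
        ha = 11 if mode == "BiPE3" else 0
        assert d.left_guide.flap == "TTGACGTCAA" + seq[290 : 290 + ha]
        assert d.right_guide.flap == revcomp("TTGACGTCAA") + (
            revcomp(seq[120 - ha : 120]) if ha else ""
        )


def test_nearest_reports_nearest_nicks_on_failure(ref400):
    sites = [s for s in bk.find_spacers(ref400) if s.strand == "+"]
    with pytest.raises(ValueError, match="nearest available"):
        _nearest(sites, 0, 0, "+ strand")
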