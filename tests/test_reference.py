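"""Guide placement, cut geometry, overhang prediction, junction assembly."""

import numpy as np
import pytest

from dualcut import (
    GuideSite,
    blunt_cut_position,
    build_junction_reference,
    predicted_overhang,
    revcomp,
)

from conftest import random_dna

# protospacer printed for the first MeCP2 cut site (sense oligo, ACCG scaffold
# overhang removed)
MECP2_1 = "CATACATGGGTCCCCGGTCA"


def _segment_with_guide(seed=1, offset=25, strand="+", length=60):
    rng = np.random.default_rng(seed)
    seg = list(random_dna(rng, length))
    if strand == "+":
        seg[offset + 21 : offset + 23] = ["G", "G"]
        seg = "".join(seg)
        return seg, seg[offset : offset + 20], seg[offset + 20 : offset + 23]
    seg[offset : offset + 2] = ["C", "C"]
    seg = "".join(seg)
    return seg, revcomp(seg[offset + 3 : offset + 23]), revcomp(seg[offset : offset + 3])


class TestBluntCut:
    def test_plus_strand_cut_three_left_of_pam(self):
        seg, proto, pam = _segment_with_guide(seed=1, offset=25, strand="+")
        assert blunt_cut_position(seg, proto, pam, "+") == 25 + 17

    def test_minus_strand_mirrors_forward_coordinates(self):
        seg, proto, pam = _segment_with_guide(seed=2, offset=25, strand="-")
        cut = blunt_cut_position(seg, proto, pam, "-")
        # string-search oracle: revcomp site starts at 25; -3/-4 boundary is +6
        assert seg.find(revcomp(proto + pam)) == 25
        assert cut == 25 + 6
        # strand symmetry: the same guide on the revcomp segment cuts at the
        # mirrored coordinate
        assert blunt_cut_position(revcomp(seg), proto, pam, "+") == len(seg) - cut

    def test_guide_not_found(self):
        with pytest.raises(ValueError, match="guide not found"):
            blunt_cut_position("A" * 50, MECP2_1, "AGG", "+")

    def test_ambiguous_placement(self):
        site = MECP2_1 + "AGG"
        with pytest.raises(ValueError, match="ambiguous"):
            blunt_cut_position(site + "TTTT" + site, MECP2_1, "AGG", "+")

    def test_non_ngg_pam_rejected(self):
        with pytest.raises(ValueError, match="PAM"):
            blunt_cut_position("ACGT" * 20, MECP2_1, "ATA", "+")


class TestPredictedOverhang:
    @pytest.fixture()
    def guide(self):
        return GuideSite("MeCP2-1", MECP2_1, "AGG", "+", cut_blunt=17)

    def test_single_base_is_minus4(self, guide):
        assert predicted_overhang(guide, 1) == MECP2_1[-4]

    def test_three_bases_pam_proximal_first(self, guide):
        # manual extraction: positions -4, -5, -6 of CATACATGGGTCCCCGGTCA
        assert predicted_overhang(guide, 3) == "GGC"
        assert predicted_overhang(guide, 3) == MECP2_1[-6:-3][::-1]

    @pytest.mark.parametrize("k", [0, 4])
    def test_out_of_range_k(self, guide, k):
        with pytest.raises(ValueError, match="overhang length unsupported"):
            predicted_overhang(guide, k)

    def test_overhang_is_fixed_offset_substring(self, guide):
        for k in (1, 2, 3):
            assert predicted_overhang(guide, k)[::-1] == MECP2_1[-3 - k : -3]


def _two_guided_segments(seed=3, length=300, offset=None):
    offset = offset if offset is not None else length // 2 - 17
    up_seg, up_proto, up_pam = _segment_with_guide(seed, offset, "+", length)
    down_seg, down_proto, down_pam = _segment_with_guide(seed + 100, offset, "+", length)
    g_up = GuideSite.place("up", up_seg, up_proto, up_pam, "+")
    g_down = GuideSite.place("down", down_seg, down_proto, down_pam, "+")
    return up_seg, down_seg, g_up, g_down


class TestBuildJunctionReference:
    def test_deletion_junction_construction(self):
        up_seg, down_seg, g_up, g_down = _two_guided_segments()
        ref = build_junction_reference(up_seg, down_seg, g_up, g_down, "deletion")
        cu, cd = g_up.cut_blunt, g_down.cut_blunt
        assert ref.upstream_arm == up_seg[:cu][-150:]
        assert ref.downstream_arm == down_seg[cd:][:150]
        assert ref.junction == len(ref.upstream_arm)

    def test_arm_window_bounds_junction_coordinate(self):
        up_seg, down_seg, g_up, g_down = _two_guided_segments(seed=5, length=400)
        ref = build_junction_reference(up_seg, down_seg, g_up, g_down, "deletion")
        assert len(ref.upstream_arm) == len(ref.downstream_arm) == 150
        assert ref.junction == 150

    def test_inversion_up_is_revcomp_of_left_cut_flank(self):
        up_seg, down_seg, g_up, g_down = _two_guided_segments()
        ref = build_junction_reference(up_seg, down_seg, g_up, g_down, "inversion_up")
        cd = g_down.cut_blunt
        assert ref.downstream_arm == revcomp(down_seg[:cd])[:150]

    def test_single_cut_concatenation_is_identity(self):
        up_seg, _, g_up, _ = _two_guided_segments()
        ref = build_junction_reference(up_seg, None, g_up, None, "single_cut",
                                       arm_window=0)
        assert ref.sequence == up_seg

    def test_deletion_at_same_cut_reduces_to_single_cut(self):
        up_seg, _, g_up, _ = _two_guided_segments()
        dele = build_junction_reference(up_seg, up_seg, g_up, g_up, "deletion")
        single = build_junction_reference(up_seg, None, g_up, None, "single_cut")
        assert dele.upstream_arm == single.upstream_arm
        assert dele.downstream_arm == single.downstream_arm

    def test_rebuild_is_idempotent(self):
        up_seg, down_seg, g_up, g_down = _two_guided_segments()
        a = build_junction_reference(up_seg, down_seg, g_up, g_down, "deletion")
        b = build_junction_reference(up_seg, down_seg, g_up, g_down, "deletion")
        assert a == b

    def test_short_arm_rejected(self):
        up_seg, down_seg, g_up, g_down = _two_guided_segments()
        with pytest.raises(ValueError, match="arm too short"):
            build_junction_reference(
                up_seg, down_seg[: g_down.cut_blunt + 5], g_up, g_down, "deletion"
            )

    def test_pam_frames_pam_out_configuration(self, ref0):
        # '+' upstream and '-' downstream guides put -4/-5/-6 on both flanks
        assert ref0.pam_frames == {"up": (-4, -1), "down": (-4, -1)}
        assert ref0.pam_positions("up", 3) == [-4, -5, -6]

    def test_pam_positions_skip_zero_on_pam_side(self):
        up_seg, _, g_up, _ = _two_guided_segments()
        ref = build_junction_reference(up_seg, None, g_up, None, "single_cut")
        # downstream of a '+' cut: -3, -2, -1 then straight into the PAM (+1)
        assert ref.pam_positions("down", 5) == [-3, -2, -1, 1, 2]
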