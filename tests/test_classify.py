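"""Outcome categories, size bins, templated-insertion calls, tallies."""

import pytest

from dualcut import (
    align_junction,
    classify,
    deletion_position_profile,
    is_templated_insertion,
    predicted_overhang,
    tally,
)
from dualcut.classify import JunctionOutcome, del_bin


class TestDelBins:
    @pytest.mark.parametrize(
        "total,expected",
        [(1, "1"), (2, "2-20"), (20, "2-20"), (21, "21-100"), (100, "21-100"),
         (101, ">100")],
    )
    def test_exact_boundaries(self, total, expected):
        assert del_bin(total) == expected

    def test_no_bin_for_zero(self):
        assert del_bin(0) is None


class TestClassify:
    def _outcome(self, ref0, scheme, read):
        return classify(align_junction(read, ref0, scheme), ref0)

    def test_precise(self, ref0, scheme):
        o = self._outcome(ref0, scheme, ref0.upstream_arm[-40:] + ref0.downstream_arm[:40])
        assert o.category == "precise"
        assert o.del_total == 0 and o.ins_len == 0

    def test_one_base_deletion_at_minus4(self, ref0, scheme):
        read = ref0.upstream_arm[:-1][-40:] + ref0.downstream_arm[:40]
        o = self._outcome(ref0, scheme, read)
        assert o.category == "deletion"
        assert o.bin == "1"
        assert o.del_positions == (-4,)

    def test_indel(self, ref0, scheme):
        # 3 nt deleted downstream plus an inserted dinucleotide
        ins = "AG"
        if is_templated_insertion(ins, ref0)[0]:
            ins = "TC"
        read = ref0.upstream_arm[-40:] + ins + ref0.downstream_arm[3:43]
        o = self._outcome(ref0, scheme, read)
        assert o.category == "indel"
        assert o.del_total == 3 and o.ins_len == 2

    def test_unmapped_category(self, ref0, scheme):
        o = self._outcome(ref0, scheme, "ACGT" * 20)
        assert o.category == "unmapped"

    def test_category_invariants_hold(self, ref0, scheme):
        reads = [
            ref0.upstream_arm[-40:] + ref0.downstream_arm[:40],
            ref0.upstream_arm[:-2][-40:] + ref0.downstream_arm[:40],
            ref0.upstream_arm[-40:] + "TTAA" + ref0.downstream_arm[:40],
        ]
        for read in reads:
            o = self._outcome(ref0, scheme, read)
            assert (o.category == "precise") == (o.del_total == 0 and o.ins_len == 0)
            assert (o.category == "indel") == (o.del_total > 0 and o.ins_len > 0)
            if o.templated:
                assert 1 <= o.ins_len <= 3


class TestTemplatedInsertion:
    def test_upstream_minus4_base_is_templated(self, ref0):
        ins = predicted_overhang(ref0.guides[0], 1)
        flag, k, source = is_templated_insertion(ins, ref0)
        assert (flag, k) == (True, 1)
        assert ref0.guides[0].label in source

    def test_both_orders_accepted(self, ref0):
        ov = predicted_overhang(ref0.guides[1], 3)
        assert is_templated_insertion(ov, ref0)[0]
        assert is_templated_insertion(ov[::-1], ref0)[0]

    def test_non_matching_base_not_templated(self, ref0):
        candidates = {predicted_overhang(g, 1) for g in ref0.guides}
        other = next(b for b in "ACGT" if b not in candidates)
        assert is_templated_insertion(other, ref0) == (False, 0, "")

    def test_four_base_insertion_never_templated(self, ref0):
        assert is_templated_insertion("ACGT", ref0)[0] is False


class TestDeletionPositionProfile:
    def test_precise_only_library_empty_profile(self, ref0):
        outs = [JunctionOutcome("r%d" % i, "precise") for i in range(5)]
        assert deletion_position_profile(outs) == {}

    def test_two_base_deletion_counts_both_positions(self, ref0):
        o = JunctionOutcome("r", "deletion", del_up=2, del_positions=(-4, -5))
        assert deletion_position_profile([o]) == {-4: 1, -5: 1}

    def test_large_deletions_excluded(self, ref0):
        o = JunctionOutcome("r", "deletion", del_up=10,
                            del_positions=tuple(range(-4, -14, -1)))
        assert deletion_position_profile([o]) == {}


class TestTally:
    def test_no_mapped_reads(self):
        t = tally([JunctionOutcome("r", "unmapped")] * 10, total_reads=100)
        assert t.repaired_fraction == 0.0

    def test_mixture_arithmetic(self):
        outs = (
            [JunctionOutcome("p%d" % i, "precise") for i in range(50)]
            + [JunctionOutcome("d%d" % i, "deletion", del_up=1) for i in range(25)]
            + [JunctionOutcome("i%d" % i, "insertion", ins_len=2, insertion="AT")
               for i in range(25)]
        )
        t = tally(outs, total_reads=100)
        assert t.repaired_fraction == 1.0
        assert t.category_frequencies["precise"] == 0.5
        assert t.bin_counts["1"] == 25

    def test_frequencies_form_distribution(self):
        outs = [
            JunctionOutcome("a", "precise"),
            JunctionOutcome("b", "deletion", del_up=3),
            JunctionOutcome("c", "insertion", ins_len=1, insertion="A"),
            JunctionOutcome("d", "indel", del_up=2, ins_len=1, insertion="C"),
            JunctionOutcome("e", "unmapped"),
        ]
        t = tally(outs, total_reads=10)
        assert sum(t.category_frequencies.values()) == pytest.approx(1.0)
        assert t.junction_reads == 4

    def test_large_resection_fraction(self):
        outs = [JunctionOutcome("r", "deletion", del_up=150)]
        t = tally(outs, total_reads=1000)
        assert t.large_resection_fraction == pytest.approx(0.001)

    def test_inconsistent_totals(self):
        with pytest.raises(ValueError, match="inconsistent totals"):
            tally([JunctionOutcome("a", "precise")] * 5, total_reads=3)
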