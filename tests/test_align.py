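"""Three-part junction alignment: construction cases, oracle agreement,
invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dualcut import (
    ScoringScheme,
    align_both_strands,
    align_junction,
    brute_force_align,
    predicted_overhang,
    revcomp,
)

from conftest import random_dna


class TestConstructedReads:
    def test_precise_ligation_scores_all_matches(self, ref0, scheme):
        read = ref0.upstream_arm[-40:] + ref0.downstream_arm[:40]
        aln = align_junction(read, ref0, scheme)
        assert aln.score == 80 * scheme.match
        assert (aln.del_up, aln.del_down, aln.overlap_len) == (0, 0, 0)
        assert aln.middle_insertion == ""
        assert aln.mapped

    def test_single_base_fill_in_insertion(self, ref0, scheme):
        ins = predicted_overhang(ref0.guides[0], 1)
        read = ref0.upstream_arm[-40:] + ins + ref0.downstream_arm[:40]
        aln = align_junction(read, ref0, scheme)
        assert aln.middle_insertion == ins
        assert (aln.del_up, aln.del_down) == (0, 0)

    def test_downstream_deletion(self, ref0, scheme):
        read = ref0.upstream_arm[-40:] + ref0.downstream_arm[5:45]
        aln = align_junction(read, ref0, scheme)
        assert (aln.del_up, aln.del_down) == (0, 5)
        assert aln.middle_insertion == ""

    def test_unrelated_read_unmapped(self, ref0, scheme):
        rng = np.random.default_rng(7)
        aln = align_junction(random_dna(rng, 80), ref0, scheme)
        assert not aln.mapped

    def test_read_too_short(self, ref0, scheme):
        with pytest.raises(ValueError, match="read too short"):
            align_junction("ACGT", ref0, scheme)

    def test_invalid_alphabet(self, ref0, scheme):
        with pytest.raises(ValueError, match="invalid alphabet"):
            align_junction("ACGTX" * 10, ref0, scheme)

    def test_score_recomputable_from_parts(self, ref0, scheme):
        read = ref0.upstream_arm[-40:] + "TTA" + ref0.downstream_arm[3:43]
        aln = align_junction(read, ref0, scheme)
        expected = (
            aln.left.score
            + aln.right.score
            + scheme.insertion_base_penalty * len(aln.middle_insertion)
        )
        assert aln.score == expected

    def test_split_indices_consistent(self, ref0, scheme):
        read = ref0.upstream_arm[-45:] + ref0.downstream_arm[:35]
        aln = align_junction(read, ref0, scheme)
        i, j = aln.split
        assert j <= i <= j + scheme.max_overlap or i <= j
        assert aln.overlap_len == max(0, i - j)
        if aln.overlap_len > 0:
            assert aln.middle_insertion == ""


class TestBothStrands:
    def test_revcomp_read_recovers_same_fields(self, ref0, scheme):
        read = ref0.upstream_arm[-40:] + "T" + ref0.downstream_arm[4:44]
        fwd = align_both_strands(read, ref0, scheme)
        rev = align_both_strands(revcomp(read), ref0, scheme)
        assert rev.strand == "-"
        assert fwd.strand == "+"
        assert (fwd.del_up, fwd.del_down) == (rev.del_up, rev.del_down)
        assert fwd.middle_insertion == rev.middle_insertion
        assert fwd.score == rev.score

    def test_forward_preferred_on_tie(self, ref0, scheme):
        read = ref0.upstream_arm[-40:] + ref0.downstream_arm[:40]
        assert align_both_strands(read, ref0, scheme).strand == "+"


class TestOracleEquivalence:
    """align_junction must match the exhaustive split-enumeration oracle."""

    def test_oracle_guard(self, ref0, scheme):
        with pytest.raises(ValueError, match="oracle size exceeded"):
            brute_force_align("A" * 80, ref0, scheme)

    def test_precise_read_agrees(self, ref0, scheme):
        read = ref0.upstream_arm[-15:] + ref0.downstream_arm[:15]
        assert (
            align_junction(read, ref0, scheme).score
            == brute_force_align(read, ref0, scheme).score
        )

    def test_deletion_grid_agrees(self, ref0, scheme):
        U, D = ref0.upstream_arm, ref0.downstream_arm
        for du in range(5):
            for dd in range(5):
                read = U[: len(U) - du][-20:] + D[dd:][:20]
                mine = align_junction(read, ref0, scheme)
                orc = brute_force_align(read, ref0, scheme)
                assert mine.score == orc.score, (du, dd)

    def test_mutated_reads_agree(self, ref0, scheme, rng):
        U, D = ref0.upstream_arm, ref0.downstream_arm
        for _ in range(40):
            base = U[-25:] + D[:25]
            read = "".join(
                random_dna(rng, 1) if rng.random() < 0.03 else c for c in base
            )
            assert (
                align_junction(read, ref0, scheme).score
                == brute_force_align(read, ref0, scheme).score
            )

    def test_insertion_reads_agree(self, ref0, scheme, rng):
        U, D = ref0.upstream_arm, ref0.downstream_arm
        for L in range(1, 8):
            read = U[-25:] + random_dna(rng, L) + D[:25]
            assert (
                align_junction(read, ref0, scheme).score
                == brute_force_align(read, ref0, scheme).score
            )

    def test_decomposition_fields_agree_on_clean_cases(self, ref0, scheme):
        U, D = ref0.upstream_arm, ref0.downstream_arm
        cases = [
            (U[-20:] + D[:20], 0, 0, ""),
            (U[-22:] + D[3:20], 0, 3, ""),
            (U[-20:] + "T" + D[:19], 0, 0, "T"),
        ]
        for read, du, dd, mid in cases:
            mine = align_junction(read, ref0, scheme)
            orc = brute_force_align(read, ref0, scheme)
            assert (mine.del_up, mine.del_down, mine.middle_insertion) == (du, dd, mid)
            assert (orc.del_up, orc.del_down, orc.middle_insertion) == (du, dd, mid)


class TestOracleProperty:
    @given(
        du=st.integers(0, 4),
        dd=st.integers(0, 4),
        ins=st.text(alphabet="ACGT", max_size=4),
    )
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_constructed_events_agree_with_oracle(self, ref0, scheme, du, dd, ins):
        U, D = ref0.upstream_arm, ref0.downstream_arm
        read = U[: len(U) - du][-20:] + ins + D[dd:][:20]
        mine = align_junction(read, ref0, scheme)
        oracle = brute_force_align(read, ref0, scheme)
        assert mine.score == oracle.score


class TestScoreMonotonicity:
    def test_appending_matched_bases_never_decreases_score(self, ref0, scheme):
        U, D = ref0.upstream_arm, ref0.downstream_arm
        prev = None
        for extra in range(0, 30, 5):
            read = U[-40:] + D[: 40 + extra]
            score = align_junction(read, ref0, scheme).score
            if prev is not None:
                assert score >= prev
            prev = score
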