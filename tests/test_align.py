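import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import brute_global_score, gotoh_scores
from tirscout.align import (
    PairwiseAlignment,
    ScoringScheme,
    align_global,
    align_local,
    identity_profile,
)
from tirscout.seq_model import revcomp

from conftest import random_dna


class TestScoringScheme:
    def test_validation(self):
        with pytest.raises(ValueError):
            ScoringScheme(match=-1)
        with pytest.raises(ValueError):
            ScoringScheme(gap_open=-1)


class TestGlobal:
    def test_identical_sequences(self):
        pa = align_global("ACGTACGT", "ACGTACGT", ScoringScheme())
        assert pa.score == 16 and "-" not in pa.aligned_a

    def test_small_gap_case(self):
        pa = align_global("ACGT", "AGT", ScoringScheme(1, -1, 2, 1))
        oracle = brute_global_score("ACGT", "AGT", 1, -1, 2, 1)
        assert pa.score == oracle == 0

    def test_all_mismatch_beats_all_gap(self):
        # linear gap cost 1 per residue (open 0, extend 1)
        pa = align_global("AAAA", "TTTT", ScoringScheme(1, -1, 0, 1))
        assert pa.score == -4

    def test_n_never_matches(self):
        pa = align_global("NNNN", "NNNN", ScoringScheme(1, -1, 2, 1))
        assert pa.score == -4

    @given(
        st.text(alphabet="AC", min_size=1, max_size=6),
        st.text(alphabet="AC", min_size=1, max_size=6),
    )
    @settings(max_examples=60)
    def test_matches_exhaustive_enumeration(self, a, b):
        scheme = ScoringScheme(2, -3, 5, 2)
        assert align_global(a, b, scheme).score == brute_global_score(
            a, b, 2, -3, 5, 2
        )

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            align_global("", "ACGT", ScoringScheme())


class TestLocal:
    def test_exact_substring(self, rng, dna_scheme):
        b = random_dna(rng, 1000)
        a = b[300:400]
        (hit,) = align_local(a, b, dna_scheme, max_reports=1)
        assert (hit.b_start, hit.b_end) == (300, 400)
        assert hit.identity() == 1.0

    def test_two_disjoint_blocks(self, rng, dna_scheme):
        blk1, blk2 = random_dna(rng, 50), random_dna(rng, 50)
        a = blk1 + random_dna(rng, 40) + blk2
        b = blk2 + random_dna(rng, 60) + blk1
        hits = align_local(a, b, dna_scheme, max_reports=2)
        spans_a = sorted((h.a_start, h.a_end) for h in hits)
        assert spans_a == [(0, 50), (90, 140)]
        # non-overlapping in both sequences
        (s1, e1), (s2, e2) = sorted((h.b_start, h.b_end) for h in hits)
        assert e1 <= s2

    def test_scores_match_dp_oracle_on_random_pairs(self, rng, dna_scheme):
        for n in (50, 120, 200, 300):
            a = random_dna(rng, n, "ACGTN")
            b = random_dna(rng, n)
            hits = align_local(a, b, dna_scheme, max_reports=1)
            _, expected = gotoh_scores(a, b, 2, -3, 5, 2, local=True)
            got = hits[0].score if hits else 0
            assert got == expected

    def test_global_scores_match_dp_oracle_up_to_300(self, rng, dna_scheme):
        for n in (30, 150, 300):
            a, b = random_dna(rng, n), random_dna(rng, n - 7)
            expected, _ = gotoh_scores(a, b, 2, -3, 5, 2, local=False)
            assert align_global(a, b, dna_scheme).score == expected

    def test_alignment_consistency(self, rng, dna_scheme):
        a, b = random_dna(rng, 150), random_dna(rng, 150)
        for hit in align_local(a, b, dna_scheme, max_reports=3):
            assert hit.aligned_a.replace("-", "") == a[hit.a_start : hit.a_end]
            assert hit.aligned_b.replace("-", "") == b[hit.b_start : hit.b_end]
            assert hit.score > 0


class TestIdentityProfile:
    def _aln(self, a, b):
        return PairwiseAlignment(a, b, 0, 0, len(a), 0, len(b), "global")

    def test_identical_gives_ones(self):
        prof = identity_profile(self._aln("ACGTACGTA", "ACGTACGTA"), 3)
        assert np.allclose(prof, 1.0)

    def test_all_mismatch_gives_zeros(self):
        prof = identity_profile(self._aln("AAAA", "TTTT"), 3)
        assert np.allclose(prof, 0.0)

    def test_alternating_interior_values(self):
        a = "A" * 40
        b = "".join("A" if i % 2 == 0 else "T" for i in range(40))
        prof = identity_profile(self._aln(a, b), 9)
        interior = prof[4:-4]
        assert set(np.round(interior * 9).astype(int)) == {4, 5}

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            identity_profile(self._aln("ACGT", "ACGT"), 2)

    def test_revcomp_invariance(self, rng, dna_scheme):
        # use a substitution-only pair so the optimal alignment is gapless
        # and unique; co-optimal gap placements would otherwise differ
        a = random_dna(rng, 120)
        b = list(a)
        for pos in rng.choice(120, size=12, replace=False):
            b[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[b[pos]]
        b = "".join(b)
        fwd = align_global(a, b, dna_scheme)
        rev = align_global(revcomp(a), revcomp(b), dna_scheme)
        p1 = identity_profile(fwd, 9)
        p2 = identity_profile(rev, 9)
        # reverse-complementing both sequences mirrors the profile
        assert np.allclose(p2, p1[::-1])
        assert fwd.score == rev.score
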