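import math

import numpy as np
import pytest

from oracles import jsd_direct
from tirscout.conservation import (
    BLOSUM62_BACKGROUND,
    ProteinMSA,
    identity_matrix,
    jsd_conservation,
    matrix_report,
    relative_entropy_logo,
    select_nonredundant,
    similarity_matrix,
)
from tirscout.synthetic_data import simulate_msa

AA = "ACDEFGHIKLMNPQRSTVWY"


def _random_msa(rng, n=5, length=30, gap_rate=0.1):
    rows = []
    for _ in range(n):
        row = "".join(
            "-" if rng.random() < gap_rate else AA[rng.integers(0, 20)]
            for _ in range(length)
        )
        rows.append(row if row.strip("-") else "A" * length)
    return ProteinMSA(ids=[f"s{i}" for i in range(n)], rows=rows)


class TestPairwiseMatrices:
    def test_identical_sequences_100(self):
        msa = ProteinMSA(ids=["a", "b"], rows=["ACDEF", "ACDEF"])
        assert identity_matrix(msa).values[0, 1] == 100
        assert similarity_matrix(msa).values[0, 1] == 100

    def test_gap_excluded_min_length_denominator(self):
        # identical pairs 4, min ungapped length 4 -> 100
        msa = ProteinMSA(ids=["a", "b"], rows=["AC-DE", "ACFDE"])
        assert identity_matrix(msa).values[0, 1] == 100

    def test_conservative_substitution_counts_only_as_similar(self):
        msa = ProteinMSA(ids=["a", "b"], rows=["I", "V"])  # BLOSUM62 I/V = +3
        assert identity_matrix(msa).values[0, 1] == 0
        assert similarity_matrix(msa).values[0, 1] == 100

    def test_symmetry_diagonal_and_ordering(self, rng):
        msa = _random_msa(rng, n=6, length=40)
        ident = identity_matrix(msa).values
        simil = similarity_matrix(msa).values
        for m in (ident, simil):
            assert np.allclose(m, m.T, equal_nan=True)
            assert np.allclose(np.diag(m), 100)
        mask = ~np.isnan(ident)
        assert (ident[mask] <= simil[mask] + 1e-9).all()
        assert (ident[mask] >= 0).all() and (simil[mask] <= 100).all()

    def test_core_window_restriction(self):
        msa = ProteinMSA(
            ids=["a", "b"], rows=["AAAACDEF", "CCCACDEF"], core_window=(3, 8)
        )
        assert identity_matrix(msa).values[0, 1] == 100

    def test_matrix_report_layout(self, rng):
        msa = _random_msa(rng, n=4)
        rep = matrix_report(identity_matrix(msa), similarity_matrix(msa))
        ident = identity_matrix(msa).values
        simil = similarity_matrix(msa).values
        assert rep.iloc[0, 2] == ident[0, 2]
        assert rep.iloc[2, 0] == simil[2, 0]


class TestJSD:
    def test_uniform_column_vs_uniform_background_is_zero(self):
        # pseudocount preserves uniformity, so p == q exactly
        msa = ProteinMSA(ids=[f"s{i}" for i in range(20)], rows=list(AA))
        track = jsd_conservation(msa, background="uniform", gap_penalty=0)
        assert track.scores[0] == pytest.approx(0.0, abs=1e-12)

    def test_all_gap_column_scores_zero_under_gap_penalty(self):
        msa = ProteinMSA(ids=["a", "b"], rows=["-A", "-A"])
        track = jsd_conservation(msa, gap_penalty=1)
        assert track.scores[0] == 0.0

    def test_matches_direct_summation_oracle(self, rng):
        for _ in range(5):
            msa = _random_msa(rng, n=5, length=30)
            track = jsd_conservation(msa, gap_penalty=1)
            for c in range(msa.n_columns):
                column = [r[c] for r in msa.rows]
                counts = {}
                for res in column:
                    if res != "-":
                        counts[res] = counts.get(res, 0) + 1
                gap_fraction = column.count("-") / len(column)
                expected = jsd_direct(
                    counts, BLOSUM62_BACKGROUND, msa.n_sequences, gap_fraction, 1
                )
                assert track.scores[c] == pytest.approx(expected, abs=1e-9)

    def test_scores_in_unit_interval_and_row_permutation_invariant(self, rng):
        msa = _random_msa(rng, n=6, length=25)
        track = jsd_conservation(msa)
        assert ((track.scores >= 0) & (track.scores <= 1)).all()
        perm = msa.subset([3, 1, 5, 0, 4, 2])
        assert np.allclose(jsd_conservation(perm).scores, track.scores)

    def test_conserved_columns_score_highest(self):
        msa, truth = simulate_msa(10, 40, {5, 20}, BLOSUM62_BACKGROUND, seed=3)
        scores = jsd_conservation(msa).scores
        background_max = max(
            scores[c] for c in range(40) if c not in truth
        )
        assert all(scores[c] > background_max for c in truth)

    def test_malformed_background_rejected(self):
        msa = ProteinMSA(ids=["a", "b"], rows=["AA", "AA"])
        bad = {a: 1.0 for a in AA}  # sums to 20
        with pytest.raises(ValueError):
            jsd_conservation(msa, background=bad)


class TestLogo:
    def test_column_matching_background_zero_bits(self):
        msa = ProteinMSA(ids=[f"s{i}" for i in range(20)], rows=list(AA))
        logo = relative_entropy_logo(msa, background="uniform")
        assert logo[logo.column == 0].total_bits.iloc[0] == pytest.approx(0.0)

    def test_invariant_rare_residue_height(self):
        # residue with background 0.025 -> log2(1/0.025) = 5.32 bits
        msa = ProteinMSA(ids=["a", "b"], rows=["C", "C"])
        logo = relative_entropy_logo(msa)
        assert logo.total_bits.iloc[0] == pytest.approx(math.log2(1 / 0.025), rel=1e-6)
        assert logo.height.iloc[0] == pytest.approx(logo.total_bits.iloc[0])


class TestNonredundant:
    def test_identical_pair_reduced(self):
        msa = ProteinMSA(ids=["a", "b"], rows=["ACDEF", "ACDEF"])
        assert select_nonredundant(msa, 0.5).ids == ["a"]

    def test_diverse_set_kept(self, rng):
        msa = ProteinMSA(
            ids=["a", "b", "c"],
            rows=["ACDEFGHIKL", "MNPQRSTVWY", "LKIHGFEDCA"],
        )
        assert select_nonredundant(msa, 0.5).ids == ["a", "b", "c"]

    def test_greedy_order(self):
        a = "ACDEFGHIKL"
        a_prime = "ACDEFG" + "WYVM"  # 60% identical to a
        b = "WWWWWWWWWW"
        msa = ProteinMSA(ids=["a", "a2", "b"], rows=[a, a_prime, b])
        assert select_nonredundant(msa, 0.5).ids == ["a", "b"]
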