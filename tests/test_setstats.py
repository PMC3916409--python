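"""Exact rank-sum test, Z-method combination, binomial enrichment."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import kstest, norm

from ciliashift import (
    GeneSet,
    ValidationError,
    binomial_set_enrichment,
    combine_z,
    load_table3_fixture,
    set_downregulation_test,
    wilcoxon_one_tailed,
)
from ciliashift.setstats import _rank_sum_p_many

from conftest import enumeration_rank_sum_p


class TestWilcoxonOneTailed:
    def test_complete_separation_three_vs_three(self):
        p = wilcoxon_one_tailed([1, 2, 3], [4, 5, 6], "case_less")
        assert p == pytest.approx(1 / 20)

    def test_complete_separation_six_vs_nine(self):
        p = wilcoxon_one_tailed(range(6), range(10, 19), "case_less")
        assert p == pytest.approx(1 / 5005)

    def test_equal_multisets_give_no_evidence(self):
        p = wilcoxon_one_tailed([1, 2, 3], [3, 2, 1], "case_less")
        assert p >= 0.5

    def test_all_identical_values(self):
        for alt in ("case_less", "case_greater"):
            assert wilcoxon_one_tailed([5, 5, 5], [5, 5], alt) == 1.0

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            wilcoxon_one_tailed([], [1.0], "case_less")

    def test_unknown_alternative_rejected(self):
        with pytest.raises(ValidationError):
            wilcoxon_one_tailed([1.0], [2.0], "less")

    @given(
        st.lists(st.integers(0, 6), min_size=1, max_size=6),
        st.lists(st.integers(0, 6), min_size=1, max_size=6),
        st.sampled_from(["case_less", "case_greater"]),
        st.booleans(),
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_enumeration_oracle_with_ties(self, case, control, alt, mid_p):
        """DP-based exact p equals complete enumeration over all
        assignments, for arbitrary tie structure at n1+n2 <= 12."""
        expected = enumeration_rank_sum_p(case, control, alt, mid_p=mid_p)
        observed = wilcoxon_one_tailed(case, control, alt, mid_p=mid_p)
        assert observed == pytest.approx(expected, abs=1e-12)

    @given(
        st.lists(st.floats(-5, 5, allow_nan=False), min_size=2, max_size=6),
        st.lists(st.floats(-5, 5, allow_nan=False), min_size=2, max_size=6),
    )
    @settings(max_examples=100, deadline=None)
    def test_one_tailed_pair_covers_unity(self, case, control):
        """p(case_less) + p(case_greater) = 1 + P(W = w_obs) >= 1 for the
        inclusive exact test; the mid-p pair sums to exactly 1."""
        less = wilcoxon_one_tailed(case, control, "case_less")
        greater = wilcoxon_one_tailed(case, control, "case_greater")
        assert less + greater >= 1.0 - 1e-12
        less_m = wilcoxon_one_tailed(case, control, "case_less", mid_p=True)
        greater_m = wilcoxon_one_tailed(case, control, "case_greater", mid_p=True)
        assert less_m + greater_m == pytest.approx(1.0)

    def test_normal_approximation_close_to_exact(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            case = rng.normal(0, 1, 10)
            control = rng.normal(0.5, 1, 10)
            exact = wilcoxon_one_tailed(case, control, "case_less")
            approx = wilcoxon_one_tailed(
                case, control, "case_less", exact_threshold=10
            )
            assert approx == pytest.approx(exact, abs=0.01)

    def test_vectorized_path_matches_scalar(self):
        rng = np.random.default_rng(9)
        case = rng.integers(0, 4, (40, 6)).astype(float)
        control = rng.integers(0, 4, (40, 9)).astype(float)
        for mid_p in (False, True):
            vec = _rank_sum_p_many(case, control, "case_less", mid_p=mid_p)
            scalar = [
                wilcoxon_one_tailed(case[i], control[i], "case_less", mid_p=mid_p)
                for i in range(40)
            ]
            assert np.allclose(vec, scalar)


class TestCombineZ:
    def test_reproduces_all_printed_combined_p(self):
        t3 = load_table3_fixture()
        for category, printed in t3.combined_p.items():
            result = combine_z(t3.per_gene_p(category))
            assert result.p_combined == pytest.approx(printed, rel=1e-4)

    def test_single_half_p_gives_zero_z(self):
        r = combine_z([0.5])
        assert r.z_combined == pytest.approx(0.0)
        assert r.p_combined == pytest.approx(0.5)

    def test_empty_list_rejected(self):
        with pytest.raises(ValidationError):
            combine_z([])

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ValidationError):
            combine_z([0.2, 1.5])

    def test_permutation_invariant(self):
        p = [0.01, 0.3, 0.7, 0.05]
        rng = np.random.default_rng(1)
        for _ in range(5):
            perm = rng.permutation(p)
            assert combine_z(perm).p_combined == pytest.approx(
                combine_z(p).p_combined
            )

    @pytest.mark.parametrize("p", [0.01, 0.2, 0.49])
    def test_replicating_a_small_p_strengthens_evidence(self, p):
        """k copies of p < 0.5 combine to sf(sqrt(k)*z), monotone in k."""
        previous = 1.0
        for k in range(1, 6):
            combined = combine_z([p] * k).p_combined
            assert combined == pytest.approx(
                float(norm.sf(np.sqrt(k) * norm.isf(p)))
            )
            assert combined < previous
            previous = combined

    def test_degenerate_p_clipped_to_finite_deviates(self):
        r = combine_z([0.0, 1.0])
        assert np.isfinite(r.z_combined)
        assert 0.0 < r.p_combined < 1.0


class TestSetDownregulationTest:
    def test_single_gene_set_equals_that_genes_p(self, small_matrix, small_design):
        s = GeneSet(name="solo", members=["down_gene"])
        r = set_downregulation_test(small_matrix, small_design, s)
        direct = wilcoxon_one_tailed(
            [1.0, 2.0, 3.0], [8.0, 9.0], "case_less", mid_p=True
        )
        assert r.k == 1
        assert r.p_combined == pytest.approx(direct)

    def test_absent_members_dropped(self, small_matrix, small_design):
        s = GeneSet(name="partial", members=["down_gene", "ghost1", "ghost2"])
        r = set_downregulation_test(small_matrix, small_design, s)
        assert r.genes == ["down_gene"] and r.k == 1

    def test_no_members_present_is_an_error(self, small_matrix, small_design):
        s = GeneSet(name="ghosts", members=["ghost"])
        with pytest.raises(ValidationError):
            set_downregulation_test(small_matrix, small_design, s)

    def test_requires_log2_matrix(self, small_matrix, small_design):
        small_matrix.is_log2 = False
        with pytest.raises(ValidationError):
            set_downregulation_test(
                small_matrix, small_design, GeneSet(name="s", members=["down_gene"])
            )

    def test_null_combined_p_is_uniform(self):
        """10,000 independent-null replicates of a 10-gene set at 6v9:
        the combined p-value's empirical distribution is uniform
        (KS < 0.02)."""
        rng = np.random.default_rng(77)
        reps, k = 10_000, 10
        case = rng.standard_normal((reps, k, 6))
        control = rng.standard_normal((reps, k, 9))
        p = _rank_sum_p_many(case, control, "case_less", mid_p=True)
        z = norm.isf(np.clip(p, 1e-16, 1 - 1e-16))
        p_combined = norm.sf(z.sum(axis=1) / np.sqrt(k))
        ks = kstest(p_combined, "uniform").statistic
        assert ks < 0.02


class TestBinomialEnrichment:
    def test_closed_form_all_hits(self):
        assert binomial_set_enrichment(10, 10, 0.5) == pytest.approx(2**-10)

    def test_near_null_at_the_expectation(self):
        # 61 hits in 602 draws at background 10%: barely above expectation
        assert binomial_set_enrichment(602, 61, 0.10) == pytest.approx(
            0.476531533, rel=1e-6
        )

    def test_zero_hits_is_certain(self):
        assert binomial_set_enrichment(20, 0, 0.1) == 1.0

    @pytest.mark.parametrize("p0", [0.0, 1.0, -0.1])
    def test_degenerate_background_rejected(self, p0):
        with pytest.raises(ValidationError):
            binomial_set_enrichment(10, 5, p0)

    def test_counts_validated(self):
        with pytest.raises(ValidationError):
            binomial_set_enrichment(10, 11, 0.5)
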