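"""ANOVA, Holm-Sidak correction, and the cluster-based permutation test."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from seizdyn import group_stats as gs
from seizdyn.errors import (
    AlignmentError,
    DegenerateSignalError,
    ParameterError,
    PreconditionError,
)
from seizdyn.group_stats import GroupSummary

from conftest import brute_force_max_cluster_masses, holm_sidak_oracle


class TestAnova:
    def test_matches_scipy_on_raw_values(self, rng):
        groups = [rng.normal(m, 2, n) for m, n in [(0, 8), (1, 12), (0.5, 6)]]
        F, p = gs.anova_oneway(groups)
        ref = sps.f_oneway(*groups)
        assert F == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)

    def test_summary_path_equals_value_path(self, rng):
        groups = [rng.normal(m, 2, n) for m, n in [(0, 9), (1.2, 14)]]
        summaries = [
            GroupSummary(f"g{i}", g.size, g.mean(), g.std(ddof=1) / np.sqrt(g.size))
            for i, g in enumerate(groups)
        ]
        Fa, pa = gs.anova_oneway(groups)
        Fb, pb = gs.anova_oneway(summaries)
        assert Fb == pytest.approx(Fa)
        assert pb == pytest.approx(pa)

    def test_identical_constants_are_degenerate(self):
        with pytest.raises(DegenerateSignalError):
            gs.anova_oneway([np.full(5, 2.0), np.full(6, 2.0)])

    def test_type_one_error_calibration(self):
        hits = 0
        runs = 1000
        for i in range(runs):
            r = np.random.default_rng(5000 + i)
            _, p = gs.anova_oneway([r.normal(0, 1, 8), r.normal(0, 1, 8)])
            hits += p < 0.05
        assert 0.03 <= hits / runs <= 0.07

    def test_printed_group_summaries_reject_equality(self):
        # the four cohort onset summaries differ at the 5 % level
        summaries = [
            GroupSummary("sham_control", 13, 15.2, 1.1),
            GroupSummary("nphr_control", 7, 17.3, 1.3),
            GroupSummary("light_control", 8, 16.3, 1.7),
            GroupSummary("experimental", 16, 21.0, 1.8),
        ]
        _, p = gs.anova_oneway(summaries)
        assert p < 0.05

    def test_small_group_rejected(self, rng):
        with pytest.raises(PreconditionError):
            gs.anova_oneway([rng.normal(0, 1, 5), np.array([1.0])])


class TestHolmSidak:
    def test_single_comparison_unchanged(self):
        assert gs.holm_sidak_vs_control([0.031])[0] == pytest.approx(0.031)

    def test_matches_hand_computed_step_down(self):
        p = [0.01, 0.04, 0.03]
        np.testing.assert_allclose(
            gs.holm_sidak_vs_control(p), holm_sidak_oracle(p), atol=1e-12
        )

    def test_all_ones_stay_one(self):
        np.testing.assert_array_equal(gs.holm_sidak_vs_control([1.0, 1.0, 1.0]), 1.0)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        st.lists(st.floats(0.0, 1.0), min_size=1, max_size=8)
    )
    def test_adjusted_monotone_and_no_smaller_than_raw(self, pvals):
        adj = gs.holm_sidak_vs_control(pvals)
        np.testing.assert_allclose(
            adj, holm_sidak_oracle(pvals), atol=1e-9
        )
        assert np.all(adj >= np.asarray(pvals) - 1e-12)
        order = np.argsort(pvals, kind="stable")
        assert np.all(np.diff(adj[order]) >= -1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ParameterError):
            gs.holm_sidak_vs_control([0.5, 1.2])


class TestClusterPermutation:
    def test_three_vs_three_matches_exhaustive_enumeration(self, rng):
        A = rng.normal(0, 1, (3, 40))
        B = rng.normal(1.0, 1, (3, 40))
        null, obs = brute_force_max_cluster_masses(A, B)
        p_oracle = float(np.mean(null >= obs - 1e-9))
        res = gs.cluster_permutation_test(A, B, n_perm=1000, seed=0)
        assert res.exact and res.n_perm == 20
        assert res.min_p == pytest.approx(p_oracle)

    def test_monte_carlo_close_to_exhaustive_for_4v4(self, rng):
        A = rng.normal(0, 1, (4, 60))
        B = rng.normal(0.8, 1, (4, 60))
        exact = gs.cluster_permutation_test(A, B, n_perm=100, seed=0)
        assert exact.exact
        mc = gs.cluster_permutation_test(A, B, n_perm=69, seed=1)
        assert not mc.exact
        assert abs(mc.min_p - exact.min_p) < 0.02 + 1.0 / 69

    def test_null_rarely_produces_clusters(self):
        sig = 0
        runs = 100
        for r in range(runs):
            g = np.random.default_rng(800 + r)
            A = g.normal(0, 1, (6, 120))
            B = g.normal(0, 1, (6, 120))
            res = gs.cluster_permutation_test(A, B, n_perm=200, seed=r)
            sig += len(res.significant(0.05)) > 0
        assert sig / runs <= 0.05 + 2.5 * np.sqrt(0.05 * 0.95 / runs)

    def test_constructed_offset_yields_covering_cluster(self, rng):
        # 5-pooled-SD offset on timepoints 100..200 must be found there
        T = 300
        A = rng.normal(0, 1, (10, T))
        B = rng.normal(0, 1, (10, T))
        B[:, 100:201] += 5.0
        res = gs.cluster_permutation_test(A, B, n_perm=500, seed=2)
        sig = res.significant(0.05)
        assert sig
        best = max(sig, key=lambda c: abs(c.mass))
        overlap = min(best.end_index, 200) - max(best.start_index, 100) + 1
        assert overlap >= 0.8 * 101
        assert best.p < 0.05

    def test_ranksum_stat_handles_ordinal_ties(self, rng):
        A = rng.integers(0, 3, (8, 60)).astype(float)
        B = np.clip(A[: 8] + rng.integers(2, 4, (8, 60)), 0, 5).astype(float)
        res = gs.cluster_permutation_test(A, B, stat="ranksum", n_perm=300, seed=3)
        assert res.min_p < 0.05

    def test_unequal_grids_rejected(self, rng):
        with pytest.raises(AlignmentError):
            gs.cluster_permutation_test(
                rng.normal(0, 1, (4, 50)), rng.normal(0, 1, (4, 60))
            )

    def test_small_groups_rejected(self, rng):
        with pytest.raises(PreconditionError):
            gs.cluster_permutation_test(
                rng.normal(0, 1, (2, 50)), rng.normal(0, 1, (4, 50))
            )

    def test_low_permutation_count_warns(self, rng):
        with pytest.warns(UserWarning):
            gs.cluster_permutation_test(
                rng.normal(0, 1, (4, 30)), rng.normal(0, 1, (4, 30)), n_perm=50, seed=0
            )

    def test_p_resolution_bounded_by_permutations(self, rng):
        A = rng.normal(0, 1, (8, 80))
        B = A + 3.0
        res = gs.cluster_permutation_test(A, B, n_perm=400, seed=0)
        assert res.min_p >= 1.0 / (res.n_perm + 1) - 1e-12
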