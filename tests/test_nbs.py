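"""Edge-wise GLM, within-subject permutation, component inference."""

import numpy as np
import pandas as pd
import pytest

import wandernet as wn
from wandernet.exceptions import DesignError, InvalidParameterError
from wandernet.nbs import (
    EdgeGLMStats,
    count_within_block_permutations,
    enumerate_within_blocks,
    freedman_lane_null,
)


def _design(n_subjects=6, scans_per=4, seed=0):
    rng = np.random.default_rng(seed)
    groups = np.repeat([f"s{i}" for i in range(n_subjects)], scans_per)
    x = rng.standard_normal(groups.size)
    return groups, x, rng


def _brute_force_t(y, groups, x):
    """Independent normal-equations solver for the full dummy design."""
    subs = pd.get_dummies(pd.Series(groups), drop_first=True, dtype=float)
    design = np.column_stack([np.ones(len(y)), subs.to_numpy(), x])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    df = len(y) - np.linalg.matrix_rank(design)
    sigma2 = resid @ resid / df
    cov = sigma2 * np.linalg.inv(design.T @ design)
    return beta[-1] / np.sqrt(cov[-1, -1]), df


class TestEdgeGLM:
    def test_matches_brute_force_normal_equations(self):
        groups, x, rng = _design(seed=1)
        y = rng.standard_normal((groups.size, 100))
        stats = wn.fit_edge_glm(y, x, groups)
        for e in range(100):
            t_ref, df_ref = _brute_force_t(y[:, e], groups, x)
            assert stats.t[e] == pytest.approx(t_ref, abs=1e-8)
        assert stats.df == df_ref

    def test_orthogonal_edge_has_zero_t(self):
        groups, x, rng = _design(seed=2)
        codes = pd.factorize(groups)[0]
        demean = lambda v: v - np.bincount(codes, weights=v)[codes] / 4
        x_res = demean(x)
        v = demean(rng.standard_normal(groups.size))
        y = (v - (v @ x_res) / (x_res @ x_res) * x_res)[:, None]
        stats = wn.fit_edge_glm(y, x, groups)
        assert abs(stats.t[0]) < 1e-10

    def test_single_block_reduces_to_simple_regression_t(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(30)
        y = rng.standard_normal((30, 5))
        stats = wn.fit_edge_glm(y, x, groups=None)
        assert stats.df == 28
        for e in range(5):
            r = np.corrcoef(x, y[:, e])[0, 1]
            t_ref = r * np.sqrt(28) / np.sqrt(1 - r**2)
            assert stats.t[e] == pytest.approx(t_ref, abs=1e-10)

    def test_subject_constant_shift_leaves_t_unchanged(self):
        groups, x, rng = _design(seed=4)
        y = rng.standard_normal((groups.size, 40))
        shifted = y.copy()
        shifted[groups == "s2"] += 5.0
        a = wn.fit_edge_glm(y, x, groups)
        b = wn.fit_edge_glm(shifted, x, groups)
        assert np.allclose(a.t, b.t, atol=1e-8)

    def test_predictor_constant_within_subjects_is_rank_deficient(self):
        groups, _, rng = _design(seed=5)
        x = pd.factorize(groups)[0].astype(float)  # subject-constant
        y = rng.standard_normal((groups.size, 3))
        with pytest.raises(DesignError, match="constant after removing"):
            wn.fit_edge_glm(y, x, groups)

    def test_subject_mean_coding_matches_per_edge_brute_force(self):
        groups, x, rng = _design(seed=6)
        y = rng.standard_normal((groups.size, 20))
        stats = wn.fit_edge_glm(y, x, groups, nuisance="subject_mean")
        codes = pd.factorize(groups)[0]
        for e in range(20):
            m = np.bincount(codes, weights=y[:, e])[codes] / 4
            design = np.column_stack([np.ones(len(x)), m, x])
            beta, *_ = np.linalg.lstsq(design, y[:, e], rcond=None)
            resid = y[:, e] - design @ beta
            df = len(x) - 3
            cov = (resid @ resid / df) * np.linalg.inv(design.T @ design)
            assert stats.t[e] == pytest.approx(
                beta[-1] / np.sqrt(cov[-1, -1]), abs=1e-8
            )

    def test_misaligned_predictor_rejected(self):
        groups, x, rng = _design()
        with pytest.raises(DesignError, match="scans"):
            wn.fit_edge_glm(rng.standard_normal((groups.size, 4)), x[:-1], groups)


class TestPermutations:
    def test_two_scans_enumerate_to_two_permutations(self):
        perms = {tuple(p) for p in enumerate_within_blocks(["a", "a"])}
        assert perms == {(0, 1), (1, 0)}

    def test_two_subjects_three_scans_give_36_distinct_permutations(self):
        groups = ["a"] * 3 + ["b"] * 3
        perms = {tuple(p) for p in enumerate_within_blocks(groups)}
        assert len(perms) == 36
        assert count_within_block_permutations(groups) == 36

    def test_sampled_permutation_is_bijection_within_each_block(self, rng):
        groups = np.repeat(np.arange(5), [2, 3, 4, 1, 4])
        perm = wn.permute_within_blocks(groups, rng)
        assert sorted(perm) == list(range(groups.size))
        for g in range(5):
            idx = np.flatnonzero(groups == g)
            assert set(perm[idx]) == set(idx)


class TestThreshold:
    def test_all_subthreshold_yields_empty_set(self):
        stats = EdgeGLMStats(t=np.array([1.0, -2.0, 0.5]), beta_hat=None, df=10)
        assert wn.threshold_edges(stats, 4.7, "two_sided").size == 0

    def test_negating_predictor_swaps_one_sided_tails(self):
        groups, x, rng = _design(seed=7)
        y = rng.standard_normal((groups.size, 50))
        a = wn.fit_edge_glm(y, x, groups)
        b = wn.fit_edge_glm(y, -x, groups)
        assert np.array_equal(
            wn.threshold_edges(a, 1.5, "positive"),
            wn.threshold_edges(b, 1.5, "negative"),
        )

    def test_mixed_field_matches_elementwise_comparison(self):
        t = np.array([5.0, -5.0, 4.69, -4.71, 0.0, 10.0])
        stats = EdgeGLMStats(t=t, beta_hat=None, df=10)
        assert list(wn.threshold_edges(stats, 4.7, "positive")) == [0, 5]
        assert list(wn.threshold_edges(stats, 4.7, "negative")) == [1, 3]
        assert list(wn.threshold_edges(stats, 4.7, "two_sided")) == [0, 1, 3, 5]

    def test_nonpositive_threshold_rejected(self):
        stats = EdgeGLMStats(t=np.zeros(3), beta_hat=None, df=10)
        with pytest.raises(InvalidParameterError):
            wn.threshold_edges(stats, -1.0, "positive")


class _UnionFind:
    """Independent oracle for connected components."""

    def __init__(self):
        self.parent = {}

    def find(self, a):
        self.parent.setdefault(a, a)
        while self.parent[a] != a:
            self.parent[a] = self.parent[self.parent[a]]
            a = self.parent[a]
        return a

    def union(self, a, b):
        self.parent[self.find(a)] = self.find(b)


def _oracle_components(edges):
    uf = _UnionFind()
    for i, j in edges:
        uf.union(i, j)
    comps = {}
    for i, j in edges:
        comps.setdefault(uf.find(i), set()).add((i, j))
    return sorted(
        (sorted(e) for e in comps.values()),
        key=lambda e: (-len(e), min(min(p) for p in e)),
    )


class TestComponents:
    def test_two_disjoint_triangles(self):
        edges = [(0, 1), (1, 2), (0, 2), (5, 6), (6, 7), (5, 7)]
        comps = wn.find_components(edges)
        assert [c.size_extent for c in comps] == [3, 3]
        assert comps[0].nodes == [0, 1, 2]
        assert comps[1].nodes == [5, 6, 7]

    def test_random_graphs_match_union_find_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            ii, jj = wn.edge_index(30)
            mask = rng.random(ii.size) < 0.1
            edges = list(zip(ii[mask], jj[mask]))
            ours = [
                [list(e) for e in c.edges] for c in wn.find_components(edges)
            ]
            oracle = [
                [list(e) for e in comp] for comp in _oracle_components(edges)
            ]
            assert ours == oracle

    def test_reference_sensorimotor_network_is_one_component(self, reference_edges):
        comps = wn.find_components(reference_edges)
        assert len(comps) == 1
        assert comps[0].size_extent == 26
        assert len(comps[0].nodes) == 19

    def test_component_intensity_accumulates_excess_statistic(self):
        edges = [(0, 1), (1, 2)]
        comps = wn.find_components(edges, edge_values=[5.0, -6.0], threshold=4.0)
        assert comps[0].intensity == pytest.approx(3.0)


class TestPValues:
    def test_observed_above_all_nulls_with_99_permutations(self):
        assert wn.component_pvalue(10, np.zeros(99)) == pytest.approx(0.01)

    def test_zero_observed_is_never_significant(self):
        assert wn.component_pvalue(0, np.arange(100)) == 1.0

    def test_direct_count_on_toy_null(self):
        assert wn.component_pvalue(3, [1, 2, 3, 4]) == pytest.approx(0.6)
        assert wn.component_pvalue(3, [1, 2, 3, 4], exact=True) == pytest.approx(0.5)

    def test_fdr_identity_for_single_test(self):
        assert wn.adjust_fdr([0.03]) == pytest.approx([0.03])

    def test_fdr_rank_one_in_six_test_family(self):
        p = [0.0081, 0.3, 0.5, 0.6, 0.7, 0.9]
        assert wn.adjust_fdr(p)[0] == pytest.approx(0.0486, abs=5e-4)

    def test_fdr_matches_independent_step_up_implementation(self, rng):
        p = rng.uniform(size=25)
        ours = wn.adjust_fdr(p)
        # hand-rolled Benjamini-Hochberg step-up with monotonicity
        order = np.argsort(p)
        m = len(p)
        adj = p[order] * m / np.arange(1, m + 1)
        adj = np.minimum.accumulate(adj[::-1])[::-1]
        expect = np.empty(m)
        expect[order] = np.minimum(adj, 1.0)
        assert np.allclose(ours, expect, atol=1e-12)


class TestCohensD:
    def test_zero_t_gives_zero_effect(self):
        stats = EdgeGLMStats(t=np.array([0.0]), beta_hat=None, df=20)
        comp = wn.NBSComponent(edges=[(0, 1)], nodes=[0, 1], size_extent=1)
        assert wn.network_cohens_d(stats, comp, n_nodes=2) == 0.0

    def test_closed_form_single_edge(self):
        stats = EdgeGLMStats(t=np.array([3.0]), beta_hat=None, df=36)
        comp = wn.NBSComponent(edges=[(0, 1)], nodes=[0, 1], size_extent=1)
        assert wn.network_cohens_d(stats, comp, n_nodes=2) == pytest.approx(1.0)

    def test_multi_edge_mean_of_conversions(self):
        # edges of a 3-node path with t = (2, -4) and df = 16
        t = np.array([2.0, -4.0, 0.0])  # edges (0,1), (0,2), (1,2)
        stats = EdgeGLMStats(t=t, beta_hat=None, df=16)
        comp = wn.NBSComponent(
            edges=[(0, 1), (0, 2)], nodes=[0, 1, 2], size_extent=2
        )
        expect = np.mean([2 * 2.0 / 4.0, 2 * 4.0 / 4.0])
        assert wn.network_cohens_d(stats, comp, n_nodes=3) == pytest.approx(
            expect, abs=1e-12
        )

    def test_nonpositive_df_rejected(self):
        stats = EdgeGLMStats(t=np.array([1.0]), beta_hat=None, df=0)
        comp = wn.NBSComponent(edges=[(0, 1)], nodes=[0, 1], size_extent=1)
        with pytest.raises(DesignError):
            wn.network_cohens_d(stats, comp, n_nodes=2)


class TestFreedmanLaneNull:
    def test_same_seed_reproduces_null_distribution(self):
        groups, x, rng = _design(seed=8)
        y = rng.standard_normal((groups.size, wn.edge_count(8)))
        a = freedman_lane_null(y, x, groups, threshold=2.0, n_perm=200, seed=5)
        b = freedman_lane_null(y, x, groups, threshold=2.0, n_perm=200, seed=5)
        assert np.array_equal(a, b)

    def test_nonempty_fraction_decreases_with_threshold(self):
        groups, x, rng = _design(n_subjects=8, seed=9)
        y = rng.standard_normal((groups.size, wn.edge_count(12)))
        fracs = [
            np.mean(
                freedman_lane_null(
                    y, x, groups, threshold=th, n_perm=300, seed=1
                )
                > 0
            )
            for th in (2.0, 3.0, 4.0)
        ]
        assert fracs[0] >= fracs[1] >= fracs[2]

    def test_intercept_only_null_equals_plain_permutation_of_raw_values(self):
        # one exchangeability block: Freedman-Lane reconstruction reduces to
        # permuting the raw edge values; verify against a brute-force oracle
        rng = np.random.default_rng(10)
        n, n_nodes = 4, 5
        y = rng.standard_normal((n, wn.edge_count(n_nodes)))
        x = rng.standard_normal(n)
        ours = freedman_lane_null(
            y, x, None, threshold=1.0, exhaustive=True, n_nodes=n_nodes
        )
        import itertools

        ii, jj = wn.edge_index(n_nodes)
        oracle = []
        for perm in itertools.permutations(range(n)):
            yp = y[list(perm)]
            stats = wn.fit_edge_glm(yp, x, groups=None)
            mask = stats.t > 1.0
            oracle.append(
                max(
                    (len(c) for c in _oracle_components(
                        list(zip(ii[mask], jj[mask]))
                    )),
                    default=0,
                )
            )
        assert sorted(ours) == sorted(oracle)

    def test_low_threshold_warns_about_uninformative_null(self):
        groups, x, rng = _design(n_subjects=4, seed=11)
        y = rng.standard_normal((groups.size, wn.edge_count(5)))
        with pytest.warns(UserWarning, match="threshold is too low"):
            freedman_lane_null(y, x, groups, threshold=0.05, n_perm=100, seed=0)


class TestEstimator:
    def test_deterministic_given_random_state(self, small_study):
        _, truth, _, stack = small_study
        x = truth.true_scores[:, :, 0].ravel()
        fits = [
            wn.NetworkBasedStatistic(
                threshold=2.5, n_perm=200, random_state=9
            ).fit(stack, x)
            for _ in range(2)
        ]
        assert np.array_equal(fits[0].null_max_sizes_, fits[1].null_max_sizes_)
        assert [c.edges for c in fits[0].components_] == [
            c.edges for c in fits[1].components_
        ]

    def test_planted_network_is_detected(self, small_study):
        params, truth, _, stack = small_study
        x = truth.true_scores[:, :, 0].ravel()
        est = wn.NetworkBasedStatistic(
            threshold=3.0, tail="positive", n_perm=300, random_state=0
        ).fit(stack, x)
        top = est.components_[0]
        assert top.p_fwe < 0.05
        assert set(top.edges) <= set(params.planted_edges)
        assert top.size_extent >= 10

    def test_sklearn_params_round_trip(self):
        from sklearn.base import clone

        est = wn.NetworkBasedStatistic(threshold=3.0, tail="two_sided")
        assert clone(est).get_params()["threshold"] == 3.0

    def test_family_run_is_reproducible(self, small_study):
        _, _, table, stack = small_study
        m = wn.MFA(n_components=3).fit(table)
        scores = wn.partial_scores_frame(m.result_, table.subject_ids)
        a = wn.run_nbs(stack, scores, threshold=3.0, n_perm=150, seed=4)
        b = wn.run_nbs(stack, scores, threshold=3.0, n_perm=150, seed=4)
        pd.testing.assert_frame_equal(a.family_table, b.family_table)

    def test_scans_without_scores_rejected(self, small_study):
        _, _, table, stack = small_study
        m = wn.MFA(n_components=3).fit(table)
        scores = wn.partial_scores_frame(m.result_, table.subject_ids).iloc[:-2]
        with pytest.raises(InvalidParameterError, match="matching scores"):
            wn.run_nbs(stack, scores, threshold=3.0, n_perm=150, seed=4)
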