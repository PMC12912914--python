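"""EM trajectory clustering: steps, diagnostics, stability, labels."""

import numpy as np
import pytest

from astraj.clustering import (
    ClusterModel,
    Trajectory,
    adjusted_rand_index,
    bic,
    e_step,
    fit_em,
    label_clusters,
    m_step,
    select_k,
    silhouette,
    stability,
    trajectory_distance,
)
from astraj.errors import InvalidInputError, UndefinedMetricError
from conftest import make_constant_trajectories


class FakeCentroid:
    """Constant- or callable-valued centroid with an edf, for toys."""

    def __init__(self, fn, edf=2.0):
        self._fn = fn if callable(fn) else (lambda t, v=fn: np.full_like(
            np.asarray(t, float), v))
        self.edf = edf

    def __call__(self, t):
        return self._fn(np.asarray(t, float))


class TestTrajectoryDistance:
    def test_zero_on_own_centroid(self):
        t = Trajectory(1, [1, 3, 5], [0.4, 0.4, 0.4])
        assert trajectory_distance(t, FakeCentroid(0.4)) == 0.0

    def test_symmetric_offsets_give_squared_deviation(self):
        t = Trajectory(1, [2, 4], [0.5 + 0.1, 0.5 - 0.1])
        assert trajectory_distance(t, FakeCentroid(0.5)) == pytest.approx(0.01)

    def test_matches_naive_loop(self):
        rng = np.random.default_rng(0)
        times = np.sort(rng.uniform(0, 10, 6))
        scores = rng.uniform(0, 1, 6)
        cubic = FakeCentroid(lambda t: 0.3 + 0.01 * t + 0.002 * t**3 / 100)
        t = Trajectory(1, times, scores)
        naive = sum((s - float(cubic(np.array([x]))[0]))**2
                    for x, s in zip(times, scores)) / 6
        assert trajectory_distance(t, cubic) == pytest.approx(naive, abs=1e-12)


class TestMStep:
    def test_constant_scores_give_constant_centroid(self):
        trajs = make_constant_trajectories([0.6], n_per_level=8, seed=1)
        (cent,) = m_step(trajs, np.zeros(len(trajs), dtype=int))
        xs = np.linspace(0, 10, 101)
        assert np.max(np.abs(cent(xs) - 0.6)) < 1e-6

    def test_two_constant_clusters_recovered(self, two_level_trajectories):
        trajs = two_level_trajectories
        assign = np.array([0] * 12 + [1] * 12)
        c0, c1 = m_step(trajs, assign)
        xs = np.linspace(0, 10, 50)
        assert np.max(np.abs(c0(xs) - 0.3)) < 1e-3
        assert np.max(np.abs(c1(xs) - 0.8)) < 1e-3

    def test_noiseless_linear_trend_matches_least_squares(self):
        rng = np.random.default_rng(2)
        trajs = []
        for sid in range(10):
            times = np.sort(rng.uniform(0, 10, 6))
            trajs.append(Trajectory(sid, times, 0.2 + 0.05 * times))
        (cent,) = m_step(trajs, np.zeros(10, dtype=int))
        xs = np.linspace(0, 10, 50)
        assert np.max(np.abs(cent(xs) - (0.2 + 0.05 * xs))) < 1e-3

    def test_empty_cluster_rejected(self, two_level_trajectories):
        with pytest.raises(InvalidInputError):
            m_step(two_level_trajectories,
                   np.ones(len(two_level_trajectories), dtype=int))


class TestEStep:
    def test_exact_match_assigned_to_its_centroid(self):
        cents = [FakeCentroid(0.2), FakeCentroid(0.5), FakeCentroid(0.8)]
        t = Trajectory(1, [1, 2, 3], [0.8, 0.8, 0.8])
        assert e_step([t], cents)[0] == 2

    def test_tie_broken_toward_lowest_index(self):
        cents = [FakeCentroid(0.4), FakeCentroid(0.6)]
        t = Trajectory(1, [1.0], [0.5])
        assert e_step([t], cents)[0] == 0

    def test_matches_exhaustive_distance_table(self):
        rng = np.random.default_rng(3)
        cents = [FakeCentroid(v) for v in (0.2, 0.5, 0.7)]
        trajs = [Trajectory(i, np.sort(rng.uniform(0, 10, 4)),
                            rng.uniform(0, 1, 4)) for i in range(15)]
        got = e_step(trajs, cents)
        table = np.array([[trajectory_distance(t, c) for c in cents]
                          for t in trajs])
        np.testing.assert_array_equal(got, table.argmin(axis=1))


class TestFitEm:
    def test_k1_objective_is_pooled_residual_mse(self, two_level_trajectories):
        model = fit_em(two_level_trajectories, k=1, seed=0)
        (cent,) = model.centroids
        num = den = 0.0
        for t in two_level_trajectories:
            num += np.sum((t.scores - cent(t.times))**2)
            den += len(t)
        assert model.within_mse == pytest.approx(num / den, abs=1e-12)

    def test_noiseless_two_level_recovery(self, two_level_trajectories):
        truth = np.array([0] * 12 + [1] * 12)
        model = fit_em(two_level_trajectories, k=2, seed=1)
        assert adjusted_rand_index(model.assignments, truth) == 1.0

    def test_seed_determinism(self, trajectories):
        a = fit_em(trajectories, 3, seed=5)
        b = fit_em(trajectories, 3, seed=5)
        np.testing.assert_array_equal(a.assignments, b.assignments)
        assert a.within_mse == b.within_mse

    def test_objective_non_increasing_and_fixed_point(self, trajectories):
        model = fit_em(trajectories, 3, seed=2)
        diffs = np.diff(model.objective_trace)
        assert (diffs <= 1e-12).all()
        assert model.converged
        np.testing.assert_array_equal(
            e_step(trajectories, model.centroids), model.assignments)

    def test_k_larger_than_cohort_rejected(self, two_level_trajectories):
        with pytest.raises(InvalidInputError):
            fit_em(two_level_trajectories, k=len(two_level_trajectories) + 1,
                   seed=0)


class TestBic:
    def test_hand_computed_toy(self):
        # 2 subjects, 5 obs each, constant centroids -> RSS by hand
        t1 = Trajectory(1, [1, 2, 3, 4, 5], [0.32, 0.28, 0.30, 0.31, 0.29])
        t2 = Trajectory(2, [1, 2, 3, 4, 5], [0.81, 0.79, 0.80, 0.82, 0.78])
        cents = [FakeCentroid(0.30, edf=1.0), FakeCentroid(0.80, edf=1.0)]
        model = ClusterModel(k=2, centroids=cents,
                             assignments=np.array([0, 1]),
                             subject_ids=[1, 2], within_mse=0.0,
                             per_cluster_mse=np.zeros(2))
        rss = (0.02**2 + 0.02**2 + 0.0 + 0.01**2 + 0.01**2) * 2
        n = 10
        p_eff = 1.0 + 1.0 + 2        # two edf + two variance terms
        expected = n * np.log(rss / n) + p_eff * np.log(n)
        assert bic(model, [t1, t2]) == pytest.approx(expected, abs=1e-9)

    def test_three_separated_levels_prefer_k3(self):
        trajs = make_constant_trajectories([0.2, 0.5, 0.8], n_per_level=10,
                                           seed=4)
        m2 = fit_em(trajs, 2, seed=0)
        m3 = fit_em(trajs, 3, seed=0)
        assert bic(m3, trajs) < bic(m2, trajs)


class TestSilhouette:
    def test_perfect_and_boundary_values(self):
        cents = [FakeCentroid(0.2), FakeCentroid(0.8)]
        on_own = Trajectory(1, [1, 2], [0.2, 0.2])
        midway = Trajectory(2, [1, 2], [0.5, 0.5])
        model = ClusterModel(k=2, centroids=cents,
                             assignments=np.array([0, 0]),
                             subject_ids=[1, 2], within_mse=0.0,
                             per_cluster_mse=np.zeros(2))
        mean_s, s = silhouette(model, [on_own, midway])
        assert s[0] == pytest.approx(1.0)
        assert s[1] == pytest.approx(0.0)

    def test_hand_computed_table(self):
        cents = [FakeCentroid(0.0), FakeCentroid(1.0)]
        t = Trajectory(1, [1.0], [0.25])    # a = 0.0625, b = 0.5625
        model = ClusterModel(k=2, centroids=cents,
                             assignments=np.array([0]), subject_ids=[1],
                             within_mse=0.0, per_cluster_mse=np.zeros(2))
        mean_s, _ = silhouette(model, [t])
        assert mean_s == pytest.approx((0.5625 - 0.0625) / 0.5625)

    def test_k1_undefined(self, two_level_trajectories):
        model = fit_em(two_level_trajectories, 1, seed=0)
        with pytest.raises(UndefinedMetricError):
            silhouette(model, two_level_trajectories)


class TestAdjustedRandIndex:
    def test_identical_partitions(self):
        assert adjusted_rand_index([0, 0, 1, 1], [0, 0, 1, 1]) == 1.0

    def test_label_permutation_invariance(self):
        assert adjusted_rand_index([0, 0, 1, 2], [2, 2, 0, 1]) == 1.0

    def test_hand_contingency_formula_on_eight_subjects(self):
        a = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        b = np.array([0, 0, 1, 1, 1, 1, 1, 0])
        # contingency: rows of a x cols of b = [[2,2],[1,3]]
        from math import comb
        sum_ij = sum(comb(n, 2) for n in (2, 2, 1, 3))
        sum_a = sum(comb(n, 2) for n in (4, 4))
        sum_b = sum(comb(n, 2) for n in (3, 5))
        n2 = comb(8, 2)
        expected_index = sum_a * sum_b / n2
        maximum = 0.5 * (sum_a + sum_b)
        hand = (sum_ij - expected_index) / (maximum - expected_index)
        assert adjusted_rand_index(a, b) == pytest.approx(hand, abs=1e-12)

    def test_subject_keyed_partitions_align_and_validate(self):
        import pandas as pd
        p1 = pd.Series([0, 1, 1], index=["a", "b", "c"])
        p2 = pd.Series([1, 0, 0], index=["c", "b", "a"])
        assert adjusted_rand_index(p1, p2) == pytest.approx(
            adjusted_rand_index([0, 1, 1], [0, 0, 1]))
        with pytest.raises(InvalidInputError):
            adjusted_rand_index(p1, pd.Series([0, 1], index=["a", "b"]))


class TestSelectK:
    def test_diagnostics_table_shape(self, two_level_trajectories):
        chosen, table, models = select_k(two_level_trajectories,
                                         k_range=range(2, 5), seeds_per_k=2)
        assert list(table["k"]) == [2, 3, 4]
        assert chosen in (2, 3, 4)
        assert set(models) == {2, 3, 4}

    def test_two_level_data_selects_two(self, two_level_trajectories):
        chosen, _, _ = select_k(two_level_trajectories, k_range=range(2, 5),
                                seeds_per_k=3)
        assert chosen == 2


class TestStability:
    def test_noiseless_separable_data_fully_stable(self, two_level_trajectories):
        rep = stability(two_level_trajectories, k=2, n_restarts=4, n_boot=4,
                        seed=0)
        assert np.allclose(np.diag(rep.restart_ari), 1.0)
        assert np.allclose(rep.restart_ari, 1.0)
        assert np.allclose(rep.bootstrap_ari, 1.0)
        assert rep.summary_ari == pytest.approx(1.0)


class TestLabelClusters:
    def _model(self, cents):
        return ClusterModel(k=len(cents), centroids=cents,
                            assignments=np.arange(len(cents)),
                            subject_ids=list(range(len(cents))),
                            within_mse=0.0,
                            per_cluster_mse=np.zeros(len(cents)))

    def test_expected_semantic_labels(self):
        ramp = FakeCentroid(lambda t: np.where(t >= 2, 0.58,
                                               0.85 - 0.135 * t))
        cents = [FakeCentroid(0.47), ramp, FakeCentroid(0.75)]
        labels = label_clusters(self._model(cents))
        assert labels == {0: "StableLow", 1: "AcceleratedProgression",
                          2: "PersistentlyHigh"}

    def test_invariant_to_cluster_permutation(self):
        ramp = FakeCentroid(lambda t: np.where(t >= 2, 0.58,
                                               0.85 - 0.135 * t))
        cents = [FakeCentroid(0.75), FakeCentroid(0.47), ramp]
        labels = label_clusters(self._model(cents))
        assert labels == {0: "PersistentlyHigh", 1: "StableLow",
                          2: "AcceleratedProgression"}

    def test_degenerate_identical_centroids_warn(self):
        cents = [FakeCentroid(0.5), FakeCentroid(0.5), FakeCentroid(0.5)]
        with pytest.warns(UserWarning, match="degenerate"):
            labels = label_clusters(self._model(cents))
        assert set(labels.values()) == set(
            ("StableLow", "AcceleratedProgression", "PersistentlyHigh"))

    def test_non_three_k_returns_indices(self, two_level_trajectories):
        model = fit_em(two_level_trajectories, 2, seed=0)
        assert label_clusters(model) == {0: 0, 1: 1}
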