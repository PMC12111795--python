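"""Temporally weighted clustering: weights, seeding, Lloyd loop, grading."""

import numpy as np
import pytest

from graincast.benchmarks import planted_blob_features
from graincast.exceptions import InfeasibleKError, ShapeError
from graincast.ksmeans import (
    KSmeans,
    apply_weights,
    assign_grade,
    build_feature,
    decay_weight,
    decay_weights,
    grade_clusters,
    init_centers_maximin,
    select_k,
)
from graincast.metrics import davies_bouldin, dunn, silhouette


class TestDecayWeight:
    def test_anchor_weight_is_one(self):
        for lam in (0.0, 0.5, 3.0):
            assert decay_weight(10, 10, lam) == 1.0

    def test_zero_lambda_flat(self):
        taus = np.arange(-5, 6)
        np.testing.assert_array_equal(decay_weight(taus, 0, 0.0), 1.0)

    def test_printed_formula_value(self):
        assert decay_weight(1, 0, 1.0) == pytest.approx(2.0 / (1.0 + np.e))

    def test_symmetric_decreasing_bounded(self):
        w = decay_weights(P=3, F=3, lam=0.7)
        np.testing.assert_allclose(w, w[::-1])
        assert (np.diff(w[3:]) < 0).all()
        assert ((w > 0) & (w <= 1)).all() and w[3] == 1.0

    def test_negative_lambda_rejected(self):
        with pytest.raises(ValueError):
            decay_weight(1, 0, -0.1)


class TestBuildFeature:
    def test_degenerate_window_is_current_row(self):
        x = np.array([[1.0, 2.0, 3.0]])
        np.testing.assert_array_equal(build_feature(x, [], P=0, F=0), x)

    def test_shape_arithmetic(self, rng):
        hist = rng.normal(size=(3, 3))
        fc = rng.normal(size=(1, 3))
        G = build_feature(hist, fc, P=2, F=1)
        assert G.shape == (4, 3)
        assert apply_weights(G, decay_weights(2, 1, 0.0)).shape == (12,)

    def test_column_equivariance(self, rng):
        hist, fc = rng.normal(size=(3, 3)), rng.normal(size=(2, 3))
        perm = [2, 0, 1]
        G = build_feature(hist, fc, P=2, F=2)
        G_perm = build_feature(hist[:, perm], fc[:, perm], P=2, F=2)
        np.testing.assert_array_equal(G_perm, G[:, perm])

    def test_missing_history_or_forecasts_error(self, rng):
        with pytest.raises(ShapeError):
            build_feature(rng.normal(size=(2, 3)), rng.normal(size=(1, 3)),
                          P=2, F=1)
        with pytest.raises(ShapeError):
            build_feature(rng.normal(size=(3, 3)), rng.normal(size=(2, 3)),
                          P=2, F=1)


class TestApplyWeights:
    def test_zero_lambda_identity(self, rng):
        G = rng.normal(size=(5, 3))
        np.testing.assert_array_equal(apply_weights(G, np.ones(5)), G.ravel())

    def test_large_lambda_keeps_only_anchor(self, rng):
        G = rng.normal(size=(4, 3))  # P=2, F=1: anchor is row 2
        w = decay_weights(2, 1, 50.0)
        flat = apply_weights(G, w)
        np.testing.assert_allclose(flat.reshape(4, 3)[[0, 1, 3]], 0.0,
                                   atol=1e-9)
        np.testing.assert_array_equal(flat.reshape(4, 3)[2], G[2])

    def test_row_scaling_hand_case(self):
        G = np.array([[1.0, 2.0], [3.0, 4.0]])
        w = np.array([1.0, 2.0 / (1.0 + np.e)])
        np.testing.assert_allclose(
            apply_weights(G, w),
            [1.0, 2.0, 3.0 * w[1], 4.0 * w[1]],
        )


class TestMaximinInit:
    def test_line_fixture(self):
        X = np.array([[0.0], [1.0], [10.0]])
        centers = init_centers_maximin(X, 2, seed=0)
        # mean 11/3: nearest point is 1; farthest from 1 is 10
        np.testing.assert_array_equal(centers, [[1.0], [10.0]])

    def test_k1_nearest_mean(self):
        X = np.array([[0.0], [4.0], [5.0]])
        np.testing.assert_array_equal(init_centers_maximin(X, 1, seed=0),
                                      [[4.0]])

    def test_k_equals_n_exhausts_points(self, rng):
        X = rng.normal(size=(6, 2))
        centers = init_centers_maximin(X, 6, seed=0)
        assert {tuple(c) for c in centers} == {tuple(p) for p in X}

    def test_infeasible_k(self):
        X = np.zeros((5, 2))
        with pytest.raises(InfeasibleKError):
            init_centers_maximin(X, 2, seed=0)


class TestFit:
    def test_separated_blobs_recovered(self):
        points, truth = planted_blob_features(2, seed=0, n_per_cluster=20,
                                              spread=0.1)
        model = KSmeans(k=2).fit(points)
        same = (model.labels_ == truth).mean()
        assert max(same, 1 - same) == 1.0  # up to label swap

    def test_k_equals_n_zero_wcss(self, rng):
        X = rng.normal(size=(8, 3))
        model = KSmeans(k=8).fit(X)
        assert model.wcss_history_[-1] == pytest.approx(0.0, abs=1e-18)

    @pytest.mark.parametrize("seed", range(5))
    def test_wcss_monotone_nonincreasing(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(60, 4))
        model = KSmeans(k=4).fit(X)
        wcss = np.array(model.wcss_history_)
        assert (np.diff(wcss) <= 1e-9).all()

    def test_deterministic_given_data(self, rng):
        X = rng.normal(size=(50, 3))
        a = KSmeans(k=3).fit(X)
        b = KSmeans(k=3).fit(X)
        np.testing.assert_array_equal(a.labels_, b.labels_)
        np.testing.assert_array_equal(a.centers_, b.centers_)


class TestLambdaLimits:
    """Decay-weight limits reduce K-Smeans to plain k-means variants."""

    def _features(self, seed, n=90):
        rng = np.random.default_rng(seed)
        centers = rng.normal(0, 8, (3, 3))
        G = np.stack([
            centers[i % 3] + rng.normal(0, 0.5, (4, 3))
            for i in range(n)
        ])  # (n, P+F+1=4, 3) with blob structure shared across rows
        return G

    def _plain_kmeans(self, X, k):
        return KSmeans(k=k, lam=0.0).fit(X)

    @pytest.mark.parametrize("seed", range(3))
    def test_lambda_zero_equals_plain_kmeans(self, seed):
        G = self._features(seed)
        w = decay_weights(2, 1, 0.0)
        weighted = np.array([apply_weights(g, w) for g in G])
        unweighted = G.reshape(len(G), -1)
        a = KSmeans(k=3).fit(weighted)
        b = self._plain_kmeans(unweighted, 3)
        np.testing.assert_array_equal(a.labels_, b.labels_)

    @pytest.mark.parametrize("seed", range(3))
    def test_lambda_large_uses_current_row_only(self, seed):
        G = self._features(seed)
        w = decay_weights(2, 1, 50.0)
        weighted = np.array([apply_weights(g, w) for g in G])
        current_only = G[:, 2, :]
        a = KSmeans(k=3).fit(weighted)
        b = self._plain_kmeans(current_only, 3)
        np.testing.assert_array_equal(a.labels_, b.labels_)


class TestSelectK:
    def test_recovers_seven_blobs(self):
        points, _ = planted_blob_features(7, seed=1)
        table, k = select_k(points, range(2, 11), seed=1)
        assert k == 7
        assert set(table.columns) == {"k", "silhouette", "davies_bouldin",
                                      "dunn"}

    def test_recovers_two_blobs(self):
        points, _ = planted_blob_features(2, seed=5)
        _, k = select_k(points, range(2, 7), seed=5)
        assert k == 2

    def test_table_matches_metrics_module(self, rng):
        X = rng.normal(size=(40, 3))
        table, _ = select_k(X, [2, 3], seed=0)
        for _, row in table.iterrows():
            model = KSmeans(k=int(row["k"]), seed=0).fit(X)
            assert row["silhouette"] == pytest.approx(
                silhouette(X, model.labels_))
            assert row["davies_bouldin"] == pytest.approx(
                davies_bouldin(X, model.labels_))
            assert row["dunn"] == pytest.approx(dunn(X, model.labels_))

    def test_empty_range_rejected(self, rng):
        with pytest.raises(ValueError):
            select_k(rng.normal(size=(10, 2)), [])


class TestGrading:
    def _fitted(self, seed=0, k=3):
        rng = np.random.default_rng(seed)
        # three germination bands: high / mid / low
        obs = np.concatenate([
            np.column_stack([rng.uniform(90, 99, 20),
                             rng.uniform(2, 9, 20),
                             rng.uniform(800, 812, 20)]),
            np.column_stack([rng.uniform(60, 80, 20),
                             rng.uniform(15, 32, 20),
                             rng.uniform(750, 790, 20)]),
            np.column_stack([rng.uniform(1, 45, 20),
                             rng.uniform(33, 52, 20),
                             rng.uniform(731, 749, 20)]),
        ])
        model = KSmeans(k=k).fit((obs - obs.mean(0)) / obs.std(0))
        return model, obs

    def test_partition_and_ordering(self):
        model, obs = self._fitted()
        names = ("germination", "fatty_acid", "density")
        table = grade_clusters(model, obs, names)
        assert table.counts["count"].sum() == len(obs)
        assert sorted(table.ranges["level"]) == [0, 1, 2]
        # grades ordered by descending germination
        g_mid = [
            obs[model.labels_ == c, 0].mean()
            for c in sorted(table.cluster_to_level,
                            key=table.cluster_to_level.get)
        ]
        assert (np.diff(g_mid) < 0).all()

    def test_disjoint_bands_give_disjoint_ranges(self):
        model, obs = self._fitted()
        table = grade_clusters(model, obs, ("germ", "fa", "bd"))
        lo = table.ranges.sort_values("level")
        for a, b in zip(lo["germ_min"].iloc[:-1], lo["germ_max"].iloc[1:]):
            assert a > b  # higher grade's minimum above next grade's maximum

    def test_single_cluster_table(self, rng):
        obs = rng.uniform(0, 1, (10, 3))
        model = KSmeans(k=1).fit(obs)
        table = grade_clusters(model, obs, ("a", "b", "c"))
        assert len(table.ranges) == 1
        assert table.ranges.loc[0, "a_min"] == obs[:, 0].min()
        assert table.ranges.loc[0, "a_max"] == obs[:, 0].max()

    def test_assign_grade_consistency(self):
        model, obs = self._fitted()
        table = grade_clusters(model, obs, ("g", "f", "b"))
        X = (obs - obs.mean(0)) / obs.std(0)
        for i in (0, 25, 50):
            expected = table.cluster_to_level[int(model.labels_[i])]
            assert assign_grade(X[i], model, table) == expected
        # the exact center maps to its own cluster's grade
        for c in range(model.k):
            assert assign_grade(model.centers_[c], model, table) == \
                table.cluster_to_level[c]

    def test_midpoint_tie_breaks_low_index(self):
        model = KSmeans(k=2)
        model.centers_ = np.array([[0.0], [2.0]])
        model.labels_ = np.array([0, 1])
        table = grade_clusters(model, np.array([[9.0, 1, 1], [5.0, 1, 1]]),
                               ("g", "f", "b"))
        assert assign_grade(np.array([1.0]), model, table) == \
            table.cluster_to_level[0]
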