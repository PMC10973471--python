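"""Z-score normalization, elbow-selected k-means, cluster profiles."""

import numpy as np
import pandas as pd
import pytest

import hybridcyc as h
from hybridcyc.errors import ModelIntegrityError, NormalizationError, ParameterError
from hybridcyc.phenotyping import compute_wcss, wcss_curve


def simplex_centers(k, d, sep):
    """k pairwise-equidistant centers at distance sep (regular simplex)."""
    P = np.eye(k) - np.ones((k, k)) / k
    U, S, _ = np.linalg.svd(P)
    pts = U[:, : k - 1] * S[: k - 1]
    pts = pts / np.linalg.norm(pts[0] - pts[1]) * sep
    out = np.zeros((k, d))
    out[:, : k - 1] = pts
    return out


def brute_min_wcss_k2(X):
    """Exhaustive 2-partition minimum of the within-cluster sum of squares."""
    n = len(X)
    best = np.inf
    for bits in range(1, 2 ** (n - 1)):
        mask = np.array([(bits >> i) & 1 for i in range(n)], dtype=bool)
        if mask.all() or (~mask).all():
            continue
        w = 0.0
        for m in (mask, ~mask):
            c = X[m].mean(axis=0)
            w += ((X[m] - c) ** 2).sum()
        best = min(best, w)
    return best


class TestZScore:
    def test_three_point_column_analytic(self):
        X = pd.DataFrame({"a": [1.0, 2.0, 3.0]})
        z = h.zscore_normalize(X)
        expected = np.array([-1.0, 0.0, 1.0]) * np.sqrt(1.5)
        assert np.allclose(z["a"], expected)

    def test_constant_column_zeroed_and_flagged(self):
        X = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [5.0, 5.0, 5.0]})
        norm = h.ZScoreNormalizer().fit(X)
        z = norm.transform(X)
        assert (z["b"] == 0).all()
        assert norm.zero_variance_columns_ == ["b"]

    def test_random_matrix_moments_by_direct_summation(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame(rng.lognormal(4, 1, size=(50, 14)))
        z = h.zscore_normalize(X).to_numpy()
        for j in range(14):
            s = 0.0
            for v in z[:, j]:
                s += v
            mean = s / 50
            ss = 0.0
            for v in z[:, j]:
                ss += (v - mean) ** 2
            assert abs(mean) < 1e-9
            assert abs((ss / 50) ** 0.5 - 1.0) < 1e-9

    def test_single_row_scope_raises(self):
        with pytest.raises(NormalizationError):
            h.zscore_normalize(pd.DataFrame({"a": [1.0]}))

    def test_median_imputation_of_missing_values(self):
        X = pd.DataFrame({"a": [1.0, np.nan, 3.0, 2.0]})
        z = h.ZScoreNormalizer(missing="median").fit(X).transform(X)
        assert np.isfinite(z["a"]).all()
        with pytest.raises(NormalizationError):
            h.ZScoreNormalizer(missing="error").fit(X)


class TestKMeans:
    def test_two_gap_clusters_exact_wcss(self):
        X = np.array([[0.0], [1.0], [10.0], [11.0]])
        model = h.kmeans_cluster(X, 2, seed=0)
        assert model.wcss == pytest.approx(1.0)
        assert model.assignments[0] == model.assignments[1]
        assert model.assignments[2] == model.assignments[3]
        assert model.assignments[0] != model.assignments[2]

    def test_k_equals_n_gives_zero_wcss(self):
        X = np.arange(10, dtype=float).reshape(5, 2)
        assert h.kmeans_cluster(X, 5, seed=0).wcss == pytest.approx(0.0)

    def test_small_instances_match_exhaustive_partition_minimum(self):
        rng = np.random.default_rng(0)
        for trial in range(10):
            X = rng.normal(size=(int(rng.integers(4, 9)), int(rng.integers(1, 4))))
            model = h.kmeans_cluster(X, 2, seed=trial, n_restarts=50)
            assert model.wcss == pytest.approx(brute_min_wcss_k2(X), rel=1e-9)

    def test_k_out_of_range_raises(self):
        X = np.zeros((3, 2))
        with pytest.raises(ParameterError):
            h.kmeans_cluster(X, 4, seed=0)
        with pytest.raises(ParameterError):
            h.kmeans_cluster(X, 0, seed=0)

    def test_wcss_matches_independent_recomputation(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(40, 3))
        model = h.kmeans_cluster(X, 3, seed=1)
        assert model.wcss == pytest.approx(
            compute_wcss(X, model.assignments, model.centroids), rel=1e-9
        )


class TestElbow:
    def test_stated_curve_selects_k2(self):
        curve = {1: 100.0, 2: 20.0, 3: 18.0, 4: 17.0, 5: 16.0}
        k = h.select_k_elbow(np.zeros((50, 2)), range(1, 6), curve=curve)
        assert k == 2

    def test_linear_decline_ties_resolve_to_smallest_interior_k(self):
        curve = {k: 100.0 - 10 * k for k in range(1, 6)}
        assert h.select_k_elbow(np.zeros((50, 2)), range(1, 6), curve=curve) == 2

    def test_short_k_range_raises(self):
        with pytest.raises(ParameterError):
            h.select_k_elbow(np.zeros((10, 2)), [1, 2])

    def test_nonconsecutive_k_range_raises(self):
        with pytest.raises(ParameterError):
            h.select_k_elbow(np.zeros((10, 2)), [1, 3, 5])

    def test_four_separated_blobs_recovered(self):
        rng = np.random.default_rng(1)
        centers = simplex_centers(4, 3, 12.0)
        X = np.concatenate([rng.normal(c, 1.0, size=(50, 3)) for c in centers])
        assert h.select_k_elbow(X, range(1, 9), seed=1) == 4

    def test_wcss_curve_non_increasing(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(60, 4))
        w = wcss_curve(X, range(1, 9), seed=0)
        vals = [w[k] for k in range(1, 9)]
        assert all(a >= b - 1e-9 for a, b in zip(vals, vals[1:]))


class TestProfiles:
    def test_single_cluster_profile_is_global_mean(self):
        rng = np.random.default_rng(4)
        X = pd.DataFrame(rng.normal(size=(20, 5)))
        model = h.kmeans_cluster(X.to_numpy(), 1, seed=0)
        prof, sizes = h.cluster_profiles(model, X)
        assert np.allclose(prof.iloc[0], X.mean(axis=0))
        assert sizes.iloc[0] == 20

    def test_singleton_clusters_profile_equal_rows(self):
        X = pd.DataFrame([[0.0, 0.0], [10.0, 10.0]], columns=["a", "b"])
        model = h.kmeans_cluster(X.to_numpy(), 2, seed=0)
        prof, _ = h.cluster_profiles(model, X)
        assert {tuple(r) for _, r in prof.iterrows()} == {(0.0, 0.0), (10.0, 10.0)}

    def test_labels_ordered_by_descending_size(self):
        X = pd.DataFrame(
            np.concatenate([np.zeros((30, 2)), np.full((10, 2), 8.0)]), columns=["a", "b"]
        )
        model = h.kmeans_cluster(X.to_numpy(), 2, seed=0, compartment="blood")
        prof, sizes = h.cluster_profiles(model, X)
        assert list(sizes.index) == ["B1", "B2"]
        assert sizes["B1"] == 30 and sizes["B2"] == 10

    def test_planted_subpop_profiles_within_tolerance(self):
        rng = np.random.default_rng(6)
        centers = simplex_centers(3, 6, 10.0)
        X = np.concatenate([rng.normal(c, 1.0, size=(200, 6)) for c in centers])
        Xz = h.zscore_normalize(pd.DataFrame(X))
        model = h.kmeans_cluster(Xz.to_numpy(), 3, seed=0)
        prof, _ = h.cluster_profiles(model, Xz)
        # each planted center (in z units) matched by some profile within 0.2 z
        centers_z = (centers - X.mean(axis=0)) / X.std(axis=0)
        for cz in centers_z:
            dists = np.abs(prof.to_numpy() - cz).max(axis=1)
            assert dists.min() < 0.2

    def test_misaligned_assignments_raise(self):
        X = pd.DataFrame(np.zeros((5, 2)))
        model = h.kmeans_cluster(np.zeros((4, 2)), 1, seed=0)
        with pytest.raises(ModelIntegrityError):
            h.cluster_profiles(model, X)


class TestHeatmapExport:
    def test_csv_columns_follow_cluster_blocks(self, tmp_path):
        X = pd.DataFrame(
            np.concatenate([np.zeros((3, 2)), np.full((2, 2), 9.0)]),
            columns=["m1", "m2"],
            index=[f"c{i}" for i in range(5)],
        )
        model = h.kmeans_cluster(X.to_numpy(), 2, seed=0)
        csv = tmp_path / "hm.csv"
        ordered = h.export_heatmap(X, model, png_path=None, csv_path=csv)
        big_first = [c for c in ordered.columns[:3]]
        assert {X.loc[c, "m1"] for c in big_first} == {0.0}

    def test_empty_set_warns_and_returns_none(self):
        X = pd.DataFrame(columns=["m1"])
        model = h.kmeans_cluster(np.zeros((2, 1)), 1, seed=0)
        with pytest.warns(UserWarning, match="empty"):
            assert h.export_heatmap(X, model) is None

    def test_csv_round_trip_reproduces_matrix_up_to_ordering(self, tmp_path):
        rng = np.random.default_rng(8)
        X = pd.DataFrame(
            rng.normal(size=(12, 4)),
            columns=list("abcd"),
            index=[f"c{i}" for i in range(12)],
        )
        model = h.kmeans_cluster(X.to_numpy(), 3, seed=0)
        csv = tmp_path / "hm.csv"
        h.export_heatmap(X, model, png_path=tmp_path / "hm.png", csv_path=csv)
        back = pd.read_csv(csv, index_col=0).T  # cells x markers
        assert np.allclose(back.sort_index().to_numpy(), X.sort_index().to_numpy())


class TestElbowKMeansEstimator:
    def test_fit_attributes_and_predict(self):
        rng = np.random.default_rng(9)
        centers = simplex_centers(3, 4, 12.0)
        X = np.concatenate([rng.normal(c, 1.0, size=(40, 4)) for c in centers])
        est = h.ElbowKMeans(k_range=range(1, 8), random_state=0).fit(X)
        assert est.k_ == 3
        assert est.cluster_centers_.shape == (3, 4)
        assert np.array_equal(est.predict(X), est.labels_)

    def test_sklearn_clone_compatible(self):
        from sklearn.base import clone

        est = h.ElbowKMeans(k=2, n_restarts=5)
        assert clone(est).get_params()["n_restarts"] == 5
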