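import itertools

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from yllburden.clustering import (
    classify_development,
    kmeans,
    select_k,
    standardize_features,
)
from yllburden.simulate import SimConfig, gen_socio


def planted_features(n=24, spread=(3.0, 0.3, 3.0), seed=0):
    cfg = SimConfig(n_locations=n, seed=seed, cluster_spread=spread)
    socio = gen_socio(cfg)
    return socio, socio[["pct_urban", "edu_years", "gdp_per_capita"]].to_numpy()


class TestStandardize:
    def test_output_has_zero_mean_unit_sample_sd(self):
        _, X = planted_features()
        z, means, sds = standardize_features(X)
        np.testing.assert_allclose(z.mean(axis=0), 0, atol=1e-12)
        np.testing.assert_allclose(z.std(axis=0, ddof=1), 1, atol=1e-12)

    def test_idempotent_on_standardized_input(self):
        _, X = planted_features()
        z, *_ = standardize_features(X)
        z2, *_ = standardize_features(z)
        np.testing.assert_allclose(z, z2, atol=1e-10)

    def test_two_locations_standardize_to_symmetric_pair(self):
        # n=2 with ddof=1: deviations +/- d/2, SD d/sqrt(2) -> z = +/- sqrt(1/2)
        z, *_ = standardize_features(np.array([[0.0, 10.0], [1.0, 30.0]]))
        np.testing.assert_allclose(np.abs(z), np.sqrt(0.5), atol=1e-12)

    def test_constant_feature_rejected(self):
        X = np.array([[1.0, 5.0], [2.0, 5.0], [3.0, 5.0]])
        with pytest.raises(ValueError, match="zero-variance"):
            standardize_features(X)


class TestKMeans:
    def test_single_cluster_center_is_mean(self):
        _, X = planted_features()
        z, *_ = standardize_features(X)
        res = kmeans(z, k=1, seed=0)
        np.testing.assert_allclose(res.centers[0], np.asarray(z).mean(axis=0), atol=1e-10)
        total_ss = float(((z - z.mean(axis=0)) ** 2).sum())
        assert res.inertia == pytest.approx(total_ss, rel=1e-10)

    def test_recovers_planted_clusters(self):
        socio, X = planted_features()
        z, *_ = standardize_features(X)
        res = kmeans(z, k=2, seed=0)
        assert adjusted_rand_score(socio["true_cluster"], res.labels) == 1.0

    def test_matches_exhaustive_two_partition_oracle(self):
        """Brute force over all 2-partitions of 6 points gives the same
        optimal within-cluster sum of squares as multi-start K-means."""
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(6, 2))

        def inertia_for(mask):
            out = 0.0
            for side in (mask, ~mask):
                if side.sum() == 0:
                    return np.inf
                c = pts[side].mean(axis=0)
                out += float(((pts[side] - c) ** 2).sum())
            return out

        best = min(
            inertia_for(np.array(m, dtype=bool))
            for m in itertools.product([0, 1], repeat=6)
            if 0 < sum(m) < 6
        )
        res = kmeans(pts, k=2, seed=1, n_init=50)
        assert res.inertia == pytest.approx(best, rel=1e-9)

    def test_inertia_non_increasing_in_k(self):
        _, X = planted_features()
        z, *_ = standardize_features(X)
        inertias = [kmeans(z, k, seed=0, n_init=10).inertia for k in range(1, 6)]
        assert all(a >= b - 1e-9 for a, b in zip(inertias, inertias[1:]))

    def test_relabeling_preserves_inertia(self):
        _, X = planted_features()
        z = np.asarray(standardize_features(X)[0])
        res = kmeans(z, k=3, seed=0)
        # recompute inertia from permuted labels: same partition, same value
        perm = {0: 2, 1: 0, 2: 1}
        relabeled = np.vectorize(perm.get)(res.labels)
        val = sum(
            float(((z[relabeled == c] - z[relabeled == c].mean(axis=0)) ** 2).sum())
            for c in range(3)
        )
        assert val == pytest.approx(res.inertia, rel=1e-9)

    def test_k_exceeding_distinct_points_rejected(self):
        pts = np.array([[0.0, 0.0], [0.0, 0.0], [1.0, 1.0]])
        with pytest.raises(ValueError, match="distinct"):
            kmeans(pts, k=3, seed=0)


class TestSelectK:
    def test_two_planted_clusters_select_two(self):
        _, X = planted_features()
        z, *_ = standardize_features(X)
        best, table = select_k(z, k_range=range(2, 8), seed=0)
        assert best == 2
        assert set(table.columns) >= {"silhouette", "calinski_harabasz", "davies_bouldin"}

    def test_three_planted_clusters_select_three(self):
        rng = np.random.default_rng(0)
        centers = np.array([[0, 0], [8, 0], [0, 8]])
        z = np.vstack([c + rng.normal(0, 0.4, size=(12, 2)) for c in centers])
        best, _ = select_k(z, k_range=range(2, 8), seed=0)
        assert best == 3

    def test_singleton_range_returned_without_voting(self):
        _, X = planted_features()
        z, *_ = standardize_features(X)
        best, _ = select_k(z, k_range=[2], seed=0)
        assert best == 2

    def test_out_of_bounds_range_rejected(self):
        _, X = planted_features(n=5)
        z, *_ = standardize_features(X)
        with pytest.raises(ValueError, match="k_range"):
            select_k(z, k_range=range(2, 9), seed=0)


class TestClassifyDevelopment:
    def test_higher_urban_cluster_labeled_hdr(self):
        socio, _ = planted_features()
        labeled = classify_development(socio, seed=0)
        assert labeled.attrs["cluster_k"] == 2
        hdr_urban = labeled.loc[labeled["development_level"] == "HDR", "pct_urban"].mean()
        ldr_urban = labeled.loc[labeled["development_level"] == "LDR", "pct_urban"].mean()
        assert hdr_urban > ldr_urban

    def test_labels_match_planted_clusters(self):
        socio, _ = planted_features()
        labeled = classify_development(socio, seed=0)
        mapped = (labeled["development_level"] == "LDR").astype(int)
        assert adjusted_rand_score(socio["true_cluster"], mapped) == 1.0
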