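import numpy as np
import pytest
from reference_impl import brute_force_dbscan

from declust import (
    ClusterLabeling,
    DBSCANParams,
    MetricSpec,
    count_outliers,
    dbscan,
    pairwise_distances,
)

ALL_METRICS = [
    MetricSpec("euclidean"),
    MetricSpec("cityblock"),
    MetricSpec("chebyshev"),
    MetricSpec("minkowski", p=0.5),
    MetricSpec("mahalanobis"),
]


class TestExamples:
    def test_coincident_points_form_one_cluster(self):
        D = np.zeros((5, 5))
        lab = dbscan(D, DBSCANParams(r=0.1, nmin=5))
        assert lab.labels.tolist() == [1] * 5
        assert count_outliers(lab) == 0

    def test_mutually_distant_points_are_all_noise(self):
        D = np.full((3, 3), 10.0)
        np.fill_diagonal(D, 0.0)
        lab = dbscan(D, DBSCANParams(r=1.0, nmin=2))
        assert lab.labels.tolist() == [-1, -1, -1]
        assert count_outliers(lab) == 3

    def test_two_blobs_and_an_isolated_point(self):
        rng = np.random.default_rng(0)
        blob1 = rng.uniform(0, 0.05, size=(6, 2))
        blob2 = blob1 + [5.0, 0.0]
        lone = np.array([[2.5, 5.0]])
        pts = np.vstack([blob1, blob2, lone])
        D = pairwise_distances(pts, MetricSpec("euclidean"))
        lab = dbscan(D, DBSCANParams(r=0.2, nmin=4))
        assert lab.labels.tolist() == [1] * 6 + [2] * 6 + [-1]
        ref_labels, ref_core = brute_force_dbscan(D.tolist(), 0.2, 4)
        assert lab.labels.tolist() == ref_labels
        assert count_outliers(lab) == 1

    def test_nmin_1_makes_every_point_core(self):
        D = np.full((4, 4), 10.0)
        np.fill_diagonal(D, 0.0)
        lab = dbscan(D, DBSCANParams(r=0.5, nmin=1))
        assert lab.core_flags.all()
        assert lab.labels.tolist() == [1, 2, 3, 4]  # four singleton clusters

    def test_border_point_joins_lowest_index_core(self):
        # hand-built distances: cores {0,1,2,3} and {5,6,7,8}; point 4 is a
        # border equidistant from core 3 and core 5 -> joins the lower index
        D = np.full((9, 9), 10.0)
        np.fill_diagonal(D, 0.0)
        for group in ([0, 1, 2, 3], [5, 6, 7, 8]):
            for i in group:
                for j in group:
                    if i != j:
                        D[i, j] = 1.0
        D[4, 3] = D[3, 4] = 1.0
        D[4, 5] = D[5, 4] = 1.0
        lab = dbscan(D, DBSCANParams(r=1.0, nmin=4))
        assert not lab.core_flags[4]
        assert lab.labels.tolist() == [1, 1, 1, 1, 1, 2, 2, 2, 2]
        ref_labels, ref_core = brute_force_dbscan(D.tolist(), 1.0, 4)
        assert lab.labels.tolist() == ref_labels and lab.core_flags.tolist() == ref_core


class TestOracleEquivalence:
    @pytest.mark.parametrize("spec", ALL_METRICS, ids=lambda s: f"{s.name}-p{s.p}")
    def test_matches_brute_force_on_random_instances(self, spec):
        """>=100 random instances across the five metrics: labels and core
        flags must match the literal enumeration + union-find reference."""
        rng = np.random.default_rng(123)
        for _ in range(25):  # 25 x 5 metrics = 125 instances
            n = int(rng.integers(5, 51))
            pts = rng.normal(0, 1, size=(n, 2)) * rng.uniform(0.3, 3.0)
            D = pairwise_distances(pts, spec)
            r = float(rng.uniform(0.05, 2.0))
            nmin = int(rng.integers(1, 8))
            lab = dbscan(D, DBSCANParams(r=r, nmin=nmin))
            ref_labels, ref_core = brute_force_dbscan(D.tolist(), r, nmin)
            assert lab.labels.tolist() == ref_labels
            assert lab.core_flags.tolist() == ref_core

    def test_core_and_noise_sets_match_sklearn(self):
        """Cross-check the core/noise split against scikit-learn's DBSCAN
        (border assignment is order-dependent there, so only the sets are
        compared)."""
        from sklearn.cluster import DBSCAN as SkDBSCAN

        rng = np.random.default_rng(5)
        for _ in range(20):
            n = int(rng.integers(10, 60))
            pts = rng.normal(size=(n, 2))
            D = pairwise_distances(pts, MetricSpec("euclidean"))
            r = float(rng.uniform(0.1, 1.5))
            nmin = int(rng.integers(2, 8))
            lab = dbscan(D, DBSCANParams(r=r, nmin=nmin))
            sk = SkDBSCAN(eps=r, min_samples=nmin, metric="precomputed").fit(D)
            assert set(np.flatnonzero(lab.core_flags)) == set(sk.core_sample_indices_)
            assert set(lab.noise_points()) == set(np.flatnonzero(sk.labels_ == -1))


class TestProperties:
    def _random_D(self, rng, n=40):
        pts = rng.normal(0, 1, size=(n, 2))
        return pairwise_distances(pts, MetricSpec("euclidean"))

    def test_noise_shrinks_as_r_grows(self):
        """Doubling the radius can only shed noise points: the noise set at
        the larger radius is a subset of the smaller-radius noise set."""
        rng = np.random.default_rng(21)
        for _ in range(20):
            D = self._random_D(rng)
            nmin = int(rng.integers(2, 8))
            r1 = float(rng.uniform(0.1, 0.8))
            noise1 = set(dbscan(D, DBSCANParams(r=r1, nmin=nmin)).noise_points())
            noise2 = set(dbscan(D, DBSCANParams(r=2 * r1, nmin=nmin)).noise_points())
            assert noise2 <= noise1

    def test_noise_count_grows_with_nmin(self):
        rng = np.random.default_rng(22)
        for _ in range(20):
            D = self._random_D(rng)
            r = float(rng.uniform(0.2, 1.0))
            counts = [
                count_outliers(dbscan(D, DBSCANParams(r=r, nmin=nmin)))
                for nmin in (2, 5, 10, 20)
            ]
            assert counts == sorted(counts)

    def test_labels_only_noise_or_contiguous_positive(self):
        rng = np.random.default_rng(23)
        for _ in range(10):
            D = self._random_D(rng, n=30)
            lab = dbscan(D, DBSCANParams(r=float(rng.uniform(0.1, 1.0)), nmin=3))
            got = set(lab.labels.tolist())
            k = lab.n_clusters
            assert got <= ({-1} | set(range(1, k + 1)))
            assert set(range(1, k + 1)) <= got

    def test_permutation_consistency(self):
        """Relabelling points by a permutation permutes labels up to cluster
        renaming; core flags permute exactly."""
        rng = np.random.default_rng(24)
        for _ in range(10):
            n = 35
            D = self._random_D(rng, n=n)
            params = DBSCANParams(r=float(rng.uniform(0.2, 0.8)), nmin=4)
            lab = dbscan(D, params)
            perm = rng.permutation(n)
            lab_p = dbscan(D[np.ix_(perm, perm)], params)
            np.testing.assert_array_equal(lab_p.core_flags, lab.core_flags[perm])
            # noise is exactly preserved; clusters agree as partitions of cores
            np.testing.assert_array_equal(lab_p.labels == -1, (lab.labels == -1)[perm])
            for k in range(1, lab.n_clusters + 1):
                members = np.flatnonzero((lab.labels[perm] == k) & lab.core_flags[perm])
                if members.size:
                    assert len(set(lab_p.labels[members])) == 1


class TestValidation:
    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            DBSCANParams(r=0.0, nmin=5)
        with pytest.raises(ValueError):
            DBSCANParams(r=1.0, nmin=0)

    def test_asymmetric_matrix_rejected(self):
        D = np.array([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            dbscan(D, DBSCANParams(r=1.0, nmin=1))

    def test_count_outliers_extremes(self):
        all_noise = ClusterLabeling(labels=np.full(7, -1), core_flags=np.zeros(7, bool))
        assert count_outliers(all_noise) == 7
        one_cluster = ClusterLabeling(labels=np.ones(5, int), core_flags=np.ones(5, bool))
        assert count_outliers(one_cluster) == 0
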