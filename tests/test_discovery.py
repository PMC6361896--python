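"""Balanced bootstraps, Ward/AC, Gap statistic, meta-clustering, stability."""

import numpy as np
import pytest
from scipy.cluster.hierarchy import linkage
from sklearn.metrics import adjusted_rand_score

from histotda.discovery import (agglomerative_coefficient, balanced_bootstrap,
                                composition_vector, gap_statistic,
                                jaccard_stability, meta_cluster, pca_project,
                                representative_bootstrap, ward_cluster)


class TestBalancedBootstrap:
    def test_study_scale_contract(self):
        labels = np.array(["G3"] * 2567 + ["G4"] * 2351 + ["G5"] * 264)
        boots = balanced_bootstrap(labels, n_bootstraps=100, seed=0)
        assert len(boots) == 100
        for bs in boots:
            assert all(len(idx) == 264 for idx in bs.indices.values())
            assert len(bs.all_indices) == 792

    def test_no_duplicates_within_bootstrap(self):
        labels = np.array(["G3"] * 30 + ["G4"] * 20 + ["G5"] * 10)
        for bs in balanced_bootstrap(labels, 20, seed=1):
            assert len(np.unique(bs.all_indices)) == 30  # 3 classes x n_min=10

    def test_equal_classes_give_full_permutations(self):
        labels = np.array(["G3"] * 8 + ["G4"] * 8 + ["G5"] * 8)
        for bs in balanced_bootstrap(labels, 5, seed=2):
            assert sorted(bs.all_indices) == list(range(24))

    def test_smallest_class_held_fixed_by_default(self):
        labels = np.array(["G3"] * 30 + ["G5"] * 5)
        boots = balanced_bootstrap(labels, 10, seed=3)
        g5 = np.flatnonzero(labels == "G5")
        for bs in boots:
            assert np.array_equal(bs.indices["G5"], g5)

    def test_deterministic_per_seed(self):
        labels = np.array(["G3"] * 30 + ["G4"] * 20 + ["G5"] * 10)
        a = balanced_bootstrap(labels, 5, seed=7)
        b = balanced_bootstrap(labels, 5, seed=7)
        for x, y in zip(a, b):
            assert np.array_equal(x.all_indices, y.all_indices)

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError):
            balanced_bootstrap(np.array([]), 5)


class TestPca:
    def test_planar_data_has_two_components(self, rng):
        basis = rng.normal(size=(2, 10))
        x = rng.normal(size=(50, 2)) @ basis
        _, evr = pca_project(x, 6)
        assert evr[2:] == pytest.approx(0.0, abs=1e-12)

    def test_rotation_invariant_spectrum(self, rng):
        x = rng.normal(size=(40, 6)) * np.arange(1, 7)
        q, _ = np.linalg.qr(rng.normal(size=(6, 6)))
        _, e1 = pca_project(x, 6)
        _, e2 = pca_project(x @ q, 6)
        assert np.allclose(e1, e2)

    def test_scores_covariance_is_diagonal_eigenvalues(self, rng):
        x = rng.normal(size=(60, 8))
        scores, _ = pca_project(x, 6)
        cov = scores.T @ scores / (len(x) - 1)
        # brute-force eigenvalues of the sample covariance
        evals = np.sort(np.linalg.eigvalsh(np.cov(x.T)))[::-1][:6]
        assert np.allclose(cov, np.diag(np.diag(cov)), atol=1e-8)
        assert np.allclose(np.diag(cov), evals)

    def test_constant_matrix_rejected(self):
        with pytest.raises(ValueError):
            pca_project(np.ones((10, 4)), 2)

    def test_low_variance_warns(self, rng):
        x = rng.normal(size=(50, 40))  # isotropic: 6 PCs explain far < 99%
        with pytest.warns(UserWarning, match="variance"):
            pca_project(x, 6)


class TestWardAndAc:
    def test_separated_pairs_grouped(self):
        x = np.array([[0, 0], [0.1, 0], [10, 10], [10.1, 10]])
        a = ward_cluster(x, 2)
        assert a.labels[0] == a.labels[1] != a.labels[2] == a.labels[3]

    def test_duplicate_points_contribute_unit_ac(self):
        x = np.array([[0.0, 0], [0.0, 0], [5, 5], [9, 9]])
        a = ward_cluster(x, 2)
        z, n = a.linkage_matrix, 4
        final = z[-1, 2]
        # the two duplicates first merge at height 0 -> contribution 1 each
        assert agglomerative_coefficient(z, n) >= 0.5

    def test_tight_blobs_ac_above_099(self, rng):
        x = np.vstack([rng.normal(c, 0.01, (15, 2))
                       for c in [(0, 0), (10, 0), (0, 10)]])
        assert ward_cluster(x, 3).ac > 0.99

    def test_ac_matches_direct_formula(self, rng):
        x = rng.normal(size=(12, 3))
        z = linkage(x, method="ward")
        first = np.empty(12)
        for a, b, h in zip(z[:, 0].astype(int), z[:, 1].astype(int), z[:, 2]):
            if a < 12:
                first[a] = h
            if b < 12:
                first[b] = h
        expect = np.mean(1 - first / z[-1, 2])
        assert agglomerative_coefficient(z, 12) == pytest.approx(expect)

    def test_invalid_k(self, rng):
        with pytest.raises(ValueError):
            ward_cluster(rng.normal(size=(5, 2)), 0)
        with pytest.raises(ValueError):
            ward_cluster(rng.normal(size=(5, 2)), 6)


class TestGapStatistic:
    def test_three_blobs_one_se_selects_three(self, rng):
        x = np.vstack([rng.normal(c, 1.0, (20, 2))
                       for c in [(0, 0), (10, 0), (0, 10)]])
        g = gap_statistic(x, range(1, 7), b_ref=50, rule="one_se", seed=4)
        assert g.chosen_k == 3

    def test_single_blob_selects_one(self, rng):
        x = rng.normal(size=(50, 2))
        g = gap_statistic(x, range(1, 7), b_ref=50, rule="one_se", seed=5)
        assert g.chosen_k == 1

    def test_s_k_definition(self, rng):
        x = rng.normal(size=(30, 2))
        g = gap_statistic(x, range(1, 5), b_ref=25, rule="max_mean", seed=6)
        assert np.allclose(g.s_k, g.sd * np.sqrt(1 + 1 / 25))

    def test_degenerate_points_rejected(self):
        with pytest.raises(ValueError):
            gap_statistic(np.ones((20, 2)), range(1, 4), b_ref=10)

    def test_requires_enough_references(self, rng):
        with pytest.raises(ValueError):
            gap_statistic(rng.normal(size=(20, 2)), range(1, 4), b_ref=5)


class TestComposition:
    def test_single_cluster_holds_class_totals(self):
        labels = np.array(["G3"] * 5 + ["G4"] * 3 + ["G5"] * 2)
        comp = composition_vector(np.ones(10, dtype=int), labels)
        assert comp.tolist() == [[5, 3, 2]]

    def test_per_coordinate_conservation(self, rng):
        labels = np.array(["G3"] * 8 + ["G4"] * 8 + ["G5"] * 8)
        assign = rng.integers(1, 4, 24)
        comp = composition_vector(assign, labels)
        assert comp.sum(axis=0).tolist() == [8, 8, 8]

    def test_matches_brute_force_tally(self, rng):
        labels = rng.choice(["G3", "G4", "G5"], 40)
        assign = rng.integers(1, 5, 40)
        comp = composition_vector(assign, labels)
        for j in range(4):
            for li, lab in enumerate(("G3", "G4", "G5")):
                assert comp[j, li] == np.sum((assign == j + 1) & (labels == lab))


ARCHETYPES = np.array([[200, 30, 20], [30, 200, 30], [20, 30, 200],
                       [120, 120, 10], [10, 120, 120], [80, 80, 80]], float)


class TestMetaCluster:
    def planted(self, rng, per=40, noise=5.0):
        vecs = np.vstack([a + rng.normal(0, noise, (per, 3)) for a in ARCHETYPES])
        truth = np.repeat(np.arange(6), per)
        return vecs, truth

    def test_identical_vectors_centroid_equals_them(self):
        vecs = np.tile([10.0, 5.0, 1.0], (8, 1))
        meta = meta_cluster(vecs, k=1)
        assert np.allclose(meta.centroids[0], [10, 5, 1])

    def test_recovers_planted_archetypes(self, rng):
        vecs, truth = self.planted(rng)
        meta = meta_cluster(vecs, k_range=range(1, 11), b_ref=50, seed=1)
        assert meta.k == 6
        assert adjusted_rand_score(truth, meta.assignment) >= 0.9

    def test_centroids_equal_member_means(self, rng):
        vecs, _ = self.planted(rng)
        meta = meta_cluster(vecs, k=6, seed=2)
        for j in range(1, 7):
            members = vecs[meta.assignment == j]
            assert np.allclose(meta.centroids[j - 1], members.mean(axis=0))

    def test_clusters_ordered_g3_heavy_first(self, rng):
        vecs, _ = self.planted(rng)
        meta = meta_cluster(vecs, k=6, seed=3)
        grades = meta.centroids @ [3, 4, 5] / meta.centroids.sum(axis=1)
        assert (np.diff(grades) >= -1e-9).all()

    def test_fewer_vectors_than_k_rejected(self):
        with pytest.raises(ValueError):
            meta_cluster(np.ones((3, 3)) + np.arange(3)[:, None], k=5)


class TestRepresentativeAndJaccard:
    def test_exact_centroid_bootstrap_selected(self, rng):
        vecs, _ = TestMetaCluster().planted(rng, per=10, noise=3.0)
        meta = meta_cluster(vecs, k=6, seed=4)
        # append one bootstrap sitting exactly on the centroids
        exact = meta.centroids.copy()
        vecs2 = np.vstack([vecs, exact])
        ids = np.concatenate([np.repeat(np.arange(10), 6), np.full(6, 99)])
        meta2 = meta_cluster(vecs2, ids, k=6, seed=4)
        assert representative_bootstrap(meta2) == 99

    def test_argmin_matches_exhaustive_scan(self, rng):
        vecs, _ = TestMetaCluster().planted(rng, per=12)
        ids = rng.integers(0, 4, len(vecs))
        meta = meta_cluster(vecs, ids, k=6, seed=5)
        dists = np.linalg.norm(meta.vectors
                               - meta.centroids[meta.assignment - 1], axis=1)
        best, best_total = None, np.inf
        for b in sorted(set(ids.tolist())):
            total = dists[meta.bootstrap_ids == b].sum()
            if total < best_total - 1e-12:
                best, best_total = b, total
        assert representative_bootstrap(meta) == best

    def test_single_bootstrap_is_itself(self, rng):
        vecs, _ = TestMetaCluster().planted(rng, per=2)
        meta = meta_cluster(vecs, np.full(len(vecs), 42), k=6, seed=6)
        assert representative_bootstrap(meta) == 42

    def test_separated_clusters_are_stable(self, rng):
        vecs, _ = TestMetaCluster().planted(rng, per=30, noise=2.0)
        meta = meta_cluster(vecs, k=6, seed=7)
        jac = jaccard_stability(meta, n_resamples=100, seed=8)
        assert (jac >= 0.95).all()

    def test_jaccard_bounded_in_unit_interval(self, rng):
        vecs = rng.uniform(0, 100, (60, 3))
        meta = meta_cluster(vecs, k=4, seed=9)
        jac = jaccard_stability(meta, n_resamples=50, seed=10)
        assert ((jac >= 0) & (jac <= 1)).all()
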