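"""Clustering: FCM updates and fixed point, spectral labels, prototype-based
soft memberships, subject averaging, and validity indices."""

import itertools

import numpy as np
import pytest
from sklearn.metrics.pairwise import rbf_kernel

from eegpheno.cluster import (
    average_subject_membership,
    fcm_fit,
    hard_assign,
    inertia,
    match_labels,
    prototypes_from_labels,
    soft_membership_from_distance,
    spectral_fit,
    suggest_elbow,
    validity_scan,
)


class TestFCM:
    def test_separated_blobs_near_hard_memberships(self, blobs):
        X, labels = blobs
        model = fcm_fit(X, 2, seed=0)
        aligned = match_labels(labels, model.hard_labels)
        np.testing.assert_array_equal(aligned, labels)
        assert model.memberships.max(axis=1).min() > 0.99

    def test_fixed_point_oracle(self, blobs):
        """Final memberships equal re-computation from final centers via the
        update formula."""
        X, _ = blobs
        model = fcm_fit(X, 2, m=1.7, seed=1)
        d2 = ((X[:, None, :] - model.prototypes[None]) ** 2).sum(axis=2)
        m = model.params["m"]
        inv = d2 ** (-1.0 / (m - 1.0))
        expected = inv / inv.sum(axis=1, keepdims=True)
        np.testing.assert_allclose(model.memberships, expected, atol=1e-6)

    def test_large_m_uniformizes_memberships(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(30, 4))
        model = fcm_fit(X, 3, m=10.0, seed=0)
        assert np.abs(model.memberships - 1.0 / 3).max() < 0.05

    def test_objective_non_increasing(self, blobs):
        X, _ = blobs
        model = fcm_fit(X, 2, seed=3)
        diffs = np.diff(model.objective_trace)
        assert (diffs <= 1e-9).all()

    def test_membership_rows_stochastic(self, blobs):
        X, _ = blobs
        model = fcm_fit(X, 3, seed=4)
        np.testing.assert_allclose(model.memberships.sum(axis=1), 1.0, atol=1e-9)
        assert ((model.memberships >= 0) & (model.memberships <= 1)).all()

    def test_sample_on_center_singularity(self):
        X = np.array([[0.0, 0.0], [0.0, 0.0], [5.0, 5.0], [5.0, 5.0]])
        model = fcm_fit(X, 2, seed=0)
        assert model.memberships.max(axis=1).min() == 1.0

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            fcm_fit(np.zeros((2, 3)), 4)


class TestSpectral:
    def test_separated_blobs_perfect_split(self, blobs):
        X, labels = blobs
        pred = spectral_fit(X, 2, seed=0)
        assert (match_labels(labels, pred) == labels).all()

    def test_row_permutation_invariance(self, blobs):
        X, _ = blobs
        rng = np.random.default_rng(5)
        perm = rng.permutation(len(X))
        a = spectral_fit(X, 2, seed=0)
        b = spectral_fit(X[perm], 2, seed=0)
        aligned = match_labels(a[perm], b)
        assert (aligned == a[perm]).all()

    def test_agrees_with_brute_force_normalized_cut(self):
        """On <= 12 points the spectral 2-way split matches the partition
        minimizing the normalized cut of the same RBF affinity graph."""
        rng = np.random.default_rng(6)
        X = np.vstack([rng.normal(0, 0.3, (5, 2)), rng.normal(4, 0.3, (6, 2))])
        A = rbf_kernel(X, gamma=1.0 / 2)
        np.fill_diagonal(A, 0.0)
        n = len(X)
        best, best_cut = None, np.inf
        for bits in itertools.product([0, 1], repeat=n - 1):
            part = np.array((0,) + bits)
            if part.min() == part.max():
                continue
            cut = A[part == 0][:, part == 1].sum()
            vol0 = A[part == 0].sum()
            vol1 = A[part == 1].sum()
            ncut = cut / vol0 + cut / vol1
            if ncut < best_cut:
                best_cut, best = ncut, part
        pred = spectral_fit(X, 2, seed=0)
        aligned = match_labels(best + 1, pred)
        assert (aligned == best + 1).all()


class TestPrototypesAndMemberships:
    def test_one_point_per_cluster(self):
        X = np.array([[1.0, 0.0], [0.0, 2.0]])
        protos = prototypes_from_labels(X, np.array([1, 2]))
        np.testing.assert_array_equal(protos, X)

    def test_two_cluster_means_by_hand(self):
        X = np.array([[0.0, 0.0], [2.0, 0.0], [10.0, 10.0], [10.0, 14.0]])
        protos = prototypes_from_labels(X, np.array([1, 1, 2, 2]))
        np.testing.assert_allclose(protos, [[1.0, 0.0], [10.0, 12.0]])

    def test_duplicated_dataset_same_prototypes(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(10, 3))
        labels = np.array([1, 2] * 5)
        a = prototypes_from_labels(X, labels)
        b = prototypes_from_labels(np.vstack([X, X]), np.tile(labels, 2))
        np.testing.assert_allclose(a, b)

    def test_empty_cluster_is_error(self):
        with pytest.raises(ValueError, match="empty"):
            prototypes_from_labels(np.zeros((3, 2)), np.array([1, 1, 3]))

    def test_equidistant_point_uniform_membership(self):
        protos = np.array([[1.0, 0.0], [-1.0, 0.0], [0.0, 1.0], [0.0, -1.0]])
        u = soft_membership_from_distance(np.zeros((1, 2)), protos)
        np.testing.assert_allclose(u, 0.25)

    def test_point_on_prototype_gets_unit_membership(self):
        protos = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 0.0], [3.0, 3.0]])
        u = soft_membership_from_distance(protos[[1]], protos)
        np.testing.assert_array_equal(u, [[0.0, 1.0, 0.0, 0.0]])

    def test_inverse_distance_formula_by_hand(self):
        # distances 1 and 2 -> memberships (2/3, 1/3)
        protos = np.array([[1.0], [-2.0]])
        u = soft_membership_from_distance(np.array([[0.0]]), protos)
        np.testing.assert_allclose(u, [[2 / 3, 1 / 3]])

    def test_membership_rows_stochastic(self):
        rng = np.random.default_rng(8)
        u = soft_membership_from_distance(rng.normal(size=(20, 5)),
                                          rng.normal(size=(3, 5)))
        np.testing.assert_allclose(u.sum(axis=1), 1.0, atol=1e-9)


class TestSubjectAveraging:
    def test_identical_sessions_unchanged(self):
        u = np.tile([0.2, 0.8], (4, 1))
        out = average_subject_membership(u, ["A"] * 4)
        np.testing.assert_allclose(out[0].membership, [0.2, 0.8])

    def test_opposite_sessions_average(self):
        u = np.array([[1.0, 0.0], [0.0, 1.0]])
        out = average_subject_membership(u, ["A", "A"])
        np.testing.assert_allclose(out[0].membership, [0.5, 0.5])

    def test_mean_matches_brute_force(self):
        rng = np.random.default_rng(9)
        u = rng.dirichlet(np.ones(4), size=8)
        ids = ["A", "B", "A", "B", "A", "B", "A", "B"]
        out = {sm.subject_id: sm.membership for sm in
               average_subject_membership(u, ids)}
        np.testing.assert_allclose(out["A"], u[::2].mean(axis=0))
        np.testing.assert_allclose(out["B"], u[1::2].mean(axis=0))
        for sm_id in ("A", "B"):
            assert abs(out[sm_id].sum() - 1.0) < 1e-9

    def test_mismatched_ids_error(self):
        with pytest.raises(ValueError):
            average_subject_membership(np.ones((3, 2)) / 2, ["A", "B"])


class TestHardAssign:
    def test_worked_example(self):
        assert hard_assign(np.array([0.2, 0.3, 0.4, 0.1])) == 3

    def test_unit_membership(self):
        assert hard_assign(np.array([1.0, 0.0])) == 1

    def test_tie_breaks_low(self):
        assert hard_assign(np.array([0.5, 0.5])) == 1

    def test_empty_error(self):
        with pytest.raises(ValueError):
            hard_assign(np.array([]))


class TestValidity:
    def test_separated_blobs_silhouette_near_one(self, blobs):
        X, _ = blobs
        report = validity_scan(X, ("fcm",), k_range=range(2, 3), seed=0)
        assert report.loc[0, "silhouette"] > 0.9

    def test_silhouette_matches_brute_force(self):
        """O(N^2) pairwise silhouette on N=60 equals the library value used
        by the scan."""
        from sklearn.metrics import silhouette_score

        rng = np.random.default_rng(10)
        X = np.vstack([rng.normal(0, 1, (30, 4)), rng.normal(4, 1, (30, 4))])
        labels = np.array([1] * 30 + [2] * 30)
        d = np.sqrt(((X[:, None] - X[None]) ** 2).sum(-1))
        svals = []
        for i in range(len(X)):
            same = (labels == labels[i]) & (np.arange(len(X)) != i)
            a = d[i, same].mean()
            b = min(d[i, labels == c].mean() for c in set(labels) - {labels[i]})
            svals.append((b - a) / max(a, b))
        assert abs(np.mean(svals) - silhouette_score(X, labels)) < 1e-12

    def test_inertia_non_increasing_in_k(self):
        rng = np.random.default_rng(11)
        X = np.vstack([rng.normal(i * 4, 0.5, (15, 3)) for i in range(4)])
        vals = []
        for k in range(2, 7):
            model = fcm_fit(X, k, seed=0)
            vals.append(inertia(X, model.prototypes, model.hard_labels))
        assert all(b <= a * 1.01 for a, b in zip(vals, vals[1:]))

    def test_scan_covers_grid(self, blobs):
        X, _ = blobs
        report = validity_scan(X, ("fcm", "spectral"), k_range=range(2, 5), seed=0)
        assert len(report) == 6
        assert {"silhouette", "davies_bouldin", "calinski_harabasz",
                "bic", "inertia"} <= set(report.columns)
        assert report["inertia"].ge(0).all()

    def test_elbow_on_synthetic_curve(self):
        ks = np.arange(2, 7)
        scores = np.array([100.0, 40.0, 12.0, 10.0, 9.0])
        assert suggest_elbow(ks, scores) == 4
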