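"""Spectral clustering primitives against closed forms and independent oracles."""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from vegrisk.errors import DomainError
from vegrisk.model import LeadRiskModel
from vegrisk.spectral import (
    calinski_harabasz,
    grid_search,
    kmeans,
    normalized_laplacian,
    rbf_affinity,
    spectral_cluster,
    spectral_embed,
    standardize_features,
)
from vegrisk.synthetic import ScenarioConfig


def _two_block_affinity(n1=4, n2=3):
    """Ideal disconnected affinity: two complete blocks, zero between."""
    n = n1 + n2
    A = np.zeros((n, n))
    A[:n1, :n1] = 1.0
    A[n1:, n1:] = 1.0
    return A


def _ari(a, b):
    from sklearn.metrics import adjusted_rand_score

    return adjusted_rand_score(a, b)


class TestStandardize:
    def test_closed_form_column(self):
        Z = standardize_features(np.array([[1.0], [2.0], [3.0]]))
        assert Z[:, 0] == pytest.approx([-1.224744871, 0.0, 1.224744871])

    def test_constant_column_passes_through_centered(self, caplog):
        X = np.array([[1.0, 5.0], [2.0, 5.0], [3.0, 5.0]])
        with caplog.at_level("WARNING"):
            Z = standardize_features(X)
        assert np.allclose(Z[:, 1], 0.0)

    def test_single_row_rejected(self):
        with pytest.raises(DomainError):
            standardize_features(np.array([[1.0, 2.0]]))

    def test_random_matrix_moments(self, rng):
        Z = standardize_features(rng.normal(size=(40, 3)) * [1, 10, 100])
        assert np.abs(Z.mean(axis=0)).max() < 1e-12
        assert np.abs(Z.var(axis=0) - 1).max() < 1e-12


class TestAffinityAndLaplacian:
    def test_identical_rows_have_unit_affinity(self):
        Z = np.array([[1.0, 2.0], [1.0, 2.0], [0.0, 0.0]])
        A = rbf_affinity(Z, 3.0)
        assert A[0, 1] == pytest.approx(1.0)
        assert np.allclose(np.diag(A), 1.0)

    def test_unit_distance_closed_form(self):
        Z = np.array([[0.0], [1.0]])
        assert rbf_affinity(Z, 1.0)[0, 1] == pytest.approx(np.exp(-1))

    def test_nonpositive_parameter_rejected(self):
        with pytest.raises(DomainError):
            rbf_affinity(np.zeros((3, 2)), 0.0)

    def test_disconnected_blocks_give_zero_eigenvalue_multiplicity_two(self):
        L = normalized_laplacian(_two_block_affinity())
        eigvals = np.linalg.eigvalsh(L)
        assert np.sum(np.abs(eigvals) < 1e-10) == 2

    def test_complete_triangle_spectrum(self):
        # equal off-diagonal affinities: eigenvalues {0, 3/2, 3/2}
        A = np.full((3, 3), 0.7)
        np.fill_diagonal(A, 1.0)
        eigvals = np.linalg.eigvalsh(normalized_laplacian(A))
        assert eigvals == pytest.approx([0.0, 1.5, 1.5], abs=1e-12)

    def test_zero_degree_row_rejected(self):
        A = np.eye(3)
        with pytest.raises(DomainError, match="degree"):
            normalized_laplacian(A)

    @given(
        hnp.arrays(
            np.float64,
            (8, 2),
            elements=st.floats(-3, 3, allow_nan=False),
        )
    )
    @settings(max_examples=30, deadline=None)
    def test_symmetry_and_eigenvalue_range(self, Z):
        A = rbf_affinity(Z, 2.0)
        assert np.abs(A - A.T).max() == 0.0
        L = normalized_laplacian(A)
        assert np.abs(L - L.T).max() == 0.0
        eigvals = np.linalg.eigvalsh(L)
        assert eigvals.min() > -1e-10
        assert eigvals.max() < 2 + 1e-10


class TestEmbedding:
    def test_block_constant_rows_for_ideal_blocks(self):
        A = _two_block_affinity(5, 4)
        E = spectral_embed(normalized_laplacian(A), 2)
        # rows within a block identical; across blocks distinct
        assert np.allclose(E[:5], E[0], atol=1e-8)
        assert np.allclose(E[5:], E[5], atol=1e-8)
        assert np.linalg.norm(E[0] - E[5]) > 0.5

    def test_rows_unit_norm(self, rng):
        A = rbf_affinity(rng.normal(size=(12, 3)), 1.0)
        E = spectral_embed(normalized_laplacian(A), 3)
        assert np.linalg.norm(E, axis=1) == pytest.approx(np.ones(12))

    def test_matches_dense_eigensolver(self, rng):
        A = rbf_affinity(rng.normal(size=(15, 3)), 1.0)
        L = normalized_laplacian(A)
        eigvals, eigvecs = np.linalg.eigh(L)  # independent solver
        k = 3
        E = spectral_embed(L, k)
        # reference embedding: row-normalized bottom-k eigenvectors, with
        # per-column signs aligned (eigenvectors are defined up to sign)
        ref = eigvecs[:, :k]
        ref = ref / np.linalg.norm(ref, axis=1, keepdims=True)
        signs = np.sign((E * ref).sum(axis=0))
        assert np.abs(E - ref * signs).max() < 1e-8

    def test_k_above_n_rejected(self):
        with pytest.raises(DomainError):
            spectral_embed(np.eye(3), 4)


class TestKMeans:
    def test_k1_inertia_is_total_scatter(self, rng):
        E = rng.normal(size=(20, 2))
        a = kmeans(E, 1, seed=0)
        assert a.inertia == pytest.approx(((E - E.mean(0)) ** 2).sum())

    def test_k_equals_n_gives_zero_inertia(self, rng):
        E = rng.normal(size=(6, 2))
        a = kmeans(E, 6, seed=0)
        assert a.inertia == pytest.approx(0.0, abs=1e-12)
        assert len(np.unique(a.labels)) == 6

    def test_two_blobs_recovered_at_global_optimum(self, rng):
        blob1 = rng.normal(size=(4, 2)) * 0.05
        blob2 = rng.normal(size=(4, 2)) * 0.05 + 10.0
        E = np.vstack([blob1, blob2])
        truth = np.array([0] * 4 + [1] * 4)
        a = kmeans(E, 2, seed=3)
        assert _ari(truth, a.labels) == 1.0
        # brute force over all non-trivial 2-partitions confirms global optimum
        best = np.inf
        for mask_bits in range(1, 2**8 - 1):
            mask = np.array([(mask_bits >> i) & 1 for i in range(8)], dtype=bool)
            inertia = sum(
                ((E[m] - E[m].mean(0)) ** 2).sum() for m in (mask, ~mask)
            )
            best = min(best, inertia)
        assert a.inertia == pytest.approx(best, rel=1e-9)

    def test_seeded_determinism(self, rng):
        E = rng.normal(size=(30, 3))
        a1 = kmeans(E, 4, seed=9)
        a2 = kmeans(E, 4, seed=9)
        assert np.array_equal(a1.labels, a2.labels)
        assert a1.inertia == a2.inertia


class TestSpectralCluster:
    def test_separable_tiers_perfectly_recovered(self, rng):
        X = np.vstack(
            [
                rng.normal(size=(10, 3)) * 0.05,
                rng.normal(size=(10, 3)) * 0.05 + [5, 0, 0],
            ]
        )
        truth = np.array([0] * 10 + [1] * 10)
        a = spectral_cluster(X, 2.0, 2, seed=0)
        assert _ari(truth, a.labels) == 1.0

    def test_row_permutation_equivariance(self, rng):
        X = np.vstack(
            [
                rng.normal(size=(8, 3)) * 0.05,
                rng.normal(size=(8, 3)) * 0.05 + [4, 4, 0],
            ]
        )
        perm = rng.permutation(len(X))
        a = spectral_cluster(X, 1.0, 2, seed=0)
        b = spectral_cluster(X[perm], 1.0, 2, seed=0)
        assert _ari(a.labels[perm], b.labels) == 1.0

    def test_ring_and_blob_components(self, rng):
        # classic non-convex case: a ring around a tight central blob
        theta = np.linspace(0, 2 * np.pi, 30, endpoint=False)
        ring = np.c_[5 * np.cos(theta), 5 * np.sin(theta)]
        blob = rng.normal(size=(10, 2)) * 0.2
        X = np.vstack([ring, blob])
        truth = np.array([0] * 30 + [1] * 10)
        spec = spectral_cluster(X, 1.0, 2, seed=0, standardize=False)
        assert _ari(truth, spec.labels) == 1.0
        raw = kmeans(X, 2, seed=0)
        assert _ari(truth, raw.labels) < 1.0  # raw k-means cuts the ring


def brute_force_ch(X, labels):
    """Independent CH oracle: explicit dispersion sums, no vectorization."""
    X = np.asarray(X, float)
    n = len(X)
    ids = sorted(set(labels.tolist()))
    k = len(ids)
    grand = X.mean(axis=0)
    b = 0.0
    w = 0.0
    for c in ids:
        members = X[np.asarray(labels) == c]
        cen = members.mean(axis=0)
        b += len(members) * sum((cen[j] - grand[j]) ** 2 for j in range(X.shape[1]))
        for row in members:
            w += sum((row[j] - cen[j]) ** 2 for j in range(X.shape[1]))
    return (b / (k - 1)) / (w / (n - k))


class TestCalinskiHarabasz:
    def test_hand_computed_1d_example(self):
        # {0,1,10,11}, two pairs: B = 2*5^2 + 2*5^2 = 100, W = 0.5+0.5 = 1
        # CH = (100/1)/(1/(4-2)) = 200
        X = np.array([[0.0], [1.0], [10.0], [11.0]])
        labels = np.array([0, 0, 1, 1])
        assert calinski_harabasz(X, labels) == pytest.approx(200.0)

    def test_matches_brute_force_oracle(self, rng):
        for n, k in [(20, 3), (100, 5), (200, 4)]:
            X = rng.normal(size=(n, 3))
            labels = rng.integers(k, size=n)
            while len(np.unique(labels)) < k:
                labels = rng.integers(k, size=n)
            assert calinski_harabasz(X, labels) == pytest.approx(
                brute_force_ch(X, labels), abs=1e-9, rel=1e-9
            )

    def test_matches_reference_library(self, rng):
        from sklearn.metrics import calinski_harabasz_score

        X = rng.normal(size=(60, 3))
        labels = rng.integers(4, size=60)
        assert calinski_harabasz(X, labels) == pytest.approx(
            calinski_harabasz_score(X, labels), rel=1e-9
        )

    def test_separation_beats_random_split(self, rng):
        X = np.vstack([rng.normal(size=(20, 2)), rng.normal(size=(20, 2)) + 20])
        good = np.array([0] * 20 + [1] * 20)
        random_split = rng.integers(2, size=40)
        while len(np.unique(random_split)) < 2:
            random_split = rng.integers(2, size=40)
        assert calinski_harabasz(X, good) > calinski_harabasz(X, random_split)

    @pytest.mark.parametrize("k", [1, 4])
    def test_degenerate_k_rejected(self, k):
        X = np.arange(8.0).reshape(4, 2)
        labels = np.arange(4) % k
        with pytest.raises(DomainError):
            calinski_harabasz(X, labels)


class TestGridSearch:
    def test_single_cell_is_best(self, rng):
        X = rng.normal(size=(20, 3))
        res = grid_search(X, [2.0], [3], seed=0)
        assert res.best == (2.0, 3)
        assert len(res.table) == 1

    def test_tied_scores_prefer_smaller_parameter(self, rng):
        # two far blobs: labels (hence CH on Z) identical for both gammas
        X = np.vstack([rng.normal(size=(6, 3)) * 0.01, rng.normal(size=(6, 3)) * 0.01 + 50])
        res = grid_search(X, [1.0, 2.0], [2], seed=0)
        scores = res.table["ch_score"]
        assert scores.iloc[0] == scores.iloc[1]
        assert res.best[0] == 1.0

    def test_failed_cells_recorded_as_nan(self, rng):
        X = rng.normal(size=(5, 3))
        res = grid_search(X, [1.0], [3, 6], seed=0)  # k=6 > n=5 fails
        assert np.isnan(res.table.set_index("k").loc[6, "ch_score"])
        assert res.best[1] == 3

    def test_planted_tiers_select_true_k(self):
        cfg = ScenarioConfig.default(seed=3)
        model, planted = LeadRiskModel.from_scenario(cfg)
        res = grid_search(model.exog, range(1, 11), range(3, 8), seed=3)
        assert res.best[1] == 5
        assert _ari(planted["tier"], res.assignment.labels) >= 0.9

    def test_end_to_end_determinism(self, rng):
        X = rng.normal(size=(30, 3))
        r1 = grid_search(X, [1.0, 2.0], [2, 3], seed=4)
        r2 = grid_search(X, [1.0, 2.0], [2, 3], seed=4)
        assert r1.best == r2.best
        assert np.array_equal(r1.assignment.labels, r2.assignment.labels)
        assert r1.table.equals(r2.table)
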