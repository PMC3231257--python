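"""Neighborhood graph, geodesics, constant shifting, spectral embedding."""

import numpy as np
import pytest
import scipy.sparse as sp
from scipy.sparse.csgraph import floyd_warshall
from scipy.spatial.distance import cdist, pdist

from kdisomap.isomap import (
    DisconnectedGraphError,
    constant_shift_c_star,
    double_center,
    geodesic_distances,
    kdisomap_fit,
    kisomap_fit,
    knn_graph,
    mercer_kernel,
    spectral_embed,
    transform,
)
from kdisomap.isomap import _c_star_bisection
from kdisomap.kernel_distance import (
    DiscriminantParams,
    gaussian_kernel,
    kernel_euclidean,
)
from kdisomap.synthetic import make_swiss_roll


def random_geodesic_kernels(rng, n):
    """Centered kernels of the geodesic matrix of a random connected graph."""
    X = rng.normal(size=(n, 3))
    G = geodesic_distances(knn_graph(cdist(X, X), max(3, n // 5)), auto_connect=True,
                           Dm=cdist(X, X))
    return double_center(G**2), double_center(G)


class TestKnnGraph:
    def test_three_collinear_points_form_path(self):
        D = cdist([[0.0], [1.0], [2.5]], [[0.0], [1.0], [2.5]])
        W = knn_graph(D, 1).toarray()
        # middle point bridges: ends pick the middle, union keeps both edges
        assert W[0, 1] > 0 and W[1, 2] > 0 and W[0, 2] == 0

    def test_full_k_gives_complete_graph(self, rng):
        D = cdist(rng.normal(size=(6, 2)), rng.normal(size=(6, 2)))
        D = 0.5 * (D + D.T)
        X = rng.normal(size=(6, 2))
        D = cdist(X, X)
        W = knn_graph(D, 5).toarray()
        assert np.all((W > 0) == ~np.eye(6, dtype=bool))

    def test_degree_at_least_k_after_union(self, rng):
        X = rng.normal(size=(20, 3))
        W = knn_graph(cdist(X, X), 4)
        degrees = (W.toarray() > 0).sum(axis=1)
        assert np.all(degrees >= 4)

    def test_k_out_of_range_rejected(self, rng):
        D = cdist(rng.normal(size=(5, 2)), rng.normal(size=(5, 2)))
        with pytest.raises(ValueError):
            knn_graph(D, 5)


class TestGeodesics:
    def test_path_graph_sums_edges(self):
        W = sp.csr_matrix(np.array([[0, 1.0, 0], [1.0, 0, 2.0], [0, 2.0, 0]]))
        G = geodesic_distances(W)
        assert G[0, 2] == pytest.approx(3.0)
        np.testing.assert_allclose(np.diag(G), 0.0)

    def test_matches_floyd_warshall_oracle(self, rng):
        X = rng.normal(size=(12, 3))
        W = knn_graph(cdist(X, X), 4)
        G = geodesic_distances(W, auto_connect=True, Dm=cdist(X, X))
        expected = floyd_warshall(W, directed=False)
        if np.isfinite(expected).all():
            np.testing.assert_allclose(G, expected, atol=1e-10)

    def test_direct_edge_never_exceeded(self, rng):
        X = rng.normal(size=(15, 2))
        W = knn_graph(cdist(X, X), 5).tocoo()
        G = geodesic_distances(W)
        for i, j, w in zip(W.row, W.col, W.data):
            assert G[i, j] <= w + 1e-12

    def test_disconnected_graph_error_names_components(self):
        X = np.vstack([np.zeros((4, 2)), 100 + np.zeros((4, 2))])
        X += np.random.default_rng(0).normal(0, 0.1, X.shape)
        W = knn_graph(cdist(X, X), 2)
        with pytest.raises(DisconnectedGraphError, match="Increase k"):
            geodesic_distances(W)

    def test_auto_connect_bridges_components(self):
        rng = np.random.default_rng(1)
        X = np.vstack([rng.normal(0, 0.1, (4, 2)), rng.normal(50, 0.1, (4, 2))])
        D = cdist(X, X)
        G = geodesic_distances(knn_graph(D, 2), auto_connect=True, Dm=D)
        assert np.isfinite(G).all()


class TestDoubleCenter:
    def test_zero_input(self):
        np.testing.assert_array_equal(double_center(np.zeros((4, 4))), 0.0)

    def test_two_point_closed_form(self):
        a = 3.0
        D2 = np.array([[0.0, a**2], [a**2, 0.0]])
        expected = np.array([[a**2 / 4, -(a**2) / 4], [-(a**2) / 4, a**2 / 4]])
        np.testing.assert_allclose(double_center(D2), expected)

    def test_row_sums_vanish(self, rng):
        M = rng.normal(size=(10, 10))
        M = M + M.T
        out = double_center(M)
        np.testing.assert_allclose(out.sum(axis=0), 0.0, atol=1e-10)
        np.testing.assert_allclose(out.sum(axis=1), 0.0, atol=1e-10)


class TestConstantShift:
    def test_block_matrix_agrees_with_bisection(self, rng):
        KD2, KD = random_geodesic_kernels(rng, 8)
        c_block = constant_shift_c_star(KD2, KD)
        c_bisect = _c_star_bisection(KD2, KD)
        assert c_block == pytest.approx(c_bisect, abs=1e-6)

    def test_kernel_psd_at_c_star(self, rng):
        for trial in range(5):
            KD2, KD = random_geodesic_kernels(rng, 10 + trial)
            c = max(constant_shift_c_star(KD2, KD), 0.0)
            w = np.linalg.eigvalsh(mercer_kernel(KD2, KD, c, check=False))
            assert w.min() >= -1e-8 * max(1.0, abs(w).max())

    def test_shift_monotone_above_c_star(self, rng):
        KD2, KD = random_geodesic_kernels(rng, 9)
        c_star = constant_shift_c_star(KD2, KD)
        for extra in (0.1, 1.0, 10.0):
            w = np.linalg.eigvalsh(
                mercer_kernel(KD2, KD, max(c_star, 0.0) + extra, check=False)
            )
            assert w.min() >= -1e-8 * max(1.0, abs(w).max())

    def test_zero_shift_recovers_centered_kernel(self, rng):
        KD2, KD = random_geodesic_kernels(rng, 7)
        np.testing.assert_array_equal(mercer_kernel(KD2, KD, 0.0, check=False), KD2)

    def test_below_c_star_warns(self, rng):
        KD2, KD = random_geodesic_kernels(rng, 12)
        c_star = constant_shift_c_star(KD2, KD)
        if c_star > 0.1:
            with pytest.warns(UserWarning, match="below"):
                mercer_kernel(KD2, KD, 0.0)


class TestSpectralEmbed:
    def test_two_point_closed_form(self):
        a = 4.0
        K = double_center(np.array([[0.0, a**2], [a**2, 0.0]]))
        w, V = spectral_embed(K, 1)
        Y = np.sqrt(w)[:, None] * V.T
        np.testing.assert_allclose(np.sort(Y.ravel()), [-a / 2, a / 2], atol=1e-12)

    def test_full_rank_reconstructs_psd_part(self, rng):
        KD2, KD = random_geodesic_kernels(rng, 10)
        c = max(constant_shift_c_star(KD2, KD), 0.0)
        K = mercer_kernel(KD2, KD, c, check=False)
        w, V = spectral_embed(K, 10)
        Y = np.sqrt(w)[:, None] * V.T
        np.testing.assert_allclose(Y.T @ Y, K, atol=1e-6)

    def test_eigenvalues_sorted_nonincreasing(self, rng):
        KD2, _ = random_geodesic_kernels(rng, 12)
        w, _ = spectral_embed(KD2, 6)
        assert np.all(np.diff(w) <= 1e-12)

    def test_dimension_bounds(self, rng):
        KD2, _ = random_geodesic_kernels(rng, 6)
        with pytest.raises(ValueError):
            spectral_embed(KD2, 7)


class TestKIsomap:
    def test_planar_data_embeds_isometrically(self, rng):
        """Points on a 2-D plane inside 10-D: graph distances approximate
        straight lines, so embedded distances match the originals."""
        Z = rng.uniform(-1, 1, size=(120, 2))
        basis, _ = np.linalg.qr(rng.normal(size=(10, 2)))
        X = Z @ basis.T
        m = kisomap_fit(X, k=10, d=2)
        emb = pdist(m.Y.T)
        orig = pdist(Z)
        # graph shortest paths overestimate straight lines by a small
        # zig-zag detour (a few % at k = 10, independent of N), so the
        # recovered geometry is a near-uniform slight inflation
        ratio = emb / orig
        assert np.corrcoef(emb, orig)[0, 1] > 0.995
        assert 1.0 <= np.median(ratio) < 1.08

    def test_swiss_roll_isometry_recovery(self):
        sr = make_swiss_roll(400, 0.0, seed=3)
        m = kisomap_fit(sr.points, k=10, d=2)
        corr = np.corrcoef(pdist(m.Y.T), pdist(sr.manifold_coords))[0, 1]
        assert corr >= 0.99

    def test_permutation_equivariance(self, rng):
        X = rng.normal(size=(40, 4))
        perm = rng.permutation(40)
        m1 = kisomap_fit(X, k=6, d=3)
        m2 = kisomap_fit(X[perm], k=6, d=3)
        np.testing.assert_allclose(
            np.abs(m1.Y[:, perm]), np.abs(m2.Y), atol=1e-6
        )

    def test_mercer_shift_option_records_c_star(self, rng):
        X = rng.normal(size=(30, 3))
        m = kisomap_fit(X, k=6, d=2, shift="mercer")
        assert m.c_star is not None and m.c == max(m.c_star, 0.0)


class TestKDIsomap:
    def test_supervision_not_worse_than_unsupervised(self, rng):
        """Paired comparison on separable Gaussian classes: the
        label-aware embedding is at least as good for 1-NN as the
        unsupervised one (mean over 10 seeds)."""
        from kdisomap.experiment import nn_classify

        diffs = []
        for seed in range(10):
            r = np.random.default_rng(seed)
            centers = np.array([[4, 0, 0, 0, 0], [0, 4, 0, 0, 0]], dtype=float)
            Xtr = np.vstack([r.normal(c, 1.0, (20, 5)) for c in centers])
            ytr = np.repeat([0, 1], 20)
            Xte = np.vstack([r.normal(c, 1.0, (10, 5)) for c in centers])
            yte = np.repeat([0, 1], 10)
            mk = kisomap_fit(Xtr, k=10, d=2, auto_connect=True)
            acc_k = np.mean(
                nn_classify(mk.Y.T, ytr, transform(mk, Xte).T) == yte
            )
            md = kdisomap_fit(
                Xtr, ytr, k=10, d=2,
                discriminant_params=DiscriminantParams(alpha=0.0),
                auto_connect=True,
            )
            acc_d = np.mean(
                nn_classify(md.Y.T, ytr, transform(md, Xte).T) == yte
            )
            diffs.append(acc_d - acc_k)
        assert np.mean(diffs) >= 0.0

    def test_single_class_reduces_to_kernel_distance_ranking(self, rng):
        """With one label the discriminant distance is a monotone transform
        of the kernel Euclidean distance, so neighbor rankings agree."""
        X = rng.normal(size=(25, 4))
        y = np.zeros(25, dtype=int)
        Dk = kernel_euclidean(gaussian_kernel(X))
        Dd = __import__("kdisomap.kernel_distance", fromlist=["discriminant_distance"]).discriminant_distance(Dk, y)
        k = 5
        for row_dk, row_dd in zip(Dk, Dd):
            nn_dk = np.argsort(row_dk, kind="stable")[1 : k + 1]
            nn_dd = np.argsort(row_dd, kind="stable")[1 : k + 1]
            np.testing.assert_array_equal(nn_dk, nn_dd)

    def test_embedding_shape(self, labeled_blobs):
        X, y = labeled_blobs
        m = kdisomap_fit(X, y, k=8, d=4, auto_connect=True)
        assert m.Y.shape == (4, X.shape[0])


class TestTransform:
    def test_training_points_self_consistent(self, labeled_blobs):
        X, y = labeled_blobs
        for model in (
            kisomap_fit(X, k=8, d=3, auto_connect=True),
            kdisomap_fit(X, y, k=8, d=3, auto_connect=True),
        ):
            Y2 = transform(model, X)
            np.testing.assert_allclose(Y2, model.Y, atol=1e-6)

    def test_duplicate_point_reproduces_training_coordinates(self, labeled_blobs):
        X, y = labeled_blobs
        m = kisomap_fit(X, k=8, d=2, auto_connect=True)
        Ynew = transform(m, X[[7]])
        np.testing.assert_allclose(Ynew[:, 0], m.Y[:, 7], atol=1e-6)

    def test_near_point_lands_near(self, labeled_blobs):
        X, y = labeled_blobs
        m = kisomap_fit(X, k=8, d=2, auto_connect=True)
        Ynew = transform(m, X[[7]] + 1e-3)
        assert np.linalg.norm(Ynew[:, 0] - m.Y[:, 7]) < 0.5

    def test_empty_input(self, labeled_blobs):
        X, y = labeled_blobs
        m = kisomap_fit(X, k=8, d=2, auto_connect=True)
        out = transform(m, np.empty((0, X.shape[1])))
        assert out.shape == (2, 0)

    def test_dimension_mismatch_rejected(self, labeled_blobs):
        X, y = labeled_blobs
        m = kisomap_fit(X, k=8, d=2, auto_connect=True)
        with pytest.raises(ValueError):
            transform(m, np.zeros((3, X.shape[1] + 1)))
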