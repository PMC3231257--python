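"""Kernel Isomap and its supervised variant KDIsomap.

Isomap approximates distances along a data manifold by shortest paths in
a k-nearest-neighbor graph and embeds them with classical multidimensional
scaling: the squared geodesic matrix D^2 is double-centered,

    K(D^2) = -1/2 H D^2 H,     H = I - (1/N) e e^T,

and the top eigenpairs give the coordinates Y = Lambda^{1/2} V^T.  The
centered matrix is not in general positive semi-definite; the
constant-shifting construction adds a constant c to every off-diagonal
geodesic distance, which at the kernel level reads

    K*(c) = K(D^2) + 2 c K(D) + 1/2 c^2 H,

and K*(c) is PSD — a Mercer kernel — for every c at least the largest
eigenvalue c* of the 2N x 2N block matrix [[0, 2 K(D^2)], [-I, -4 K(D)]].
With a Mercer kernel the embedding gains an out-of-sample extension by
the usual kernel trick, exactly as in kernel PCA.

KIsomap runs this pipeline on plain Euclidean input distances.  KDIsomap
replaces them with the kernel discriminant distance (see
:mod:`kdisomap.kernel_distance`), so that within-class neighborhoods are
tightened and between-class ones inflated before the graph is built.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np
import scipy.linalg
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components, dijkstra
from scipy.spatial.distance import cdist

from .kernel_distance import (
    DiscriminantParams,
    KernelParams,
    average_pairwise_beta,
    discriminant_distance,
    gaussian_cross_kernel,
    gaussian_kernel,
    kernel_euclidean,
)

__all__ = [
    "DisconnectedGraphError",
    "EmbeddingModel",
    "knn_graph",
    "geodesic_distances",
    "double_center",
    "constant_shift_c_star",
    "mercer_kernel",
    "spectral_embed",
    "kisomap_fit",
    "kdisomap_fit",
    "transform",
]

logger = logging.getLogger(__name__)


class DisconnectedGraphError(ValueError):
    """Raised when the neighborhood graph has more than one component."""

    def __init__(self, component_labels: np.ndarray, k: int):
        self.component_labels = component_labels
        self.k = k
        sizes = np.bincount(component_labels)
        super().__init__(
            f"neighborhood graph is disconnected: {len(sizes)} components of "
            f"sizes {sizes.tolist()} at k={k}. Increase k (or pass "
            "auto_connect=True to bridge components with their shortest "
            "inter-component edge)."
        )


def knn_graph(Dm: np.ndarray, k: int) -> sp.csr_matrix:
    """Symmetrized k-nearest-neighbor graph from a dissimilarity matrix.

    Each node is linked to its k smallest-dissimilarity neighbors
    (self excluded, ties broken toward the smaller index); the edge set is
    the union over both endpoints, with edge weight equal to the input
    dissimilarity.  Returns a sparse symmetric CSR matrix.
    """
    Dm = np.asarray(Dm, dtype=np.float64)
    n = Dm.shape[0]
    if Dm.ndim != 2 or Dm.shape[1] != n:
        raise ValueError(f"dissimilarity matrix must be square, got {Dm.shape}")
    if not 1 <= k < n:
        raise ValueError(f"k must satisfy 1 <= k < N={n}, got {k}")
    with_self = Dm.copy()
    np.fill_diagonal(with_self, np.inf)
    # stable argsort: equal dissimilarities resolve to the smaller index
    order = np.argsort(with_self, axis=1, kind="stable")[:, :k]
    rows = np.repeat(np.arange(n), k)
    cols = order.ravel()
    weights = Dm[rows, cols]
    W = sp.coo_matrix((weights, (rows, cols)), shape=(n, n)).tocsr()
    return W.maximum(W.T)  # union symmetrization


def geodesic_distances(
    graph: sp.spmatrix, auto_connect: bool = False, Dm: np.ndarray | None = None
) -> np.ndarray:
    """All-pairs shortest-path distances through the neighborhood graph.

    Uses Dijkstra's algorithm on the sparse graph.  A disconnected graph
    raises :class:`DisconnectedGraphError` unless ``auto_connect`` is set,
    in which case the single shortest inter-component edge (taken from the
    full dissimilarity matrix ``Dm``) is added repeatedly until one
    component remains.
    """
    graph = sp.csr_matrix(graph)
    n_comp, comp = connected_components(graph, directed=False)
    if n_comp > 1:
        if not auto_connect:
            raise DisconnectedGraphError(comp, k=int((graph.getnnz() // graph.shape[0])))
        if Dm is None:
            raise ValueError("auto_connect requires the dense dissimilarity matrix")
        graph = graph.tolil()
        while n_comp > 1:
            best = (np.inf, -1, -1)
            for a in range(n_comp):
                ia = np.flatnonzero(comp == a)
                for b in range(a + 1, n_comp):
                    ib = np.flatnonzero(comp == b)
                    block = Dm[np.ix_(ia, ib)]
                    i, j = np.unravel_index(np.argmin(block), block.shape)
                    if block[i, j] < best[0]:
                        best = (block[i, j], ia[i], ib[j])
            w, i, j = best
            logger.info("auto-connect: bridging nodes %d-%d with weight %.4g", i, j, w)
            graph[i, j] = w
            graph[j, i] = w
            n_comp, comp = connected_components(sp.csr_matrix(graph), directed=False)
        graph = sp.csr_matrix(graph)
    D = dijkstra(graph, directed=False)
    return 0.5 * (D + D.T)


def double_center(M: np.ndarray) -> np.ndarray:
    """Apply the double-centering map M -> -1/2 H M H.

    With M the squared geodesic matrix this is the classical-MDS Gram
    matrix; every row and column of the output sums to zero.
    """
    M = np.asarray(M, dtype=np.float64)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError(f"input must be square, got {M.shape}")
    row = M.mean(axis=1, keepdims=True)
    col = M.mean(axis=0, keepdims=True)
    out = -0.5 * (M - row - col + M.mean())
    return 0.5 * (out + out.T)


def _min_eig(A: np.ndarray) -> float:
    return float(scipy.linalg.eigvalsh(A, subset_by_index=[0, 0])[0])


def _c_star_bisection(KD2: np.ndarray, KD: np.ndarray, tol: float = 1e-8) -> float:
    """Smallest c making K*(c) PSD, by bisection on the minimum eigenvalue."""
    lo, hi = 0.0, 1.0
    if _min_eig(mercer_kernel(KD2, KD, lo, check=False)) >= -tol:
        # already PSD at 0; search negative side down to some floor
        lo = -1.0
        while _min_eig(mercer_kernel(KD2, KD, lo, check=False)) >= -tol and lo > -1e6:
            hi = lo
            lo *= 2.0
    else:
        while _min_eig(mercer_kernel(KD2, KD, hi, check=False)) < -tol and hi < 1e6:
            lo = hi
            hi *= 2.0
    for _ in range(100):
        mid = 0.5 * (lo + hi)
        if _min_eig(mercer_kernel(KD2, KD, mid, check=False)) >= -tol:
            hi = mid
        else:
            lo = mid
        if hi - lo < 1e-10 * max(1.0, abs(hi)):
            break
    return hi


def constant_shift_c_star(KD2: np.ndarray, KD: np.ndarray) -> float:
    """Smallest admissible shift constant c*.

    c* is the largest (real) eigenvalue of the 2N x 2N block matrix
    [[0, 2 K(D^2)], [-I, -4 K(D)]]; K*(c) is guaranteed PSD for c >= c*.
    If the numerically largest-real-part eigenvalue has a non-negligible
    imaginary part, falls back to bisection on the PSD condition.
    """
    n = KD2.shape[0]
    if KD2.shape != (n, n) or KD.shape != (n, n):
        raise ValueError("KD2 and KD must be square matrices of equal size")
    B = np.zeros((2 * n, 2 * n))
    B[:n, n:] = 2.0 * KD2
    B[n:, :n] = -np.eye(n)
    B[n:, n:] = -4.0 * KD
    eigvals = scipy.linalg.eigvals(B)
    idx = int(np.argmax(eigvals.real))
    lam = eigvals[idx]
    if abs(lam.imag) > 1e-6 * max(1.0, abs(lam.real)):
        logger.warning(
            "largest-real-part eigenvalue %s has a large imaginary part; "
            "falling back to bisection for c*",
            lam,
        )
        return _c_star_bisection(KD2, KD)
    return float(lam.real)


def mercer_kernel(
    KD2: np.ndarray, KD: np.ndarray, c: float, check: bool = True
) -> np.ndarray:
    """Constant-shifted kernel K*(c) = K(D^2) + 2c K(D) + 1/2 c^2 H."""
    n = KD2.shape[0]
    H = np.eye(n) - 1.0 / n
    K = KD2 + 2.0 * c * KD + 0.5 * c**2 * H
    K = 0.5 * (K + K.T)
    if check:
        me = _min_eig(K)
        if me < -1e-8 * max(1.0, float(np.abs(K).max())):
            warnings.warn(
                f"K*(c={c:.4g}) has minimum eigenvalue {me:.3e}: c is below "
                "the admissible shift c*",
                stacklevel=2,
            )
    return K


def spectral_embed(Kstar: np.ndarray, d: int) -> tuple[np.ndarray, np.ndarray]:
    """Top-d eigenpairs of K* and embedded coordinates.

    Returns (eigvals, V) with eigenvalues in non-increasing order and the
    sign of each eigenvector fixed so its largest-magnitude entry is
    positive.  Negative eigenvalues among the top d are clamped to zero
    with a warning (their directions carry no real coordinate).
    Coordinates follow as Y = diag(sqrt(eigvals)) @ V.T (d x N).
    """
    Kstar = np.asarray(Kstar, dtype=np.float64)
    n = Kstar.shape[0]
    if not 1 <= d <= n:
        raise ValueError(f"embedding dimension must satisfy 1 <= d <= N={n}, got {d}")
    w, V = scipy.linalg.eigh(Kstar)
    w = w[::-1][:d].copy()
    V = V[:, ::-1][:, :d].copy()
    if w[-1] < -1e-8 * max(1.0, float(np.abs(Kstar).max())):
        warnings.warn(
            f"clamping {int((w < 0).sum())} negative eigenvalues "
            f"(most negative {w.min():.3e}) to zero",
            stacklevel=2,
        )
    np.clip(w, 0.0, None, out=w)
    # deterministic eigenvector signs across LAPACK implementations
    flip = V[np.argmax(np.abs(V), axis=0), np.arange(V.shape[1])] < 0
    V[:, flip] *= -1.0
    return w, V


@dataclass
class EmbeddingModel:
    """Fitted (KD)Isomap embedding with everything needed to project new points.

    Coordinates of the training points are ``Y`` (d x N).  ``transform``
    metadata: the shifted squared geodesic row means and grand mean
    reproduce the training double-centering; ``geodesics`` are the
    *unshifted* shortest-path distances.
    """

    SCHEMA_VERSION = 1

    method: Literal["kisomap", "kdisomap"]
    k: int
    d: int
    c_star: float | None
    c: float
    eigenvalues: np.ndarray  # (d,)
    eigenvectors: np.ndarray  # (N, d)
    geodesics: np.ndarray  # (N, N)
    row_means: np.ndarray  # (N,) column means of shifted D^2
    grand_mean: float
    train_X: np.ndarray
    train_labels: np.ndarray | None = None
    kernel_params: KernelParams | None = None
    beta: float | None = None
    alpha: float | None = None
    # out-of-sample edges for kdisomap use the within-class transform of the
    # kernel Euclidean distance, because a test point's label is unknown
    oos_edge_rule: str = "euclidean"

    @property
    def Y(self) -> np.ndarray:
        """Embedded training coordinates, d x N."""
        return (np.sqrt(self.eigenvalues)[:, None]) * self.eigenvectors.T

    @property
    def n_samples(self) -> int:
        return self.train_X.shape[0]


def _fit_from_dissimilarity(
    Dm: np.ndarray,
    d: int,
    k: int,
    auto_connect: bool,
    shift: str | float = "none",
) -> tuple[np.ndarray, float | None, float, np.ndarray, np.ndarray, np.ndarray, float]:
    graph = knn_graph(Dm, k)
    G = geodesic_distances(graph, auto_connect=auto_connect, Dm=Dm)
    KD2 = double_center(G**2)
    KD = double_center(G)
    # Shift policy.  The minimal Mercer shift c* grows with the graph-path
    # overestimation of manifold distances and inflates the trailing
    # spectrum, which distorts recovered distances in a rank-d readout;
    # the top-d eigenvalues of the unshifted centered kernel are positive
    # already (negatives are clamped), so the default embeds without a
    # shift.  shift="mercer" applies c = max(c*, 0) for a fully PSD K*.
    c_star: float | None
    if shift == "none":
        c_star, c = None, 0.0
        Kstar = KD2
    elif shift == "mercer":
        c_star = constant_shift_c_star(KD2, KD)
        c = max(c_star, 0.0)
        Kstar = mercer_kernel(KD2, KD, c)
    elif isinstance(shift, (int, float)):
        c_star, c = None, float(shift)
        Kstar = mercer_kernel(KD2, KD, c, check=False)
    else:
        raise ValueError(f"shift must be 'none', 'mercer' or a number, got {shift!r}")
    w, V = spectral_embed(Kstar, d)
    # shifted distances: the constant shift adds c to every off-diagonal entry
    Gs = np.where(G > 0.0, G + c, 0.0)
    Gs2 = Gs**2
    row_means = Gs2.mean(axis=0)
    grand_mean = float(Gs2.mean())
    return G, c_star, c, w, V, row_means, grand_mean


def kisomap_fit(
    X,
    k: int = 10,
    d: int = 2,
    auto_connect: bool = False,
    shift: str | float = "none",
) -> EmbeddingModel:
    """Fit the (kernelizable) Isomap on Euclidean input distances.

    ``shift="mercer"`` applies the minimal constant shift making the
    geodesic kernel positive semi-definite; the default embeds the
    unshifted centered kernel (see :func:`mercer_kernel`).
    """
    X = np.asarray(X, dtype=np.float64)
    Dm = cdist(X, X)
    G, c_star, c, w, V, row_means, grand_mean = _fit_from_dissimilarity(
        Dm, d, k, auto_connect, shift
    )
    return EmbeddingModel(
        method="kisomap",
        k=k,
        d=d,
        c_star=c_star,
        c=c,
        eigenvalues=w,
        eigenvectors=V,
        geodesics=G,
        row_means=row_means,
        grand_mean=grand_mean,
        train_X=X,
        oos_edge_rule="euclidean",
    )


def kdisomap_fit(
    X,
    labels,
    k: int = 10,
    d: int = 2,
    kernel_params: KernelParams = KernelParams(),
    discriminant_params: DiscriminantParams = DiscriminantParams(),
    auto_connect: bool = False,
    shift: str | float = "none",
) -> EmbeddingModel:
    """Fit the supervised KDIsomap.

    Pipeline: Gaussian kernel -> kernel Euclidean distance -> beta (auto
    average-pairwise unless given) -> kernel discriminant distance ->
    k-NN graph -> geodesics -> double centering -> constant shift ->
    Mercer kernel -> spectral embedding.
    """
    X = np.asarray(X, dtype=np.float64)
    labels = np.asarray(labels)
    if labels.shape[0] != X.shape[0]:
        raise ValueError("labels length does not match number of samples")
    K = gaussian_kernel(X, kernel_params)
    Dk = kernel_euclidean(K)
    beta = (
        discriminant_params.beta
        if discriminant_params.beta is not None
        else average_pairwise_beta(Dk)
    )
    dp = DiscriminantParams(alpha=discriminant_params.alpha, beta=beta)
    Dm = discriminant_distance(Dk, labels, dp)
    G, c_star, c, w, V, row_means, grand_mean = _fit_from_dissimilarity(
        Dm, d, k, auto_connect, shift
    )
    return EmbeddingModel(
        method="kdisomap",
        k=k,
        d=d,
        c_star=c_star,
        c=c,
        eigenvalues=w,
        eigenvectors=V,
        geodesics=G,
        row_means=row_means,
        grand_mean=grand_mean,
        train_X=X,
        train_labels=labels,
        kernel_params=kernel_params,
        beta=beta,
        alpha=dp.alpha,
        oos_edge_rule="intraclass_kernel",
    )


def _oos_edges(model: EmbeddingModel, Xnew: np.ndarray) -> np.ndarray:
    """M x N edge lengths from new points to every training point."""
    if model.oos_edge_rule == "euclidean":
        return cdist(Xnew, model.train_X)
    # label of a new point is unknown, so the discriminant distance cannot be
    # evaluated; use the bounded within-class transform of the kernel
    # Euclidean distance, which preserves neighbor ranking
    Kc = gaussian_cross_kernel(Xnew, model.train_X, model.kernel_params)
    d2 = np.clip(2.0 - 2.0 * Kc, 0.0, None)
    return 1.0 - np.exp(-d2 / model.beta)


def transform(model: EmbeddingModel, Xnew) -> np.ndarray:
    """Project new points into a fitted embedding (d x M coordinates).

    A new point is wired to its k nearest training points (under the
    model's out-of-sample edge rule); its geodesic distance to training
    point i is min_j [edge(new, j) + geo(j, i)] over those neighbors.
    The distances are constant-shifted like the training ones, turned
    into a centered kernel column with the training means, and projected:
    y = Lambda^{-1/2} V^T k.  Training points fed back through transform
    reproduce their training coordinates.
    """
    Xnew = np.asarray(Xnew, dtype=np.float64)
    if Xnew.ndim != 2:
        raise ValueError(f"expected an M x D matrix, got shape {Xnew.shape}")
    if Xnew.shape[1] != model.train_X.shape[1]:
        raise ValueError(
            f"feature dimension mismatch: model has {model.train_X.shape[1]}, "
            f"input has {Xnew.shape[1]}"
        )
    m = Xnew.shape[0]
    d = model.eigenvalues.shape[0]
    if m == 0:
        return np.empty((d, 0))
    edges = _oos_edges(model, Xnew)  # (M, N)
    # a point coinciding with a training point inherits its coordinates:
    # for kdisomap the out-of-sample edge rule is label-free, so this is the
    # only way training geodesics (which are label-aware) are reproduced
    nearest = np.argmin(edges, axis=1)
    dup = edges[np.arange(m), nearest] <= 1e-12
    k = min(model.k, model.n_samples)
    nn = np.argsort(edges, axis=1, kind="stable")[:, :k]
    geo = np.empty_like(edges)
    for i in range(m):
        through = edges[i, nn[i]][:, None] + model.geodesics[nn[i], :]
        geo[i] = through.min(axis=0)
    gs = np.where(geo > 0.0, geo + model.c, 0.0)
    gs2 = gs**2
    # double-center the new columns with the training statistics
    kcol = -0.5 * (
        gs2 - gs2.mean(axis=1, keepdims=True) - model.row_means[None, :] + model.grand_mean
    )
    w = model.eigenvalues
    inv_sqrt = np.where(w > 1e-12, 1.0 / np.sqrt(np.where(w > 1e-12, w, 1.0)), 0.0)
    out = (inv_sqrt[:, None]) * (model.eigenvectors.T @ kcol.T)
    if np.any(dup):
        Ytr = model.Y
        out[:, dup] = Ytr[:, nearest[dup]]
    return out
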