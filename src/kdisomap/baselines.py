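"""Linear and kernel baseline embeddings: PCA, LDA, KPCA, KLDA.

These are the standard comparison methods for the supervised kernel
Isomap: two linear projections (principal component analysis and Fisher
linear discriminant analysis) and their kernelized counterparts with a
Gaussian kernel.  Out-of-sample projection is a matrix product for the
linear methods and the usual centered-kernel-column trick for the kernel
methods.  LDA-type methods yield at most c - 1 meaningful dimensions for
c classes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .kernel_distance import KernelParams, gaussian_cross_kernel, gaussian_kernel

__all__ = [
    "LinearModel",
    "KernelModel",
    "pca_fit",
    "lda_fit",
    "kpca_fit",
    "klda_fit",
    "linear_transform",
    "kernel_transform",
]

logger = logging.getLogger(__name__)

#: ridge added to the within-class scatter, as a fraction of its trace
LDA_RIDGE = 1e-6


@dataclass
class LinearModel:
    method: str  # "pca" or "lda"
    mean: np.ndarray  # (D,)
    components: np.ndarray  # (D, d) projection matrix
    eigenvalues: np.ndarray  # (d,)


@dataclass
class KernelModel:
    method: str  # "kpca" or "klda"
    train_X: np.ndarray
    kernel_params: KernelParams
    dual_coef: np.ndarray  # (N, r) centered-kernel eigvecs scaled by 1/sqrt(eig)
    eigenvalues: np.ndarray  # (r,) KPCA eigenvalues actually retained
    col_means: np.ndarray  # (N,) training kernel column means
    grand_mean: float
    lda: LinearModel | None = None  # KLDA = LDA in the KPCA-whitened space
    kernel: str = "gaussian"


def _sign_fix(V: np.ndarray) -> np.ndarray:
    flip = V[np.argmax(np.abs(V), axis=0), np.arange(V.shape[1])] < 0
    V[:, flip] *= -1.0
    return V


def pca_fit(X, d: int) -> LinearModel:
    """Principal component analysis: top-d variance-maximizing directions."""
    X = np.asarray(X, dtype=np.float64)
    n, D = X.shape
    if not 1 <= d <= min(n, D):
        raise ValueError(f"d must be in [1, min(N, D)={min(n, D)}], got {d}")
    mean = X.mean(axis=0)
    Xc = X - mean
    U, s, Vt = scipy.linalg.svd(Xc, full_matrices=False)
    comps = _sign_fix(Vt[:d].T.copy())
    eigvals = (s[:d] ** 2) / max(n - 1, 1)
    return LinearModel("pca", mean, comps, eigvals)


def _scatter_matrices(X: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    classes = np.unique(labels)
    D = X.shape[1]
    Sw = np.zeros((D, D))
    Sb = np.zeros((D, D))
    for c in classes:
        Xc = X[labels == c]
        mc = Xc.mean(axis=0)
        dc = Xc - mc
        Sw += dc.T @ dc
        dm = (mc - mean)[:, None]
        Sb += Xc.shape[0] * (dm @ dm.T)
    return Sw, Sb


def lda_fit(X, labels, d: int | None = None) -> LinearModel:
    """Fisher linear discriminant analysis.

    Maximizes the ratio of between-class to within-class scatter; at most
    c - 1 dimensions are meaningful.  The within-class scatter receives a
    small ridge (1e-6 of its trace) when near-singular.
    """
    X = np.asarray(X, dtype=np.float64)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    max_d = len(classes) - 1
    if max_d < 1:
        raise ValueError("LDA needs at least two classes")
    if d is None:
        d = max_d
    if not 1 <= d <= max_d:
        raise ValueError(f"LDA dimension must be in [1, c-1={max_d}], got {d}")
    Sw, Sb = _scatter_matrices(X, labels)
    ridge = LDA_RIDGE * max(np.trace(Sw), 1e-30) / X.shape[1]
    Sw = Sw + ridge * np.eye(X.shape[1])
    w, V = scipy.linalg.eigh(Sb, Sw)
    order = np.argsort(w)[::-1][:d]
    comps = _sign_fix(V[:, order].copy())
    return LinearModel("lda", X.mean(axis=0), comps, w[order])


def _kernel_matrix(X, kp: KernelParams, kernel: str) -> np.ndarray:
    if kernel == "gaussian":
        return gaussian_kernel(X, kp)
    if kernel == "linear":
        return X @ X.T
    raise ValueError(f"unknown kernel {kernel!r}")


def _cross_kernel(Xnew, X, kp: KernelParams, kernel: str) -> np.ndarray:
    if kernel == "gaussian":
        return gaussian_cross_kernel(Xnew, X, kp)
    if kernel == "linear":
        return Xnew @ X.T
    raise ValueError(f"unknown kernel {kernel!r}")


def _kpca_core(X: np.ndarray, kp: KernelParams, max_rank: int | None = None,
               kernel: str = "gaussian"):
    K = _kernel_matrix(X, kp, kernel)
    n = K.shape[0]
    col_means = K.mean(axis=0)
    grand = float(K.mean())
    Kc = K - col_means[None, :] - col_means[:, None] + grand
    Kc = 0.5 * (Kc + Kc.T)
    w, V = scipy.linalg.eigh(Kc)
    w = w[::-1]
    V = V[:, ::-1]
    keep = w > max(1e-10 * max(w[0], 0.0), 1e-12)
    if max_rank is not None:
        keep &= np.arange(n) < max_rank
    w = w[keep]
    V = _sign_fix(V[:, keep].copy())
    return w, V, col_means, grand


def kpca_fit(X, d: int, kp: KernelParams = KernelParams(),
             kernel: str = "gaussian") -> KernelModel:
    """Kernel PCA: eigendecomposition of the double-centered kernel matrix.

    ``kernel="linear"`` uses the plain inner-product kernel, in which
    case the coordinates coincide with PCA up to sign.
    """
    X = np.asarray(X, dtype=np.float64)
    n = X.shape[0]
    if not 1 <= d <= n:
        raise ValueError(f"d must be in [1, N={n}], got {d}")
    w, V, col_means, grand = _kpca_core(X, kp, max_rank=d, kernel=kernel)
    if w.shape[0] < d:
        logger.info(
            "kernel matrix rank %d below requested dimension %d; truncating",
            w.shape[0],
            d,
        )
    dual = V / np.sqrt(w)[None, :]
    return KernelModel("kpca", X, kp, dual, w, col_means, grand, kernel=kernel)


def klda_fit(X, labels, d: int | None = None, kp: KernelParams = KernelParams()) -> KernelModel:
    """Kernel Fisher discriminant analysis (Gaussian kernel).

    Solved as LDA in the kernel-PCA coordinate space of (numerically)
    full rank — an equivalent, well-conditioned formulation of the
    kernelized Fisher problem; at most c - 1 dimensions.
    """
    X = np.asarray(X, dtype=np.float64)
    labels = np.asarray(labels)
    w, V, col_means, grand = _kpca_core(X, kp)
    dual = V / np.sqrt(w)[None, :]
    Z = V * np.sqrt(w)[None, :]  # KPCA training coordinates, N x r
    lda = lda_fit(Z, labels, d)
    return KernelModel("klda", X, kp, dual, w, col_means, grand, lda=lda)


def linear_transform(model: LinearModel, Xnew) -> np.ndarray:
    """Project new points with a fitted linear model (M x d)."""
    Xnew = np.asarray(Xnew, dtype=np.float64)
    if Xnew.ndim != 2 or Xnew.shape[1] != model.mean.shape[0]:
        raise ValueError(
            f"expected M x {model.mean.shape[0]} features, got {Xnew.shape}"
        )
    return (Xnew - model.mean) @ model.components


def kernel_transform(model: KernelModel, Xnew) -> np.ndarray:
    """Project new points with a fitted kernel model (M x d).

    Builds the kernel block against the training set, centers it with the
    training statistics, and multiplies by the dual coefficients (then
    the inner LDA projection for KLDA).
    """
    Xnew = np.asarray(Xnew, dtype=np.float64)
    if Xnew.ndim != 2 or Xnew.shape[1] != model.train_X.shape[1]:
        raise ValueError(
            f"expected M x {model.train_X.shape[1]} features, got {Xnew.shape}"
        )
    Kx = _cross_kernel(Xnew, model.train_X, model.kernel_params, model.kernel)
    Kxc = Kx - model.col_means[None, :] - Kx.mean(axis=1, keepdims=True) + model.grand_mean
    Z = Kxc @ model.dual_coef
    if model.lda is not None:
        return linear_transform(model.lda, Z)
    return Z


def fit_coordinates(model: LinearModel | KernelModel, X) -> np.ndarray:
    """Training-set coordinates of a fitted model (N x d)."""
    if isinstance(model, LinearModel):
        return linear_transform(model, X)
    return kernel_transform(model, X)
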