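"""Kernel-induced distances and the supervised discriminant distance.

A Gaussian kernel kappa(x, y) = exp(-||x - y||^2 / (2 sigma^2)) implicitly
maps points into a reproducing kernel Hilbert space.  The kernel Euclidean
distance between the mapped points is

    d_k(x, y)^2 = kappa(x, x) - 2 kappa(x, y) + kappa(y, y),

which for the Gaussian kernel equals 2 - 2 kappa(x, y) in [0, 2).  The
kernel discriminant distance injects class labels, shrinking within-class
dissimilarities to [0, 1) and inflating between-class ones:

    D_k(x, y) = 1 - exp(-d_k^2 / beta)        if labels agree,
    D_k(x, y) = exp(+d_k^2 / beta) - alpha    otherwise,

with beta a density scale (by default the average kernel Euclidean
distance over all unordered sample pairs) and alpha in [0, 1] a constant
that lets within-class dissimilarities occasionally exceed between-class
ones.  At alpha = 0 every between-class value (>= 1) strictly exceeds
every within-class value (< 1).  Both branches increase monotonically in
d_k, so local geometry is preserved within each branch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "KernelParams",
    "DiscriminantParams",
    "gaussian_kernel",
    "gaussian_cross_kernel",
    "kernel_euclidean",
    "average_pairwise_beta",
    "discriminant_distance",
]

# d^2 values in [-CLAMP_EPS, 0] arising from floating point are clamped to 0
CLAMP_EPS = 1e-12


@dataclass(frozen=True)
class KernelParams:
    """Gaussian kernel bandwidth sigma (> 0, default 1)."""

    sigma: float = 1.0

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValueError(f"sigma must be > 0, got {self.sigma}")


@dataclass(frozen=True)
class DiscriminantParams:
    """Constant factor alpha in [0, 1] and smoothing parameter beta.

    ``beta=None`` means "auto": use the average pairwise kernel
    Euclidean distance of the training set.
    """

    alpha: float = 0.5
    beta: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must be in [0, 1], got {self.alpha}")
        if self.beta is not None and not self.beta > 0:
            raise ValueError(f"beta must be > 0 (or None for auto), got {self.beta}")


def _check_finite(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2:
        raise ValueError(f"expected an N x D feature matrix, got shape {X.shape}")
    if not np.all(np.isfinite(X)):
        raise ValueError("features contain non-finite values")
    return X


def gaussian_kernel(X, params: KernelParams = KernelParams()) -> np.ndarray:
    """N x N Gaussian kernel matrix; symmetric with unit diagonal."""
    X = _check_finite(X)
    sq = cdist(X, X, metric="sqeuclidean")
    K = np.exp(-sq / (2.0 * params.sigma**2))
    np.fill_diagonal(K, 1.0)
    return 0.5 * (K + K.T)


def gaussian_cross_kernel(Xnew, X, params: KernelParams = KernelParams()) -> np.ndarray:
    """M x N kernel block between new points and training points."""
    Xnew = _check_finite(Xnew)
    X = _check_finite(X)
    if Xnew.shape[1] != X.shape[1]:
        raise ValueError(
            f"feature dimension mismatch: {Xnew.shape[1]} vs {X.shape[1]}"
        )
    sq = cdist(Xnew, X, metric="sqeuclidean")
    return np.exp(-sq / (2.0 * params.sigma**2))


def kernel_euclidean(K: np.ndarray) -> np.ndarray:
    """Kernel Euclidean distance matrix induced by a kernel matrix.

    d^2_ij = K_ii - 2 K_ij + K_jj; tiny negative d^2 from floating point
    is clamped to zero, larger negatives (non-Mercer input) raise.
    """
    K = np.asarray(K, dtype=np.float64)
    if K.ndim != 2 or K.shape[0] != K.shape[1]:
        raise ValueError(f"kernel matrix must be square, got {K.shape}")
    diag = np.diag(K)
    d2 = diag[:, None] - 2.0 * K + diag[None, :]
    if d2.min() < -CLAMP_EPS:
        raise ValueError(
            f"negative squared kernel distance {d2.min():.3e}: input is not a "
            "valid (Mercer) kernel matrix"
        )
    np.clip(d2, 0.0, None, out=d2)
    D = np.sqrt(d2)
    np.fill_diagonal(D, 0.0)
    return 0.5 * (D + D.T)


def average_pairwise_beta(Dk: np.ndarray) -> float:
    """Average kernel Euclidean distance over all unordered pairs i < j.

    Self-pairs are excluded.  Raises if the result is zero (all points
    identical), because the discriminant distance divides by beta.
    """
    Dk = np.asarray(Dk, dtype=np.float64)
    n = Dk.shape[0]
    if n < 2:
        raise ValueError("need at least two samples to estimate beta")
    iu = np.triu_indices(n, k=1)
    beta = float(Dk[iu].mean())
    if beta <= 0.0:
        raise ValueError(
            "beta is zero: all samples coincide, the discriminant distance "
            "is undefined"
        )
    return beta


def discriminant_distance(
    Dk: np.ndarray,
    labels,
    params: DiscriminantParams = DiscriminantParams(),
) -> np.ndarray:
    """Label-aware kernel discriminant distance matrix.

    Applies the bounded within-class transform 1 - exp(-d^2/beta) where
    labels agree and the inflating between-class transform
    exp(d^2/beta) - alpha where they differ.  ``params.beta=None``
    estimates beta from ``Dk`` by the average-pairwise rule.
    """
    Dk = np.asarray(Dk, dtype=np.float64)
    labels = np.asarray(labels)
    if labels.shape[0] != Dk.shape[0]:
        raise ValueError("labels length does not match distance matrix")
    beta = params.beta if params.beta is not None else average_pairwise_beta(Dk)
    if not beta > 0:
        raise ValueError(f"beta must be > 0, got {beta}")
    same = labels[:, None] == labels[None, :]
    e = np.exp(Dk**2 / beta)
    out = np.where(same, 1.0 - 1.0 / e, e - params.alpha)
    np.fill_diagonal(out, 0.0)
    return 0.5 * (out + out.T)
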