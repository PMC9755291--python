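"""Sample-level kernel matrices for multivariate association testing.

Two kernels are provided: the Gaussian (RBF) kernel with a median-heuristic
bandwidth, the workhorse characteristic kernel for generic multivariate
data, and a Bray-Curtis-derived kernel for compositional (e.g. microbiome
relative abundance) data, obtained by Gower double-centering of the squared
dissimilarities followed by projection onto the positive semi-definite cone.

Conventions
-----------
* Gaussian kernel: ``k(x, x') = exp(-||x - x'||^2 / h^2)`` with ``h`` the
  median of all pairwise Euclidean distances over distinct unordered sample
  pairs.  The exponent convention (no factor 2) is pinned by
  :data:`GAUSSIAN_EXPONENT_SCALE`; it is the convention under which the
  package's simulation study reproduces the reference rejection rates, and
  is equivalent to the common ``exp(-d^2 / median(d^2))`` form since the
  median commutes with squaring.
* All constructors symmetrize their output, ``K <- (K + K^t) / 2``, to
  absorb floating-point asymmetry.
* Missing values are rejected, never imputed.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "GAUSSIAN_EXPONENT_SCALE",
    "pairwise_sq_distances",
    "median_heuristic",
    "gaussian_kernel",
    "bray_curtis_dissimilarity",
    "bray_curtis_kernel",
    "double_center",
    "psd_project",
    "build_kernel",
]

#: The Gaussian kernel is exp(-d^2 / (GAUSSIAN_EXPONENT_SCALE * h^2)).
GAUSSIAN_EXPONENT_SCALE = 1.0

#: Relative eigenvalue tolerance used when checking / enforcing PSD-ness.
PSD_TOL = 1e-8


def _as_sample_matrix(X, name: str = "X") -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.ndim != 2:
        raise ValueError(f"{name} must be a 2-D samples-by-features matrix")
    if X.shape[0] < 2:
        raise ValueError(f"{name} needs at least 2 samples, got {X.shape[0]}")
    bad = ~np.isfinite(X)
    if bad.any():
        rows = np.unique(np.nonzero(bad)[0])
        raise ValueError(
            f"{name} contains non-finite values in row(s) {rows.tolist()[:5]}"
        )
    return X


def pairwise_sq_distances(X) -> np.ndarray:
    """Squared Euclidean distances between all sample pairs.

    Returns the symmetric N x N matrix with zero diagonal.  Computed via
    ``scipy.spatial.distance.pdist``; tiny negative round-off is clamped.
    """
    X = _as_sample_matrix(X)
    D2 = squareform(pdist(X, metric="sqeuclidean"))
    np.maximum(D2, 0.0, out=D2)
    return D2


def median_heuristic(X) -> float:
    """Median-heuristic kernel bandwidth.

    The median of the N(N-1)/2 pairwise Euclidean distances over unordered
    distinct sample pairs (self-pairs excluded).  For an even pair count
    this is the midpoint of the two central order statistics (the numpy
    median convention).

    Raises
    ------
    ValueError
        If all samples coincide: the median distance is then 0, which is
        not a usable bandwidth; supply one explicitly.
    """
    X = _as_sample_matrix(X)
    d = pdist(X, metric="euclidean")
    h = float(np.median(d))
    if h <= 0.0:
        raise ValueError(
            "median pairwise distance is 0 (all samples identical); "
            "supply an explicit bandwidth"
        )
    return h


def gaussian_kernel(X, bandwidth: float | None = None) -> np.ndarray:
    """Gaussian kernel matrix ``exp(-||x_i - x_j||^2 / h^2)``.

    With ``bandwidth=None`` the median heuristic is used.  The result has
    unit diagonal and is positive semi-definite by construction.
    """
    X = _as_sample_matrix(X)
    if bandwidth is None:
        bandwidth = median_heuristic(X)
    if not bandwidth > 0:
        raise ValueError(f"bandwidth must be positive, got {bandwidth}")
    K = np.exp(-pairwise_sq_distances(X) / (GAUSSIAN_EXPONENT_SCALE * bandwidth**2))
    np.fill_diagonal(K, 1.0)
    return (K + K.T) / 2.0


def bray_curtis_dissimilarity(X) -> np.ndarray:
    """Bray-Curtis dissimilarity matrix, d(i,j) = sum|x_i - x_j| / sum(x_i + x_j).

    Requires nonnegative entries and strictly positive row sums; values lie
    in [0, 1] with zero diagonal.
    """
    X = _as_sample_matrix(X)
    neg = np.nonzero((X < 0).any(axis=1))[0]
    if neg.size:
        raise ValueError(
            f"Bray-Curtis requires nonnegative abundances; sample row(s) "
            f"{neg.tolist()[:5]} contain negative entries"
        )
    zero = np.nonzero(X.sum(axis=1) <= 0)[0]
    if zero.size:
        raise ValueError(
            f"Bray-Curtis requires positive row sums; sample row(s) "
            f"{zero.tolist()[:5]} sum to zero"
        )
    D = squareform(pdist(X, metric="braycurtis"))
    np.clip(D, 0.0, 1.0, out=D)
    return D


def bray_curtis_kernel(X) -> np.ndarray:
    """Kernel matrix derived from Bray-Curtis dissimilarities.

    Follows standard kernel-machine practice for microbiome data: Gower
    double-centering of the squared dissimilarity matrix,
    ``K = -1/2 H D^2 H``, then projection to the PSD cone by clamping
    negative eigenvalues (Bray-Curtis is not Euclidean-embeddable in
    general, so the centered matrix can have small negative eigenvalues).
    """
    D = bray_curtis_dissimilarity(X)
    K = -0.5 * double_center(D**2)
    return psd_project(K)


def double_center(K) -> np.ndarray:
    """Double centering ``H K H`` with ``H = I - 11^t / n``.

    Makes all row and column sums zero; idempotent.
    """
    K = np.asarray(K, dtype=float)
    return K - K.mean(axis=0)[None, :] - K.mean(axis=1)[:, None] + K.mean()


def psd_project(K, tol: float = PSD_TOL) -> np.ndarray:
    """Nearest-PSD projection by clamping negative eigenvalues to zero.

    A no-op (to within ``tol`` times the largest eigenvalue) when the input
    is already PSD.  The output is exactly symmetric.
    """
    K = np.asarray(K, dtype=float)
    K = (K + K.T) / 2.0
    w, V = np.linalg.eigh(K)
    if w.size and w[0] >= -tol * max(w[-1], 0.0):
        return K
    Kp = (V * np.maximum(w, 0.0)) @ V.T
    return (Kp + Kp.T) / 2.0


def build_kernel(X, kind: str = "gaussian", bandwidth: float | None = None):
    """Build a kernel matrix by name.

    Returns ``(K, bandwidth)``; the bandwidth is None for kernels that do
    not use one.
    """
    if kind == "gaussian":
        if bandwidth is None:
            bandwidth = median_heuristic(X)
        return gaussian_kernel(X, bandwidth), bandwidth
    if kind in ("braycurtis", "bray-curtis", "bray_curtis"):
        return bray_curtis_kernel(X), None
    raise ValueError(f"unknown kernel {kind!r}; choose 'gaussian' or 'braycurtis'")
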