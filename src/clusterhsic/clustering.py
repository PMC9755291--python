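"""Cluster structure and block-averaging of kernel matrices.

With cluster-correlated samples (repeated measures, families) the
exchangeable units are clusters, not samples.  The sample-level N x N
kernel is collapsed to an m x m cluster-wise kernel by averaging each
between-cluster (and within-cluster) block of kernel values.  Collapse is
the congruence ``K_cl = M^t K M`` with a column-stochastic averaging matrix
M, so symmetry and positive semi-definiteness carry over exactly; diagonal
blocks average all l_a^2 entries including the kernel's own diagonal, which
is precisely what makes M's columns sum to one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ClusterAssignment", "collapse_kernel", "cluster_mean_features"]


@dataclass(frozen=True)
class ClusterAssignment:
    """Assignment of N samples to m clusters.

    ``cluster_ids`` preserves first-appearance order of the labels, which
    fixes the row/column order of every collapsed matrix.
    """

    labels: np.ndarray
    cluster_ids: np.ndarray = field(init=False)
    codes: np.ndarray = field(init=False)
    sizes: np.ndarray = field(init=False)

    def __post_init__(self):
        labels = np.asarray(self.labels)
        if labels.ndim != 1:
            raise ValueError("cluster labels must be a 1-D sequence")
        if labels.size == 0:
            raise ValueError("cluster labels are empty")
        ids, codes = np.unique(labels, return_inverse=True)
        # np.unique sorts; remap to first-appearance order
        first = np.array([np.argmax(codes == c) for c in range(ids.size)])
        order = np.argsort(first, kind="stable")
        rank = np.empty_like(order)
        rank[order] = np.arange(order.size)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "cluster_ids", ids[order])
        object.__setattr__(self, "codes", rank[codes])
        object.__setattr__(self, "sizes", np.bincount(rank[codes]))

    @property
    def n_samples(self) -> int:
        return self.labels.size

    @property
    def n_clusters(self) -> int:
        return self.cluster_ids.size

    def averaging_matrix(self) -> np.ndarray:
        """N x m matrix M with M[i, c] = 1/l_c for sample i in cluster c."""
        N, m = self.n_samples, self.n_clusters
        M = np.zeros((N, m))
        M[np.arange(N), self.codes] = 1.0 / self.sizes[self.codes]
        return M

    @classmethod
    def singletons(cls, n: int) -> "ClusterAssignment":
        return cls(np.arange(n))


def _check_alignment(n: int, clusters: ClusterAssignment, what: str) -> None:
    if clusters.n_samples != n:
        raise ValueError(
            f"cluster assignment covers {clusters.n_samples} samples but "
            f"{what} has {n} rows"
        )


def collapse_kernel(K, clusters: ClusterAssignment) -> np.ndarray:
    """Collapse an N x N kernel to the m x m cluster-wise kernel.

    Entry (a, b) is the arithmetic mean of the l_a x l_b block of K formed
    by the samples of clusters a and b; diagonal blocks include K's own
    diagonal entries.  PSD-ness of K is preserved (congruence with a
    nonnegative averaging matrix).
    """
    K = np.asarray(K, dtype=float)
    if K.ndim != 2 or K.shape[0] != K.shape[1]:
        raise ValueError("K must be a square kernel matrix")
    _check_alignment(K.shape[0], clusters, "the kernel matrix")
    M = clusters.averaging_matrix()
    Kcl = M.T @ K @ M
    return (Kcl + Kcl.T) / 2.0


def cluster_mean_features(X, clusters: ClusterAssignment) -> np.ndarray:
    """Per-cluster mean of each feature: the m x d matrix of cluster averages.

    Used by the cluster-mean baseline test, which averages the repeated
    observations of each cluster before computing kernels.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    _check_alignment(X.shape[0], clusters, "the feature matrix")
    out = np.zeros((clusters.n_clusters, X.shape[1]))
    np.add.at(out, clusters.codes, X)
    return out / clusters.sizes[:, None]
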