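"""Exact moments of the kernel trace statistic under the permutation null.

The statistic of interest is

    T(pi) = sum_{i,j} A[i, j] * B[pi(i), pi(j)] = trace(A P B P^t),

where ``A`` and ``B`` are symmetric k x k matrices (here: doubly centered
kernel matrices) and ``pi`` ranges uniformly over all k! permutations.
Moment-matching p-value approximations need the first three moments of T
exactly, not by Monte Carlo.

The raw moment E[T^r] expands into a sum over r index pairs
(i_1, j_1), ..., (i_r, j_r).  Because a uniform random permutation maps any
d distinct indices to a uniform ordered d-subset, the expectation of the
B-product depends only on the *coincidence pattern* of the 2r index slots,
i.e. on the set partition they induce.  Writing N_A(sigma) for the sum of
A-products over index assignments whose equality pattern is exactly sigma,
and (k)_d for the falling factorial with d = #blocks(sigma),

    E[T^r] = sum_sigma N_A(sigma) * N_B(sigma) / (k)_d .

The "exactly equal" sums N(sigma) follow from the unconstrained sums
M(sigma) (a tensor contraction, one einsum per pattern) by subtracting the
coarser patterns, coarsest first.  This is exact for every k and any pair of
symmetric matrices; no asymptotics are involved.

For doubly centered matrices every pattern with a block touching a single
slot contracts a row or column sum of A and therefore vanishes, which is
what makes the evaluation cheap (41 surviving patterns for the third
moment).  ``permutation_moments`` re-centers its inputs so this holds to
machine precision.
"""

from __future__ import annotations

import math
import string
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

__all__ = ["PermutationMoments", "permutation_moments", "raw_permutation_moment"]


@dataclass(frozen=True)
class PermutationMoments:
    """First three permutation-null moments of the kernel trace statistic.

    Attributes
    ----------
    mu : float
        Mean of T over all permutations.
    sigma2 : float
        Variance of T.  Zero flags a degenerate permutation distribution
        (e.g. a constant kernel); moment-matching p-values are then
        undefined.
    gamma : float
        Skewness of T (third central moment over sigma^3); set to 0.0 when
        the distribution is degenerate.
    """

    mu: float
    sigma2: float
    gamma: float

    @property
    def degenerate(self) -> bool:
        return not (self.sigma2 > 0.0)


def _set_partitions(n: int):
    """All set partitions of range(n), each a tuple of sorted tuples."""
    if n == 0:
        return [()]
    parts = [((0,),)]
    for item in range(1, n):
        grown = []
        for p in parts:
            for i in range(len(p)):
                grown.append(p[:i] + (p[i] + (item,),) + p[i + 1 :])
            grown.append(p + ((item,),))
        parts = grown
    return parts


def _is_coarser(q, p) -> bool:
    """True if partition q is strictly coarser than p (merges blocks of p)."""
    if len(q) >= len(p):
        return False
    qsets = [set(b) for b in q]
    return all(any(set(b) <= qs for qs in qsets) for b in p)


@lru_cache(maxsize=None)
def _moment_structure(r: int):
    """Pattern table for the r-th raw moment.

    Returns (partitions, subscripts, n_blocks, has_singleton, coarser)
    where ``coarser[i]`` lists indices of partitions strictly coarser than
    partition i, and partitions are ordered coarsest-first so the
    exact-coincidence sums can be computed by forward subtraction.
    """
    parts = _set_partitions(2 * r)
    parts.sort(key=len)
    letters = string.ascii_lowercase
    subscripts = []
    for p in parts:
        block_of = {}
        for bi, block in enumerate(p):
            for slot in block:
                block_of[slot] = letters[bi]
        subs = ",".join(block_of[2 * t] + block_of[2 * t + 1] for t in range(r))
        subscripts.append(subs + "->")
    n_blocks = [len(p) for p in parts]
    has_singleton = [any(len(b) == 1 for b in p) for p in parts]
    coarser = [
        [j for j in range(len(parts)) if _is_coarser(parts[j], parts[i])]
        for i in range(len(parts))
    ]
    return parts, subscripts, n_blocks, has_singleton, coarser


def _pattern_sums(K: np.ndarray, r: int, assume_centered: bool) -> np.ndarray:
    """Exact-coincidence sums N(sigma) of products of r entries of K."""
    _, subscripts, n_blocks, has_singleton, coarser = _moment_structure(r)
    k = K.shape[0]
    operands = [K] * r
    M = np.empty(len(subscripts))
    for i, subs in enumerate(subscripts):
        if assume_centered and has_singleton[i]:
            M[i] = 0.0
        else:
            M[i] = float(np.einsum(subs, *operands, optimize=True))
    N = np.empty_like(M)
    for i in range(len(M)):  # coarsest first
        N[i] = M[i] - sum(N[j] for j in coarser[i])
        if n_blocks[i] > k:
            N[i] = 0.0  # pattern needs more distinct indices than exist
    return N


def raw_permutation_moment(
    A: np.ndarray, B: np.ndarray, r: int, assume_centered: bool = False
) -> float:
    """Exact raw moment E[T^r] of T(pi) = trace(A P B P^t), r in {1, 2, 3}.

    ``assume_centered`` skips contractions that vanish for doubly centered
    inputs; leave False for arbitrary symmetric matrices.
    """
    if r not in (1, 2, 3):
        raise ValueError("only the first three moments are implemented")
    k = A.shape[0]
    parts, _, n_blocks, _, _ = _moment_structure(r)
    NA = _pattern_sums(A, r, assume_centered)
    NB = _pattern_sums(B, r, assume_centered)
    total = 0.0
    for i in range(len(parts)):
        d = n_blocks[i]
        if d > k:
            continue
        total += NA[i] * NB[i] / math.perm(k, d)
    return total


def permutation_moments(A: np.ndarray, B: np.ndarray) -> PermutationMoments:
    """Exact mean, variance and skewness of the permutation distribution.

    Parameters
    ----------
    A, B : (k, k) ndarray
        Doubly centered symmetric matrices (centering is re-applied
        defensively; it is idempotent).  ``k >= 4`` is required: with fewer
        exchangeable units the third-moment pattern sums degenerate and a
        three-moment approximation is meaningless.

    Returns
    -------
    PermutationMoments
        Exact functionals of A and B, not Monte Carlo estimates.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.shape != B.shape or A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError(
            f"A and B must be square matrices of equal size, got {A.shape} and {B.shape}"
        )
    k = A.shape[0]
    if k < 4:
        raise ValueError(
            f"permutation moments require at least 4 exchangeable units, got {k}"
        )
    # idempotent double centering; makes the singleton-pattern shortcut exact
    A = A - A.mean(axis=0) - A.mean(axis=1)[:, None] + A.mean()
    B = B - B.mean(axis=0) - B.mean(axis=1)[:, None] + B.mean()

    m1 = raw_permutation_moment(A, B, 1, assume_centered=True)
    m2 = raw_permutation_moment(A, B, 2, assume_centered=True)
    m3 = raw_permutation_moment(A, B, 3, assume_centered=True)

    var = m2 - m1 * m1
    m3c = m3 - 3.0 * m1 * m2 + 2.0 * m1**3
    if var > 0.0:
        gamma = m3c / var**1.5
    else:
        var = max(var, 0.0)
        gamma = 0.0
    return PermutationMoments(mu=m1, sigma2=var, gamma=gamma)
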