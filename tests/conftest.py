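import itertools

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    max_examples=25,
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def center(M):
    """Double centering, written independently of the package."""
    return M - M.mean(axis=0) - M.mean(axis=1)[:, None] + M.mean()


def random_centered_pair(rng, k):
    """A pair of random doubly centered symmetric k x k matrices."""
    out = []
    for _ in range(2):
        M = rng.normal(size=(k, k))
        M = (M + M.T) / 2.0
        out.append(center(M))
    return out


def all_permutation_stats(A, B):
    """T(pi) = sum_ij A_ij B_pi(i)pi(j) for every one of the k! permutations."""
    k = A.shape[0]
    perms = np.array(list(itertools.permutations(range(k))))
    return np.einsum("ij,pij->p", A, B[perms[:, :, None], perms[:, None, :]])


def enumeration_moments(A, B):
    """Exact permutation mean/variance/skewness by brute-force enumeration."""
    T = all_permutation_stats(A, B)
    mu = T.mean()
    var = ((T - mu) ** 2).mean()
    m3c = ((T - mu) ** 3).mean()
    gamma = m3c / var**1.5 if var > 0 else 0.0
    return mu, var, gamma


def hsic_vstat_quadruple_loop(KX, KY):
    """The V-statistic expansion of the empirical HSIC, by literal loops.

    HSIC = (1/N^2) sum_ij kx_ij ky_ij + (1/N^4) sum_ijuv kx_ij ky_uv
           - (2/N^3) sum_iju kx_ij ky_iu
    """
    N = KX.shape[0]
    t1 = t2 = t3 = 0.0
    for i in range(N):
        for j in range(N):
            t1 += KX[i, j] * KY[i, j]
    for i in range(N):
        for j in range(N):
            for u in range(N):
                t3 += KX[i, j] * KY[i, u]
                for v in range(N):
                    t2 += KX[i, j] * KY[u, v]
    return t1 / N**2 + t2 / N**4 - 2.0 * t3 / N**3
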