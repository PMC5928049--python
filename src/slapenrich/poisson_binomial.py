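"""Exact Poisson-binomial distribution.

The number of successes among ``M`` independent Bernoulli trials with
heterogeneous success probabilities ``pi = (p_1, ..., p_M)`` follows the
Poisson-binomial distribution.  It is the null distribution of the number of
cohort samples altered in a pathway, with ``p_j`` the per-sample chance
alteration probability.

The PMF is computed exactly by iterative convolution (dynamic programming):
starting from the point mass at zero, each trial convolves the current PMF
with its two-point Bernoulli distribution.  This is O(M^2), exact and
numerically stable for the cohort sizes met in practice (hundreds to a few
thousand samples); no normal or saddlepoint approximation is used.  A
subset-enumeration oracle (feasible for M <= 16) implements the defining
sum over all success subsets and is used for cross-validation.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

__all__ = ["pb_pmf", "pb_tail", "pb_enumerate_oracle", "PoissonBinomialDist"]

_MAX_ENUM = 16


def _check_probs(pi: np.ndarray) -> np.ndarray:
    pi = np.asarray(pi, dtype=np.float64).ravel()
    if pi.size and (np.isnan(pi).any() or pi.min() < 0.0 or pi.max() > 1.0):
        raise ValueError("trial probabilities must lie in [0, 1]")
    return pi


def pb_pmf(pi) -> np.ndarray:
    """Exact PMF over the support {0, ..., M} via iterative convolution."""
    pi = _check_probs(pi)
    m = pi.size
    pmf = np.zeros(m + 1, dtype=np.float64)
    pmf[0] = 1.0
    for t, p in enumerate(pi, start=1):
        # support so far is 0..t-1; convolve with Bernoulli(p)
        pmf[1 : t + 1] = pmf[1 : t + 1] * (1.0 - p) + pmf[0:t] * p
        pmf[0] *= 1.0 - p
    np.clip(pmf, 0.0, None, out=pmf)
    return pmf


def pb_tail(pi, z: int) -> float:
    """Upper tail Pr(O >= z).

    Summed in ascending order of magnitude to limit cancellation; the result
    is clamped to [0, 1].  ``z = 0`` returns exactly 1.
    """
    pi = _check_probs(pi)
    m = pi.size
    if not float(z).is_integer():
        raise ValueError("z must be an integer")
    z = int(z)
    if z < 0 or z > m:
        raise ValueError(f"z={z} outside support 0..{m}")
    if z == 0:
        return 1.0
    tail = float(np.sort(pb_pmf(pi)[z:]).sum())
    return min(max(tail, 0.0), 1.0)


def pb_enumerate_oracle(pi) -> np.ndarray:
    """PMF by explicit enumeration of all success subsets.

    For each count ``y``, sums prod(p over A) * prod(1-p over complement)
    across every subset ``A`` of ``y`` trials.  Exponential in M; refuses
    M > 16.
    """
    pi = _check_probs(pi)
    m = pi.size
    if m > _MAX_ENUM:
        raise ValueError(f"enumeration oracle limited to M <= {_MAX_ENUM}")
    q = 1.0 - pi
    pmf = np.zeros(m + 1, dtype=np.float64)
    idx = range(m)
    for y in range(m + 1):
        total = 0.0
        for subset in combinations(idx, y):
            chosen = set(subset)
            prob = 1.0
            for j in idx:
                prob *= pi[j] if j in chosen else q[j]
            total += prob
        pmf[y] = total
    return pmf


@dataclass
class PoissonBinomialDist:
    """A Poisson-binomial distribution with precomputed PMF."""

    pi: np.ndarray

    def __post_init__(self) -> None:
        self.pi = _check_probs(self.pi)
        self.pmf = pb_pmf(self.pi)

    @property
    def mean(self) -> float:
        return float(self.pi.sum())

    def tail(self, z: int) -> float:
        return pb_tail(self.pi, z)
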