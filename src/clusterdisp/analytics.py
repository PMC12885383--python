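"""Closed-form predictions for assembly under cluster dispersal.

All functions here are pure.  Regime applicability mirrors the piecewise
theory: the low-dispersal expressions assume the community is seeded by a
single cluster and then filled by replication (``c`` well below
``r / (2 ln K)``), the high-dispersal ones assume dispersal dominates
(``c`` well above ``r``).  Enforcing the regime is the caller's business.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "mean_contributing_clusters",
    "bc_low_dispersal",
    "bc_high_dispersal",
    "mean_abundance_low_dispersal",
    "RichnessPMF",
    "richness_pmf",
    "richness_pmf_exact",
    "monochromatic_probability",
    "SharedSpeciesPMF",
    "shared_species_pmf",
    "mean_jaccard",
]

# exact integer arithmetic is used up to this cluster size; beyond it the
# k^n terms are evaluated in log space
_EXACT_N_MAX = 500


def mean_contributing_clusters(c: float, r: float, K: float, n: int) -> float:
    """Mean number of clusters contributing to assembly, (c/r) log(1 + rK/(nc)).

    Valid beyond the low-dispersal regime; in the low-dispersal limit the
    community is seeded by a single cluster and the mean is simply 1.  The
    mean number of immigrating individuals is ``n`` times this value.  The
    expression is asymptotic: relative to the exact jump-chain expectation
    it carries an O(1) negative offset (about 0.5 cluster for n = 1) that
    shrinks only in relative terms as the count grows.
    """
    if c <= 0:
        raise ValueError("dispersal rate c must be > 0")
    if r <= 0:
        raise ValueError("replication rate r must be > 0")
    if K < 1 or n < 1:
        raise ValueError("K and n must be >= 1")
    return (c / r) * math.log1p(r * K / (n * c))


def bc_low_dispersal(n: int, pA: float) -> float:
    """Bimodality coefficient of the abundance fluctuation distribution
    in the low-dispersal regime (K >> 1).

    The community composition is set by the single founding cluster, whose
    A-count is Binomial(n, pA), amplified by neutral replication.  The
    result depends only on ``n`` and ``pA``, not on ``K``.  At ``pA = 1/2``
    it reduces to ``(n+2)(n+3) / (3 (n+1)^2)``, which spans 1 at ``n = 1``
    down to 1/3 as ``n`` grows.
    """
    if n < 1:
        raise ValueError("cluster size n must be >= 1")
    if not 0.0 < pA < 1.0:
        raise ValueError("BC is undefined for a single-species pool (pA must be in (0,1))")
    v = (pA - 1.0) * pA  # = -pA(1-pA)
    num = (n + 2.0) * (n + 3.0) * v * (
        1.0 - 9.0 * (n + 1.0) * (1.0 - 2.0 * pA) ** 2 / (2.0 * (n + 2.0) ** 2 * v)
    )
    den = 3.0 * (n + 1.0) * ((n - 7.0) * v - 2.0)
    return num / den


def bc_high_dispersal() -> float:
    """Bimodality coefficient in the high-dispersal regime: exactly 1/3."""
    return 1.0 / 3.0


def mean_abundance_low_dispersal(s: float, pA: float, K: int, n: int) -> float:
    """Mean absolute abundance of species A at completion, low-dispersal regime.

    ``pA K (1 + n + (-1 + n + pA - n pA) s log(K/n)) / (n + 1)``, valid to
    first order in the selection coefficient ``s = rA - rB`` (|s| << 1).
    At ``s = 0``, or at ``n = 1`` or ``n = K`` for any ``s``, this is
    ``pA K``; for ``s != 0`` it is non-monotone in ``n`` with an extremum
    at intermediate cluster sizes.  The mean relative abundance is this
    value divided by ``K``.
    """
    if n < 1:
        raise ValueError("cluster size n must be >= 1")
    if n > K:
        raise ValueError(f"cluster size n={n} exceeds carrying capacity K={K}")
    return (
        pA * K * (1.0 + n + (-1.0 + n + pA - n * pA) * s * math.log(K / n)) / (n + 1.0)
    )


def monochromatic_probability(n: int, p: Sequence[float]) -> float:
    """Probability that a cluster of size ``n`` contains a single species.

    Equal to ``sum_i p_i^n``; for ``pA = 1/2`` this is 1/2 at ``n = 2``
    and 1/512 at ``n = 10``.
    """
    if n < 1:
        raise ValueError("cluster size n must be >= 1")
    return float(sum(float(x) ** n for x in p))


# -- richness of a single cluster (equal pool abundances) ------------------


def _surjections(n: int, a: int) -> int:
    """Number of ways to distribute n labelled balls onto a labelled boxes
    with no box empty: sum_{k=1..a} (-1)^(a-k) C(a,k) k^n."""
    return sum((-1) ** (a - k) * math.comb(a, k) * k**n for k in range(1, a + 1))


def richness_pmf_exact(n: int, S: int) -> list[Fraction]:
    """Exact richness pmf of one cluster as Fractions, index alpha = 1..S.

    Big-integer arithmetic; intended for moderate ``n`` (the float path in
    :func:`richness_pmf` switches to log space beyond ``_EXACT_N_MAX``).
    """
    total = Fraction(S) ** n
    out = []
    for a in range(1, S + 1):
        if a > min(n, S):
            out.append(Fraction(0))
        else:
            out.append(Fraction(math.comb(S, a) * _surjections(n, a)) / total)
    return out


@dataclass(frozen=True)
class RichnessPMF:
    """Distribution of the number of distinct species in one cluster."""

    S: int
    n: int
    pmf: np.ndarray  # index alpha-1, alpha = 1..S

    @property
    def mean(self) -> float:
        return float(np.dot(np.arange(1, self.S + 1), self.pmf))


def richness_pmf(n: int, S: int) -> RichnessPMF:
    """Richness distribution of a cluster of size ``n`` from ``S`` equally
    abundant species: P(alpha) = C(S, alpha) * Surj(n, alpha) / S^n.

    Uses exact integer arithmetic for moderate ``n``; beyond that the
    alternating ``k^n`` sums cancel catastrophically in floats, so the pmf
    is instead propagated through the occupancy Markov chain (each added
    individual occupies a new species with probability ``(S - alpha)/S``),
    which involves only non-negative terms.
    """
    if n < 1 or S < 1:
        raise ValueError("n and S must be >= 1")
    if n <= _EXACT_N_MAX:
        pmf = np.array([float(x) for x in richness_pmf_exact(n, S)])
    else:
        occ = np.zeros(S + 1)
        occ[0] = 1.0
        alpha = np.arange(S + 1, dtype=float)
        stay = alpha / S
        grow = (S - alpha[:-1]) / S
        for _ in range(n):
            nxt = occ * stay
            nxt[1:] += occ[:-1] * grow
            occ = nxt
        pmf = occ[1:]
    return RichnessPMF(S=S, n=n, pmf=pmf)


# -- species shared by two independently seeded communities ----------------


@dataclass(frozen=True)
class SharedSpeciesPMF:
    """Approximate distribution of the number of species shared by the
    founding clusters of two communities (independent Bernoulli presence
    per species with probability ``q``)."""

    S: int
    n: int
    q: float
    pmf: np.ndarray  # index k = 0..S

    @property
    def mean(self) -> float:
        """S * q; exact even though the binomial shape is approximate."""
        return self.S * self.q


def shared_species_pmf(n: int, S: int) -> SharedSpeciesPMF:
    """Binomial(S, q) approximation with q = (1 - (1 - 1/S)^n)^2.

    ``q`` is the exact probability that a given species appears in both of
    two independent clusters; treating species as independent makes the
    count Binomial.  The mean ``S q`` is exact, the shape approximate
    (within-cluster presences are negatively correlated).
    """
    if n < 1 or S < 1:
        raise ValueError("n and S must be >= 1")
    q = (1.0 - (1.0 - 1.0 / S) ** n) ** 2
    pmf = stats.binom.pmf(np.arange(S + 1), S, q)
    return SharedSpeciesPMF(S=S, n=n, q=q, pmf=pmf)


def mean_jaccard(n: int, S: int) -> float:
    """Mean pairwise Jaccard distance between communities in the
    low-dispersal regime.

    For ``n = 1`` the exact value ``1 - 1/S`` is returned (each community
    holds one uniformly chosen species).  Otherwise the approximation
    ``1 - <k> / (2 <alpha_R> - <k>)`` is used, with ``<alpha_R>`` the mean
    cluster richness and ``<k> = S q`` the mean number of shared species.
    Decreases from ``1 - 1/S`` toward 0 as clusters grow.
    """
    if n < 1 or S < 1:
        raise ValueError("n and S must be >= 1")
    if n == 1:
        return 1.0 - 1.0 / S
    mean_rich = richness_pmf(n, S).mean
    mean_shared = shared_species_pmf(n, S).mean
    return 1.0 - mean_shared / (2.0 * mean_rich - mean_shared)
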