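import itertools
import math
from fractions import Fraction

import numpy as np
import pytest
from scipy import stats

from clusterdisp import analytics
from conftest import exact_mean_dispersal_events


# -- independent oracles ---------------------------------------------------


def bc_from_beta_mixture(n: int, pA: float) -> float:
    """Population BC of the low-dispersal abundance fluctuation
    distribution, derived independently of the closed form: the founding
    cluster carries a ~ Binomial(n, pA) individuals of A, and under
    neutral replication the final fraction converges (K -> inf) to
    Beta(a, n - a), with atoms at 0 and 1 for monochromatic clusters.
    BC follows from the mixture's first four moments."""

    def moment(m):
        tot = 0.0
        for a in range(n + 1):
            w = math.comb(n, a) * pA**a * (1 - pA) ** (n - a)
            prod = 1.0
            for j in range(m):
                prod *= (a + j) / (n + j)
            tot += w * prod
        return tot

    m1, m2, m3, m4 = (moment(m) for m in (1, 2, 3, 4))
    mu2 = m2 - m1**2
    mu3 = m3 - 3 * m1 * m2 + 2 * m1**3
    mu4 = m4 - 4 * m1 * m3 + 6 * m1**2 * m2 - 3 * m1**4
    g = mu3 / mu2**1.5
    kappa = mu4 / mu2**2 - 3.0
    return (g * g + 1.0) / (kappa + 3.0)


def occupancy_chain_pmf(n: int, S: int) -> list[Fraction]:
    """Exact richness pmf via the occupancy Markov chain: adding one
    individual occupies a new species with probability (S - alpha)/S."""
    probs = {0: Fraction(1)}
    for _ in range(n):
        nxt: dict[int, Fraction] = {}
        for a, w in probs.items():
            nxt[a] = nxt.get(a, Fraction(0)) + w * Fraction(a, S)
            nxt[a + 1] = nxt.get(a + 1, Fraction(0)) + w * Fraction(S - a, S)
        probs = nxt
    return [probs.get(a, Fraction(0)) for a in range(1, S + 1)]


def exact_shared_species_pmf(n: int, S: int) -> list[Fraction]:
    """Exact law of the number of species present in both of two
    independent clusters, by enumeration over presence patterns."""
    comps = []

    def rec(prefix, rem, left):
        if left == 1:
            comps.append(tuple(prefix) + (rem,))
            return
        for k in range(rem + 1):
            rec(prefix + [k], rem - k, left - 1)

    rec([], n, S)
    presence: dict[tuple, Fraction] = {}
    denom = Fraction(S) ** n
    for comp in comps:
        w = Fraction(math.factorial(n)) / math.prod(
            math.factorial(x) for x in comp
        ) / denom
        key = tuple(1 if x > 0 else 0 for x in comp)
        presence[key] = presence.get(key, Fraction(0)) + w
    pmf = [Fraction(0)] * (S + 1)
    for a, wa in presence.items():
        for b, wb in presence.items():
            k = sum(x & y for x, y in zip(a, b))
            pmf[k] += wa * wb
    return pmf


# -- mean contributing clusters -------------------------------------------


class TestMeanContributingClusters:
    def test_direct_evaluation(self):
        assert analytics.mean_contributing_clusters(1, 1, 1e5, 1) == pytest.approx(
            math.log(1 + 1e5), rel=1e-12
        )

    def test_all_dispersal_limit_is_K_over_n(self):
        # c -> inf: log(1 + x) ~ x so mcluster -> K/n
        assert analytics.mean_contributing_clusters(1e12, 1, 1e5, 10) == pytest.approx(
            1e4, rel=1e-6
        )

    def test_decreasing_in_cluster_size(self):
        vals = [analytics.mean_contributing_clusters(1.0, 1.0, 1e5, n) for n in (1, 2, 10, 100)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    @pytest.mark.parametrize("bad", [dict(c=0), dict(r=0), dict(c=-1)])
    def test_nonpositive_rates_rejected(self, bad):
        kwargs = dict(c=1.0, r=1.0, K=1000, n=1)
        kwargs.update(bad)
        with pytest.raises(ValueError):
            analytics.mean_contributing_clusters(**kwargs)

    @pytest.mark.parametrize("c,n", [(1.0, 1), (1.0, 10), (10.0, 1), (100.0, 10)])
    def test_matches_exact_jump_chain_beyond_low_dispersal(self, c, n):
        """The closed form is asymptotic; beyond the low-dispersal regime
        it tracks the exact jump-chain expectation to within ~10%."""
        exact, _ = exact_mean_dispersal_events(c, 1.0, 1000, n)
        approx = analytics.mean_contributing_clusters(c, 1.0, 1000, n)
        assert approx == pytest.approx(exact, rel=0.10)


# -- bimodality coefficient closed forms -----------------------------------


class TestBCClosedForms:
    def test_boundary_values(self):
        assert analytics.bc_low_dispersal(1, 0.5) == pytest.approx(1.0, abs=1e-12)
        assert analytics.bc_low_dispersal(2, 0.5) == pytest.approx(20 / 27, rel=1e-12)
        assert abs(analytics.bc_low_dispersal(10**6, 0.5) - 1 / 3) < 1e-5
        assert analytics.bc_high_dispersal() == pytest.approx(1 / 3)

    def test_symmetric_pool_reduction(self):
        # general expression collapses to (n+2)(n+3)/(3(n+1)^2) at pA=1/2
        for n in range(1, 201):
            reduced = (n + 2) * (n + 3) / (3.0 * (n + 1) ** 2)
            assert abs(analytics.bc_low_dispersal(n, 0.5) - reduced) < 1e-12

    @pytest.mark.parametrize(
        "n,pA", [(1, 0.5), (2, 0.5), (5, 0.3), (3, 0.25), (20, 0.7), (50, 0.9)]
    )
    def test_matches_beta_mixture_oracle(self, n, pA):
        assert analytics.bc_low_dispersal(n, pA) == pytest.approx(
            bc_from_beta_mixture(n, pA), rel=1e-9
        )

    def test_strictly_decreasing_and_bounded(self):
        vals = [analytics.bc_low_dispersal(n, 0.5) for n in range(1, 201)]
        assert all(a > b for a, b in zip(vals, vals[1:]))
        assert all(1 / 3 < v <= 1.0 for v in vals)

    @pytest.mark.parametrize("pA", [0.0, 1.0])
    def test_single_species_pool_rejected(self, pA):
        with pytest.raises(ValueError):
            analytics.bc_low_dispersal(5, pA)


# -- mean abundance under selection ----------------------------------------


class TestMeanAbundanceLowDispersal:
    @pytest.mark.parametrize("n", [1, 2, 10, 100, 1000])
    def test_neutral_value_is_pool_abundance(self, n):
        assert analytics.mean_abundance_low_dispersal(0.0, 0.3, 100_000, n) == pytest.approx(
            0.3 * 100_000
        )

    @pytest.mark.parametrize("s", [-0.05, 0.0, 0.05])
    def test_single_individual_cluster_is_neutral(self, s):
        # n = 1: the lone founder fixes regardless of replication rates
        assert analytics.mean_abundance_low_dispersal(s, 0.5, 100_000, 1) == pytest.approx(50_000)

    def test_cluster_of_size_K_is_neutral(self):
        # log(K/n) vanishes at n = K
        assert analytics.mean_abundance_low_dispersal(-0.05, 0.5, 1000, 1000) == pytest.approx(500)

    def test_linear_in_selection_coefficient(self):
        f = lambda s: analytics.mean_abundance_low_dispersal(s, 0.4, 10_000, 7)
        assert f(0.02) - f(0.0) == pytest.approx(f(0.0) - f(-0.02), rel=1e-9)

    def test_deleterious_species_dips_below_half_at_intermediate_n(self):
        K = 100_000
        rel = [analytics.mean_abundance_low_dispersal(-0.05, 0.5, K, n) / K for n in range(1, 1000)]
        assert min(rel) < 0.5
        assert rel[0] == pytest.approx(0.5)  # n = 1

    def test_cluster_larger_than_K_rejected(self):
        with pytest.raises(ValueError):
            analytics.mean_abundance_low_dispersal(0.0, 0.5, 100, 101)


# -- cluster richness and monochromatic clusters ---------------------------


class TestRichnessPMF:
    def test_single_individual(self):
        pmf = analytics.richness_pmf(1, 5)
        assert pmf.pmf[0] == pytest.approx(1.0)
        assert pmf.mean == pytest.approx(1.0)

    def test_two_species_pair(self):
        pmf = analytics.richness_pmf(2, 2)
        assert pmf.pmf == pytest.approx([0.5, 0.5])

    def test_literal_enumeration_three_cubed(self):
        # all 27 equally likely assignments of 3 individuals to 3 species
        counts = [0, 0, 0]
        for assign in itertools.product(range(3), repeat=3):
            counts[len(set(assign)) - 1] += 1
        pmf = analytics.richness_pmf(3, 3)
        assert pmf.pmf == pytest.approx([c / 27 for c in counts], abs=1e-14)

    def test_sums_to_one_and_support(self):
        for n, S in [(4, 9), (12, 3), (2, 6)]:
            pmf = analytics.richness_pmf(n, S)
            assert pmf.pmf.sum() == pytest.approx(1.0, abs=1e-12)
            assert np.all(pmf.pmf[min(n, S):] == 0.0)

    def test_log_space_branch_matches_exact(self):
        # n = 501 exceeds the exact-arithmetic bound, so the public
        # function takes the signed log-space path; S = 200 keeps the
        # distribution non-degenerate there
        exact = [float(x) for x in analytics.richness_pmf_exact(501, 200)]
        big = analytics.richness_pmf(501, 200)
        assert big.pmf.sum() == pytest.approx(1.0)
        assert big.pmf == pytest.approx(exact, abs=1e-9)
        assert big.mean == pytest.approx(
            200 * (1 - (1 - 1 / 200) ** 501), rel=1e-9
        )


class TestMonochromaticProbability:
    @pytest.mark.parametrize(
        "n,p,expected",
        [
            (2, (0.5, 0.5), 0.5),
            (10, (0.5, 0.5), 1 / 512),
            (1, (0.2, 0.8), 1.0),
            (4, (1 / 3, 1 / 3, 1 / 3), 1 / 27),
        ],
    )
    def test_power_sum(self, n, p, expected):
        assert analytics.monochromatic_probability(n, p) == pytest.approx(expected, rel=1e-12)

    def test_enumeration_cross_check(self):
        # brute force over 3^4 assignments with equal pool abundances
        mono = sum(
            1 for a in itertools.product(range(3), repeat=4) if len(set(a)) == 1
        ) / 3**4
        assert analytics.monochromatic_probability(4, (1 / 3,) * 3) == pytest.approx(mono)


# -- shared species and Jaccard --------------------------------------------


class TestSharedSpeciesPMF:
    def test_presence_probability_limits(self):
        assert analytics.shared_species_pmf(500, 7).q == pytest.approx(1.0)
        one = analytics.shared_species_pmf(1, 7)
        assert one.q == pytest.approx(1 / 49)
        assert one.mean == pytest.approx(1 / 7)

    def test_mean_is_exact_despite_approximate_shape(self):
        # S*q equals the exact enumeration mean; the binomial shape is the
        # documented independence approximation (TV ~ 0.15 at n=5, S=7)
        exact = exact_shared_species_pmf(5, 7)
        exact_mean = float(sum(k * p for k, p in enumerate(exact)))
        approx = analytics.shared_species_pmf(5, 7)
        assert approx.mean == pytest.approx(exact_mean, abs=1e-12)
        tv = 0.5 * sum(abs(float(e) - a) for e, a in zip(exact, approx.pmf))
        assert tv < 0.2

    def test_pmf_is_binomial(self):
        out = analytics.shared_species_pmf(3, 5)
        assert out.pmf == pytest.approx(stats.binom.pmf(np.arange(6), 5, out.q))
        assert out.pmf.sum() == pytest.approx(1.0)


class TestMeanJaccard:
    def test_exact_single_individual_case(self):
        assert analytics.mean_jaccard(1, 7) == pytest.approx(6 / 7)
        assert analytics.mean_jaccard(1, 3) == pytest.approx(2 / 3)

    def test_vanishes_for_huge_clusters(self):
        assert analytics.mean_jaccard(2000, 7) == pytest.approx(0.0, abs=1e-6)

    def test_nonincreasing_in_cluster_size(self):
        vals = [analytics.mean_jaccard(n, 7) for n in (1, 2, 3, 5, 10, 20, 50, 100)]
        assert all(a >= b - 1e-12 for a, b in zip(vals, vals[1:]))
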