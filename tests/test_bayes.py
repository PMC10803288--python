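"""Beta-Binomial primitives: conjugate updates, superiority, tails, exact CIs."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, special, stats

from aftrial.bayes import (
    ArmCounts,
    BetaParams,
    UNIFORM_PRIOR,
    exact_binomial_ci,
    posterior_update,
    prob_exceeds,
    prob_superiority,
    round_half_away,
)


class TestPosteriorUpdate:
    @pytest.mark.parametrize(
        "counts, expected",
        [
            (ArmCounts(n=0, x=0), (1, 1)),      # no data leaves the prior
            (ArmCounts(n=22, x=12), (13, 11)),
            (ArmCounts(n=25, x=0), (1, 26)),
        ],
    )
    def test_conjugate_identity(self, counts, expected):
        post = posterior_update(UNIFORM_PRIOR, counts)
        assert (post.alpha, post.beta) == expected

    def test_inputs_not_mutated(self):
        prior = BetaParams(2.0, 3.0)
        posterior_update(prior, ArmCounts(n=5, x=2))
        assert (prior.alpha, prior.beta) == (2.0, 3.0)

    @pytest.mark.parametrize("n, x", [(3, 5), (-1, 0), (2, -1)])
    def test_invalid_counts_rejected(self, n, x):
        with pytest.raises(ValueError):
            ArmCounts(n=n, x=x)

    def test_invalid_shapes_rejected(self):
        with pytest.raises(ValueError):
            BetaParams(0.0, 1.0)


class TestProbSuperiority:
    def test_identical_posteriors_give_half(self):
        b = BetaParams(13, 11)
        assert prob_superiority(b, b) == pytest.approx(0.5, abs=1e-12)

    def test_observed_counts_exceed_999(self):
        # 12/22 active vs 0/25 pooled placebo under uniform priors
        p = prob_superiority(BetaParams(13, 11), BetaParams(1, 26))
        assert p > 0.999

    def test_matches_beta_function_closed_form(self):
        # comparator Beta(1,b): P(p_c >= p_a) = E[(1-p_a)^b], a Beta ratio
        expected = 1.0 - special.beta(6, 8 + 26) / special.beta(6, 8)
        assert prob_superiority(BetaParams(6, 8), BetaParams(1, 26)) == pytest.approx(
            expected, abs=1e-12
        )
        assert expected == pytest.approx(0.99947, abs=5e-6)

    def test_matches_monte_carlo(self):
        rng = np.random.default_rng(20230913)
        n = 10**7
        draws_a = rng.beta(6, 8, n)
        draws_c = rng.beta(1, 26, n)
        mc = float(np.mean(draws_a > draws_c))
        se = np.sqrt(mc * (1 - mc) / n)
        assert prob_superiority(BetaParams(6, 8), BetaParams(1, 26)) == pytest.approx(
            mc, abs=3 * se
        )

    @pytest.mark.parametrize(
        "active, comparator",
        [((5, 5), (3, 7)), ((40, 70), (12, 30)), ((13, 11), (2, 26))],
    )
    def test_integer_sum_agrees_with_independent_quadrature(self, active, comparator):
        a1, b1 = active
        a2, b2 = comparator

        def integrand(q):
            return stats.beta.pdf(q, a1, b1) * stats.beta.cdf(q, a2, b2)

        oracle, _ = integrate.quad(integrand, 0, 1, epsabs=1e-13, limit=300)
        assert prob_superiority(BetaParams(a1, b1), BetaParams(a2, b2)) == pytest.approx(
            oracle, abs=1e-9
        )

    def test_noninteger_shapes_use_quadrature_and_match_mc(self):
        rng = np.random.default_rng(7)
        n = 10**6
        mc = float(np.mean(rng.beta(4.5, 6.2, n) > rng.beta(2.3, 7.7, n)))
        se = np.sqrt(mc * (1 - mc) / n)
        p = prob_superiority(BetaParams(4.5, 6.2), BetaParams(2.3, 7.7), tolerance=1e-9)
        assert p == pytest.approx(mc, abs=3 * se)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        a1=st.integers(1, 60), b1=st.integers(1, 60),
        a2=st.integers(1, 60), b2=st.integers(1, 60),
    )
    def test_complement_identity(self, a1, b1, a2, b2):
        # ties have measure zero for continuous variates
        x, y = BetaParams(a1, b1), BetaParams(a2, b2)
        assert prob_superiority(x, y) + prob_superiority(y, x) == pytest.approx(
            1.0, abs=2e-10
        )

    def test_monotone_in_active_successes(self):
        comparator = BetaParams(1, 26)
        probs = [
            prob_superiority(posterior_update(UNIFORM_PRIOR, ArmCounts(n=22, x=x)), comparator)
            for x in range(23)
        ]
        assert all(b >= a for a, b in zip(probs, probs[1:]))

    def test_invalid_tolerance(self):
        with pytest.raises(ValueError):
            prob_superiority(BetaParams(1, 1), BetaParams(1, 1), tolerance=0.0)


class TestProbExceeds:
    def test_uniform_tail(self):
        assert prob_exceeds(BetaParams(1, 1), 0.65) == pytest.approx(0.35, abs=1e-12)

    def test_binomial_tail_identity_single(self):
        # I_t(a, b) = P(Bin(a+b-1, t) >= a), so P(p > 0.65) = P(Bin(13, 0.65) <= 5)
        oracle = sum(
            special.comb(13, k) * 0.65**k * 0.35 ** (13 - k) for k in range(6)
        )
        assert prob_exceeds(BetaParams(6, 8), 0.65) == pytest.approx(oracle, abs=1e-12)
        assert oracle == pytest.approx(0.04620106984183905, abs=1e-12)

    def test_alpha_one_closed_form(self):
        assert prob_exceeds(BetaParams(1, 26), 0.65) == pytest.approx(0.35**26, rel=1e-9)

    def test_binomial_tail_identity_grid(self):
        thresholds = np.arange(0.1, 0.95, 0.1)
        for a in range(1, 21):
            for b in range(1, 21):
                post = BetaParams(a, b)
                n = a + b - 1
                for t in thresholds:
                    oracle = float(stats.binom.cdf(a - 1, n, t))
                    assert abs(prob_exceeds(post, t) - oracle) < 1e-9

    @pytest.mark.parametrize("t", [0.0, 1.0, -0.2, 1.5])
    def test_threshold_domain(self, t):
        with pytest.raises(ValueError):
            prob_exceeds(BetaParams(2, 2), t)


class TestExactBinomialCI:
    @pytest.mark.parametrize(
        "x, n, lower, upper",
        [
            (0, 25, 0.0, 0.1372), (5, 12, 0.1517, 0.7233), (12, 22, 0.3221, 0.7561),
        ],
    )
    def test_reported_intervals(self, x, n, lower, upper):
        ci = exact_binomial_ci(ArmCounts(n=n, x=x))
        assert ci.lower == pytest.approx(lower, abs=5e-5)
        assert ci.upper == pytest.approx(upper, abs=5e-5)

    def test_zero_successes_closed_form(self):
        ci = exact_binomial_ci(ArmCounts(n=25, x=0))
        assert ci.lower == 0.0
        assert ci.upper == pytest.approx(1 - 0.025 ** (1 / 25), rel=1e-12)

    @pytest.mark.parametrize(
        "x, n, pct", [(0, 25, (0, 14)), (5, 12, (15, 72)), (12, 22, (32, 76))]
    )
    def test_percent_rounding(self, x, n, pct):
        assert exact_binomial_ci(ArmCounts(n=n, x=x)).as_percent() == pct

    def test_statsmodels_cross_check(self):
        from statsmodels.stats.proportion import proportion_confint

        for x, n in [(0, 25), (5, 12), (12, 22), (7, 7), (3, 30)]:
            lo, hi = proportion_confint(x, n, alpha=0.05, method="beta")
            ci = exact_binomial_ci(ArmCounts(n=n, x=x))
            assert ci.lower == pytest.approx(0.0 if np.isnan(lo) else lo, abs=1e-10)
            assert ci.upper == pytest.approx(1.0 if np.isnan(hi) else hi, abs=1e-10)

    def test_coverage_at_least_nominal(self):
        # brute-force binomial coverage over all x for n <= 30 and a p grid
        level = 0.95
        for n in range(1, 31):
            xs = np.arange(n + 1)
            bounds = [exact_binomial_ci(ArmCounts(n=n, x=int(x)), level) for x in xs]
            lowers = np.array([b.lower for b in bounds])
            uppers = np.array([b.upper for b in bounds])
            for p in np.arange(0.05, 0.96, 0.05):
                pmf = stats.binom.pmf(xs, n, p)
                covered = (lowers <= p) & (p <= uppers)
                assert pmf[covered].sum() >= level - 1e-12, (n, p)

    def test_empty_arm_rejected(self):
        with pytest.raises(ValueError):
            exact_binomial_ci(ArmCounts(n=0, x=0))


@pytest.mark.parametrize(
    "value, expected", [(0.5, 1), (1.5, 2), (2.5, 3), (-0.5, -1), (13.6, 14), (45.45, 45)]
)
def test_round_half_away(value, expected):
    assert round_half_away(value) == expected
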