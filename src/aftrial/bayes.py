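"""Conjugate Beta-Binomial inference for arm-level cardioversion rates.

The trial's primary analysis places a uniform Beta(1, 1) prior on each arm's
probability of pharmacological cardioversion within the 90-minute assessment
window, updates it with the observed successes/failures in the full analysis
set, and declares an active dose superior to (pooled) placebo when the
posterior probability ``P(p_active > p_placebo)`` exceeds 0.95. This module
provides those primitives plus the exact (Clopper-Pearson) within-arm
confidence interval used for descriptive reporting.

All functions are pure and operate on small immutable value types.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import integrate, special, stats

__all__ = [
    "BetaParams",
    "ArmCounts",
    "ProportionCI",
    "UNIFORM_PRIOR",
    "posterior_update",
    "prob_superiority",
    "prob_exceeds",
    "exact_binomial_ci",
    "round_half_away",
    "NumericalError",
]


class NumericalError(RuntimeError):
    """Raised when a quadrature result cannot meet the requested tolerance."""


@dataclass(frozen=True)
class BetaParams:
    """Shape pair (alpha, beta) of a Beta belief about a success probability.

    ``alpha`` counts pseudo-successes, ``beta`` pseudo-failures; the uniform
    prior is ``BetaParams(1, 1)``.
    """

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if not (self.alpha > 0 and self.beta > 0):
            raise ValueError(
                f"Beta shapes must be positive, got alpha={self.alpha}, beta={self.beta}"
            )

    @property
    def mean(self) -> float:
        return self.alpha / (self.alpha + self.beta)


@dataclass(frozen=True)
class ArmCounts:
    """Evaluable patients ``n`` and primary-endpoint successes ``x`` for one arm."""

    n: int
    x: int

    def __post_init__(self) -> None:
        if self.n < 0 or self.x < 0:
            raise ValueError(f"counts must be nonnegative, got n={self.n}, x={self.x}")
        if self.x > self.n:
            raise ValueError(f"successes exceed sample size: x={self.x} > n={self.n}")

    @property
    def proportion(self) -> float:
        if self.n == 0:
            raise ValueError("proportion undefined for n = 0")
        return self.x / self.n


@dataclass(frozen=True)
class ProportionCI:
    """Two-sided confidence interval for a binomial proportion."""

    lower: float
    upper: float
    level: float

    def __post_init__(self) -> None:
        if not 0 < self.level < 1:
            raise ValueError(f"level must lie in (0,1), got {self.level}")
        if not (0 <= self.lower <= self.upper <= 1):
            raise ValueError(f"bounds out of order: [{self.lower}, {self.upper}]")

    def as_percent(self) -> tuple[int, int]:
        """Bounds as nearest-integer percents (ties away from zero)."""
        return round_half_away(self.lower * 100), round_half_away(self.upper * 100)


UNIFORM_PRIOR = BetaParams(1.0, 1.0)


def round_half_away(value: float) -> int:
    """Round to the nearest integer with ties going away from zero.

    Python's built-in ``round`` is banker's rounding; printed trial tables use
    conventional half-away-from-zero rounding.
    """
    import math

    return int(math.floor(value + 0.5)) if value >= 0 else int(math.ceil(value - 0.5))


def posterior_update(prior: BetaParams, counts: ArmCounts) -> BetaParams:
    """Conjugate update: Beta(a, b) + (n, x) -> Beta(a + x, b + n - x)."""
    return BetaParams(prior.alpha + counts.x, prior.beta + counts.n - counts.x)


def prob_exceeds(post: BetaParams, threshold: float) -> float:
    """P(p > threshold) under ``post`` — the upper regularized-incomplete-beta tail.

    This is the quantity the interim dose-adaptation rule thresholds against
    0.90 (close for efficacy) and 0.10 (close for futility), with ``threshold``
    being the target cardioversion rate (0.65 in the trial design).
    """
    if not 0 < threshold < 1:
        raise ValueError(f"threshold must lie in (0,1), got {threshold}")
    return float(special.betainc(post.beta, post.alpha, 1.0 - threshold))


def prob_superiority(
    active: BetaParams, comparator: BetaParams, tolerance: float = 1e-10
) -> float:
    """P(p_active > p_comparator) for independent Beta posteriors.

    When the comparator has alpha = 1 (e.g. a zero-success placebo arm under
    the uniform prior) the probability has the closed form
    ``1 - B(a, b + b_c) / B(a, b)`` with (a, b) the active shapes, since
    ``P(p_c >= q) = (1 - q)^{b_c}``. More generally, whenever the comparator
    alpha is a (moderate) integer — always the case for posteriors built from
    integer counts under an integer prior — the complement has the exact
    finite-sum form

        P(p_c > p_a) = sum_{j<a_c} B(a+j, b+b_c) / [(b_c+j) B(1+j, b_c) B(a, b)]

    evaluated stably in log space. A 1-D adaptive quadrature of
    ``\\int f_active(q) F_comparator(q) dq`` covers non-integer shapes, and
    raises :class:`NumericalError` if its error estimate exceeds ``tolerance``.
    """
    import math

    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    if comparator.alpha == 1.0:
        # E[(1-p_a)^{b_c}] is a Beta-function ratio; exact up to floating point.
        log_ratio = special.betaln(
            active.alpha, active.beta + comparator.beta
        ) - special.betaln(active.alpha, active.beta)
        return 1.0 - math.exp(log_ratio)
    a_c = comparator.alpha
    if float(a_c).is_integer() and a_c <= 10_000:
        import numpy as np

        j = np.arange(int(a_c))
        log_terms = (
            special.betaln(active.alpha + j, active.beta + comparator.beta)
            - np.log(comparator.beta + j)
            - special.betaln(1 + j, comparator.beta)
            - special.betaln(active.alpha, active.beta)
        )
        complement = float(np.exp(log_terms).sum())
        return min(max(1.0 - complement, 0.0), 1.0)

    def integrand(q: float) -> float:
        return stats.beta.pdf(q, active.alpha, active.beta) * stats.beta.cdf(
            q, comparator.alpha, comparator.beta
        )

    value, err = integrate.quad(integrand, 0.0, 1.0, epsabs=tolerance, limit=200)
    if err > tolerance:
        raise NumericalError(
            f"quadrature achieved absolute error {err:.3g} > tolerance {tolerance:.3g}"
        )
    return min(max(value, 0.0), 1.0)


def exact_binomial_ci(counts: ArmCounts, level: float = 0.95) -> ProportionCI:
    """Exact two-sided Clopper-Pearson interval for ``x`` successes of ``n``.

    Bounds are beta quantiles: lower = Q(alpha/2; x, n-x+1) (0 when x = 0),
    upper = Q(1-alpha/2; x+1, n-x) (1 when x = n), alpha = 1 - level. This is
    the interval obtained by inverting the binomial tail tests, guaranteeing
    coverage at least ``level`` for every true proportion.
    """
    if counts.n < 1:
        raise ValueError("confidence interval requires n >= 1")
    if not 0 < level < 1:
        raise ValueError(f"level must lie in (0,1), got {level}")
    alpha = 1.0 - level
    x, n = counts.x, counts.n
    lower = 0.0 if x == 0 else float(stats.beta.ppf(alpha / 2, x, n - x + 1))
    upper = 1.0 if x == n else float(stats.beta.ppf(1 - alpha / 2, x + 1, n - x))
    return ProportionCI(lower=lower, upper=upper, level=level)
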