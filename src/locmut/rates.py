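"""Mutation-rate estimation and binomial significance machinery.

Rates are expressed as SNV / Mb / patient.  For a family (or set) with
``n_snv`` mutations over a genomic span of ``span_bp`` windows in a cohort of
``n_patients``:

    rate = n_snv / (n_patients * span_bp) * 1e6

Significance of a rate increase is a one-sided upper-tail binomial test with
``n = n_patients * span_bp`` trials and the reference per-site per-patient
probability as success probability.  Multiple testing uses Bonferroni.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats


@dataclass(frozen=True)
class RateEstimate:
    """Pooled SNV/Mb/patient rate with an exact (Clopper-Pearson) 99% CI."""

    n_snv: int
    span_bp: int
    n_patients: int
    rate: float
    ci99: tuple[float, float]


@dataclass(frozen=True)
class BaselineConfig:
    """Null mutation rate; ``per_site_prob`` is the per-bp per-patient
    probability, i.e. baseline_rate * 1e-6."""

    baseline_rate: float

    @property
    def per_site_prob(self) -> float:
        p = self.baseline_rate * 1e-6
        if not 0.0 < p < 1.0:
            raise ValueError("per-site probability must lie in (0, 1)")
        return p


@dataclass(frozen=True)
class RateComparison:
    subset: RateEstimate
    reference: RateEstimate
    fold: float
    p_value: float
    p_adjusted: float
    n_tests: int


def _clopper_pearson(x: int, n: int, conf: float = 0.99) -> tuple[float, float]:
    alpha = 1.0 - conf
    lo = 0.0 if x == 0 else float(stats.beta.ppf(alpha / 2, x, n - x + 1))
    hi = 1.0 if x == n else float(stats.beta.ppf(1 - alpha / 2, x + 1, n - x))
    return lo, hi


def mutation_rate(n_snv: int, n_patients: int, span_bp: int) -> RateEstimate:
    if n_patients <= 0:
        raise ValueError("n_patients must be positive")
    if span_bp <= 0:
        raise ValueError("span_bp must be positive")
    if n_snv < 0:
        raise ValueError("n_snv must be non-negative")
    trials = n_patients * span_bp
    rate = n_snv / trials * 1e6
    lo, hi = _clopper_pearson(n_snv, trials)
    return RateEstimate(n_snv, span_bp, n_patients, rate, (lo * 1e6, hi * 1e6))


def weighted_set_rate(
    members: list[tuple[int, int]], n_patients: int
) -> RateEstimate:
    """Pooled rate of a set of families given ``(n_snv, span_bp)`` members."""
    if not members:
        raise ValueError("member list is empty")
    n_snv = sum(m[0] for m in members)
    span = sum(m[1] for m in members)
    if span <= 0:
        raise ValueError("total span of the set is zero")
    return mutation_rate(n_snv, n_patients, span)


def _per_site_prob(reference: "BaselineConfig | RateEstimate | float") -> float:
    if isinstance(reference, BaselineConfig):
        return reference.per_site_prob
    if isinstance(reference, RateEstimate):
        rate = reference.rate
    else:
        rate = float(reference)
    if rate <= 0:
        raise ValueError("reference rate must be positive")
    p = rate * 1e-6
    if p >= 1.0:
        raise ValueError("reference per-site probability must be below 1")
    return p


def binomial_rate_test(
    n_snv: int,
    span_bp: int,
    n_patients: int,
    reference: "BaselineConfig | RateEstimate | float",
) -> float:
    """Exact one-sided upper-tail p-value, P(X >= n_snv) under the null."""
    if span_bp <= 0 or n_patients <= 0:
        raise ValueError("span and patient count must be positive")
    q = _per_site_prob(reference)
    trials = n_patients * span_bp
    if n_snv <= 0:
        return 1.0
    return float(stats.binom.sf(n_snv - 1, trials, q))


def min_significant_count(
    span_bp: int,
    n_patients: int,
    baseline: "BaselineConfig | RateEstimate | float",
    alpha: float,
) -> int:
    """Smallest SNV count whose upper-tail p-value is <= alpha."""
    if not 0.0 < alpha <= 1.0:
        raise ValueError("alpha must lie in (0, 1]")
    if alpha == 1.0:
        return 0
    q = _per_site_prob(baseline)
    trials = n_patients * span_bp
    # stats.binom.isf(alpha) gives the smallest c with P(X > c) <= alpha;
    # the p-value of observing count c is P(X >= c) = P(X > c-1).
    c = int(stats.binom.isf(alpha, trials, q)) + 1
    while c > 1 and stats.binom.sf(c - 2, trials, q) <= alpha:
        c -= 1
    while stats.binom.sf(c - 1, trials, q) > alpha:
        c += 1
    return c


def min_count_for_fold(
    span_bp: int,
    n_patients: int,
    baseline: "BaselineConfig | RateEstimate | float",
    fold: float,
    strict: bool = False,
) -> int:
    """Smallest integer count whose implied rate reaches (or, with ``strict``,
    exceeds) fold x baseline."""
    if fold <= 0:
        raise ValueError("fold must be positive")
    q = _per_site_prob(baseline)
    target = fold * q * n_patients * span_bp
    if strict:
        c = math.floor(target) + 1
    else:
        c = math.ceil(target - 1e-12)
    return max(c, 1)


def fraction_fold_significant(
    span_bp: int,
    fold: float,
    alpha: float,
    n_patients: int,
    baseline: "BaselineConfig | RateEstimate | float",
    strict: bool = False,
    max_counts: int = 1000,
) -> float:
    """Percentage of integer SNV counts implying a rate >= fold x baseline
    (strictly > with ``strict``) whose exact tail p-value is <= alpha.

    The binomial tail is strictly decreasing in the count, so the result is
    100% exactly when the minimal qualifying count is already significant;
    otherwise it is the deterministic fraction over the first ``max_counts``
    qualifying counts.
    """
    c_min = min_count_for_fold(span_bp, n_patients, baseline, fold, strict=strict)
    c_alpha = min_significant_count(span_bp, n_patients, baseline, alpha)
    if c_alpha <= c_min:
        return 100.0
    n_sig = max(0, max_counts - (c_alpha - c_min))
    return 100.0 * n_sig / max_counts


def statistical_power(
    span_bp: int,
    fold: float,
    alpha: float,
    n_patients: int,
    baseline: "BaselineConfig | RateEstimate | float",
) -> float:
    """Power of the binomial test against a true rate of fold x baseline:
    P(X >= c_alpha) with X ~ Binomial(n, fold x per-site probability).

    Complements :func:`fraction_fold_significant`, which is the analytic
    fraction over qualifying integer counts rather than a sampling
    probability.
    """
    if fold <= 0:
        raise ValueError("fold must be positive")
    q = _per_site_prob(baseline)
    if fold * q >= 1.0:
        raise ValueError("alternative per-site probability must be below 1")
    c_alpha = min_significant_count(span_bp, n_patients, baseline, alpha)
    if c_alpha == 0:
        return 1.0
    trials = n_patients * span_bp
    return float(stats.binom.sf(c_alpha - 1, trials, fold * q))


def compare_rates(
    subset: RateEstimate, reference: RateEstimate, n_tests: int = 1
) -> RateComparison:
    """One-sided binomial comparison of a subset rate against a reference rate
    with Bonferroni correction over ``n_tests`` comparisons."""
    if reference.rate <= 0:
        raise ValueError("reference rate must be positive")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    fold = subset.rate / reference.rate
    p = binomial_rate_test(subset.n_snv, subset.span_bp, subset.n_patients, reference)
    return RateComparison(
        subset=subset,
        reference=reference,
        fold=fold,
        p_value=p,
        p_adjusted=min(1.0, p * n_tests),
        n_tests=n_tests,
    )
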