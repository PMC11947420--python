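"""Liability-threshold-model mathematics.

The trait (here, an autism diagnosis) is modelled as a latent, additive and
normally distributed liability; individuals whose liability exceeds a
sex-specific threshold are affected.  The threshold is fixed by the trait
prevalence in that sex: a male prevalence of 2.5% places the male threshold
at 1.96 standard deviations, and a 4:1 male:female prevalence ratio places
the female threshold at about 2.50.

The effect size of a class of rare variants is expressed as ``z``: the mean
liability shift of carriers relative to the population, in population
standard-deviation units.  It is obtained from the carrier penetrance
(probability of the trait given carriage, estimated from carrier rates in
cases and controls via Bayes' rule) by inverting the threshold model:

    z = T - Phi^-1_upper(penetrance)

i.e. the shift that would give carriers exactly the observed penetrance.
A mixture-of-truncated-means convention (penetrance-weighted means of the
affected and unaffected tails) is also provided for comparison; it is
systematically attenuated relative to the generative carrier shift and is
not the default.

Standard errors follow the published convention of back-solving the normal
approximation from the exact binomial p-value (``se = |z| / q`` with ``q``
the two-sided normal quantile of p); confidence intervals for estimates
computed from event counts are instead mapped from the exact
Clopper-Pearson interval on the case/control event split through the
monotone rate-ratio -> penetrance -> z transform, which preserves the exact
test's coverage.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

from scipy.stats import binomtest, norm

Z_95 = norm.isf(0.025)  # 1.959964: half-width multiplier for 95% intervals

__all__ = [
    "PrevalenceSpec",
    "ThresholdValue",
    "LiabilityEstimate",
    "SexDifference",
    "female_prevalence_from_ratio",
    "subgroup_prevalence",
    "liability_threshold",
    "truncated_liability_means",
    "carrier_penetrance",
    "liability_effect",
    "se_and_ci",
    "liability_estimate_from_counts",
    "sex_difference_liability",
    "unequal_variance_adjustment",
]


@dataclass(frozen=True)
class PrevalenceSpec:
    """Sex-specific trait prevalences and liability-scale parameters.

    ``female_prevalence`` is derived as ``male_prevalence /
    male_to_female_ratio`` unless given explicitly.  ``male_variance`` /
    ``female_variance`` are liability variances (1 = the standard
    equal-variance model); an unequal-variance model with male variance
    2-3x the female variance is an alternative the study considers.
    Subgroup proportions scale the sex prevalence for phenotype-defined
    subgroups (e.g. the fraction of autistic individuals with cognitive
    impairment).
    """

    male_prevalence: float = 0.025
    male_to_female_ratio: float = 4.0
    female_prevalence: float = field(default=None)  # type: ignore[assignment]
    male_variance: float = 1.0
    female_variance: float = 1.0
    subgroup_proportion_male: float | None = None
    subgroup_proportion_female: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.male_prevalence < 1.0:
            raise ValueError(f"male_prevalence must be in (0,1), got {self.male_prevalence}")
        if self.male_to_female_ratio <= 0:
            raise ValueError("male_to_female_ratio must be positive")
        if self.female_prevalence is None:
            object.__setattr__(
                self,
                "female_prevalence",
                female_prevalence_from_ratio(self.male_prevalence, self.male_to_female_ratio),
            )
        if not 0.0 < self.female_prevalence < 1.0:
            raise ValueError("female_prevalence must be in (0,1)")
        if self.male_variance <= 0 or self.female_variance <= 0:
            raise ValueError("liability variances must be positive")
        for p in (self.subgroup_proportion_male, self.subgroup_proportion_female):
            if p is not None and not 0.0 <= p <= 1.0:
                raise ValueError("subgroup proportions must be in [0,1]")

    def prevalence(self, sex: str) -> float:
        return {"male": self.male_prevalence, "female": self.female_prevalence}[sex]

    def variance(self, sex: str) -> float:
        return {"male": self.male_variance, "female": self.female_variance}[sex]


@dataclass(frozen=True)
class ThresholdValue:
    """A liability threshold ``t`` (raw-scale SD units of a N(0, variance)
    liability) implied by a prevalence."""

    t: float
    prevalence: float
    variance: float = 1.0

    @property
    def standardized(self) -> float:
        """Threshold on the variance-1 population scale."""
        return self.t / math.sqrt(self.variance)


@dataclass(frozen=True)
class LiabilityEstimate:
    """A liability-scale effect size with its uncertainty.

    ``z`` is the mean carrier liability shift in SD units; ``se``,
    ``ci_low``/``ci_high`` and ``p_value`` may be NaN when not yet
    completed (``liability_effect`` returns z only) or undefined
    (p = 1 gives no usable standard error).
    """

    z: float
    se: float = float("nan")
    ci_low: float = float("nan")
    ci_high: float = float("nan")
    p_value: float = float("nan")
    prevalence_used: float = float("nan")
    label: str = ""

    def __post_init__(self) -> None:
        if math.isfinite(self.se) and self.se < 0:
            raise ValueError("se must be nonnegative")
        if math.isfinite(self.ci_low) and math.isfinite(self.ci_high):
            if not self.ci_low <= self.z <= self.ci_high:
                raise ValueError("CI must bracket the point estimate")


@dataclass(frozen=True)
class SexDifference:
    z_diff: float
    se_diff: float
    p_value: float
    ci_low: float
    ci_high: float


def female_prevalence_from_ratio(male_prevalence: float, ratio: float) -> float:
    """Female prevalence implied by the male prevalence and a male:female
    prevalence ratio (4:1 in the base model)."""
    if not 0.0 < male_prevalence < 1.0:
        raise ValueError(f"male_prevalence must be in (0,1), got {male_prevalence}")
    if ratio <= 0:
        raise ValueError("ratio must be positive")
    out = male_prevalence / ratio
    if out >= 1.0:
        raise ValueError("implied female prevalence is not below 1")
    return out


def subgroup_prevalence(sex_prevalence: float, proportion_with_feature: float) -> tuple[float, float]:
    """Split a sex-specific prevalence into a featured subgroup and its
    complement, e.g. 23% of autistic males with cognitive impairment at a
    male prevalence of 2.5% gives (0.575%, 1.925%)."""
    if not 0.0 < sex_prevalence <= 1.0:
        raise ValueError("sex_prevalence must be in (0,1]")
    if not 0.0 < proportion_with_feature <= 1.0:
        raise ValueError("proportion_with_feature must be in (0,1]")
    featured = sex_prevalence * proportion_with_feature
    return featured, sex_prevalence - featured


def liability_threshold(prevalence: float, variance: float = 1.0) -> ThresholdValue:
    """Liability threshold implied by a prevalence: the upper-tail normal
    quantile, scaled by the liability SD."""
    if not 0.0 < prevalence < 1.0:
        raise ValueError(f"prevalence must be strictly inside (0,1), got {prevalence}")
    if variance <= 0:
        raise ValueError("variance must be positive")
    return ThresholdValue(t=float(math.sqrt(variance) * norm.isf(prevalence)), prevalence=prevalence, variance=variance)


def truncated_liability_means(prevalence: float) -> tuple[float, float]:
    """Mean standardized liability of the affected (upper tail) and
    unaffected (lower tail) fractions of the population.

    phi(T)/K and -phi(T)/(1-K): the usual truncated-normal tail means,
    which satisfy K*m_aff + (1-K)*m_unaff = 0.
    """
    thr = liability_threshold(prevalence)
    dens = float(norm.pdf(thr.t))
    return dens / prevalence, -dens / (1.0 - prevalence)


def carrier_penetrance(
    rate_cases: float, rate_controls: float, prevalence: float, check_rare: bool = True
) -> float:
    """P(affected | carrier) from carrier rates in cases and controls and
    the trait prevalence, by Bayes' rule under the rare-carrier
    approximation (carrier frequency dropped from the normalization)."""
    if rate_cases < 0 or rate_controls < 0:
        raise ValueError("rates must be nonnegative")
    if rate_cases == 0 and rate_controls == 0:
        raise ValueError("carrier penetrance undefined when both rates are zero")
    if not 0.0 < prevalence < 1.0:
        raise ValueError("prevalence must be in (0,1)")
    if check_rare and max(rate_cases, rate_controls) > 0.1:
        warnings.warn(
            "rare-carrier approximation is questionable at rates > 0.1 per sample",
            stacklevel=2,
        )
    num = rate_cases * prevalence
    return float(num / (num + rate_controls * (1.0 - prevalence)))


def liability_effect(
    rate_cases: float,
    rate_controls: float,
    prevalence: float,
    variance: float = 1.0,
    method: str = "threshold_shift",
    label: str = "",
    check_rare: bool = True,
) -> LiabilityEstimate:
    """Mean liability shift of variant carriers, from case/control carrier
    rates and the trait prevalence (point estimate only).

    ``threshold_shift`` (default) inverts the threshold model so that the
    shifted carrier distribution has exactly the estimated penetrance;
    under the generative model it is a consistent estimator of the carrier
    shift.  ``mixture`` is the penetrance-weighted average of the affected
    and unaffected tail means; it is attenuated and retained only for
    comparison with that convention.
    """
    pen = carrier_penetrance(rate_cases, rate_controls, prevalence, check_rare=check_rare)
    sd = math.sqrt(variance)
    if method == "threshold_shift":
        z = float(sd * (norm.isf(prevalence) - norm.isf(pen)))
    elif method == "mixture":
        m_aff, m_unaff = truncated_liability_means(prevalence)
        z = float(sd * (pen * m_aff + (1.0 - pen) * m_unaff))
    else:
        raise ValueError(f"unknown method {method!r}")
    if rate_cases == rate_controls:
        z = 0.0  # exact, avoids float residue from the quantile round trip
    return LiabilityEstimate(z=z, prevalence_used=prevalence, label=label)


def se_and_ci(z: float, p_binomial: float, prevalence: float = float("nan"), label: str = "") -> LiabilityEstimate:
    """Complete a liability estimate with the published Wald-consistent
    uncertainty: se = |z| / q where q is the two-sided normal quantile of
    the binomial p-value, CI = z +/- 1.96 se.

    At p = 1 (or z = 0) the construction is degenerate; se and the CI are
    reported as NaN.
    """
    if not 0.0 < p_binomial <= 1.0:
        raise ValueError("p_binomial must be in (0,1]")
    if not math.isfinite(z):
        raise ValueError("z must be finite")
    q = float(norm.isf(p_binomial / 2.0))
    if p_binomial == 1.0 or q <= 0.0 or z == 0.0:
        return LiabilityEstimate(z=z, p_value=p_binomial, prevalence_used=prevalence, label=label)
    se = float(abs(z) / q)
    return LiabilityEstimate(
        z=z,
        se=se,
        ci_low=z - Z_95 * se,
        ci_high=z + Z_95 * se,
        p_value=p_binomial,
        prevalence_used=prevalence,
        label=label,
    )


def _z_from_ratio(ratio: float, prevalence: float, variance: float, method: str) -> float:
    """Carrier shift implied by a case/control rate ratio (rates enter the
    penetrance only through their ratio)."""
    if math.isinf(ratio):
        pen = 1.0
    else:
        pen = carrier_penetrance(ratio, 1.0, prevalence, check_rare=False) if ratio > 0 else 0.0
    sd = math.sqrt(variance)
    if method == "threshold_shift":
        if pen == 0.0:
            return float("-inf")
        if pen == 1.0:
            return float("inf")
        return float(sd * (norm.isf(prevalence) - norm.isf(pen)))
    m_aff, m_unaff = truncated_liability_means(prevalence)
    return float(sd * (pen * m_aff + (1.0 - pen) * m_unaff))


def liability_estimate_from_counts(
    events_case: int,
    n_case: int,
    events_control: int,
    n_control: int,
    prevalence: float,
    variance: float = 1.0,
    method: str = "threshold_shift",
    label: str = "",
) -> LiabilityEstimate:
    """Full liability estimate from event counts and denominators.

    The p-value is the exact binomial test of the case/control event split
    against the sample-size expectation; ``se`` follows the published
    reconstruction from that p-value; the CI is the exact Clopper-Pearson
    interval on the split mapped through the monotone ratio -> z transform
    (so its coverage is that of the exact interval).
    """
    if n_case <= 0 or n_control <= 0:
        raise ValueError("denominators must be positive")
    total = events_case + events_control
    if total == 0:
        raise ValueError("no events: liability undefined")
    f0 = n_case / (n_case + n_control)
    test = binomtest(events_case, total, f0)
    pvalue = float(max(test.pvalue, 1e-300))  # guard against underflow at extreme splits
    rate_case = events_case / n_case
    rate_control = events_control / n_control
    # z depends on the rates only through their ratio; normalize so that
    # allele-count "rates" (unit denominators) stay in the rare regime
    norm_const = rate_case + rate_control
    est = liability_effect(rate_case / norm_const, rate_control / norm_const,
                           prevalence, variance, method, label, check_rare=False)
    completed = se_and_ci(est.z, pvalue, prevalence, label)
    ci = test.proportion_ci(confidence_level=0.95, method="exact")
    scale = n_control / n_case
    lo_ratio = ci.low / (1.0 - ci.low) * scale if ci.low < 1.0 else float("inf")
    hi_ratio = ci.high / (1.0 - ci.high) * scale if ci.high < 1.0 else float("inf")
    ci_low = _z_from_ratio(lo_ratio, prevalence, variance, method)
    ci_high = _z_from_ratio(hi_ratio, prevalence, variance, method)
    return replace(completed, ci_low=ci_low, ci_high=ci_high)


def sex_difference_liability(z_f: float, se_f: float, z_m: float, se_m: float) -> SexDifference:
    """Female-minus-male difference of two liability estimates, with
    pooled standard error and a two-sided normal p-value."""
    for v in (z_f, z_m):
        if not math.isfinite(v):
            raise ValueError("z estimates must be finite")
    if se_f < 0 or se_m < 0:
        raise ValueError("standard errors must be nonnegative")
    z_diff = z_f - z_m
    se_diff = math.hypot(se_f, se_m)
    if se_diff == 0.0:
        p = 1.0 if z_diff == 0.0 else 0.0
    else:
        p = 2.0 * norm.sf(abs(z_diff) / se_diff)
    return SexDifference(
        z_diff=z_diff,
        se_diff=se_diff,
        p_value=min(p, 1.0),
        ci_low=z_diff - Z_95 * se_diff,
        ci_high=z_diff + Z_95 * se_diff,
    )


def unequal_variance_adjustment(
    spec: PrevalenceSpec,
    rates_male: tuple[float, float] | None = None,
    rates_female: tuple[float, float] | None = None,
    method: str = "threshold_shift",
) -> dict:
    """Per-sex thresholds (and, given (case, control) carrier rates,
    liability effects) under sex-specific liability variances.

    Male quantities are computed under N(0, male_variance) and reported
    both on that raw scale and rescaled to the standardized (female,
    variance-1) scale so the sexes stay comparable.  With variance ratio 1
    this reduces exactly to the standard model.
    """
    out: dict = {
        "male_threshold": liability_threshold(spec.male_prevalence, spec.male_variance),
        "female_threshold": liability_threshold(spec.female_prevalence, spec.female_variance),
    }
    for sex, rates in (("male", rates_male), ("female", rates_female)):
        if rates is None:
            continue
        var = spec.variance(sex)
        est = liability_effect(rates[0], rates[1], spec.prevalence(sex), var, method, label=f"{sex}_raw_scale")
        out[f"{sex}_effect_raw"] = est
        out[f"{sex}_effect_standardized"] = replace(
            est, z=est.z / math.sqrt(var), label=f"{sex}_standardized"
        )
    return out
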