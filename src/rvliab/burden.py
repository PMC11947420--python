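"""Exact-binomial burden and transmission tests on count data.

Enrichment of rare variants in probands is measured as a rate ratio:
de novo mutations (DNMs) per proband over DNMs per sibling, or transmitted
over untransmitted parental alleles.  Deviations from the null ratio are
tested with the two-sided exact binomial test (minimum-likelihood
convention: the p-value sums the probabilities of all outcomes no more
likely than the observed one) on the event split, against the expected
fraction implied by the sample sizes (DNM / case-control modes) or 0.5
(transmission).  Confidence intervals come from the exact Clopper-Pearson
interval on the split, mapped to the ratio scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import binomtest, poisson

VARIANT_CLASSES = ("damaging_PTV", "damaging_missense", "synonymous", "other")
MODES = ("de_novo", "transmitted_untransmitted", "case_control", "parent_of_origin")

__all__ = [
    "BurdenCounts",
    "RateRatioResult",
    "exact_binomial_two_sided",
    "rate_ratio_test",
    "dnm_rate_ratio",
    "transmission_test",
    "sex_difference_observed",
    "sex_difference_transmission",
    "parent_of_origin_burden",
    "poisson_two_sided",
    "mutational_model_test",
    "relative_risk",
    "burden_table",
]


@dataclass(frozen=True)
class BurdenCounts:
    """Event counts and denominators for one stratum.

    For ``de_novo`` / ``case_control`` / ``parent_of_origin`` modes,
    ``events_*`` are variant counts and ``n_*`` sample counts; for
    ``transmitted_untransmitted``, events_case/events_control are the
    transmitted/untransmitted allele counts and the denominators are
    absent.
    """

    cohort: str
    sex: str
    phenotype_group: str
    variant_class: str
    mode: str
    events_case: int
    events_control: int
    n_case: int | None = None
    n_control: int | None = None

    def __post_init__(self) -> None:
        if self.events_case < 0 or self.events_control < 0:
            raise ValueError("counts must be nonnegative")
        for n in (self.n_case, self.n_control):
            if n is not None and n <= 0:
                raise ValueError("denominators must be positive where present")


@dataclass(frozen=True)
class RateRatioResult:
    ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    expected_fraction: float
    n_events_total: int

    def __post_init__(self) -> None:
        if self.ratio < 0:
            raise ValueError("ratio must be nonnegative")
        if math.isfinite(self.ratio) and not self.ci_low <= self.ratio <= self.ci_high + 1e-12:
            raise ValueError("CI must bracket the ratio")


def exact_binomial_two_sided(successes: int, trials: int, p0: float) -> float:
    """Two-sided exact binomial p-value (minimum-likelihood method)."""
    if trials <= 0:
        raise ValueError("trials must be positive")
    if not 0 <= successes <= trials:
        raise ValueError("successes must lie in [0, trials]")
    if not 0.0 < p0 < 1.0:
        raise ValueError("p0 must be in (0,1)")
    return float(binomtest(successes, trials, p0).pvalue)


def _split_ci_to_ratio(events_case: int, events_control: int, scale: float) -> tuple[float, float]:
    """Clopper-Pearson interval on the case fraction of events, mapped to
    the rate-ratio scale via f -> f/(1-f) * scale."""
    total = events_case + events_control
    ci = binomtest(events_case, total, 0.5).proportion_ci(confidence_level=0.95, method="exact")
    lo = float(ci.low / (1.0 - ci.low) * scale) if ci.low < 1.0 else float("inf")
    hi = float(ci.high / (1.0 - ci.high) * scale) if ci.high < 1.0 else float("inf")
    return lo, hi


def rate_ratio_test(
    events_case: int,
    events_control: int,
    n_case: int,
    n_control: int,
    expected_ratio: float = 1.0,
) -> RateRatioResult:
    """Exact test of a case/control rate ratio against ``expected_ratio``
    (1 = the plain sample-size null; other values arise from
    permutation-calibrated gene-set nulls).

    An empty control count gives an infinite ratio with a one-sided
    (upper-unbounded) interval; the exact test itself remains valid.
    """
    if n_case <= 0 or n_control <= 0:
        raise ValueError("denominators must be positive")
    if events_case < 0 or events_control < 0:
        raise ValueError("counts must be nonnegative")
    total = events_case + events_control
    if total == 0:
        raise ValueError("no events observed in either group")
    if not math.isfinite(expected_ratio) or expected_ratio <= 0:
        raise ValueError("expected_ratio must be positive and finite")
    f0 = expected_ratio * n_case / (expected_ratio * n_case + n_control)
    p = exact_binomial_two_sided(events_case, total, f0)
    rate_case = events_case / n_case
    rate_control = events_control / n_control
    ratio = rate_case / rate_control if rate_control > 0 else float("inf")
    lo, hi = _split_ci_to_ratio(events_case, events_control, n_control / n_case)
    return RateRatioResult(
        ratio=ratio, ci_low=lo, ci_high=hi, p_value=p, expected_fraction=f0, n_events_total=total
    )


def dnm_rate_ratio(counts: BurdenCounts) -> RateRatioResult:
    """Proband/sibling DNM (or case/control variant) rate ratio with the
    sample-size expected fraction n_case/(n_case+n_control)."""
    if counts.mode not in ("de_novo", "case_control", "parent_of_origin"):
        raise ValueError(f"mode {counts.mode!r} has no per-sample rate ratio")
    if counts.n_case is None or counts.n_control is None:
        raise ValueError("de novo / case-control counts need sample denominators")
    return rate_ratio_test(counts.events_case, counts.events_control, counts.n_case, counts.n_control)


def transmission_test(transmitted: int, untransmitted: int, expected_ratio: float = 1.0) -> RateRatioResult:
    """Transmitted:untransmitted ratio of parental rare alleles tested
    against equilibrium (0.5 transmitted, i.e. ratio 1) or a
    permutation-derived expected ratio."""
    return rate_ratio_test(transmitted, untransmitted, 1, 1, expected_ratio=expected_ratio)


def sex_difference_observed(events_f: int, events_m: int, n_f: int, n_m: int) -> RateRatioResult:
    """Female vs male variant-rate contrast: the fraction of events in
    females is tested against the female fraction of samples; ratio > 1
    means a female excess."""
    return rate_ratio_test(events_f, events_m, n_f, n_m)


def sex_difference_transmission(
    transmitted_f: int,
    transmitted_total: int,
    parental_alleles_f: int,
    parental_alleles_total: int,
) -> RateRatioResult:
    """Female share of transmitted alleles tested against the female
    share of all parental alleles."""
    if not 0 <= transmitted_f <= transmitted_total:
        raise ValueError("female transmitted count exceeds the total")
    if not 0 < parental_alleles_f <= parental_alleles_total:
        raise ValueError("parental allele totals must be positive and ordered")
    if transmitted_total == 0:
        raise ValueError("no transmitted alleles")
    f0 = parental_alleles_f / parental_alleles_total
    if not 0.0 < f0 < 1.0:
        raise ValueError("expected fraction must be strictly inside (0,1)")
    p = exact_binomial_two_sided(transmitted_f, transmitted_total, f0)
    transmitted_m = transmitted_total - transmitted_f
    alleles_m = parental_alleles_total - parental_alleles_f
    ratio = (
        (transmitted_f / parental_alleles_f) / (transmitted_m / alleles_m)
        if transmitted_m > 0 and alleles_m > 0
        else float("inf")
    )
    lo, hi = _split_ci_to_ratio(transmitted_f, transmitted_m, alleles_m / parental_alleles_f)
    return RateRatioResult(
        ratio=ratio, ci_low=lo, ci_high=hi, p_value=p, expected_fraction=f0,
        n_events_total=transmitted_total,
    )


def parent_of_origin_burden(
    events_mothers: int, n_mothers: int, events_fathers: int, n_fathers: int
) -> RateRatioResult:
    """Mother vs father per-parent variant burden (mothers as 'case')."""
    return rate_ratio_test(events_mothers, events_fathers, n_mothers, n_fathers)


def poisson_two_sided(observed: int, expected: float) -> float:
    """Two-sided exact Poisson p-value by the minimum-likelihood method."""
    if observed < 0:
        raise ValueError("observed must be nonnegative")
    if expected < 0:
        raise ValueError("expected must be nonnegative")
    if expected == 0:
        return 1.0 if observed == 0 else 0.0
    kmax = int(max(observed, expected + 10.0 * math.sqrt(expected) + 20))
    ks = np.arange(kmax + 1)
    pmf = poisson.pmf(ks, expected)
    obs_pmf = poisson.pmf(observed, expected)
    p = float(pmf[pmf <= obs_pmf * (1 + 1e-12)].sum())
    # mass beyond kmax is below the observed pmf whenever kmax >> expected
    p += float(poisson.sf(kmax, expected))
    return min(p, 1.0)


def mutational_model_test(
    per_gene_rates, n_trios: int, observed: int, rates_convention: str = "haploid"
) -> tuple[float, float]:
    """Observed DNM count against the expectation from per-gene mutation
    rates: expected = 2 * n_trios * sum(rates) for per-haploid-genome
    rates (factor 1 if the rate table is documented as diploid)."""
    rates = np.asarray(list(per_gene_rates), dtype=float)
    if (rates < 0).any():
        raise ValueError("mutation rates must be nonnegative")
    if n_trios <= 0:
        raise ValueError("n_trios must be positive")
    factor = {"haploid": 2.0, "diploid": 1.0}[rates_convention]
    expected = factor * n_trios * float(rates.sum())
    if expected == 0 and observed > 0:
        return expected, 0.0
    return expected, poisson_two_sided(observed, expected)


def relative_risk(events_a: int, n_a: int, events_b: int, n_b: int) -> float:
    """Ratio of per-sample event rates between two groups."""
    if n_a <= 0 or n_b <= 0:
        raise ValueError("denominators must be positive")
    if events_b == 0:
        return float("inf")
    return (events_a / n_a) / (events_b / n_b)


def burden_table(counts: pd.DataFrame) -> pd.DataFrame:
    """Run the mode-appropriate exact test on every stratum row of a
    BurdenCounts table and return the results table (one row per stratum,
    sorted on the stratum key so the output is invariant to input row
    order)."""
    required = {"cohort", "sex", "phenotype_group", "variant_class", "mode", "events_case", "events_control"}
    missing = required - set(counts.columns)
    if missing:
        raise ValueError(f"counts table is missing columns: {sorted(missing)}")
    key = ["cohort", "sex", "phenotype_group", "variant_class", "mode"]
    rows = []
    for _, r in counts.sort_values(key, kind="mergesort").iterrows():
        if r["events_case"] + r["events_control"] == 0:
            res = dict(ratio=np.nan, ci_low=np.nan, ci_high=np.nan, p_value=np.nan,
                       expected_fraction=np.nan, n_events_total=0)
        elif r["mode"] == "transmitted_untransmitted":
            res = vars(transmission_test(int(r["events_case"]), int(r["events_control"])))
        else:
            res = vars(rate_ratio_test(int(r["events_case"]), int(r["events_control"]),
                                       int(r["n_case"]), int(r["n_control"])))
        rows.append({**{k: r[k] for k in key},
                     "events_case": int(r["events_case"]), "events_control": int(r["events_control"]),
                     "n_case": r.get("n_case"), "n_control": r.get("n_control"), **res})
    return pd.DataFrame(rows).reset_index(drop=True)
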