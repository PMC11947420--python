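"""Fixed-effect meta-analysis and multiple-testing adjustment.

Cohort estimates are combined with inverse-variance weights (1/se^2);
rate ratios are combined on the log scale, with the log-scale standard
error reconstructed from the CI width, and exponentiated for reporting.
The exome-wide family comprises 54 tests (3 sex comparisons x 3 cohorts x
3 variant classes x 2 inheritance modes); the phenotype-stratified family
doubles this to 108.  Significance tiers: '***' below 0.05 after
Bonferroni, '**' after Benjamini-Hochberg FDR, '*' only before
correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

from .liability import Z_95

EXOME_WIDE_FAMILY = 54
STRATIFIED_FAMILY = 108

__all__ = [
    "MetaInput",
    "MetaResult",
    "ivw_meta",
    "ivw_meta_rate_ratios",
    "log_se_from_ci",
    "bonferroni",
    "bh_fdr",
    "significance_tier",
    "adjust_results_table",
    "EXOME_WIDE_FAMILY",
    "STRATIFIED_FAMILY",
]


@dataclass(frozen=True)
class MetaInput:
    estimate: float
    se: float
    cohort: str = ""


@dataclass(frozen=True)
class MetaResult:
    estimate: float
    se: float
    p_value: float
    ci_low: float
    ci_high: float
    n_studies: int


def ivw_meta(inputs: Sequence[MetaInput]) -> MetaResult:
    """Inverse-variance-weighted fixed-effect combination of estimates on
    a common additive scale (log rate ratio, or liability z)."""
    usable = [m for m in inputs if m.se > 0 and math.isfinite(m.se) and math.isfinite(m.estimate)]
    if not usable:
        raise ValueError("no inputs with a positive, finite standard error")
    w = np.array([1.0 / m.se**2 for m in usable])
    x = np.array([m.estimate for m in usable])
    est = float(np.sum(w * x) / np.sum(w))
    se = float(1.0 / math.sqrt(np.sum(w)))
    p = float(2.0 * norm.sf(abs(est) / se))
    return MetaResult(est, se, min(p, 1.0), est - Z_95 * se, est + Z_95 * se, len(usable))


def log_se_from_ci(ci_low: float, ci_high: float) -> float:
    """Log-scale se of a rate ratio reconstructed from its 95% CI width."""
    if not (ci_low > 0 and math.isfinite(ci_high)):
        raise ValueError("CI must be positive and finite to recover a log-scale se")
    return (math.log(ci_high) - math.log(ci_low)) / (2.0 * Z_95)


def ivw_meta_rate_ratios(
    ratios: Sequence[float], ci_lows: Sequence[float], ci_highs: Sequence[float],
    cohorts: Sequence[str] | None = None,
) -> MetaResult:
    """Meta-analyse rate ratios on the log scale; the returned estimate
    and CI are exponentiated back to the ratio scale."""
    cohorts = cohorts or [""] * len(ratios)
    inputs = []
    for r, lo, hi, c in zip(ratios, ci_lows, ci_highs, cohorts):
        if not (r > 0 and math.isfinite(r)):
            continue
        try:
            se = log_se_from_ci(lo, hi)
        except ValueError:
            continue
        inputs.append(MetaInput(math.log(r), se, c))
    res = ivw_meta(inputs)
    return MetaResult(
        estimate=math.exp(res.estimate), se=res.se, p_value=res.p_value,
        ci_low=math.exp(res.ci_low), ci_high=math.exp(res.ci_high), n_studies=res.n_studies,
    )


def bonferroni(p: float, m: int) -> float:
    if m < 1:
        raise ValueError("family size must be at least 1")
    return min(1.0, p * m)


def bh_fdr(ps: Iterable[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values."""
    ps = list(ps)
    if not ps:
        return []
    if any(not 0.0 < p <= 1.0 for p in ps):
        raise ValueError("p-values must be in (0,1]")
    return list(multipletests(ps, method="fdr_bh")[1])


def significance_tier(p_raw: float, p_fdr: float, p_bonf: float) -> str:
    """Highest significance tier whose adjusted p-value is below 0.05."""
    if not p_raw <= p_fdr + 1e-12 or not p_fdr <= p_bonf + 1e-12:
        raise ValueError("expected p_raw <= p_fdr <= p_bonferroni")
    if p_bonf < 0.05:
        return "***"
    if p_fdr < 0.05:
        return "**"
    if p_raw < 0.05:
        return "*"
    return ""


def adjust_results_table(
    results: pd.DataFrame, p_col: str = "p_value", family_size: int | None = None
) -> pd.DataFrame:
    """Append p_fdr, p_bonferroni and tier columns to a results table.

    ``family_size`` defaults to the number of non-missing p-values, but
    the declared family (54 exome-wide, 108 stratified) should be passed
    when the table holds only part of the family.
    """
    out = results.copy()
    mask = out[p_col].notna()
    m = family_size if family_size is not None else int(mask.sum())
    out["p_fdr"] = np.nan
    out["p_bonferroni"] = np.nan
    out["tier"] = ""
    if mask.any():
        raw = out.loc[mask, p_col].astype(float)
        fdr = bh_fdr(list(raw))
        bonf = [bonferroni(p, m) for p in raw]
        # BH on a partial table cannot exceed its Bonferroni counterpart
        fdr = [min(f, b) for f, b in zip(fdr, bonf)]
        out.loc[mask, "p_fdr"] = fdr
        out.loc[mask, "p_bonferroni"] = bonf
        out.loc[mask, "tier"] = [
            significance_tier(p, f, b) for p, f, b in zip(raw, fdr, bonf)
        ]
    return out
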