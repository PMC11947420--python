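"""Covariate-matched random gene-set nulls.

The observed burden of a gene set (SFARI autism-predisposition genes,
sex-biased cortical expression sets, ...) is gauged against random gene
sets of the same size drawn from the remaining protein-coding genes and
matched for LoF constraint (exact LOEUF decile), sex-averaged brain
expression and coding-sequence length (quantile bins, quintiles by
default).  Each of the (default 10,000) permutations draws, for every
target gene, one pool gene uniformly with replacement from the same
stratum; the average rate ratio over draws becomes the expected ratio of
the exact binomial test, and the average per-sample rates replace the
sibling rates in the excess-liability conversion.

The generator is numpy's seedable PCG64 (``numpy.random.default_rng``);
the seed is recorded in the returned summary, and fixed seeds reproduce
draws bit-for-bit.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, replace as dc_replace

import numpy as np
import pandas as pd

from . import burden
from .liability import LiabilityEstimate, liability_effect, se_and_ci

logger = logging.getLogger(__name__)

GENE_COLUMNS = [
    "gene_id", "loeuf_decile", "brain_expression", "cds_length",
    "sfari", "sfari_loeuf1", "fetal_male_biased", "fetal_female_biased",
    "adult_male_biased", "adult_female_biased",
    "mutation_rate_ptv", "mutation_rate_missense", "mutation_rate_synonymous",
]

__all__ = [
    "MatchedNullSummary",
    "stratify_pool",
    "draw_matched_set",
    "expected_ratio",
    "enumerate_expected_ratio",
    "test_vs_expected",
    "excess_liability",
]


@dataclass(frozen=True)
class MatchedNullSummary:
    expected_ratio: float
    n_permutations: int
    permutation_mean_case_rate: float
    permutation_mean_control_rate: float
    quantiles: dict
    seed: int | None
    n_undefined: int = 0
    mode: str = "de_novo"


def stratify_pool(genes: pd.DataFrame, n_expression_bins: int = 5, n_length_bins: int = 5) -> pd.Series:
    """Assign every gene a matching stratum: its LOEUF decile crossed with
    quantile bins of brain expression and CDS length (bins computed on the
    full table passed in)."""
    if genes.empty:
        raise ValueError("empty gene pool")
    if n_expression_bins < 1 or n_length_bins < 1:
        raise ValueError("bin counts must be at least 1")

    def _bins(values: pd.Series, n: int) -> pd.Series:
        if n == 1 or values.nunique() == 1:
            return pd.Series(0, index=values.index)
        return pd.qcut(values.rank(method="first"), q=min(n, values.nunique()), labels=False)

    expr = _bins(genes["brain_expression"], n_expression_bins)
    length = _bins(genes["cds_length"], n_length_bins)
    return (
        genes["loeuf_decile"].astype(int).astype(str)
        + "|" + expr.astype(int).astype(str)
        + "|" + length.astype(int).astype(str)
    ).rename("stratum")


def _candidates_for_targets(
    target: pd.DataFrame, pool: pd.DataFrame, strata: pd.Series
) -> list[np.ndarray]:
    pool_strata = strata.loc[pool.index]
    by_stratum = {s: idx.to_numpy() for s, idx in pool.groupby(pool_strata).groups.items()}
    by_decile = {int(d): idx.to_numpy() for d, idx in pool.groupby(pool["loeuf_decile"].astype(int)).groups.items()}
    all_pool = pool.index.to_numpy()
    if all_pool.size == 0:
        raise ValueError("empty pool: nothing to draw from")
    cands = []
    for gid, stratum, decile in zip(target["gene_id"], strata.loc[target.index], target["loeuf_decile"].astype(int)):
        c = by_stratum.get(stratum)
        if c is None or c.size == 0:
            c = by_decile.get(decile)
            if c is None or c.size == 0:
                c = all_pool
            logger.warning("no pool gene in stratum %s for target %s; nearest-stratum fallback", stratum, gid)
        cands.append(c)
    return cands


def draw_matched_set(
    target: pd.DataFrame, pool: pd.DataFrame, strata: pd.Series, seed: int | np.random.Generator
) -> np.ndarray:
    """One matched random gene set: per target gene, a uniform draw with
    replacement from its stratum in the pool.  Returns pool gene_ids (a
    drawn set may repeat genes)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cands = _candidates_for_targets(target, pool, strata)
    return np.array([pool.loc[c[rng.integers(c.size)], "gene_id"] for c in cands])


def expected_ratio(
    target: pd.DataFrame,
    pool: pd.DataFrame,
    counts_by_gene: pd.DataFrame,
    n_case: int = 1,
    n_control: int = 1,
    mode: str = "de_novo",
    n_permutations: int = 10_000,
    seed: int | None = 0,
    strata: pd.Series | None = None,
    n_expression_bins: int = 5,
    n_length_bins: int = 5,
) -> MatchedNullSummary:
    """Permutation-averaged rate ratio of matched random gene sets.

    ``counts_by_gene`` is indexed by gene_id with columns ``events_case``
    and ``events_control`` (probands/siblings for DNM mode,
    transmitted/untransmitted for transmission mode).  Draws whose control
    count is zero are dropped from the average; if more than 1% of draws
    are undefined the ratio of summed counts across all draws is used
    instead (logged).
    """
    if strata is None:
        strata = stratify_pool(pd.concat([target, pool]), n_expression_bins, n_length_bins)
    rng = np.random.default_rng(seed)
    cands = _candidates_for_targets(target, pool, strata)
    case_by_gene = counts_by_gene["events_case"].reindex(pool["gene_id"]).fillna(0.0).to_numpy(float)
    ctrl_by_gene = counts_by_gene["events_control"].reindex(pool["gene_id"]).fillna(0.0).to_numpy(float)
    pos_of = {idx: i for i, idx in enumerate(pool.index)}
    draw_case = np.zeros(n_permutations)
    draw_ctrl = np.zeros(n_permutations)
    for c in cands:
        pos = np.fromiter((pos_of[i] for i in c), dtype=np.int64, count=c.size)
        picks = pos[rng.integers(c.size, size=n_permutations)]
        draw_case += case_by_gene[picks]
        draw_ctrl += ctrl_by_gene[picks]
    scale = n_control / n_case  # converts a count ratio to a per-sample rate ratio
    defined = draw_ctrl > 0
    n_undef = int(n_permutations - defined.sum())
    if n_undef == n_permutations:
        raise ValueError("all permutation draws had empty control counts")
    if n_undef > 0.01 * n_permutations:
        logger.warning("%d/%d permutation ratios undefined; using ratio of summed counts", n_undef, n_permutations)
        exp_ratio = float((draw_case.sum() / draw_ctrl.sum()) * scale)
    else:
        exp_ratio = float(np.mean(draw_case[defined] / draw_ctrl[defined]) * scale)
    qs = {q: float(np.quantile(draw_case[defined] / draw_ctrl[defined] * scale, q)) for q in (0.025, 0.5, 0.975)}
    return MatchedNullSummary(
        expected_ratio=exp_ratio,
        n_permutations=n_permutations,
        permutation_mean_case_rate=float(draw_case.mean() / n_case),
        permutation_mean_control_rate=float(draw_ctrl.mean() / n_control),
        quantiles=qs,
        seed=seed,
        n_undefined=n_undef,
        mode=mode,
    )


def enumerate_expected_ratio(
    target: pd.DataFrame,
    pool: pd.DataFrame,
    counts_by_gene: pd.DataFrame,
    n_case: int = 1,
    n_control: int = 1,
    strata: pd.Series | None = None,
    n_expression_bins: int = 5,
    n_length_bins: int = 5,
) -> float:
    """Exact expectation of the matched-draw ratio by exhaustive
    enumeration of all per-gene draw combinations (tiny pools only);
    the independent oracle for ``expected_ratio``."""
    if strata is None:
        strata = stratify_pool(pd.concat([target, pool]), n_expression_bins, n_length_bins)
    cands = _candidates_for_targets(target, pool, strata)
    n_combos = math.prod(c.size for c in cands)
    if n_combos > 2_000_000:
        raise ValueError(f"{n_combos} draw combinations: too many to enumerate")
    cg = counts_by_gene.reindex(pool["gene_id"]).fillna(0.0)
    case = dict(zip(pool.index, cg["events_case"]))
    ctrl = dict(zip(pool.index, cg["events_control"]))
    scale = n_control / n_case
    total, n_def = 0.0, 0
    for combo in itertools.product(*[list(c) for c in cands]):
        cs = sum(case[i] for i in combo)
        ct = sum(ctrl[i] for i in combo)
        if ct > 0:
            total += cs / ct * scale
            n_def += 1
    if n_def == 0:
        raise ValueError("all combinations undefined")
    return total / n_def


def test_vs_expected(
    events_case: int,
    events_control: int,
    null: MatchedNullSummary | float,
    n_case: int = 1,
    n_control: int = 1,
) -> burden.RateRatioResult:
    """Exact binomial test of the observed gene-set counts against the
    permutation-derived expected ratio R: the null split fraction becomes
    R*n_case/(R*n_case+n_control) (transmission: R/(1+R)); R = 1 reduces
    exactly to the exome-wide test."""
    R = null.expected_ratio if isinstance(null, MatchedNullSummary) else float(null)
    return burden.rate_ratio_test(events_case, events_control, n_case, n_control, expected_ratio=R)


def excess_liability(
    observed_case_rate: float,
    null: MatchedNullSummary,
    prevalence: float,
    p_binomial: float | None = None,
    variance: float = 1.0,
    method: str = "threshold_shift",
    label: str = "",
) -> LiabilityEstimate:
    """Liability attributed to a gene set in excess of matched genes: the
    carrier-shift conversion with the sibling/control rate replaced by the
    permutation-mean rate in the same (case) group."""
    if null.permutation_mean_case_rate <= 0:
        raise ValueError("permutation mean rate must be positive")
    est = liability_effect(
        observed_case_rate, null.permutation_mean_case_rate, prevalence, variance, method, label
    )
    if p_binomial is not None:
        est = dc_replace(se_and_ci(est.z, p_binomial, prevalence, label), prevalence_used=prevalence)
    return est
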