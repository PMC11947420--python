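"""Generative trio/duo cohort model under a sex-specific liability
threshold model.

Each child draws a normally distributed background liability (variance 1
by default, optionally higher in males), to which carried damaging
variants add fixed per-class shifts beta.  A child is autistic when the
total exceeds the sex-specific threshold implied by the configured
prevalences (2.5% in males, 4:1 male:female by default).  Families are
ascertained through an affected proband; one non-autistic sibling is
generated per ascertained family.  Co-occurring motor/cognitive
impairment is a second, higher threshold on the same liability axis
(default) or on a correlated second axis; either way the threshold is
calibrated so the impairment fraction among autistic probands matches the
configured targets (0.35 in males, 0.40 in females).

Variants are emitted in the same tab-delimited person/variant/gene
schemas the QC module consumes, so every downstream stage can be
validated by round-trip and parameter recovery.  Two sampling paths are
provided:

* ``simulate_cohort`` — table-level rejection sampling with full
  Mendelian bookkeeping (parental heterozygotes, transmitted and
  untransmitted alleles, per-gene de novo assignment);
* exact-conditional samplers (``proband_count_pmf`` and the replicate
  studies built on it) that draw per-child damaging counts directly from
  the distribution conditional on (un)affected status.  Conditioning is
  on proband status only, so these are distributionally identical to
  rejection sampling and keep replicate studies (hundreds of cohorts of
  tens of thousands of families) at desk scale.

All randomness flows through numpy's seedable PCG64 generator; a fixed
seed reproduces a cohort bit-for-bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import binomtest, multivariate_normal, norm, poisson

from .liability import (
    PrevalenceSpec,
    liability_estimate_from_counts,
    liability_threshold,
)

__all__ = [
    "SimulationConfig",
    "SimulatedCohort",
    "simulate_cohort",
    "emit_count_tables",
    "per_gene_count_table",
    "proband_count_pmf",
    "impairment_thresholds",
    "expected_sex_ratio_of_carriers",
    "sample_stratified_counts",
    "replicate_liability_recovery",
    "replicate_null_rejection",
    "sex_ratio_study",
    "asymptotic_liability_estimate",
    "null_exact_size",
]

DEFAULT_DNM_EXPECTED = {"damaging_PTV": 0.02, "damaging_missense": 0.06, "synonymous": 0.30}
DEFAULT_INHERITED_CARRIER_RATE = {"damaging_PTV": 0.05, "damaging_missense": 0.15, "synonymous": 0.50}
_CONSEQUENCE = {"damaging_PTV": "PTV", "damaging_missense": "missense", "synonymous": "synonymous"}
_MPC = {"damaging_PTV": float("nan"), "damaging_missense": 2.5, "synonymous": float("nan")}


@dataclass(frozen=True)
class SimulationConfig:
    """Generative parameters of a synthetic cohort.

    ``dnm_expected`` are expected de novo counts per child and class
    (i.e. 2 x the summed haploid per-generation gene rates);
    ``inherited_carrier_rate`` are expected heterozygous rare alleles per
    parent and class.  ``effect_sizes`` are carrier liability shifts in
    SD units per carried damaging allele.  Impairment targets are the
    fractions of autistic probands with co-occurring motor/cognitive
    impairment.
    """

    n_families: int = 1000
    male_prevalence: float = 0.025
    sex_ratio: float = 4.0
    male_variance: float = 1.0
    female_variance: float = 1.0
    n_genes: int = 200
    dnm_expected: dict = field(default_factory=lambda: dict(DEFAULT_DNM_EXPECTED))
    inherited_carrier_rate: dict = field(default_factory=lambda: dict(DEFAULT_INHERITED_CARRIER_RATE))
    effect_sizes: dict = field(default_factory=lambda: {"damaging_PTV": 0.0, "damaging_missense": 0.0, "synonymous": 0.0})
    impairment_mechanism: str = "shared_axis"  # or "correlated"
    impairment_target_male: float = 0.35
    impairment_target_female: float = 0.40
    impairment_correlation: float = 0.6
    impairment_threshold_offset: float | None = None  # SD units above the autism threshold; overrides calibration
    ascertainment: str = "proband_trio"
    seed: int = 0
    max_attempt_factor: int = 400  # candidate children per requested family before giving up

    def __post_init__(self) -> None:
        if self.n_families <= 0:
            raise ValueError("n_families must be positive")
        if not 0.0 < self.male_prevalence < 1.0:
            raise ValueError("male_prevalence must be in (0,1)")
        if self.sex_ratio <= 0:
            raise ValueError("sex_ratio must be positive")
        if self.ascertainment not in ("proband_trio", "duo", "case_control"):
            raise ValueError(f"unknown ascertainment {self.ascertainment!r}")
        if self.impairment_mechanism not in ("shared_axis", "correlated"):
            raise ValueError(f"unknown impairment mechanism {self.impairment_mechanism!r}")
        for b in self.effect_sizes.values():
            if not math.isfinite(b):
                raise ValueError("effect sizes must be finite")

    @property
    def prevalences(self) -> PrevalenceSpec:
        return PrevalenceSpec(
            male_prevalence=self.male_prevalence,
            male_to_female_ratio=self.sex_ratio,
            male_variance=self.male_variance,
            female_variance=self.female_variance,
        )

    def threshold(self, sex: str) -> float:
        spec = self.prevalences
        return liability_threshold(spec.prevalence(sex), spec.variance(sex)).t

    def sigma(self, sex: str) -> float:
        return math.sqrt(self.prevalences.variance(sex))

    @property
    def classes(self) -> list[str]:
        return sorted(set(self.dnm_expected) | set(self.inherited_carrier_rate) | set(self.effect_sizes))


@dataclass
class SimulatedCohort:
    persons: pd.DataFrame
    variants: pd.DataFrame
    genes: pd.DataFrame
    truth: dict
    config: SimulationConfig


# ---------------------------------------------------------------------------
# gene table


def build_gene_table(cfg: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Synthetic gene metadata: LOEUF deciles assigned evenly, lognormal
    brain expression and CDS length, a SFARI-like flag on a subset of
    decile-1 genes.  Damaging-PTV mutation rates are carried by decile-1
    genes only (PTVs elsewhere would not classify as damaging); missense
    and synonymous rates are uniform across genes."""
    g = cfg.n_genes
    decile = np.tile(np.arange(1, 11), g // 10 + 1)[:g]
    decile.sort()
    n_d1 = int((decile == 1).sum())
    mu_ptv = np.where(decile == 1, cfg.dnm_expected.get("damaging_PTV", 0.0) / 2.0 / max(n_d1, 1), 0.0)
    mu_mis = np.full(g, cfg.dnm_expected.get("damaging_missense", 0.0) / 2.0 / g)
    mu_syn = np.full(g, cfg.dnm_expected.get("synonymous", 0.0) / 2.0 / g)
    sfari = np.zeros(g, dtype=bool)
    d1_idx = np.flatnonzero(decile == 1)
    sfari[rng.choice(d1_idx, size=max(1, n_d1 // 3), replace=False)] = True
    genes = pd.DataFrame({
        "gene_id": [f"g{i:04d}" for i in range(g)],
        "loeuf_decile": decile,
        "brain_expression": np.round(rng.lognormal(2.0, 1.0, g), 4),
        "cds_length": np.round(rng.lognormal(7.5, 0.6, g)).astype(int) + 200,
        "sfari": sfari,
        "sfari_loeuf1": sfari & (decile == 1),
        "fetal_male_biased": False, "fetal_female_biased": False,
        "adult_male_biased": False, "adult_female_biased": False,
        "mutation_rate_ptv": mu_ptv,
        "mutation_rate_missense": mu_mis,
        "mutation_rate_synonymous": mu_syn,
    })
    return genes


def _class_gene_weights(cfg: SimulationConfig, genes: pd.DataFrame) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per class: (gene positions, normalized sampling weights) for
    assigning events to genes."""
    col = {"damaging_PTV": "mutation_rate_ptv", "damaging_missense": "mutation_rate_missense",
           "synonymous": "mutation_rate_synonymous"}
    out = {}
    for cls, c in col.items():
        w = genes[c].to_numpy(float)
        pos = np.flatnonzero(w > 0)
        if pos.size:
            out[cls] = (pos, w[pos] / w[pos].sum())
    return out


# ---------------------------------------------------------------------------
# impairment threshold calibration


def _shift_distribution(cfg: SimulationConfig, kmax: int = 8) -> tuple[np.ndarray, np.ndarray]:
    """Distribution of the total variant liability shift per child.

    Per-child carried damaging counts per class are Poisson to a very
    good approximation (many genes, small per-gene probabilities): the
    de novo component is Poisson exactly and the inherited component,
    expected ``carrier_rate`` per child (half of each parent's), is a
    sum of many small Bernoullis.
    """
    shifts = np.array([0.0])
    weights = np.array([1.0])
    for cls in cfg.classes:
        beta = cfg.effect_sizes.get(cls, 0.0)
        if beta == 0.0:
            continue
        lam = cfg.dnm_expected.get(cls, 0.0) + cfg.inherited_carrier_rate.get(cls, 0.0)
        if lam == 0.0:
            continue
        ks = np.arange(kmax + 1)
        pk = poisson.pmf(ks, lam)
        pk[-1] += poisson.sf(kmax, lam)
        shifts = (shifts[:, None] + beta * ks[None, :]).ravel()
        weights = (weights[:, None] * pk[None, :]).ravel()
    return shifts, weights


def _p_affected(cfg: SimulationConfig, sex: str) -> float:
    """Marginal P(autistic) for a child of the given sex, integrating the
    variant-shift distribution against the threshold."""
    shifts, weights = _shift_distribution(cfg)
    T, s = cfg.threshold(sex), cfg.sigma(sex)
    return float(np.sum(weights * norm.sf((T - shifts) / s)))


def impairment_thresholds(cfg: SimulationConfig) -> dict[str, float]:
    """Raw-scale impairment thresholds per sex.

    With an explicit ``impairment_threshold_offset`` the threshold is
    autism threshold + offset x sigma; otherwise it is calibrated by
    root-finding so P(impaired | autistic) equals the configured target
    under the analytic liability model.
    """
    out = {}
    shifts, weights = _shift_distribution(cfg)
    for sex, target in (("male", cfg.impairment_target_male), ("female", cfg.impairment_target_female)):
        T, s = cfg.threshold(sex), cfg.sigma(sex)
        if cfg.impairment_threshold_offset is not None:
            out[sex] = T + cfg.impairment_threshold_offset * s
            continue
        p_aff = float(np.sum(weights * norm.sf((T - shifts) / s)))

        if cfg.impairment_mechanism == "shared_axis":
            def frac(T2: float) -> float:
                hi = np.maximum(T2, T)
                return float(np.sum(weights * norm.sf((hi - shifts) / s))) / p_aff
        else:
            rho = cfg.impairment_correlation
            mvn = multivariate_normal(mean=[0.0, 0.0], cov=[[1.0, rho], [rho, 1.0]])

            def frac(T2: float) -> float:
                a = (T - shifts) / s
                b = (T2 - shifts) / s
                upper = 1.0 - norm.cdf(a) - norm.cdf(b) + np.array(
                    [mvn.cdf([ai, bi]) for ai, bi in zip(a, b)]
                )
                return float(np.sum(weights * np.clip(upper, 0.0, 1.0))) / p_aff

        out[sex] = brentq(lambda t2: frac(t2) - target, T - 2.0 * s, T + 8.0 * s, xtol=1e-8)
    return out


# ---------------------------------------------------------------------------
# table-level rejection-sampling simulator


def _draw_children(
    cfg: SimulationConfig,
    rng: np.random.Generator,
    n: int,
    mother_het: dict[str, np.ndarray],
    father_het: dict[str, np.ndarray],
) -> dict:
    """Vectorised draw of one child per family given parental genotypes:
    transmission coins, de novo totals, sex, background and total
    liability."""
    sex_male = rng.random(n) < 0.5
    sigma = np.where(sex_male, cfg.sigma("male"), cfg.sigma("female"))
    background = rng.standard_normal(n) * sigma
    shift = np.zeros(n)
    trans_m, trans_f, dnm = {}, {}, {}
    for cls in cfg.classes:
        beta = cfg.effect_sizes.get(cls, 0.0)
        if cls in mother_het:
            tm = mother_het[cls] & (rng.random(mother_het[cls].shape) < 0.5)
            tf = father_het[cls] & (rng.random(father_het[cls].shape) < 0.5)
            trans_m[cls], trans_f[cls] = tm, tf
            shift += beta * (tm.sum(axis=1) + tf.sum(axis=1))
        k = rng.poisson(cfg.dnm_expected.get(cls, 0.0), n)
        dnm[cls] = k
        shift += beta * k
    liability = background + shift
    threshold = np.where(sex_male, cfg.threshold("male"), cfg.threshold("female"))
    if cfg.impairment_mechanism == "shared_axis":
        liability2 = liability
    else:
        rho = cfg.impairment_correlation
        g2 = rng.standard_normal(n) * sigma
        liability2 = rho * background + math.sqrt(1.0 - rho**2) * g2 + shift
    return dict(
        sex_male=sex_male, liability=liability, liability2=liability2,
        affected=liability > threshold, trans_m=trans_m, trans_f=trans_f, dnm=dnm,
    )


def _parent_het(cfg: SimulationConfig, rng: np.random.Generator, n: int, genes: pd.DataFrame) -> dict[str, np.ndarray]:
    """Heterozygous rare-allele indicator matrix (families x genes in
    class) for one parent."""
    out = {}
    weights = _class_gene_weights(cfg, genes)
    for cls, rate in cfg.inherited_carrier_rate.items():
        if rate <= 0 or cls not in weights:
            continue
        pos, w = weights[cls]
        het_prob = rate * w  # per-gene heterozygote probability, summing to `rate`
        out[cls] = rng.random((n, pos.size)) < het_prob[None, :]
    return out


def simulate_cohort(cfg: SimulationConfig) -> SimulatedCohort:
    """Rejection-sampling simulation of an ascertained cohort with full
    per-gene, per-allele bookkeeping.

    Returns persons/variants/genes tables in the QC module's schemas plus
    a truth record (per-person latent liabilities, thresholds, effect
    sizes, seed).  Raises after a bounded number of candidate draws if
    ascertainment is infeasible (e.g. vanishing prevalence).
    """
    rng = np.random.default_rng(cfg.seed)
    genes = build_gene_table(cfg, rng)
    weights = _class_gene_weights(cfg, genes)
    imp_thr = impairment_thresholds(cfg)

    kept: list[dict] = []
    attempts = 0
    batch = max(1024, min(cfg.n_families * 64, 200_000))
    while len(kept) < cfg.n_families:
        if attempts > cfg.max_attempt_factor * cfg.n_families + batch:
            raise RuntimeError(
                f"ascertainment infeasible: {attempts} candidate families yielded {len(kept)} probands"
            )
        attempts += batch
        m_het = _parent_het(cfg, rng, batch, genes)
        f_het = _parent_het(cfg, rng, batch, genes)
        child = _draw_children(cfg, rng, batch, m_het, f_het)
        idx = np.flatnonzero(child["affected"])[: cfg.n_families - len(kept)]
        for i in idx:
            kept.append(dict(
                mother={cls: np.flatnonzero(m_het[cls][i]) for cls in m_het},
                father={cls: np.flatnonzero(f_het[cls][i]) for cls in f_het},
                proband=dict(
                    sex="male" if child["sex_male"][i] else "female",
                    liability=child["liability"][i], liability2=child["liability2"][i],
                    trans_m={cls: np.flatnonzero(child["trans_m"][cls][i]) for cls in child["trans_m"]},
                    trans_f={cls: np.flatnonzero(child["trans_f"][cls][i]) for cls in child["trans_f"]},
                    dnm={cls: child["dnm"][cls][i] for cls in child["dnm"]},
                ),
            ))

    # every ascertainment mode carries one unaffected child per family:
    # a sibling for trios/duos, an unrelated-style control for case_control
    _attach_siblings(cfg, rng, kept)

    persons, variants, liab_rows = _emit_tables(cfg, rng, kept, genes, weights, imp_thr)
    truth = dict(
        effect_sizes=dict(cfg.effect_sizes),
        thresholds={"male": cfg.threshold("male"), "female": cfg.threshold("female")},
        impairment_thresholds=imp_thr,
        liabilities=pd.DataFrame(liab_rows),
        seed=cfg.seed,
        n_candidate_children=attempts,
    )
    return SimulatedCohort(persons=persons, variants=variants, genes=genes, truth=truth, config=cfg)


def _attach_siblings(cfg: SimulationConfig, rng: np.random.Generator, kept: list[dict]) -> None:
    """One non-autistic sibling per ascertained family, redrawn (same
    parents) until unaffected."""
    pending = list(range(len(kept)))
    while pending:
        # per-family redraw; sibling rejection is cheap (>=97% acceptance)
        still = []
        for j in pending:
            fam = kept[j]
            m_idx, f_idx = fam["mother"], fam["father"]
            sex_male = rng.random() < 0.5
            sigma = cfg.sigma("male" if sex_male else "female")
            background = rng.standard_normal() * sigma
            shift = 0.0
            tm, tf, dnm = {}, {}, {}
            for cls in cfg.classes:
                beta = cfg.effect_sizes.get(cls, 0.0)
                if cls in m_idx:
                    coins_m = rng.random(m_idx[cls].size) < 0.5
                    coins_f = rng.random(f_idx[cls].size) < 0.5
                    tm[cls] = m_idx[cls][coins_m]
                    tf[cls] = f_idx[cls][coins_f]
                    shift += beta * (tm[cls].size + tf[cls].size)
                k = rng.poisson(cfg.dnm_expected.get(cls, 0.0))
                dnm[cls] = k
                shift += beta * k
            liability = background + shift
            if liability > cfg.threshold("male" if sex_male else "female"):
                still.append(j)  # autistic: redraw this sibling
                continue
            if cfg.impairment_mechanism == "shared_axis":
                liability2 = liability
            else:
                rho = cfg.impairment_correlation
                liability2 = rho * background + math.sqrt(1 - rho**2) * rng.standard_normal() * sigma + shift
            fam["sibling"] = dict(
                sex="male" if sex_male else "female", liability=liability, liability2=liability2,
                trans_m=tm, trans_f=tf, dnm=dnm,
            )
        pending = still


def _emit_tables(cfg, rng, kept, genes, weights, imp_thr):
    """Materialise persons/variants tables from the kept family records."""
    gene_ids = genes["gene_id"].to_numpy()
    persons, variants, liab = [], [], []
    duo = cfg.ascertainment == "duo"
    case_control = cfg.ascertainment == "case_control"

    def add_person(pid, fid, sex, role, autism, child_rec=None):
        imp = "unknown"
        if child_rec is not None and role == "proband":
            imp = "yes" if child_rec["liability2"] > imp_thr[sex] else "no"
        if role == "sibling":
            imp = "no"
        persons.append(dict(
            person_id=pid, family_id=fid, sex=sex, role=role, autism=autism,
            cognitive_impairment=imp, motor_delay="no" if role in ("proband", "sibling") else "unknown",
            iq=np.nan,
        ))
        if child_rec is not None:
            liab.append(dict(person_id=pid, liability=child_rec["liability"], liability2=child_rec["liability2"]))

    def add_dnm_rows(fid, cid, child_rec):
        for cls, k in child_rec["dnm"].items():
            if k == 0 or cls not in weights:
                continue
            pos, w = weights[cls]
            picks = rng.choice(pos, size=k, p=w)
            for gp in picks:
                variants.append(_vrow(fid, cid, gene_ids[gp], cls, "de_novo"))

    def add_transmission_rows(fid, cid, fam, child_rec):
        parents = [("mother", fam["mother"], child_rec["trans_m"])]
        if not duo:
            parents.append(("father", fam["father"], child_rec["trans_f"]))
        for pname, het, trans in parents:
            for cls, het_pos in het.items():
                tset = set(trans[cls].tolist())
                for gp in het_pos:
                    kind = f"transmitted_{pname}" if gp in tset else f"untransmitted_{pname}"
                    variants.append(_vrow(fid, cid, gene_ids[gp], cls, kind))

    for i, fam in enumerate(kept):
        fid = f"f{i:05d}"
        pro = fam["proband"]
        pid = f"{fid}_p"
        add_person(pid, fid, pro["sex"], "proband", True, pro)
        if not case_control:
            add_person(f"{fid}_m", fid, "female", "mother", False)
            if not duo:
                add_person(f"{fid}_f", fid, "male", "father", False)
        sib = fam["sibling"]
        sid = f"{fid}_s"
        add_person(sid, fid, sib["sex"], "sibling", False, sib)
        add_dnm_rows(fid, pid, pro)
        add_dnm_rows(fid, sid, sib)
        if not case_control:
            add_transmission_rows(fid, pid, fam, pro)

    persons_df = pd.DataFrame(persons, columns=["person_id", "family_id", "sex", "role", "autism",
                                                "cognitive_impairment", "motor_delay", "iq"])
    vcols = ["family_id", "child_id", "gene_id", "consequence", "mpc", "inheritance",
             "af_cohort", "af_gnomad", "n_families_with_allele", "dp", "gq", "vaf", "variant_class_true"]
    variants_df = pd.DataFrame(variants, columns=vcols)
    return persons_df, variants_df, liab


def _vrow(fid, cid, gid, cls, inheritance):
    return dict(
        family_id=fid, child_id=cid, gene_id=gid, consequence=_CONSEQUENCE[cls],
        mpc=_MPC[cls], inheritance=inheritance, af_cohort=1e-5, af_gnomad=np.nan,
        n_families_with_allele=1, dp=50, gq=99, vaf=0.5, variant_class_true=cls,
    )


# ---------------------------------------------------------------------------
# count-table emission (independent bookkeeping used as a cross-module oracle)


def emit_count_tables(cohort: SimulatedCohort, cohort_label: str = "sim") -> pd.DataFrame:
    """BurdenCounts table computed directly from the simulator's own
    records by plain counting; ``qc.tabulate_counts`` applied to the
    emitted raw tables must agree exactly (round-trip identity)."""
    persons, variants = cohort.persons, cohort.variants
    rows = []
    pro = persons[persons["role"] == "proband"]
    sib = persons[persons["role"] == "sibling"]
    classes = sorted(variants["variant_class_true"].unique()) if len(variants) else []
    sexes = {"female": ("female",), "male": ("male",), "both": ("female", "male")}
    for label, sel in sexes.items():
        pro_ids = {p for p, s in zip(pro["person_id"], pro["sex"]) if s in sel}
        sib_ids = {p for p, s in zip(sib["person_id"], sib["sex"]) if s in sel}
        if not pro_ids or not sib_ids:
            continue
        for cls in classes:
            sub = variants[variants["variant_class_true"] == cls]
            dn = sub[sub["inheritance"] == "de_novo"]
            rows.append(dict(cohort=cohort_label, sex=label, phenotype_group="all", variant_class=cls,
                             mode="de_novo",
                             events_case=int(sum(c in pro_ids for c in dn["child_id"])),
                             events_control=int(sum(c in sib_ids for c in dn["child_id"])),
                             n_case=len(pro_ids), n_control=len(sib_ids)))
            tr = sub[sub["inheritance"].str.startswith("transmitted") & sub["child_id"].isin(pro_ids)]
            un = sub[sub["inheritance"].str.startswith("untransmitted") & sub["child_id"].isin(pro_ids)]
            rows.append(dict(cohort=cohort_label, sex=label, phenotype_group="all", variant_class=cls,
                             mode="transmitted_untransmitted",
                             events_case=len(tr), events_control=len(un),
                             n_case=None, n_control=None))
    cols = ["cohort", "sex", "phenotype_group", "variant_class", "mode",
            "events_case", "events_control", "n_case", "n_control"]
    out = pd.DataFrame(rows, columns=cols)
    return out.sort_values(cols[:5], kind="mergesort").reset_index(drop=True)


def per_gene_count_table(cohort: SimulatedCohort, mode: str = "de_novo") -> pd.DataFrame:
    """Per-gene event counts (probands vs siblings for DNMs; transmitted
    vs untransmitted for inherited alleles), indexed by gene_id — the
    input format of the gene-set permutation null."""
    persons, variants = cohort.persons, cohort.variants
    pro = set(persons.loc[persons["role"] == "proband", "person_id"])
    sib = set(persons.loc[persons["role"] == "sibling", "person_id"])
    if mode == "de_novo":
        dn = variants[variants["inheritance"] == "de_novo"]
        case = dn[dn["child_id"].isin(pro)].groupby("gene_id").size()
        ctrl = dn[dn["child_id"].isin(sib)].groupby("gene_id").size()
    elif mode == "transmitted_untransmitted":
        inh = variants[variants["child_id"].isin(pro)]
        case = inh[inh["inheritance"].str.startswith("transmitted")].groupby("gene_id").size()
        ctrl = inh[inh["inheritance"].str.startswith("untransmitted")].groupby("gene_id").size()
    else:
        raise ValueError(f"unknown mode {mode!r}")
    out = pd.DataFrame({"events_case": case, "events_control": ctrl}).reindex(
        cohort.genes["gene_id"]
    ).fillna(0).astype(int)
    out.index.name = "gene_id"
    return out


# ---------------------------------------------------------------------------
# exact-conditional samplers and replicate studies


def proband_count_pmf(
    cfg: SimulationConfig, sex: str, class_name: str, affected: bool = True, kmax: int = 12
) -> np.ndarray:
    """Distribution of the per-child de novo damaging count of one class
    conditional on (un)affected status, for configs where only that class
    shifts liability:  P(k | status) ∝ Poisson(k; lam) x tail
    probability of the background beyond the shifted threshold."""
    for cls, beta in cfg.effect_sizes.items():
        if beta != 0.0 and cls != class_name:
            raise ValueError("exact-conditional sampling supports a single effective class")
    for cls, beta in cfg.effect_sizes.items():
        if beta != 0.0 and cfg.inherited_carrier_rate.get(cls, 0.0) > 0:
            raise ValueError("exact-conditional sampling assumes a de-novo-only effective class")
    lam = cfg.dnm_expected.get(class_name, 0.0)
    beta = cfg.effect_sizes.get(class_name, 0.0)
    T, s = cfg.threshold(sex), cfg.sigma(sex)
    ks = np.arange(kmax + 1)
    w = poisson.pmf(ks, lam)
    tail = norm.sf((T - beta * ks) / s)
    w = w * (tail if affected else (1.0 - tail))
    return w / w.sum()


def _proband_male_fraction(cfg: SimulationConfig) -> float:
    pm = _p_affected(cfg, "male")
    pf = _p_affected(cfg, "female")
    return pm / (pm + pf)


def sample_stratified_counts(
    cfg: SimulationConfig, rng: np.random.Generator, class_name: str, kmax: int = 12
) -> dict:
    """One cohort's sex-stratified event counts for one variant class,
    via exact-conditional sampling: probands ascertained as affected
    (sex split follows the sex-specific prevalences), one unaffected
    sibling per family with fair sex."""
    n = cfg.n_families
    n_mp = int(rng.binomial(n, _proband_male_fraction(cfg)))
    n_fp = n - n_mp
    n_ms = int(rng.binomial(n, 0.5))
    n_fs = n - n_ms
    ks = np.arange(kmax + 1)
    out = {}
    for sex, n_pro, n_sib in (("male", n_mp, n_ms), ("female", n_fp, n_fs)):
        p_aff = proband_count_pmf(cfg, sex, class_name, affected=True, kmax=kmax)
        p_un = proband_count_pmf(cfg, sex, class_name, affected=False, kmax=kmax)
        out[sex] = dict(
            n_probands=n_pro, n_siblings=n_sib,
            events_probands=int(rng.choice(ks, size=n_pro, p=p_aff).sum()) if n_pro else 0,
            events_siblings=int(rng.choice(ks, size=n_sib, p=p_un).sum()) if n_sib else 0,
        )
    return out


def replicate_liability_recovery(
    cfg: SimulationConfig,
    n_replicates: int = 200,
    seed: int = 0,
    class_name: str = "damaging_PTV",
    sex: str = "male",
) -> pd.DataFrame:
    """Parameter-recovery study: for each replicate cohort, the
    liability-scale effect of the class estimated from sex-matched
    proband/sibling counts, with its 95% CI and whether it covers the
    true carrier shift."""
    beta = cfg.effect_sizes.get(class_name, 0.0)
    rng = np.random.default_rng(seed)
    spec = cfg.prevalences
    rows = []
    for _ in range(n_replicates):
        counts = sample_stratified_counts(cfg, rng, class_name)[sex]
        est = liability_estimate_from_counts(
            counts["events_probands"], counts["n_probands"],
            counts["events_siblings"], counts["n_siblings"],
            spec.prevalence(sex), spec.variance(sex),
        )
        rows.append(dict(z=est.z, se=est.se, ci_low=est.ci_low, ci_high=est.ci_high,
                         covered=bool(est.ci_low <= beta <= est.ci_high)))
    return pd.DataFrame(rows)


def replicate_null_rejection(
    cfg: SimulationConfig,
    n_replicates: int = 2000,
    seed: int = 0,
    class_name: str = "synonymous",
    alpha: float = 0.05,
) -> float:
    """Size of the exact binomial burden test under the simulator's null
    (no variant effects): the fraction of replicate cohorts rejecting at
    level alpha."""
    if any(b != 0.0 for b in cfg.effect_sizes.values()):
        raise ValueError("null calibration requires all effect sizes zero")
    rng = np.random.default_rng(seed)
    lam = cfg.dnm_expected.get(class_name, 0.0)
    n = cfg.n_families
    rejections = 0
    n_pro = n_sib = n  # one sibling per family, sexes pooled
    for _ in range(n_replicates):
        ev_p = int(rng.poisson(lam * n_pro))
        ev_s = int(rng.poisson(lam * n_sib))
        if ev_p + ev_s == 0:
            continue
        p = binomtest(ev_p, ev_p + ev_s, n_pro / (n_pro + n_sib)).pvalue
        rejections += p < alpha
    return rejections / n_replicates


def sex_ratio_study(
    cfg_base: SimulationConfig,
    betas: Iterable[float],
    n_families: int = 50_000,
    seed: int = 0,
    class_name: str = "damaging_PTV",
) -> pd.DataFrame:
    """Headline-reproduction study: at each carrier shift beta, the
    simulated female:male proband DNM rate ratio (observed scale), its
    analytic expectation, and the female-minus-male liability-scale
    difference with its standard error."""
    from dataclasses import replace as dc_replace

    from .liability import sex_difference_liability

    rows = []
    rng = np.random.default_rng(seed)
    for i, beta in enumerate(betas):
        cfg = dc_replace(
            cfg_base, n_families=n_families,
            effect_sizes={**cfg_base.effect_sizes, class_name: float(beta)},
        )
        counts = sample_stratified_counts(cfg, rng, class_name)
        est = {}
        for sex in ("male", "female"):
            c = counts[sex]
            est[sex] = liability_estimate_from_counts(
                c["events_probands"], c["n_probands"], c["events_siblings"], c["n_siblings"],
                cfg.prevalences.prevalence(sex), cfg.prevalences.variance(sex),
            )
        c_f, c_m = counts["female"], counts["male"]
        rate_f = c_f["events_probands"] / c_f["n_probands"]
        rate_m = c_m["events_probands"] / c_m["n_probands"]
        diff = sex_difference_liability(est["female"].z, est["female"].se, est["male"].z, est["male"].se)
        rows.append(dict(
            beta=float(beta),
            observed_fm_rate_ratio=rate_f / rate_m,
            expected_fm_rate_ratio=expected_sex_ratio_of_carriers(cfg, class_name),
            z_female=est["female"].z, z_male=est["male"].z,
            z_diff=diff.z_diff, se_diff=diff.se_diff, p_diff=diff.p_value,
        ))
    return pd.DataFrame(rows)


def asymptotic_liability_estimate(
    cfg: SimulationConfig, class_name: str = "damaging_PTV", sex: str = "male", kmax: int = 12
) -> float:
    """Large-sample limit of the liability-effect estimator under the
    generative model: the z implied by the analytic proband and sibling
    count rates.

    Because probands can carry more than one damaging variant (Poisson
    multiplicity) while the rate-based penetrance treats the count rate
    as a single-carrier frequency, the limit is slightly attenuated
    relative to the true per-allele shift beta (about -1% at beta = 0.6
    and -4% at beta = 1.0 with the default de novo rate)."""
    ks = np.arange(kmax + 1)
    p_aff = proband_count_pmf(cfg, sex, class_name, affected=True, kmax=kmax)
    p_un = proband_count_pmf(cfg, sex, class_name, affected=False, kmax=kmax)
    from .liability import liability_effect

    spec = cfg.prevalences
    return liability_effect(
        float(np.sum(ks * p_aff)), float(np.sum(ks * p_un)),
        spec.prevalence(sex), spec.variance(sex), check_rare=False,
    ).z


def null_exact_size(cfg: SimulationConfig, class_name: str = "synonymous", alpha: float = 0.05) -> float:
    """Analytic rejection probability of the exact binomial burden test
    under the simulator's null (equal proband/sibling rates): the exact
    minimum-likelihood test size at each Poisson total event count,
    averaged over that count's distribution.  Slightly below alpha by
    discreteness."""
    from scipy.stats import binom

    lam = cfg.dnm_expected.get(class_name, 0.0)
    mean_total = 2.0 * lam * cfg.n_families
    lo = max(1, int(mean_total - 8 * math.sqrt(mean_total)))
    hi = int(mean_total + 8 * math.sqrt(mean_total)) + 1
    total = 0.0
    for N in range(lo, hi):
        pmf = binom.pmf(np.arange(N + 1), N, 0.5)
        order = np.argsort(pmf)
        cum = np.cumsum(pmf[order])
        ranks = np.searchsorted(pmf[order], pmf * (1 + 1e-12), side="right")
        size_n = float(pmf[cum[ranks - 1] < alpha].sum())
        total += poisson.pmf(N, mean_total) * size_n
    return total


def expected_sex_ratio_of_carriers(cfg: SimulationConfig, class_name: str = "damaging_PTV", kmax: int = 12) -> float:
    """Analytic female:male ratio of per-proband damaging-count rates
    among ascertained probands, by integrating the liability model; the
    different-threshold model predicts a female excess that grows with
    the carrier shift."""
    ks = np.arange(kmax + 1)
    rates = {}
    for sex in ("female", "male"):
        pmf = proband_count_pmf(cfg, sex, class_name, affected=True, kmax=kmax)
        rates[sex] = float(np.sum(ks * pmf))
    return rates["female"] / rates["male"]
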