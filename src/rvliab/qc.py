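"""Variant classification, genotype-level QC, rarity tiers, unrelated-set
pruning and stratum count tabulation.

The contract boundary is a pre-filtered per-variant table (site-quality
filtering, annotation and kinship inference happen upstream); this module
applies the genotype thresholds (DP >= 10, GQ >= 10, VAF >= 0.25 — the
paper's exclusions are phrased as strict '<', so passes are inclusive),
the rarity tiers (cohort and gnomAD MAF < 0.1%; ultra-rare: single family
and absent from gnomAD, or AF < 0.005% for case-control data), the
damaging-variant definitions (PTVs in the most LoF-intolerant LOEUF
decile(s); missense with MPC >= 2, or >= 1 relaxed), the greedy
maximal-unrelated selection that preferentially retains females, the
phenotype stratification schemes, and finally the aggregation of
per-variant rows into per-stratum BurdenCounts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

VARIANT_COLUMNS = [
    "family_id", "child_id", "gene_id", "consequence", "mpc", "inheritance",
    "af_cohort", "af_gnomad", "n_families_with_allele", "dp", "gq", "vaf",
]
PERSON_COLUMNS = [
    "person_id", "family_id", "sex", "role", "autism",
    "cognitive_impairment", "motor_delay", "iq",
]

TRANSMITTED = ("transmitted_mother", "transmitted_father")
UNTRANSMITTED = ("untransmitted_mother", "untransmitted_father")

__all__ = [
    "ClassificationConfig",
    "genotype_pass",
    "rarity_pass",
    "classify_variant",
    "max_unrelated",
    "phenotype_stratify",
    "tabulate_counts",
]


@dataclass(frozen=True)
class ClassificationConfig:
    """Damaging-variant thresholds: strict (decile 1, MPC >= 2) by
    default; the relaxed sensitivity filters admit deciles 2-3 and
    MPC >= 1."""

    ptv_decile_max: int = 1
    mpc_threshold: float = 2.0
    rarity_mode: str = "rare_0.1pct"

    def __post_init__(self) -> None:
        if not 1 <= self.ptv_decile_max <= 10:
            raise ValueError("ptv_decile_max must be in 1..10")
        if self.mpc_threshold <= 0:
            raise ValueError("mpc_threshold must be positive")
        if self.rarity_mode not in ("rare_0.1pct", "ultra_rare_duo", "ultra_rare_casecontrol"):
            raise ValueError(f"unknown rarity mode {self.rarity_mode!r}")


def genotype_pass(variants: pd.DataFrame) -> pd.Series:
    """Genotype-level QC: DP >= 10, GQ >= 10 and VAF >= 0.25, all
    inclusive at the boundary.  Missing metrics fail closed (warned)."""
    dp = pd.to_numeric(variants["dp"], errors="coerce")
    gq = pd.to_numeric(variants["gq"], errors="coerce")
    vaf = pd.to_numeric(variants["vaf"], errors="coerce")
    missing = dp.isna() | gq.isna() | vaf.isna()
    if missing.any():
        warnings.warn(f"{int(missing.sum())} genotypes with missing QC metrics fail closed", stacklevel=2)
    return ((dp >= 10) & (gq >= 10) & (vaf >= 0.25)).fillna(False) & ~missing


def rarity_pass(variants: pd.DataFrame, mode: str = "rare_0.1pct") -> pd.Series:
    """Allele-frequency tier filter.  ``rare_0.1pct``: cohort and gnomAD
    MAF < 0.1% (absent from gnomAD counts as passing); ``ultra_rare_duo``:
    seen in exactly one family and absent from gnomAD;
    ``ultra_rare_casecontrol``: cohort AF strictly below 0.005%."""
    af_c = pd.to_numeric(variants["af_cohort"], errors="coerce")
    af_g = pd.to_numeric(variants["af_gnomad"], errors="coerce")
    if mode == "rare_0.1pct":
        return (af_c < 0.001) & (af_g.isna() | (af_g < 0.001))
    if mode == "ultra_rare_duo":
        nfam = pd.to_numeric(variants["n_families_with_allele"], errors="coerce")
        return (nfam == 1) & (af_g.isna() | (af_g == 0.0))
    if mode == "ultra_rare_casecontrol":
        return af_c < 0.00005
    raise ValueError(f"unknown rarity mode {mode!r}")


def classify_variant(
    variants: pd.DataFrame, genes: pd.DataFrame, cfg: ClassificationConfig = ClassificationConfig()
) -> pd.Series:
    """Variant class per row: damaging_PTV for PTVs in genes at or below
    the configured LOEUF decile, damaging_missense for missense with
    MPC >= threshold, synonymous passthrough, otherwise 'other'.
    Variants in genes missing from the gene table become 'other'
    (warned)."""
    decile = variants["gene_id"].map(genes.set_index("gene_id")["loeuf_decile"])
    unknown = decile.isna()
    if unknown.any():
        warnings.warn(f"{int(unknown.sum())} variants in unknown genes classified as 'other'", stacklevel=2)
    mpc = pd.to_numeric(variants["mpc"], errors="coerce")
    cls = pd.Series("other", index=variants.index, dtype=object)
    cls[(variants["consequence"] == "PTV") & (decile <= cfg.ptv_decile_max)] = "damaging_PTV"
    cls[(variants["consequence"] == "missense") & (mpc >= cfg.mpc_threshold)] = "damaging_missense"
    cls[variants["consequence"] == "synonymous"] = "synonymous"
    return cls.rename("variant_class")


def max_unrelated(relatedness_pairs, persons: pd.DataFrame) -> set:
    """Greedy maximal unrelated set: while any relatedness edge remains,
    remove the individual with the most relatives; ties are broken by
    removing a male before a female, then by lexicographically smaller
    id.  Individuals with no edges are always retained."""
    sex = dict(zip(persons["person_id"], persons["sex"]))
    adj: dict[str, set] = {p: set() for p in persons["person_id"]}
    for a, b in relatedness_pairs:
        if a not in adj or b not in adj:
            raise ValueError(f"relatedness pair ({a},{b}) references unknown person")
        if a != b:
            adj[a].add(b)
            adj[b].add(a)
    removed = set()
    while True:
        deg = {p: len(nb) for p, nb in adj.items() if p not in removed and nb - removed}
        if not deg:
            break
        victim = min(deg, key=lambda p: (-deg[p], 0 if sex.get(p) == "male" else 1, p))
        removed.add(victim)
    return set(persons["person_id"]) - removed


def phenotype_stratify(persons: pd.DataFrame, scheme: str = "spark_motor_cognitive", iq_cutoff: int | None = None) -> pd.Series:
    """Phenotype group per proband.

    ``asc_cognitive`` (IQ cutoff 70 by default): 'impaired' for reported
    cognitive impairment or IQ below the cutoff, everyone else (including
    unknowns) 'not_impaired_or_unknown'.  ``spark_motor_cognitive`` (IQ
    cutoff 80): 'impaired' for IQ < cutoff, cognitive impairment or motor
    delay; 'not_impaired' only with an explicit 'no' on every flag;
    otherwise 'unclassified'.  Non-probands get ''.
    """
    if scheme not in ("asc_cognitive", "spark_motor_cognitive"):
        raise ValueError(f"unknown scheme {scheme!r}")
    cutoff = iq_cutoff if iq_cutoff is not None else (70 if scheme == "asc_cognitive" else 80)
    iq = pd.to_numeric(persons["iq"], errors="coerce")
    cog = persons["cognitive_impairment"].astype(str)
    motor = persons["motor_delay"].astype(str)
    low_iq = iq < cutoff
    out = pd.Series("", index=persons.index, dtype=object)
    proband = persons["role"] == "proband"
    if scheme == "asc_cognitive":
        impaired = (cog == "yes") | low_iq
        out[proband] = np.where(impaired[proband], "impaired", "not_impaired_or_unknown")
        return out.rename("phenotype_group")
    impaired = (cog == "yes") | (motor == "yes") | low_iq
    clean = (cog == "no") & (motor == "no") & (iq.isna() | (iq >= cutoff))
    grp = np.select([impaired[proband], clean[proband]], ["impaired", "not_impaired"], default="unclassified")
    out[proband] = grp
    return out.rename("phenotype_group")


def _count_stratum(
    variants: pd.DataFrame, persons: pd.DataFrame, cohort: str, sexes: dict
) -> list[dict]:
    """Aggregate classified, person-joined variant rows into BurdenCounts
    rows for one (sex-selection label -> sex filter) mapping."""
    rows: list[dict] = []
    probands = persons[persons["role"] == "proband"]
    siblings = persons[persons["role"] == "sibling"]
    classes = sorted(variants["variant_class"].unique()) if len(variants) else []
    groups = sorted(g for g in probands["phenotype_group"].unique() if g != "") or ["all"]
    for sex_label, sex_sel in sexes.items():
        pro_sex = probands[probands["sex"].isin(sex_sel)]
        sib_sex = siblings[siblings["sex"].isin(sex_sel)]
        for group in ["all"] + [g for g in groups if g != "all"]:
            pro = pro_sex if group == "all" else pro_sex[pro_sex["phenotype_group"] == group]
            if len(pro) == 0 or len(sib_sex) == 0:
                continue
            pro_ids = set(pro["person_id"])
            sib_ids = set(sib_sex["person_id"])
            for mode in ("de_novo", "transmitted_untransmitted"):
                for cls in classes:
                    sub = variants[variants["variant_class"] == cls]
                    if mode == "de_novo":
                        dn = sub[sub["inheritance"] == "de_novo"]
                        ev_case = int(dn["child_id"].isin(pro_ids).sum())
                        ev_ctrl = int(dn["child_id"].isin(sib_ids).sum())
                        rows.append(dict(
                            cohort=cohort, sex=sex_label, phenotype_group=group,
                            variant_class=cls, mode="de_novo",
                            events_case=ev_case, events_control=ev_ctrl,
                            n_case=len(pro), n_control=len(sib_sex),
                        ))
                    else:
                        keep = sub["child_id"].isin(pro_ids)
                        t = int((keep & sub["inheritance"].isin(TRANSMITTED)).sum())
                        u = int((keep & sub["inheritance"].isin(UNTRANSMITTED)).sum())
                        rows.append(dict(
                            cohort=cohort, sex=sex_label, phenotype_group=group,
                            variant_class=cls, mode="transmitted_untransmitted",
                            events_case=t, events_control=u,
                            n_case=None, n_control=None,
                        ))
    return rows


def tabulate_counts(
    variants: pd.DataFrame,
    persons: pd.DataFrame,
    genes: pd.DataFrame,
    cfg: ClassificationConfig = ClassificationConfig(),
    scheme: str | None = None,
    cohort: str = "cohort",
    apply_genotype_qc: bool = True,
) -> pd.DataFrame:
    """Per-stratum BurdenCounts table from raw per-variant and per-person
    tables: QC filter, rarity tier, classification, phenotype
    stratification, then counting per (sex x phenotype group x class x
    mode); de novo events are counted per child against same-sex
    siblings, transmission events per parental allele in probands.
    Variants carried by unknown persons are dropped with a warning.
    """
    v = variants.copy()
    if apply_genotype_qc:
        v = v[genotype_pass(v) & rarity_pass(v, cfg.rarity_mode)]
    v = v.assign(variant_class=classify_variant(v, genes, cfg))
    known = v["child_id"].isin(set(persons["person_id"]))
    if (~known).any():
        warnings.warn(f"dropping {int((~known).sum())} variant rows with unknown child_id", stacklevel=2)
        v = v[known]
    p = persons.copy()
    if scheme is not None:
        p = p.assign(phenotype_group=phenotype_stratify(p, scheme))
    else:
        p = p.assign(phenotype_group=np.where(p["role"] == "proband", "all", ""))
    sexes = {"female": {"female"}, "male": {"male"}, "both": {"female", "male"}}
    rows = _count_stratum(v, p, cohort, sexes)
    cols = ["cohort", "sex", "phenotype_group", "variant_class", "mode",
            "events_case", "events_control", "n_case", "n_control"]
    out = pd.DataFrame(rows, columns=cols)
    return out.sort_values(cols[:5], kind="mergesort").reset_index(drop=True)
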