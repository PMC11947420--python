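"""End-to-end orchestration of the analysis recipe.

classify -> stratify -> counts -> burden -> liability -> (gene set) ->
meta -> multiplicity, from tab-delimited person/variant/gene tables to a
single results table with one row per stratum x test carrying the rate
ratio, exact CI and p-value, liability z/se/CI, and FDR/Bonferroni
adjusted p-values with significance tiers.  A JSON manifest records the
configuration hash and seeds; a rerun with the same configuration is
bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .liability import (
    PrevalenceSpec,
    liability_estimate_from_counts,
    sex_difference_liability,
    subgroup_prevalence,
)
from .meta import MetaInput, adjust_results_table, ivw_meta, ivw_meta_rate_ratios
from .burden import burden_table, sex_difference_observed
from .qc import ClassificationConfig, tabulate_counts

__all__ = ["RunConfig", "run_pipeline", "prevalence_for_group", "liability_for_results"]


def _as_proportion(x: float) -> float:
    """Config prevalences may be given in percent; normalize once here."""
    return x / 100.0 if x >= 1.0 else x


@dataclass
class RunConfig:
    persons: str = ""
    variants: str = ""
    genes: str = ""
    cohort: str = "cohort"
    male_prevalence: float = 0.025
    sex_ratio: float = 4.0
    variance_ratio: float = 1.0  # male over female liability variance
    subgroup_proportion_male: float | None = None
    subgroup_proportion_female: float | None = None
    ptv_decile_max: int = 1
    mpc_threshold: float = 2.0
    rarity_mode: str = "rare_0.1pct"
    scheme: str | None = None
    family_size: int | None = None
    n_permutations: int = 10_000
    seed: int = 0
    out_dir: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.male_prevalence = _as_proportion(cfg.male_prevalence)
        return cfg

    @property
    def prevalences(self) -> PrevalenceSpec:
        return PrevalenceSpec(
            male_prevalence=self.male_prevalence,
            male_to_female_ratio=self.sex_ratio,
            male_variance=self.variance_ratio,
            female_variance=1.0,
            subgroup_proportion_male=self.subgroup_proportion_male,
            subgroup_proportion_female=self.subgroup_proportion_female,
        )

    @property
    def classification(self) -> ClassificationConfig:
        return ClassificationConfig(
            ptv_decile_max=self.ptv_decile_max,
            mpc_threshold=self.mpc_threshold,
            rarity_mode=self.rarity_mode,
        )

    def analysis_config(self) -> dict:
        """The configuration that determines the analysis output
        (out_dir only chooses where it lands)."""
        d = asdict(self)
        d.pop("out_dir")
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.analysis_config(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def prevalence_for_group(spec: PrevalenceSpec, sex: str, group: str) -> float | None:
    """Sex prevalence scaled for a phenotype subgroup: the featured
    fraction for the impaired group, its complement for the explicitly
    unimpaired (or unknown-merged) group, the full sex prevalence for
    'all'; None when the subgroup proportion is not configured or the
    group cannot be assigned a prevalence."""
    base = spec.prevalence(sex)
    if group == "all":
        return base
    prop = {"male": spec.subgroup_proportion_male, "female": spec.subgroup_proportion_female}[sex]
    if prop is None:
        return None
    featured, complement = subgroup_prevalence(base, prop)
    if group == "impaired":
        return featured
    if group in ("not_impaired", "not_impaired_or_unknown"):
        return complement
    return None


def liability_for_results(results: pd.DataFrame, spec: PrevalenceSpec) -> pd.DataFrame:
    """Append liability-scale columns (z, se, CI, p) to a burden results
    table, per sex-specific row.  Transmission rows use the
    transmitted/untransmitted split with unit denominators; the 'both'
    and zero-event rows are left NaN."""
    out = results.copy()
    for col in ("liability_z", "liability_se", "liability_ci_low", "liability_ci_high", "liability_p"):
        out[col] = np.nan
    for i, r in out.iterrows():
        if r["sex"] not in ("female", "male") or r["events_case"] + r["events_control"] == 0:
            continue
        prev = prevalence_for_group(spec, r["sex"], r["phenotype_group"])
        if prev is None:
            continue
        var = spec.variance(r["sex"])
        if r["mode"] == "transmitted_untransmitted":
            n_case = n_ctrl = 1
        else:
            if not (r["n_case"] and r["n_control"]):
                continue
            n_case, n_ctrl = int(r["n_case"]), int(r["n_control"])
        try:
            est = liability_estimate_from_counts(
                int(r["events_case"]), n_case, int(r["events_control"]), n_ctrl, prev, var
            )
        except ValueError:
            continue
        out.loc[i, ["liability_z", "liability_se", "liability_ci_low", "liability_ci_high", "liability_p"]] = [
            est.z, est.se, est.ci_low, est.ci_high, est.p_value,
        ]
    return out


def _sex_difference_rows(results: pd.DataFrame) -> pd.DataFrame:
    """Female-vs-male contrast rows (observed scale for DNM rates,
    liability scale for both modes) per stratum."""
    rows = []
    key = ["cohort", "phenotype_group", "variant_class", "mode"]
    for vals, sub in results[results["sex"].isin(["female", "male"])].groupby(key):
        sub = sub.set_index("sex")
        if not {"female", "male"}.issubset(sub.index):
            continue
        f, m = sub.loc["female"], sub.loc["male"]
        row = dict(zip(key, vals))
        row.update(sex="sex_difference", events_case=int(f["events_case"]), events_control=int(m["events_case"]))
        if row["mode"] == "de_novo" and f["n_case"] and m["n_case"]:
            if f["events_case"] + m["events_case"] > 0:
                rr = sex_difference_observed(
                    int(f["events_case"]), int(m["events_case"]), int(f["n_case"]), int(m["n_case"])
                )
                row.update(ratio=rr.ratio, ci_low=rr.ci_low, ci_high=rr.ci_high,
                           p_value=rr.p_value, expected_fraction=rr.expected_fraction,
                           n_events_total=rr.n_events_total)
        if np.isfinite(f.get("liability_z", np.nan)) and np.isfinite(m.get("liability_z", np.nan)) \
                and np.isfinite(f.get("liability_se", np.nan)) and np.isfinite(m.get("liability_se", np.nan)):
            d = sex_difference_liability(f["liability_z"], f["liability_se"], m["liability_z"], m["liability_se"])
            row.update(liability_z=d.z_diff, liability_se=d.se_diff,
                       liability_ci_low=d.ci_low, liability_ci_high=d.ci_high, liability_p=d.p_value)
        rows.append(row)
    return pd.DataFrame(rows)


def meta_analyse(results: pd.DataFrame) -> pd.DataFrame:
    """Inverse-variance meta rows across cohorts, per (sex, group, class,
    mode): rate ratios on the log scale, liability on the z scale."""
    key = ["sex", "phenotype_group", "variant_class", "mode"]
    rows = []
    for vals, sub in results.groupby(key):
        if sub["cohort"].nunique() < 2:
            continue
        row = dict(zip(key, vals))
        row["cohort"] = "meta"
        ok = sub[(sub["ratio"] > 0) & np.isfinite(sub["ratio"]) & (sub["ci_low"] > 0) & np.isfinite(sub["ci_high"])]
        if len(ok) >= 2:
            mr = ivw_meta_rate_ratios(ok["ratio"], ok["ci_low"], ok["ci_high"], list(ok["cohort"]))
            row.update(ratio=mr.estimate, ci_low=mr.ci_low, ci_high=mr.ci_high, p_value=mr.p_value)
        okz = sub[np.isfinite(sub["liability_z"]) & (sub["liability_se"] > 0)]
        if len(okz) >= 2:
            mz = ivw_meta([MetaInput(z, s, c) for z, s, c in zip(okz["liability_z"], okz["liability_se"], okz["cohort"])])
            row.update(liability_z=mz.estimate, liability_se=mz.se,
                       liability_ci_low=mz.ci_low, liability_ci_high=mz.ci_high, liability_p=mz.p_value)
        if len(row) > len(key) + 1:
            rows.append(row)
    return pd.DataFrame(rows)


RESULT_COLUMNS = [
    "cohort", "sex", "phenotype_group", "variant_class", "mode",
    "events_case", "events_control", "n_case", "n_control",
    "ratio", "ci_low", "ci_high", "p_value", "expected_fraction", "n_events_total",
    "liability_z", "liability_se", "liability_ci_low", "liability_ci_high", "liability_p",
    "p_fdr", "p_bonferroni", "tier",
]


def run_pipeline(cfg: RunConfig, tables: dict[str, pd.DataFrame] | None = None) -> dict:
    """Run the canonical recipe.  ``tables`` may inject in-memory
    persons/variants/genes frames (the CLI reads them from the configured
    paths).  Returns {'counts', 'results', 'manifest'}; when
    ``cfg.out_dir`` is set the completed outputs are written afterwards
    (never partially)."""
    if tables is None:
        tables = {
            "persons": pd.read_csv(cfg.persons, sep="\t"),
            "variants": pd.read_csv(cfg.variants, sep="\t"),
            "genes": pd.read_csv(cfg.genes, sep="\t"),
        }
    spec = cfg.prevalences
    counts = tabulate_counts(
        tables["variants"], tables["persons"], tables["genes"],
        cfg.classification, scheme=cfg.scheme, cohort=cfg.cohort,
    )
    results = burden_table(counts)
    results = liability_for_results(results, spec)
    diff = _sex_difference_rows(results)
    results = pd.concat([results, diff], ignore_index=True)
    meta_rows = meta_analyse(results)
    if len(meta_rows):
        results = pd.concat([results, meta_rows], ignore_index=True)
    results = adjust_results_table(results, family_size=cfg.family_size)
    results = results.reindex(columns=RESULT_COLUMNS)
    sort_key = ["cohort", "phenotype_group", "variant_class", "mode", "sex"]
    results = results.sort_values(sort_key, kind="mergesort").reset_index(drop=True)
    manifest = dict(
        package_version=__version__,
        config=cfg.analysis_config(),
        config_hash=cfg.config_hash(),
        seed=cfg.seed,
        n_count_rows=int(len(counts)),
        n_result_rows=int(len(results)),
        filters=dict(
            n_variants_in=int(len(tables["variants"])),
            n_persons=int(len(tables["persons"])),
        ),
    )
    out = {"counts": counts, "results": results, "manifest": manifest}
    if cfg.out_dir:
        d = Path(cfg.out_dir)
        d.mkdir(parents=True, exist_ok=True)
        counts.to_csv(d / "counts.tsv", sep="\t", index=False)
        results.to_csv(d / "results.tsv", sep="\t", index=False, float_format="%.6g")
        (d / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return out
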