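"""Simulate the study cohorts: one null trio cohort (no variant
effects) and one with a damaging-PTV carrier shift of 0.6 liability SD,
each of 2,000 ascertained families under the 2.5%-male / 4:1 prevalence
model.  Writes the person/variant/gene tables every later step consumes.
"""

import json
from pathlib import Path

from rvliab.simulate import SimulationConfig, simulate_cohort

OUT = Path(__file__).resolve().parents[1] / "results" / "sim"

CONFIGS = {
    "null": SimulationConfig(
        n_families=2000, seed=101, n_genes=200,
        effect_sizes={"damaging_PTV": 0.0, "damaging_missense": 0.0, "synonymous": 0.0},
    ),
    "ptv_effect": SimulationConfig(
        n_families=2000, seed=102, n_genes=200,
        effect_sizes={"damaging_PTV": 0.6, "damaging_missense": 0.2, "synonymous": 0.0},
    ),
}


def main() -> None:
    for name, cfg in CONFIGS.items():
        cohort = simulate_cohort(cfg)
        d = OUT / name
        d.mkdir(parents=True, exist_ok=True)
        cohort.persons.to_csv(d / "persons.tsv", sep="\t", index=False)
        cohort.variants.to_csv(d / "variants.tsv", sep="\t", index=False)
        cohort.genes.to_csv(d / "genes.tsv", sep="\t", index=False)
        truth = {k: v for k, v in cohort.truth.items() if k != "liabilities"}
        (d / "truth.json").write_text(json.dumps(truth, indent=2, sort_keys=True, default=float) + "\n")
        pro = cohort.persons[cohort.persons["role"] == "proband"]
        print(f"[{name}] {len(pro)} probands "
              f"({(pro['sex'] == 'female').mean():.1%} female), "
              f"{len(cohort.variants)} variant rows, "
              f"impaired fraction {(pro['cognitive_impairment'] == 'yes').mean():.2f}")
    print(f"tables under {OUT}")


if __name__ == "__main__":
    main()
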