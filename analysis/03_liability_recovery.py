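"""Parameter recovery of the liability-scale estimator: replicate
cohorts at carrier shifts of 0.3/0.6/1.0 SD, measuring CI coverage of
the truth and the estimator's analytic large-sample limit.

Finding to expect: near-nominal coverage and near-unbiased estimates at
moderate shifts; a few percent attenuation of the large-sample limit at
beta = 1 from probands carrying more than one variant.
"""

from pathlib import Path

import pandas as pd

from rvliab.simulate import (
    SimulationConfig,
    asymptotic_liability_estimate,
    replicate_liability_recovery,
)

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    rows = []
    for beta in (0.3, 0.6, 1.0):
        cfg = SimulationConfig(
            n_families=20_000, seed=0,
            effect_sizes={"damaging_PTV": beta, "damaging_missense": 0.0, "synonymous": 0.0},
            inherited_carrier_rate={"damaging_PTV": 0.0, "damaging_missense": 0.0, "synonymous": 0.0},
        )
        rec = replicate_liability_recovery(cfg, n_replicates=200, seed=int(beta * 1000))
        rows.append(dict(
            beta=beta,
            mean_z=rec["z"].mean(), sd_z=rec["z"].std(),
            coverage=rec["covered"].mean(),
            asymptotic_z=asymptotic_liability_estimate(cfg),
        ))
    df = pd.DataFrame(rows)
    OUT.mkdir(parents=True, exist_ok=True)
    df.to_csv(OUT / "liability_recovery.tsv", sep="\t", index=False, float_format="%.4f")
    print(df.round(4).to_string(index=False))
    print(f"\nwrote {OUT / 'liability_recovery.tsv'}")


if __name__ == "__main__":
    main()
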