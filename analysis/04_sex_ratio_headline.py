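"""The headline in silico: under the different-threshold model, the
female:male rate ratio of damaging DNMs among probands exceeds 1 and
grows with the carrier shift, while the female-minus-male liability
difference stays centred on zero — observed-scale sex bias without any
sex difference in effect size.
"""

from pathlib import Path

from rvliab.simulate import SimulationConfig, sex_ratio_study

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    cfg = SimulationConfig(
        seed=0,
        effect_sizes={"damaging_PTV": 0.0, "damaging_missense": 0.0, "synonymous": 0.0},
        inherited_carrier_rate={"damaging_PTV": 0.0, "damaging_missense": 0.0, "synonymous": 0.0},
    )
    study = sex_ratio_study(cfg, betas=[0.0, 0.3, 0.6, 1.0], n_families=50_000, seed=404)
    OUT.mkdir(parents=True, exist_ok=True)
    study.to_csv(OUT / "sex_ratio_headline.tsv", sep="\t", index=False, float_format="%.4f")
    print(study.round(4).to_string(index=False))
    grows = (study["observed_fm_rate_ratio"].diff().dropna() > 0).all()
    centred = (study["z_diff"].abs() < 3 * study["se_diff"]).all()
    print(f"\nfemale excess grows with beta: {grows}; liability difference centred on 0: {centred}")
    print(f"wrote {OUT / 'sex_ratio_headline.tsv'}")


if __name__ == "__main__":
    main()
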