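"""The generative cohort model: determinism, calibration, Mendelian
bookkeeping and the analytic cross-checks."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import binomtest, norm

from rvliab.burden import rate_ratio_test
from rvliab.simulate import (
    SimulationConfig,
    asymptotic_liability_estimate,
    emit_count_tables,
    expected_sex_ratio_of_carriers,
    impairment_thresholds,
    null_exact_size,
    proband_count_pmf,
    replicate_liability_recovery,
    sample_stratified_counts,
    simulate_cohort,
)

NULL_EFFECTS = {"damaging_PTV": 0.0, "damaging_missense": 0.0, "synonymous": 0.0}
PTV_ONLY = {"damaging_PTV": 0.6, "damaging_missense": 0.0, "synonymous": 0.0}
NO_INHERITED = {"damaging_PTV": 0.0, "damaging_missense": 0.0, "synonymous": 0.0}


class TestDeterminism:
    def test_fixed_seed_identical_cohort(self):
        cfg = SimulationConfig(n_families=80, seed=123, n_genes=40)
        a, b = simulate_cohort(cfg), simulate_cohort(cfg)
        assert a.persons.equals(b.persons)
        assert a.variants.equals(b.variants)
        assert a.genes.equals(b.genes)

    def test_different_seed_differs(self):
        a = simulate_cohort(SimulationConfig(n_families=80, seed=1, n_genes=40))
        b = simulate_cohort(SimulationConfig(n_families=80, seed=2, n_genes=40))
        assert not a.variants.equals(b.variants)


class TestStructure:
    def test_probands_exceed_threshold_and_siblings_do_not(self, small_effect_cohort):
        cohort = small_effect_cohort
        liab = cohort.truth["liabilities"].set_index("person_id")["liability"]
        persons = cohort.persons.set_index("person_id")
        thr = cohort.truth["thresholds"]
        for pid, row in persons[persons["role"].isin(["proband", "sibling"])].iterrows():
            t = thr[row["sex"]]
            if row["role"] == "proband":
                assert liab[pid] > t
            else:
                assert liab[pid] <= t

    def test_one_nonautistic_sibling_per_family(self, small_effect_cohort):
        p = small_effect_cohort.persons
        sib = p[p["role"] == "sibling"]
        assert len(sib) == p["family_id"].nunique()
        assert not sib["autism"].any()

    def test_mendelian_bookkeeping(self, small_effect_cohort):
        """Every parental heterozygous allele yields exactly one
        transmitted-or-untransmitted row for the proband, so per family
        and class the two sum to the parental heterozygote count."""
        v = small_effect_cohort.variants.copy()
        inh = v[v["inheritance"].str.contains("transmitted")]
        # each parental heterozygous allele is recorded exactly once, as
        # either transmitted or untransmitted from that parent
        side = inh["inheritance"].str.split("_").str[-1]
        dup = inh.assign(side=side).groupby(
            ["family_id", "gene_id", "variant_class_true", "side"]
        ).size()
        assert (dup == 1).all()
        # transmission is fair overall for a null class (synonymous)
        syn = inh[inh["variant_class_true"] == "synonymous"]
        t = int(syn["inheritance"].str.startswith("transmitted").sum())
        assert binomtest(t, len(syn), 0.5).pvalue > 1e-4

    def test_infeasible_ascertainment_signalled(self):
        cfg = SimulationConfig(n_families=500, male_prevalence=1e-5, sex_ratio=4,
                               n_genes=20, seed=0, max_attempt_factor=5)
        with pytest.raises(RuntimeError, match="infeasible"):
            simulate_cohort(cfg)


class TestCalibration:
    def test_population_prevalence_matches_config(self):
        """Unconditioned children are affected at the configured
        sex-specific prevalences (binomial MC tolerance)."""
        cfg = SimulationConfig(n_families=1, seed=4, effect_sizes=dict(NULL_EFFECTS))
        rng = np.random.default_rng(11)
        n = 200_000
        sex_male = rng.random(n) < 0.5
        liab = rng.standard_normal(n)
        thr = np.where(sex_male, cfg.threshold("male"), cfg.threshold("female"))
        prev_m = (liab[sex_male] > thr[sex_male]).mean()
        prev_f = (liab[~sex_male] > thr[~sex_male]).mean()
        assert prev_m == pytest.approx(0.025, abs=3 * np.sqrt(0.025 * 0.975 / (n / 2)))
        assert prev_f == pytest.approx(0.00625, abs=3 * np.sqrt(0.00625 / (n / 2)))

    def test_impairment_fraction_matches_targets(self):
        cfg = SimulationConfig(n_families=3000, seed=21, n_genes=40,
                               effect_sizes={"damaging_PTV": 0.8, "damaging_missense": 0.0, "synonymous": 0.0})
        cohort = simulate_cohort(cfg)
        pro = cohort.persons[cohort.persons["role"] == "proband"]
        for sex, target in (("male", 0.35), ("female", 0.40)):
            sub = pro[pro["sex"] == sex]
            frac = (sub["cognitive_impairment"] == "yes").mean()
            tol = 3 * np.sqrt(target * (1 - target) / len(sub))
            assert frac == pytest.approx(target, abs=tol)

    def test_correlated_mechanism_also_calibrated(self):
        cfg = SimulationConfig(n_families=2500, seed=22, n_genes=40,
                               impairment_mechanism="correlated",
                               effect_sizes=dict(NULL_EFFECTS))
        cohort = simulate_cohort(cfg)
        pro = cohort.persons[cohort.persons["role"] == "proband"]
        male = pro[pro["sex"] == "male"]
        frac = (male["cognitive_impairment"] == "yes").mean()
        assert frac == pytest.approx(0.35, abs=3 * np.sqrt(0.35 * 0.65 / len(male)))

    def test_explicit_offset_bypasses_calibration(self):
        cfg = SimulationConfig(impairment_threshold_offset=0.5)
        thr = impairment_thresholds(cfg)
        assert thr["male"] == pytest.approx(cfg.threshold("male") + 0.5)

    def test_null_rate_ratio_ci_covers_one(self, null_cohort):
        counts = emit_count_tables(null_cohort)
        row = counts[(counts["sex"] == "both") & (counts["variant_class"] == "synonymous")
                     & (counts["mode"] == "de_novo")].iloc[0]
        r = rate_ratio_test(int(row["events_case"]), int(row["events_control"]),
                            int(row["n_case"]), int(row["n_control"]))
        assert r.ci_low <= 1.0 <= r.ci_high


class TestConditionalSampler:
    def test_pmf_normalised_and_null_is_poisson(self):
        cfg = SimulationConfig(effect_sizes=dict(NULL_EFFECTS))
        pmf = proband_count_pmf(cfg, "male", "synonymous", affected=True)
        from scipy.stats import poisson

        assert pmf.sum() == pytest.approx(1.0)
        expect = poisson.pmf(np.arange(13), 0.30)
        assert np.allclose(pmf, expect / expect.sum(), atol=1e-12)

    def test_effect_shifts_proband_distribution_up(self):
        cfg = SimulationConfig(effect_sizes=dict(PTV_ONLY),
                               inherited_carrier_rate=dict(NO_INHERITED))
        aff = proband_count_pmf(cfg, "male", "damaging_PTV", affected=True)
        un = proband_count_pmf(cfg, "male", "damaging_PTV", affected=False)
        ks = np.arange(13)
        assert (ks * aff).sum() > (ks * un).sum()

    def test_requires_single_effective_class(self):
        cfg = SimulationConfig(effect_sizes={"damaging_PTV": 0.5, "damaging_missense": 0.4, "synonymous": 0.0})
        with pytest.raises(ValueError, match="single effective class"):
            proband_count_pmf(cfg, "male", "damaging_PTV")

    def test_agrees_with_rejection_sampler(self):
        """Proband damaging-count rates from the table-level rejection
        simulator match the exact-conditional expectation."""
        cfg = SimulationConfig(n_families=3000, seed=17, n_genes=40,
                               effect_sizes=dict(PTV_ONLY),
                               inherited_carrier_rate=dict(NO_INHERITED))
        cohort = simulate_cohort(cfg)
        counts = emit_count_tables(cohort)
        row = counts[(counts["sex"] == "male") & (counts["variant_class"] == "damaging_PTV")
                     & (counts["mode"] == "de_novo")].iloc[0]
        rate = row["events_case"] / row["n_case"]
        pmf = proband_count_pmf(cfg, "male", "damaging_PTV", affected=True)
        expected = float((np.arange(13) * pmf).sum())
        se = np.sqrt(expected / row["n_case"])  # Poisson-scale MC error
        assert rate == pytest.approx(expected, abs=4 * se)


class TestSexRatioPrediction:
    def test_no_effect_no_sex_bias(self):
        cfg = SimulationConfig(effect_sizes=dict(NULL_EFFECTS))
        assert expected_sex_ratio_of_carriers(cfg, "damaging_PTV") == pytest.approx(1.0)

    def test_ratio_increases_with_effect_size(self):
        ratios = []
        for beta in (0.2, 0.5, 1.0):
            cfg = SimulationConfig(
                effect_sizes={"damaging_PTV": beta, "damaging_missense": 0.0, "synonymous": 0.0},
                inherited_carrier_rate=dict(NO_INHERITED),
            )
            ratios.append(expected_sex_ratio_of_carriers(cfg))
        assert ratios[0] > 1.0
        assert ratios == sorted(ratios)

    def test_simulated_ratio_matches_integral(self):
        for beta in (0.5, 1.0):
            cfg = SimulationConfig(
                n_families=60_000, seed=31,
                effect_sizes={"damaging_PTV": beta, "damaging_missense": 0.0, "synonymous": 0.0},
                inherited_carrier_rate=dict(NO_INHERITED),
            )
            rng = np.random.default_rng(77)
            counts = sample_stratified_counts(cfg, rng, "damaging_PTV")
            ev_f, n_f = counts["female"]["events_probands"], counts["female"]["n_probands"]
            ev_m, n_m = counts["male"]["events_probands"], counts["male"]["n_probands"]
            simulated = (ev_f / n_f) / (ev_m / n_m)
            analytic = expected_sex_ratio_of_carriers(cfg)
            se_log = np.sqrt(1 / ev_f + 1 / ev_m)  # Poisson-scale MC error
            assert abs(np.log(simulated / analytic)) < 3.5 * se_log


class TestEstimatorLimits:
    def test_asymptotic_estimate_near_beta_for_moderate_effects(self):
        for beta, tol in ((0.3, 0.01), (0.6, 0.02)):
            cfg = SimulationConfig(
                effect_sizes={"damaging_PTV": beta, "damaging_missense": 0.0, "synonymous": 0.0},
                inherited_carrier_rate=dict(NO_INHERITED),
            )
            assert asymptotic_liability_estimate(cfg) == pytest.approx(beta, abs=tol)

    def test_multicarrier_attenuation_at_large_beta(self):
        """At beta = 1 the rate-based estimator is attenuated a few
        percent by probands carrying more than one variant."""
        cfg = SimulationConfig(
            effect_sizes={"damaging_PTV": 1.0, "damaging_missense": 0.0, "synonymous": 0.0},
            inherited_carrier_rate=dict(NO_INHERITED),
        )
        z = asymptotic_liability_estimate(cfg)
        assert 0.93 < z < 1.0

    def test_recovery_at_default_scale_across_beta_grid(self):
        """At the generator's default cohort size the estimate's 95% CI
        covers the true shift in at least 90% of replicates for each
        beta on the grid."""
        for beta in (0.3, 0.6, 1.0):
            cfg = SimulationConfig(
                n_families=1000,
                effect_sizes={"damaging_PTV": beta, "damaging_missense": 0.0, "synonymous": 0.0},
                inherited_carrier_rate=dict(NO_INHERITED),
            )
            rec = replicate_liability_recovery(cfg, n_replicates=120, seed=int(beta * 10))
            assert rec["covered"].mean() >= 0.90

    def test_null_exact_size_close_to_nominal(self):
        cfg = SimulationConfig(n_families=2000, effect_sizes=dict(NULL_EFFECTS))
        size = null_exact_size(cfg, "synonymous", alpha=0.05)
        assert 0.04 < size <= 0.05


class TestAscertainmentModes:
    def test_duo_emits_single_parent(self):
        cfg = SimulationConfig(n_families=60, seed=9, n_genes=30, ascertainment="duo")
        cohort = simulate_cohort(cfg)
        roles = cohort.persons["role"].value_counts()
        assert roles.get("father", 0) == 0 and roles["mother"] == 60
        inh = cohort.variants["inheritance"]
        assert not inh.str.endswith("father").any()

    def test_case_control_has_no_parents_or_transmission(self):
        cfg = SimulationConfig(n_families=60, seed=9, n_genes=30, ascertainment="case_control")
        cohort = simulate_cohort(cfg)
        assert set(cohort.persons["role"]) == {"proband", "sibling"}
        assert (cohort.variants["inheritance"] == "de_novo").all()
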