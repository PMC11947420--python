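"""Liability-threshold-model mathematics: thresholds, prevalence algebra,
penetrance, effect-size conversion and its uncertainty."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad
from scipy.optimize import brentq
from scipy.stats import norm

from rvliab.liability import (
    PrevalenceSpec,
    Z_95,
    carrier_penetrance,
    female_prevalence_from_ratio,
    liability_effect,
    liability_estimate_from_counts,
    liability_threshold,
    se_and_ci,
    sex_difference_liability,
    subgroup_prevalence,
    truncated_liability_means,
    unequal_variance_adjustment,
)


class TestThreshold:
    @pytest.mark.parametrize("prevalence,expected", [
        (0.025, 1.95996),   # male autism threshold
        (0.00625, 2.49771),  # female threshold at a 4:1 ratio
        (0.40, 0.25335),    # impairment-among-autistic threshold, females
        (0.35, 0.38532),    # same, males
        (0.5, 0.0),
    ])
    def test_known_quantiles(self, prevalence, expected):
        assert liability_threshold(prevalence).t == pytest.approx(expected, abs=1e-5)

    def test_agrees_with_root_find_oracle(self):
        """The quantile matches a numeric root-find of the normal CDF to
        1e-9 across the full prevalence range."""
        for k in np.geomspace(1e-4, 0.5, 25):
            t_root = brentq(lambda t: norm.sf(t) - k, -10, 40, xtol=1e-12)
            assert liability_threshold(float(k)).t == pytest.approx(t_root, abs=1e-9)

    def test_variance_scales_threshold(self):
        assert liability_threshold(0.025, variance=2.0).t == pytest.approx(
            math.sqrt(2) * 1.9599640, abs=1e-6
        )

    def test_monotone_in_variance_and_prevalence(self):
        ts = [liability_threshold(0.025, v).t for v in (0.5, 1, 2, 3)]
        assert ts == sorted(ts)
        ks = [liability_threshold(k).t for k in (0.4, 0.2, 0.1, 0.01)]
        assert ks == sorted(ks)

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.1, 1.5])
    def test_degenerate_prevalence_rejected(self, bad):
        with pytest.raises(ValueError):
            liability_threshold(bad)

    def test_alternative_sex_ratios_order_female_thresholds(self):
        """At 3:1 and 2:1 the female threshold lies strictly between the
        male threshold and the 4:1 female threshold."""
        t_male = liability_threshold(0.025).t
        t_4 = liability_threshold(female_prevalence_from_ratio(0.025, 4)).t
        for ratio in (3, 2):
            t_r = liability_threshold(female_prevalence_from_ratio(0.025, ratio)).t
            assert t_male < t_r < t_4


class TestPrevalenceAlgebra:
    def test_female_prevalence_from_ratio(self):
        assert female_prevalence_from_ratio(0.025, 4) == pytest.approx(0.00625)
        assert female_prevalence_from_ratio(0.02, 4 / 3) == pytest.approx(0.015)
        assert female_prevalence_from_ratio(0.025, 1) == pytest.approx(0.025)

    def test_subgroup_split(self):
        featured, complement = subgroup_prevalence(0.025, 0.23)
        assert featured == pytest.approx(0.00575)
        featured, complement = subgroup_prevalence(0.025, 0.35)
        assert featured == pytest.approx(0.00875)
        assert complement == pytest.approx(0.01625)

    def test_full_feature_moves_everything(self):
        assert subgroup_prevalence(0.0173, 1.0) == pytest.approx((0.0173, 0.0))

    @given(k=st.floats(0.001, 0.999), p=st.floats(0.001, 1.0))
    @settings(max_examples=60, derandomize=True)
    def test_split_conserves_prevalence(self, k, p):
        featured, complement = subgroup_prevalence(k, p)
        assert featured + complement == pytest.approx(k)
        assert featured >= 0 and complement >= -1e-15

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            female_prevalence_from_ratio(1.2, 4)
        with pytest.raises(ValueError):
            female_prevalence_from_ratio(0.025, 0)
        with pytest.raises(ValueError):
            subgroup_prevalence(0.025, 1.2)

    def test_spec_object_derives_female_prevalence(self):
        spec = PrevalenceSpec(male_prevalence=0.025, male_to_female_ratio=4)
        assert spec.female_prevalence == pytest.approx(0.00625)
        with pytest.raises(ValueError):
            PrevalenceSpec(male_prevalence=0.0)


class TestTruncatedMeans:
    def test_symmetric_case(self):
        m_aff, m_unaff = truncated_liability_means(0.5)
        assert m_aff == pytest.approx(0.7978846, abs=1e-6)
        assert m_unaff == pytest.approx(-0.7978846, abs=1e-6)

    def test_against_numeric_integration(self):
        """Tail means agree with brute-force integration of x*phi(x)."""
        for k in (0.025, 0.1, 0.35):
            t = liability_threshold(k).t
            upper = quad(lambda x: x * norm.pdf(x), t, 12)[0] / k
            lower = quad(lambda x: x * norm.pdf(x), -12, t)[0] / (1 - k)
            m_aff, m_unaff = truncated_liability_means(k)
            assert m_aff == pytest.approx(upper, rel=1e-6)
            assert m_unaff == pytest.approx(lower, rel=1e-6)
        assert truncated_liability_means(0.025)[0] == pytest.approx(2.3378, abs=2e-4)

    @given(k=st.floats(0.001, 0.999))
    @settings(max_examples=60, derandomize=True)
    def test_population_mean_conserved(self, k):
        m_aff, m_unaff = truncated_liability_means(k)
        assert k * m_aff + (1 - k) * m_unaff == pytest.approx(0.0, abs=1e-12)


class TestCarrierPenetrance:
    def test_equal_rates_give_prevalence(self):
        assert carrier_penetrance(0.01, 0.01, 0.37) == pytest.approx(0.37)

    def test_bayes_by_hand(self):
        assert carrier_penetrance(0.02, 0.01, 0.4) == pytest.approx(0.8 / 1.4)

    def test_case_only_variant_fully_penetrant(self):
        assert carrier_penetrance(0.01, 0.0, 0.025) == 1.0

    def test_both_zero_signalled(self):
        with pytest.raises(ValueError):
            carrier_penetrance(0.0, 0.0, 0.025)

    def test_high_rate_warns(self):
        with pytest.warns(UserWarning, match="rare-carrier"):
            carrier_penetrance(0.5, 0.01, 0.025)


class TestLiabilityEffect:
    def test_zero_at_equal_rates(self):
        assert liability_effect(0.02, 0.02, 0.025).z == 0.0

    def test_threshold_shift_inverts_generative_model(self):
        """A carrier shift beta yields penetrance sf(T - beta); the
        inversion must hand back exactly beta."""
        for k in (0.025, 0.00625, 0.35):
            t = liability_threshold(k).t
            for beta in (0.2, 0.6, 1.3):
                pen = norm.sf(t - beta)
                # rates with the right Bayes ratio: rate_c/rate_s = pen(1-K)/(K(1-pen))
                rate_c = pen / k
                rate_s = (1 - pen) / (1 - k)
                est = liability_effect(rate_c * 1e-3, rate_s * 1e-3, k)
                assert est.z == pytest.approx(beta, abs=1e-10)

    def test_mixture_convention_reference_value(self):
        """The mixture-of-truncated-means convention at a 2-fold rate
        ratio and prevalence 0.40 gives 0.27590."""
        est = liability_effect(0.02, 0.01, 0.40, method="mixture")
        assert est.z == pytest.approx(0.27590, abs=1e-4)

    def test_monotone_in_case_rate_and_scale_invariant(self):
        zs = [liability_effect(r, 0.01, 0.025).z for r in (0.01, 0.015, 0.02, 0.04)]
        assert zs[0] == 0.0 and zs == sorted(zs) and len(set(zs)) == len(zs)
        a = liability_effect(0.02, 0.01, 0.025).z
        b = liability_effect(0.002, 0.001, 0.025).z
        assert a == pytest.approx(b, rel=1e-12)

    @given(ratio=st.floats(1.01, 50), k=st.floats(0.002, 0.45))
    @settings(max_examples=80, derandomize=True)
    def test_positive_enrichment_positive_liability(self, ratio, k):
        base = 1e-3
        for method in ("threshold_shift", "mixture"):
            assert liability_effect(base * ratio, base, k, method=method).z > 0


class TestSeAndCi:
    def test_p05_halfwidth_equals_z(self):
        est = se_and_ci(0.4, 0.05)
        assert est.se == pytest.approx(0.4 / Z_95, rel=1e-9)
        assert est.ci_high - est.z == pytest.approx(abs(est.z), rel=1e-6)

    def test_round_trip_reconstructs_p(self):
        for p in (0.3, 0.05, 1e-4):
            est = se_and_ci(-0.25, p)
            back = 2 * norm.sf(abs(est.z) / est.se)
            assert back == pytest.approx(p, rel=1e-9)

    def test_published_sex_difference_consistency(self):
        """From a printed z = 0.093 with CI upper 0.20, the implied se
        reconstructs a p close to the printed 0.087 (rounding slack)."""
        se = (0.20 - 0.093) / 1.96
        p = 2 * norm.sf(0.093 / se)
        assert p == pytest.approx(0.087, abs=0.005)

    def test_degenerate_p(self):
        est = se_and_ci(0.4, 1.0)
        assert math.isnan(est.se) and math.isnan(est.ci_low)
        with pytest.raises(ValueError):
            se_and_ci(0.4, 0.0)


class TestCountBasedEstimate:
    def test_matches_rate_pipeline(self):
        est = liability_estimate_from_counts(30, 1000, 10, 1000, 0.025)
        raw = liability_effect(0.03, 0.01, 0.025)
        assert est.z == pytest.approx(raw.z, rel=1e-12)
        assert est.ci_low < est.z < est.ci_high

    def test_exact_ci_brackets_and_orders(self):
        est = liability_estimate_from_counts(60, 2000, 40, 2000, 0.025)
        assert est.ci_low < est.z < est.ci_high
        wider = liability_estimate_from_counts(6, 200, 4, 200, 0.025)
        assert (wider.ci_high - wider.ci_low) > (est.ci_high - est.ci_low)


class TestSexDifference:
    def test_identical_estimates_no_difference(self):
        d = sex_difference_liability(0.4, 0.1, 0.4, 0.1)
        assert d.z_diff == 0.0 and d.p_value == pytest.approx(1.0)

    def test_antisymmetry(self):
        a = sex_difference_liability(0.66, 0.06, 0.53, 0.056)
        b = sex_difference_liability(0.53, 0.056, 0.66, 0.06)
        assert a.z_diff == pytest.approx(-b.z_diff)
        assert a.p_value == pytest.approx(b.p_value)

    def test_published_cognitive_impairment_contrast(self):
        """0.66 (CI 0.54-0.78) in females vs 0.53 (CI 0.42-0.64) in males:
        difference 0.13, not significant."""
        se_f = (0.78 - 0.54) / (2 * 1.96)
        se_m = (0.64 - 0.42) / (2 * 1.96)
        d = sex_difference_liability(0.66, se_f, 0.53, se_m)
        assert d.z_diff == pytest.approx(0.13, abs=1e-12)
        assert d.p_value > 0.05


class TestUnequalVariance:
    def test_ratio_one_reduces_to_standard(self):
        spec = PrevalenceSpec()
        out = unequal_variance_adjustment(spec, rates_male=(0.02, 0.01))
        assert out["male_threshold"].t == pytest.approx(liability_threshold(0.025).t)
        assert out["male_effect_raw"].z == pytest.approx(out["male_effect_standardized"].z)

    def test_male_variance_two_scales_threshold(self):
        spec = PrevalenceSpec(male_variance=2.0)
        out = unequal_variance_adjustment(spec)
        assert out["male_threshold"].t == pytest.approx(math.sqrt(2) * 1.9599640, abs=1e-6)
        assert out["male_threshold"].standardized == pytest.approx(1.9599640, abs=1e-6)

    def test_raw_effect_scales_with_sd(self):
        spec = PrevalenceSpec(male_variance=2.0)
        out = unequal_variance_adjustment(spec, rates_male=(0.02, 0.01))
        assert out["male_effect_raw"].z == pytest.approx(
            math.sqrt(2) * out["male_effect_standardized"].z
        )
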