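import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import integrate

from defekit.errors import DegenerateFitError, InsufficientSampleError
from defekit.stats import (
    MANN_WHITNEY_U,
    WELCH_T,
    adjust_pvalues,
    bsfs_contrasts,
    choose_test,
    compare_groups,
    fit_lognormal,
    iqr_filter,
    linear_fit,
    lognormal_from_moments,
    lognormal_pdf,
)


class TestIqrFilter:
    def test_hand_computed_fences(self):
        # Q1 = 3.25, Q3 = 7.75 under linear-interpolation quartiles,
        # upper fence 14.5 -> only the 100 is dropped
        kept = iqr_filter([1, 2, 3, 4, 5, 6, 7, 8, 9, 100])
        assert list(kept) == [1, 2, 3, 4, 5, 6, 7, 8, 9]

    def test_all_equal_unchanged(self):
        assert list(iqr_filter([5.0] * 6)) == [5.0] * 6

    def test_empty(self):
        assert len(iqr_filter([])) == 0

    def test_single_pass_idempotent_when_no_new_outliers(self):
        data = [1, 2, 3, 4, 5, 6, 7, 8, 9, 100]
        once = iqr_filter(data)
        assert list(iqr_filter(once)) == list(once)

    def test_negative_multiplier_rejected(self):
        with pytest.raises(ValueError):
            iqr_filter([1, 2, 3], multiplier=-1)


class TestNormalityGate:
    def test_gaussian_pair_uses_welch(self):
        rng = np.random.default_rng(42)
        assert choose_test(rng.normal(0, 1, 50), rng.normal(0, 1, 50)) == WELCH_T

    def test_lognormal_sample_uses_mann_whitney(self):
        rng = np.random.default_rng(42)
        a = np.exp(rng.normal(0, 1, 50))
        b = rng.normal(0, 1, 50)
        assert choose_test(a, b) == MANN_WHITNEY_U

    def test_tiny_sample_rejected(self):
        with pytest.raises(InsufficientSampleError):
            choose_test([1.0, 2.0], [1.0, 2.0, 3.0])


class TestCompareGroups:
    def test_identical_samples_give_zero_statistic_unit_p(self):
        rng = np.random.default_rng(7)
        a = rng.normal(10, 2, 30)
        res = compare_groups(a, a.copy())
        assert res.test_used == WELCH_T
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)
        assert not res.significant

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_two_sided_symmetry_under_group_swap(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(0, 1, 12)
        b = rng.normal(0.5, 1.5, 15)
        assert compare_groups(a, b).p_value == pytest.approx(
            compare_groups(b, a).p_value, rel=1e-12
        )

    def test_synthetic_gender_tenesmus_contrast_detected(self):
        """Female eu-tenesmus exceeds male with n=25 per group drawn from
        the generator's gender-specific distributions."""
        from defekit.synthetic import sample_etd_population

        f, m = sample_etd_population(25, seed=1, n_participants_per_gender=25)
        res = compare_groups(f, m, labels=("female", "male"))
        assert res.means[0] > res.means[1]
        assert res.significant


class TestLogNormalFit:
    def test_degenerate_point_mass(self):
        fit = fit_lognormal([math.e] * 10)
        assert fit.mu_hat == pytest.approx(1.0)
        assert fit.sigma_hat == pytest.approx(0.0, abs=1e-12)

    def test_parameter_recovery_from_seeded_draws(self):
        rng = np.random.default_rng(2024)
        x = rng.lognormal(0.694, 0.932, 5000)
        fit = fit_lognormal(x)
        se_mu = 0.932 / math.sqrt(5000)
        se_sigma = 0.932 / math.sqrt(2 * 5000)
        assert abs(fit.mu_hat - 0.694) < 3 * se_mu
        assert abs(fit.sigma_hat - 0.932) < 3 * se_sigma

    def test_refit_consistency_chain(self):
        """Sampling from a fitted law and refitting recovers the fit."""
        rng = np.random.default_rng(5)
        fit = fit_lognormal(rng.lognormal(0.7, 0.9, 2000))
        resampled = rng.lognormal(fit.mu_hat, fit.sigma_hat, 10000)
        refit = fit_lognormal(resampled)
        assert abs(refit.mu_hat - fit.mu_hat) < 3 * fit.sigma_hat / math.sqrt(10000)
        assert abs(refit.sigma_hat - fit.sigma_hat) < 3 * fit.sigma_hat / math.sqrt(20000)

    def test_moment_inversion_closed_form(self):
        mu, sigma = lognormal_from_moments(3.214, 3.800)
        assert sigma == pytest.approx(0.9352, abs=1e-4)
        assert mu == pytest.approx(0.7302, abs=1e-4)

    def test_nonpositive_values_rejected(self):
        with pytest.raises(ValueError):
            fit_lognormal([1.0, -2.0, 3.0])


class TestLogNormalPdf:
    def test_standard_value(self):
        assert lognormal_pdf(1.0, 0.0, 1.0) == pytest.approx(1 / math.sqrt(2 * math.pi))

    def test_zero_outside_support(self):
        assert lognormal_pdf(-1.0, 0.0, 1.0) == 0.0
        assert lognormal_pdf(0.0, 0.0, 1.0) == 0.0

    def test_density_integrates_to_one(self):
        val, _ = integrate.quad(lambda x: lognormal_pdf(x, 0.694, 0.932), 0, np.inf)
        assert val == pytest.approx(1.0, abs=1e-6)

    def test_invalid_sigma(self):
        with pytest.raises(ValueError):
            lognormal_pdf(1.0, 0.0, 0.0)


class TestBsfsContrasts:
    def test_single_group_table_flags_all_not_computable(self):
        table = pd.DataFrame({"BSFS": [4] * 10, "ST": np.linspace(18, 28, 10)})
        contrasts = bsfs_contrasts(table, "ST")
        assert len(contrasts) == 5
        assert all(not c.computable for c in contrasts)
        assert contrasts[-1].groups == ((1, 2, 3), (5, 6, 7))

    def test_contrast_order_matches_reporting_scheme(self, feature_table):
        labels = [c.label for c in bsfs_contrasts(feature_table, "ST")]
        assert labels == [
            "BSFS1/2 vs BSFS3",
            "BSFS3 vs BSFS4",
            "BSFS4 vs BSFS5",
            "BSFS5 vs BSFS6/7",
            "BSFS1/2/3 vs BSFS5/6/7",
        ]

    def test_pooled_thickness_contrast_significant_thicker_at_low_bsfs(self, feature_table):
        pooled = bsfs_contrasts(feature_table, "ST")[-1]
        assert pooled.computable
        assert pooled.result.significant
        assert pooled.result.means[0] > pooled.result.means[1]


class TestLinearFit:
    def test_exact_line(self):
        x = np.arange(1.0, 9.0)
        fit = linear_fit(x, 2.0 * x)
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(0.0, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0)

    def test_constant_regressor_rejected(self):
        with pytest.raises(DegenerateFitError):
            linear_fit([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_recovers_generator_thickness_coupling(self):
        """Regression of thickness on dropping duration recovers the
        configured 6.68 mm/s slope within 10% on ~200 synthetic events."""
        from defekit.synthetic import generate_cohort, simulate_dataset

        cohort = generate_cohort(40, 20, seed=9)
        table = simulate_dataset(cohort, 5, seed=9).truth_table()
        fit = linear_fit(table["SDD"], table["ST"])
        assert fit.n == 200
        assert fit.slope == pytest.approx(6.68, rel=0.10)
        assert fit.r_squared > 0.8


class TestMultiplicityAdjustment:
    def test_bonferroni_and_bh(self):
        p = np.array([0.01, 0.02, 0.5])
        assert np.allclose(adjust_pvalues(p, "bonferroni"), [0.03, 0.06, 1.0])
        bh = adjust_pvalues(p, "bh")
        assert np.all(bh >= p) and bh[2] == 0.5
        assert np.allclose(adjust_pvalues(p, "none"), p)
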