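import numpy as np
import pytest
from scipy import stats

from germstrata.rates import (
    HUMAN,
    MOUSE,
    AgeEffect,
    GermlineDemography,
    SensitivityCorrections,
    VEETransmissionModel,
    adjusted_vee_count,
    bonferroni,
    compare_rate_estimates,
    compare_rate_samples,
    corrected_mean_mutations,
    fit_age_effect,
    fit_vee_transmission,
    overdispersion_test,
    poisson_ci,
    rate_set,
    stage_rates,
)

MOUSE_GENOME = 2_222_635_788.0


class TestDemography:
    def test_mouse_defaults(self):
        assert MOUSE.divisions_paternal == 62
        assert MOUSE.divisions_maternal == 25
        assert MOUSE.generation_time_years == 0.75
        assert MOUSE.ssc_divisions_per_year == 42

    def test_human_defaults(self):
        assert HUMAN.total_divisions == 432
        assert HUMAN.replication_ratio == pytest.approx(401 / 31)

    def test_replication_ratios(self):
        assert round(MOUSE.replication_ratio, 1) == 2.5
        assert round(HUMAN.replication_ratio) == 13

    def test_invalid_rejected(self):
        with pytest.raises(ValueError):
            GermlineDemography("x", 0.0, 62, 25, 0.1, 42)


class TestCorrectedMean:
    def test_arithmetic(self):
        corr = SensitivityCorrections(0.9, 1.0, 1.0)
        assert corrected_mean_mutations(18.0, corr) == pytest.approx(20.0)

    def test_identity_product_one(self):
        assert corrected_mean_mutations(17.3, SensitivityCorrections()) == 17.3

    def test_average_coverage_example(self):
        # product 0.899 is the study-average interrogated fraction
        corr = SensitivityCorrections(0.899, 1.0, 1.0)
        assert corrected_mean_mutations(20.0, corr) == pytest.approx(22.247, abs=1e-3)

    def test_invalid_corrections_rejected(self):
        with pytest.raises(ValueError):
            SensitivityCorrections(0.0, 1.0, 1.0)


class TestRateSet:
    def test_mouse_point_estimate(self):
        rs = rate_set(20.0, MOUSE_GENOME, MOUSE)
        assert rs.mu_generation == pytest.approx(4.4993e-9, rel=1e-4)

    def test_cell_division_rate_human(self):
        rs = rate_set(2.0 * 1.22e-8 * 2_394_138_713, 2_394_138_713, HUMAN)
        assert rs.mu_generation == pytest.approx(1.22e-8, rel=1e-12)
        assert rs.mu_cell_division == pytest.approx(1.22e-8 / 216, rel=1e-12)
        assert rs.mu_cell_division == pytest.approx(5.648e-11, rel=1e-3)

    def test_identities_hold_exactly(self):
        rs = rate_set(20.0, MOUSE_GENOME, MOUSE, total_count=200)
        assert rs.mu_year * MOUSE.generation_time_years == pytest.approx(
            rs.mu_generation, rel=1e-12
        )
        assert rs.mu_cell_division * (MOUSE.total_divisions / 2) == pytest.approx(
            rs.mu_generation, rel=1e-12
        )

    def test_zero_mutations(self):
        rs = rate_set(0.0, MOUSE_GENOME, MOUSE, total_count=0)
        assert rs.mu_generation == 0.0
        assert rs.ci_generation[0] == 0.0

    def test_ci_contains_point_estimate(self):
        rs = rate_set(20.0, MOUSE_GENOME, MOUSE, total_count=120)
        lo, hi = rs.ci_generation
        assert lo <= rs.mu_generation <= hi

    def test_poisson_ci_is_garwood(self):
        lo, hi = poisson_ci(10)
        assert lo == pytest.approx(stats.chi2.ppf(0.025, 20) / 2)
        assert hi == pytest.approx(stats.chi2.ppf(0.975, 22) / 2)
        assert lo < 10 < hi


class TestVeeTransmission:
    def test_exact_collinearity(self):
        model = fit_vee_transmission([(0.1, 0.2), (0.2, 0.4), (0.3, 0.6)])
        assert model.beta0 == pytest.approx(0.0, abs=1e-12)
        assert model.beta1 == pytest.approx(2.0)
        assert model.pearson_r == pytest.approx(1.0)

    def test_identity_slope(self):
        pts = [(x, x) for x in (0.05, 0.15, 0.25, 0.35)]
        model = fit_vee_transmission(pts)
        assert model.beta1 == pytest.approx(1.0)

    def test_constant_x_rejected(self):
        with pytest.raises(ValueError):
            fit_vee_transmission([(0.1, 0.2), (0.1, 0.3), (0.1, 0.4)])

    def test_recovery_with_noise(self, rng):
        # n = 26 pairs, known slope/intercept, Gaussian noise: recovered
        # within 2 SE in >= 95% of replicates
        beta0, beta1 = 0.05, 1.2
        hits = 0
        reps = 200
        for _ in range(reps):
            x = rng.uniform(0.05, 0.45, size=26)
            y = beta0 + beta1 * x + rng.normal(0, 0.05, size=26)
            res = stats.linregress(x, y)
            model = fit_vee_transmission(list(zip(x, y)))
            assert model.beta1 == pytest.approx(res.slope)
            hits += abs(model.beta1 - beta1) <= 2 * res.stderr
        assert hits / reps >= 0.90

    def test_adjusted_count(self):
        model = VEETransmissionModel(0.0, 2.0, 1.0)
        assert adjusted_vee_count([0.25, 0.20], model) == pytest.approx(1.8)

    def test_adjusted_equals_raw_when_flat_half(self):
        model = VEETransmissionModel(0.5, 0.0, 0.0)
        assert adjusted_vee_count([0.1, 0.2, 0.3], model) == pytest.approx(3.0)

    def test_empty_list(self):
        assert adjusted_vee_count([], VEETransmissionModel(0, 1, 1)) == 0.0

    def test_bounds(self, rng):
        model = VEETransmissionModel(0.1, 1.5, 0.9)
        vafs = rng.uniform(0, 0.5, 50).tolist()
        adj = adjusted_vee_count(vafs, model)
        assert 0.0 <= adj <= 2 * len(vafs)


class TestStageRates:
    def test_pre_puberty_count_formula(self):
        # N = mean - (age_mean - puberty) * annual slope
        out = stage_rates(
            demography=HUMAN,
            genome_size=2_394_138_713.0,
            mean_total=70.0,
            annual_slope=2.0,
            age_mean_years=30.0,
        )
        d_pre = HUMAN.pre_puberty_divisions_paternal()
        assert out["pre_puberty"].rate == pytest.approx(
            40.0 / 2_394_138_713.0 / d_pre / 2.0
        )

    def test_post_puberty_mouse_values(self):
        out = stage_rates(
            demography=MOUSE,
            genome_size=MOUSE_GENOME,
            mean_total=20.0,
            annual_slope=4.5,
            age_mean_years=0.5,
        )
        assert out["post_puberty"].rate == pytest.approx(4.82e-11, rel=1e-3)

    def test_zero_slope_zero_post_puberty(self):
        out = stage_rates(
            demography=MOUSE,
            genome_size=MOUSE_GENOME,
            mean_total=20.0,
            annual_slope=0.0,
            age_mean_years=0.5,
        )
        assert out["post_puberty"].rate == 0.0

    def test_age_below_puberty_rejected(self):
        with pytest.raises(ValueError):
            stage_rates(
                demography=HUMAN,
                genome_size=1e9,
                mean_total=70.0,
                annual_slope=2.0,
                age_mean_years=10.0,
            )

    def test_sex_averages_scale_with_phasing(self):
        out = stage_rates(
            demography=MOUSE,
            genome_size=MOUSE_GENOME,
            mean_total=20.0,
            frac_paternal_phased=0.73,
        )
        assert out["paternal"].rate == pytest.approx(20.0 * 0.73 / 62 / MOUSE_GENOME)
        assert out["maternal"].rate == pytest.approx(20.0 * 0.27 / 25 / MOUSE_GENOME)

    def test_vee_quasi_poisson_ci(self):
        out = stage_rates(
            demography=MOUSE,
            genome_size=MOUSE_GENOME,
            mean_total=20.0,
            vee_counts=[3, 5, 8, 2, 9, 4, 6, 1],
        )
        lo, hi = out["VEE"].ci
        assert lo <= out["VEE"].rate <= hi


class TestAgeEffect:
    def test_noiseless_recovery_single_pedigree(self):
        ages = np.array([0.3, 0.4, 0.5, 0.6, 0.8])
        counts = 10 + 4.5 * ages
        eff = fit_age_effect(counts, ages, ["P"] * 5)
        assert eff.slope_per_year == pytest.approx(4.5, abs=1e-9)
        assert eff.intercept == pytest.approx(10.0, abs=1e-9)

    def test_two_pedigrees_offset_intercepts(self, rng):
        ages = np.tile(np.linspace(0.3, 0.9, 10), 2)
        peds = ["A"] * 10 + ["B"] * 10
        offsets = np.where(np.array(peds) == "A", 5.0, 12.0)
        counts = offsets + 4.5 * ages + rng.normal(0, 0.3, 20)
        eff = fit_age_effect(counts, ages, peds)
        assert eff.slope_per_year == pytest.approx(4.5, abs=0.5)

    def test_permuted_ages_null(self, rng):
        pvals = []
        ages = np.linspace(0.3, 0.9, 24)
        for _ in range(100):
            counts = rng.poisson(15, size=24).astype(float)
            eff = fit_age_effect(counts, rng.permutation(ages), ["P"] * 24)
            pvals.append(eff.p_value)
        # slope centred on zero, p roughly uniform
        assert 0.02 <= np.mean(np.array(pvals) < 0.5) <= 0.75
        assert np.mean(np.array(pvals) < 0.05) < 0.15

    def test_single_age_rejected(self):
        with pytest.raises(ValueError):
            fit_age_effect([1.0, 2.0], [0.5, 0.5], ["P", "P"])


class TestOverdispersion:
    def test_equal_counts_underdispersed(self, rng):
        res = overdispersion_test([5] * 20, rng=rng)
        assert res.phi <= 1.0
        assert res.p_value >= 0.5

    def test_gamma_poisson_detected(self, rng):
        hits = 0
        for _ in range(20):
            lam = rng.gamma(0.5, 10.0, size=40)  # variance 3x mean
            counts = rng.poisson(lam)
            if counts.sum() == 0:
                continue
            res = overdispersion_test(counts, n_boot=500, rng=rng)
            hits += res.p_value < 0.05
        assert hits >= 12

    def test_too_few_rejected(self):
        with pytest.raises(ValueError):
            overdispersion_test([1, 2, 3])

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            overdispersion_test([0] * 10)


class TestCompareRates:
    def test_identical_samples_p_one(self):
        out = compare_rate_samples({"a": [3, 4, 5, 6], "b": [3, 4, 5, 6]})
        assert (out["p_rank_adj"] == 1.0).all()
        assert (out["p_t_adj"] == 1.0).all()

    def test_bonferroni_definition(self):
        assert bonferroni(0.01, 3) == pytest.approx(0.03)
        assert bonferroni(0.5, 4) == 1.0

    def test_threefold_difference_detected(self, rng):
        sig = 0
        for _ in range(30):
            a = rng.poisson(5, 20)
            b = rng.poisson(15, 20)
            out = compare_rate_samples({"a": a, "b": b})
            sig += (out["p_rank_adj"] < 0.05).all()
        assert sig >= 25

    def test_estimates_with_cis(self):
        out = compare_rate_estimates(
            {
                "a": (5.67e-11, (5.28e-11, 6.05e-11)),
                "b": (9.07e-11, (8.41e-11, 9.69e-11)),
            }
        )
        assert (out["p_adj"] < 0.05).all()

    def test_incompatible_inputs_rejected(self):
        with pytest.raises((TypeError, ValueError)):
            compare_rate_estimates({"a": (1.0, None), "b": (2.0, (1, 3))})
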