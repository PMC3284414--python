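"""Synthetic TTO data, OLS refitting, equivalence and SE propagation."""

import numpy as np
import pandas as pd
import pytest

from eqtariff import (
    D1C,
    D1O,
    DisutilityModel,
    ModelSpec,
    SimConfig,
    US_D1O_TARIFF,
    enumerate_states,
    predict_value,
    recovery_experiment,
    reparameterize,
    simulate_tto,
    true_coefficients,
)
from eqtariff.design import DUMMY_NAMES, INTERCEPT


@pytest.fixture(scope="module")
def noiseless_data():
    return simulate_tto(SimConfig(noise_sd=0.0, n_respondents=1, seed=1))


@pytest.fixture(scope="module")
def noisy_data():
    return simulate_tto(SimConfig(noise_sd=0.2, n_respondents=5, seed=42))


@pytest.fixture(scope="module")
def paired_fits(noisy_data):
    fit_o = DisutilityModel.from_dataframe(noisy_data, D1O).fit()
    fit_c = DisutilityModel.from_dataframe(noisy_data, D1C).fit()
    return fit_o, fit_c


class TestSimulateTTO:
    def test_noiseless_observations_equal_true_disutility(self, noiseless_data):
        for _, row in noiseless_data.sample(20, random_state=0).iterrows():
            truth = 1.0 - predict_value(US_D1O_TARIFF, row["state"])
            assert row["disutility"] == pytest.approx(truth, abs=1e-12)

    def test_all_level_2_state_disutility(self, noiseless_data):
        value = noiseless_data.set_index("state").loc["22222", "disutility"]
        assert float(value) == pytest.approx(0.406, abs=1e-12)

    def test_record_count_and_shape(self):
        data = simulate_tto(SimConfig(n_respondents=3, seed=0))
        assert len(data) == 242 * 3
        assert set(data.columns) == {"state", "respondent", "disutility"}

    def test_fixed_seed_reproduces_exactly(self):
        config = SimConfig(n_respondents=2, noise_sd=0.3, seed=123)
        pd.testing.assert_frame_equal(simulate_tto(config), simulate_tto(config))

    def test_different_seeds_differ(self):
        a = simulate_tto(SimConfig(seed=1, n_respondents=1))
        b = simulate_tto(SimConfig(seed=2, n_respondents=1))
        assert not np.allclose(a["disutility"], b["disutility"])

    def test_clipping_bounds_observations(self):
        config = SimConfig(noise_sd=2.0, n_respondents=2, seed=5, clip=(0.0, 1.0))
        data = simulate_tto(config)
        assert data["disutility"].between(0.0, 1.0).all()

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(n_respondents=0)
        with pytest.raises(ValueError):
            SimConfig(noise_sd=-0.1)
        with pytest.raises(ValueError):
            SimConfig(states=())


class TestNoiselessRecovery:
    @pytest.mark.parametrize("spec", [D1O, D1C])
    def test_each_spec_recovers_its_generating_coefficients(
        self, noiseless_data, spec
    ):
        fit = DisutilityModel.from_dataframe(noiseless_data, spec).fit()
        truth = true_coefficients(US_D1O_TARIFF, spec)
        for name in spec.columns:
            assert fit.params[name] == pytest.approx(truth[name], abs=1e-10), name

    def test_noiseless_fit_reproduces_all_state_values(self, noiseless_data):
        fit = DisutilityModel.from_dataframe(noiseless_data, D1C).fit()
        for state in enumerate_states()[::17]:
            assert fit.predict_utility(state) == pytest.approx(
                predict_value(US_D1O_TARIFF, state), abs=1e-10
            )


class TestEquivalenceUnderNoise:
    def test_identical_fitted_values_residuals_and_r2(self, paired_fits):
        fit_o, fit_c = paired_fits
        np.testing.assert_allclose(fit_o.fittedvalues, fit_c.fittedvalues, atol=1e-10)
        np.testing.assert_allclose(fit_o.resid, fit_c.resid, atol=1e-10)
        assert fit_o.ssr == pytest.approx(fit_c.ssr, abs=1e-10)
        assert fit_o.rsquared == pytest.approx(fit_c.rsquared, abs=1e-10)

    def test_fitted_constant_is_negative_fitted_d1(self, paired_fits):
        fit_o, fit_c = paired_fits
        assert fit_c.params[INTERCEPT] == pytest.approx(
            -fit_o.params["D1"], abs=1e-10
        )

    def test_fitted_dummies_shift_by_fitted_d1(self, paired_fits):
        fit_o, fit_c = paired_fits
        d1 = fit_o.params["D1"]
        for name in DUMMY_NAMES:
            assert fit_c.params[name] == pytest.approx(
                fit_o.params[name] + d1, abs=1e-10
            ), name
        for name in ("I3", "I22", "I32"):
            assert fit_c.params[name] == pytest.approx(fit_o.params[name], abs=1e-10)

    def test_round_trip_through_tariff_objects(self, paired_fits):
        fit_o, _ = paired_fits
        again = reparameterize(fit_o.to_tariff())
        _, fit_c = paired_fits
        for name in D1C.columns:
            assert again.coef(name) == pytest.approx(fit_c.params[name], abs=1e-10)


class TestModelValidation:
    def test_rank_deficient_design_names_columns(self, noisy_data):
        bad = ModelSpec("BAD", DUMMY_NAMES + ("I3", "I22", "I32", "D1"), intercept=True)
        with pytest.raises(ValueError, match="rank deficient"):
            DisutilityModel.from_dataframe(noisy_data, bad)

    def test_missing_columns_rejected(self, noisy_data):
        with pytest.raises(ValueError, match="no column"):
            DisutilityModel.from_dataframe(
                noisy_data.rename(columns={"disutility": "x"}), D1O
            )

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="observations"):
            DisutilityModel([0.1, 0.2], ["21111"], D1O)

    def test_summary_lists_all_terms(self, paired_fits):
        _, fit_c = paired_fits
        text = fit_c.summary()
        assert "D1C" in text
        for name in D1C.columns:
            assert name in text


class TestPredictionSE:
    def test_full_covariance_invariant_under_reparameterization(self, paired_fits):
        fit_o, fit_c = paired_fits
        for state in enumerate_states():
            assert fit_o.prediction_se(state) == pytest.approx(
                fit_c.prediction_se(state), abs=1e-8
            ), state.code

    def test_perfect_health_has_zero_se(self, paired_fits):
        fit_o, fit_c = paired_fits
        assert fit_o.prediction_se("11111") == 0.0
        assert fit_c.prediction_se("11111", mode="diagonal_only") == 0.0

    def test_diagonal_mode_matches_manual_propagation(self, paired_fits):
        """For a five-impairment state the D1 variance enters with weight
        4^2, the I32 variance with 16^2, while a constant enters once."""
        fit_o, fit_c = paired_fits
        cov_o = fit_o.cov_params()
        var_o = sum(
            (x**2) * cov_o.loc[n, n]
            for n, x in [
                *[(d, 1) for d in DUMMY_NAMES[5:]],
                ("I3", 4), ("I32", 16), ("D1", 4),
            ]
        )
        assert fit_o.prediction_se("33333", mode="diagonal_only") == pytest.approx(
            np.sqrt(var_o), abs=1e-12
        )
        cov_c = fit_c.cov_params()
        var_c = sum(
            (x**2) * cov_c.loc[n, n]
            for n, x in [
                (INTERCEPT, 1),
                *[(d, 1) for d in DUMMY_NAMES[5:]],
                ("I3", 4), ("I32", 16),
            ]
        )
        assert fit_c.prediction_se("33333", mode="diagonal_only") == pytest.approx(
            np.sqrt(var_c), abs=1e-12
        )

    def test_unknown_mode_rejected(self, paired_fits):
        with pytest.raises(ValueError, match="mode"):
            paired_fits[0].prediction_se("22222", mode="bogus")


@pytest.fixture(scope="module")
def summary():
    config = SimConfig(n_respondents=10, noise_sd=0.2, seed=7)
    return recovery_experiment(config, replicates=60)


class TestRecoveryExperiment:
    def test_bias_within_monte_carlo_error(self, summary):
        z = (summary["bias"] / summary["mc_se"]).abs()
        assert (z < 4).all()

    def test_reported_se_consistent_with_empirical_sd(self, summary):
        ratio = summary["mean_reported_se"] / summary["empirical_sd"]
        assert abs(ratio.median() - 1) < 0.10

    def test_deterministic_under_config_seed(self):
        config = SimConfig(n_respondents=5, noise_sd=0.2, seed=11)
        a = recovery_experiment(config, replicates=4)
        b = recovery_experiment(config, replicates=4)
        pd.testing.assert_frame_equal(a, b)

    def test_replicates_floor(self):
        with pytest.raises(ValueError, match="replicates"):
            recovery_experiment(SimConfig(seed=1), replicates=1)


def test_empirical_se_scales_with_noise_and_sample_size():
    """OLS SEs shrink like sd/sqrt(n): quadrupling n halves the SE."""
    base = SimConfig(n_respondents=4, noise_sd=0.2, seed=3)
    big = SimConfig(n_respondents=16, noise_sd=0.2, seed=3)
    se_small = DisutilityModel.from_dataframe(simulate_tto(base), D1C).fit().bse
    se_big = DisutilityModel.from_dataframe(simulate_tto(big), D1C).fit().bse
    ratio = (se_small / se_big).median()
    assert ratio == pytest.approx(2.0, rel=0.15)
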