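import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trialmed.config import MEDIATORS, default_config
from trialmed.errors import DegenerateDataError, InsufficientDataError
from trialmed.models import (
    fit_attrition_model,
    fit_mediator_model,
    fit_outcome_model,
    fit_total_effect,
    standardize_mediator,
    summarize,
)
from trialmed.simulate import simulate_trial

from conftest import FAST_SAMPLER


class TestStandardize:
    def test_centring(self):
        z, mean, sd = standardize_mediator([5.0, 5.0], [4.0, 6.0])
        assert mean == 5.0
        assert np.allclose(z, 0.0)

    def test_sd_convention_is_n_minus_1(self):
        # reference {1, 3}: sd = sqrt(2), so value 3 maps to 1/sqrt(2)
        z, mean, sd = standardize_mediator([3.0], [1.0, 3.0])
        assert sd == pytest.approx(np.sqrt(2.0))
        assert z[0] == pytest.approx((3.0 - 2.0) / np.sqrt(2.0))

    def test_round_trip(self, rng):
        vals = rng.normal(5, 2, 100)
        z, mean, sd = standardize_mediator(vals, vals)
        assert np.allclose(z * sd + mean, vals, atol=1e-12)

    def test_degenerate_reference_rejected(self):
        with pytest.raises(DegenerateDataError):
            standardize_mediator([1.0], [2.0, 2.0, 2.0])


class TestSummarize:
    def test_odd_count_median(self):
        s = summarize(np.array([-1.0, 0.0, 1.0]))
        assert s.estimate == 0.0
        assert s.scale == "standardised_difference"

    def test_degenerate_draws_exp(self):
        s = summarize(np.full(10, 0.7), transform="exp")
        assert s.estimate == s.ci_low == s.ci_high == pytest.approx(np.exp(0.7))
        assert s.scale == "odds_ratio"

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_monotone_transform_equivariance(self, seed):
        """exp of the log-scale summary equals the summary of exp draws for
        the median and both interval endpoints."""
        draws = np.random.default_rng(seed).normal(0, 1.5, 401)
        log_s = summarize(draws)
        exp_s = summarize(draws, transform="exp")
        assert np.exp(log_s.estimate) == pytest.approx(exp_s.estimate, rel=1e-9)
        assert np.exp(log_s.ci_low) == pytest.approx(exp_s.ci_low, rel=1e-9)
        assert np.exp(log_s.ci_high) == pytest.approx(exp_s.ci_high, rel=1e-9)

    def test_empty_draws_rejected(self):
        with pytest.raises(ValueError):
            summarize(np.array([]))


class TestMediatorModel:
    def test_insufficient_rows_error_names_interval(self, cfg):
        df = simulate_trial(cfg.replace(n=30), seed=1, with_missingness=False)
        with pytest.raises(InsufficientDataError, match="3 months"):
            fit_mediator_model(df, "knowhow", 3, min_rows=100)

    def test_null_effect_direction_probability_centred(self):
        """Under a zero arm effect Pr(effect > 0) averages to ~1/2 over replicates."""
        null = default_config(n=600)
        null.arm_effect["knowhow"] = {1: 0.0, 3: 0.0, 6: 0.0}
        probs = []
        for seed in range(24):
            df = simulate_trial(null, seed=seed, with_missingness=False)
            fit = fit_mediator_model(df, "knowhow", 1, random_state=seed, **FAST_SAMPLER)
            probs.append(summarize(fit.coef("arm")).prob_direction)
        assert abs(np.mean(probs) - 0.5) < 0.2

    @pytest.mark.parametrize("n", [1000, 4000, 16000])
    def test_posterior_median_converges_to_truth(self, n):
        """Recovery error stays inside a root-n envelope as n grows."""
        cfg = default_config(n)
        df = simulate_trial(cfg, seed=n, with_missingness=False)
        fit = fit_mediator_model(df, "confidence", 1, random_state=n, **FAST_SAMPLER)
        from trialmed.oracle import realized_mediator_effect

        truth = realized_mediator_effect(cfg, "confidence", 1, n_mc=200_000, seed=1)
        assert abs(np.median(fit.coef("arm")) - truth) < 5.0 / np.sqrt(n)

    def test_rows_and_transforms_recorded(self, trial_complete):
        fit = fit_mediator_model(trial_complete, "confidence", 1, random_state=0, **FAST_SAMPLER)
        assert len(fit.rows) == len(trial_complete)
        assert "confidence_1" in fit.transforms and "confidence_0" in fit.transforms
        assert fit.draws.rows is not None


class TestOutcomeModel:
    def test_rare_outcome_mediator_coefficient_recovery(self):
        cfg = default_config(n=20_000)
        cfg.mediator_baseline_sd["knowhow"] = 1.5  # keep clipping negligible
        for key in cfg.outcome_params:
            cfg.outcome_params[key].b = {"importance": 0.0, "knowhow": 0.8, "confidence": 0.0}
        cfg.outcome_params["prolonged_3"].theta_0 = -4.5
        df = simulate_trial(cfg, seed=5, with_missingness=False)
        assert df.prolonged_3.mean() < 0.03
        fit = fit_outcome_model(df, "prolonged", 3, ("knowhow",), random_state=3, **FAST_SAMPLER)
        assert np.median(fit.coef("z(knowhow_1)")) == pytest.approx(0.8, abs=0.1)

    def test_null_mediator_coefficients(self):
        cfg = default_config(n=8000)
        for key in cfg.outcome_params:
            cfg.outcome_params[key].b = {m: 0.0 for m in MEDIATORS}
        df = simulate_trial(cfg, seed=6, with_missingness=False)
        fit = fit_outcome_model(df, "prolonged", 3, MEDIATORS, random_state=4, **FAST_SAMPLER)
        for m in MEDIATORS:
            s = summarize(fit.coef(f"z({m}_1)"))
            assert abs(s.estimate) < 0.1
            assert 0.02 < s.prob_direction < 0.98


class TestTotalEffect:
    def test_null_effect_gives_unit_or(self):
        cfg = default_config(n=6000)
        for key in cfg.outcome_params:
            cfg.outcome_params[key].theta_A = 0.0
            cfg.outcome_params[key].b = {m: 0.0 for m in MEDIATORS}
        df = simulate_trial(cfg, seed=7, with_missingness=False)
        summ, _ = fit_total_effect(df, "prolonged", 6, random_state=5, **FAST_SAMPLER)
        assert summ.estimate == pytest.approx(1.0, abs=0.2)
        assert summ.ci_low < 1.0 < summ.ci_high

    def test_subsample_rule_identity(self, trial_complete):
        full_summ, full_fit = fit_total_effect(
            trial_complete, "prolonged", 3, random_state=6, **FAST_SAMPLER
        )
        sub_summ, sub_fit = fit_total_effect(
            trial_complete, "prolonged", 3, subsample_rule=lambda d: d.index,
            random_state=6, **FAST_SAMPLER,
        )
        assert full_fit.rows.equals(sub_fit.rows)
        assert np.array_equal(full_fit.draws.draws, sub_fit.draws.draws)
        assert full_summ.estimate == sub_summ.estimate


class TestAttritionModel:
    def test_recovered_structure_on_default_generator(self, trial_missing):
        """Positive age effect in both arms; FTND lowers response in the
        intervention arm only at 1 month."""
        _, arm_effects = fit_attrition_model(
            trial_missing, 1, "responded_med_1", random_state=8
        )
        assert arm_effects["control"]["age_z"].estimate > 0.05
        assert arm_effects["intervention"]["age_z"].estimate > 0.05
        assert arm_effects["intervention"]["ftnd_z"].estimate < -0.1
        assert arm_effects["intervention"]["ftnd_z"].prob_direction < 0.1
        assert abs(arm_effects["control"]["ftnd_z"].estimate) < 0.15

    def test_mcar_missingness_gives_null_covariate_effects(self, cfg):
        from trialmed.config import ResponseParams, solve_response_intercept

        c = cfg.copy()
        b0 = solve_response_intercept(0.5, 0.0)
        c.response_params = ResponseParams(
            med_intercept={t: {"intervention": b0, "control": b0} for t in (1, 3, 6)},
            out_intercept={t: {"intervention": b0, "control": b0} for t in (3, 6)},
            age_slope=0.0,
            ftnd_intervention_slope_1m=0.0,
        )
        df = simulate_trial(c, seed=9)
        _, arm_effects = fit_attrition_model(df, 1, "responded_med_1", random_state=9)
        for arm in arm_effects:
            for cov, s in arm_effects[arm].items():
                assert abs(s.estimate) < 0.15, (arm, cov)

    def test_shrinkage_robust_to_noise_covariates(self, trial_missing):
        """Adding 20 pure-noise covariates moves the age effect by < 25%."""
        _, base = fit_attrition_model(trial_missing, 1, "responded_med_1", random_state=10)
        noisy = trial_missing.copy()
        rng = np.random.default_rng(11)
        noise_cols = []
        for j in range(20):
            col = f"noise_{j}"
            noisy[col] = rng.standard_normal(len(noisy))
            noise_cols.append(col)
        _, wide = fit_attrition_model(
            noisy, 1, "responded_med_1", random_state=10, extra_covariates=noise_cols
        )
        a0 = base["intervention"]["age_z"].estimate
        a1 = wide["intervention"]["age_z"].estimate
        assert abs(a1 - a0) <= 0.25 * abs(a0) + 0.02

    def test_constant_response_rejected(self, trial_missing):
        df = trial_missing.copy()
        df["responded_med_1"] = 1
        with pytest.raises(DegenerateDataError):
            fit_attrition_model(df, 1, "responded_med_1", random_state=0)
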