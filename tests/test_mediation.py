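import numpy as np
import pandas as pd
import pytest

from trialmed.config import MEDIATORS, default_config
from trialmed.errors import AlignmentError, ConfigurationError
from trialmed.glm import PosteriorDraws
from trialmed.mediation import (
    MediationResult,
    MediationSpec,
    NaturalEffects,
    counterfactual_risk,
    joint_natural_effects,
    mediation_table,
    natural_effects,
)
from trialmed.models import EffectSummary, ModelFit, summarize
from trialmed.simulate import generate_baseline, randomize, simulate_trial

from conftest import FAST_SAMPLER


# ----------------------------------------------------------------------
# hand-built fits for exercising the integration operator in isolation
# ----------------------------------------------------------------------

class _FakeLinearModel:
    def __init__(self, sigma_draws):
        self.sigma_draws_ = np.asarray(sigma_draws, dtype=float)


def _fake_fits(df, b=0.5, sigma=1.0, n_draws=8, med_arm_shift=0.4):
    """Outcome fit (intercept, arm, one mediator) and a matching mediator fit
    with hand-chosen coefficient draws (no covariates)."""
    rows = df.index
    transforms = {"knowhow_1": (5.5, 2.6)}
    out_draws = np.column_stack(
        [
            np.full(n_draws, -1.0),  # intercept
            np.full(n_draws, 0.3),  # arm
            np.full(n_draws, b),  # z(knowhow_1)
        ]
    )
    out = ModelFit(
        model=None,
        draws=PosteriorDraws(
            names=["intercept", "arm", "z(knowhow_1)"], draws=out_draws, rows=rows
        ),
        terms=["arm", "z(knowhow_1)"],
        transforms=transforms,
        rows=rows,
        response="prolonged_3",
    )
    med_draws = np.column_stack(
        [np.full(n_draws, 0.1), np.full(n_draws, med_arm_shift)]
    )
    med = ModelFit(
        model=_FakeLinearModel(np.full(n_draws, sigma)),
        draws=PosteriorDraws(names=["intercept", "arm"], draws=med_draws, rows=rows),
        terms=["arm"],
        transforms=transforms,
        rows=rows,
        response="knowhow_1",
    )
    return out, {"knowhow": med}


@pytest.fixture(scope="module")
def small_df():
    cfg = default_config(n=200)
    return randomize(generate_baseline(cfg, seed=1), seed=1)


def _expit(x):
    return 1.0 / (1.0 + np.exp(-x))


class TestCounterfactualRisk:
    def test_zero_mediator_coefficient_collapses_integral(self, small_df):
        """With b = 0 the result is the mediator-free marginal logistic
        probability at a_direct, independent of a_mediator."""
        out, med = _fake_fits(small_df, b=0.0)
        spec = MediationSpec(mediators=("knowhow",))
        for a_dir in (0, 1):
            expected = _expit(-1.0 + 0.3 * a_dir)
            p0 = counterfactual_risk(out, med, small_df, a_dir, 0, spec=spec)
            p1 = counterfactual_risk(out, med, small_df, a_dir, 1, spec=spec)
            assert np.allclose(p0, expected, atol=1e-12)
            assert np.allclose(p0, p1, atol=1e-12)

    def test_vanishing_residual_sd_reduces_to_plug_in(self, small_df):
        out, med = _fake_fits(small_df, b=0.5, sigma=1e-12)
        spec = MediationSpec(mediators=("knowhow",))
        for a_med in (0, 1):
            mu = 0.1 + 0.4 * a_med
            expected = _expit(-1.0 + 0.3 + 0.5 * mu)
            p = counterfactual_risk(out, med, small_df, 1, a_med, spec=spec)
            assert np.allclose(p, expected, atol=1e-9)

    def test_gauss_hermite_agrees_with_monte_carlo(self, small_df):
        """Two independent integration routes agree to three decimals."""
        out, med = _fake_fits(small_df, b=0.7, sigma=1.3, n_draws=2)
        gh = counterfactual_risk(
            out, med, small_df, 1, 1,
            spec=MediationSpec(mediators=("knowhow",), method="gauss_hermite", size=64),
        )
        mc = counterfactual_risk(
            out, med, small_df, 1, 1,
            spec=MediationSpec(mediators=("knowhow",), method="monte_carlo", size=5000),
            seed=5,
        )
        assert np.allclose(gh, mc, atol=1e-3)

    def test_invalid_integration_size_rejected(self):
        with pytest.raises(ConfigurationError):
            MediationSpec(mediators=("knowhow",), size=0)

    def test_misaligned_rows_rejected(self, small_df):
        out, med = _fake_fits(small_df)
        med["knowhow"].rows = small_df.index[:-5]
        med["knowhow"].draws.rows = med["knowhow"].rows
        with pytest.raises(AlignmentError):
            counterfactual_risk(out, med, small_df, 0, 0,
                                spec=MediationSpec(mediators=("knowhow",)))


class TestNaturalEffectsEstimator:
    def test_null_mediation_gives_unit_nie_and_nde_equals_te(self):
        cfg = default_config(n=4000)
        for key in cfg.outcome_params:
            cfg.outcome_params[key].b = {m: 0.0 for m in MEDIATORS}
        df = simulate_trial(cfg, seed=3, with_missingness=False)
        est = NaturalEffects(
            outcome="prolonged", outcome_interval=3, mediators=("knowhow",),
            sampler_params=FAST_SAMPLER, random_state=4,
        ).fit(df)
        assert est.nie_.estimate == pytest.approx(1.0, abs=0.07)
        assert est.nde_.estimate == pytest.approx(est.te_.estimate, rel=0.07)

    def test_pairing_identities_hold_per_draw(self, trial_complete):
        est = NaturalEffects(
            outcome="prolonged", outcome_interval=3, mediators=("knowhow",),
            sampler_params=FAST_SAMPLER, random_state=5,
        ).fit(trial_complete)
        d = est.result_.or_draws
        assert np.allclose(d["nde_total"] * d["nie_pure"], d["te"], atol=1e-10)
        assert np.allclose(d["nde_pure"] * d["nie_total"], d["te"], atol=1e-10)

    def test_mediator_scale_invariance(self, trial_complete):
        """Multiplying raw mediator scores by 10 leaves the ORs unchanged
        (standardisation removes the scale)."""
        est1 = NaturalEffects(
            outcome="prolonged", outcome_interval=3, mediators=("knowhow",),
            sampler_params=FAST_SAMPLER, random_state=6,
        ).fit(trial_complete)
        scaled = trial_complete.copy()
        for col in ["knowhow_0", "knowhow_1"]:
            scaled[col] = scaled[col] * 10.0
        est2 = NaturalEffects(
            outcome="prolonged", outcome_interval=3, mediators=("knowhow",),
            sampler_params=FAST_SAMPLER, random_state=6,
        ).fit(scaled)
        assert est2.nie_.estimate == pytest.approx(est1.nie_.estimate, abs=1e-3)
        assert est2.nde_.estimate == pytest.approx(est1.nde_.estimate, abs=1e-3)

    def test_joint_reduces_to_single_when_one_mediator_active(self):
        cfg = default_config(n=4000)
        for key in cfg.outcome_params:
            cfg.outcome_params[key].b = {"importance": 0.0, "knowhow": 0.45, "confidence": 0.0}
        df = simulate_trial(cfg, seed=7, with_missingness=False)
        single = NaturalEffects(
            outcome="prolonged", outcome_interval=3, mediators=("knowhow",),
            sampler_params=FAST_SAMPLER, random_state=8,
        ).fit(df)
        joint = NaturalEffects(
            outcome="prolonged", outcome_interval=3, mediators=MEDIATORS,
            sampler_params=FAST_SAMPLER, random_state=9,
        ).fit(df)
        assert joint.nie_.estimate == pytest.approx(single.nie_.estimate, abs=0.06)
        # the functional wrapper reproduces the estimator's result from its fits
        res = joint_natural_effects(
            joint.mediator_fits_, joint.outcome_fit_, df,
            spec=joint.result_.spec, n_draws=500, seed=1,
        )
        assert res.nie.estimate == pytest.approx(joint.nie_.estimate, abs=0.03)

    def test_joint_null_gives_unit_nie(self):
        cfg = default_config(n=3000)
        for key in cfg.outcome_params:
            cfg.outcome_params[key].b = {m: 0.0 for m in MEDIATORS}
        df = simulate_trial(cfg, seed=10, with_missingness=False)
        res = NaturalEffects(
            outcome="prolonged", outcome_interval=3, mediators=MEDIATORS,
            sampler_params=FAST_SAMPLER, random_state=11,
        ).fit(df)
        assert res.nie_.estimate == pytest.approx(1.0, abs=0.06)


class TestMediationTable:
    def _degenerate_result(self):
        spec = MediationSpec(outcome="pp", outcome_interval=6, mediators=("confidence",))
        point = summarize(np.full(100, np.log(1.2)), transform="exp")
        return MediationResult(spec=spec, nde=point, nie=point, te=point, n_rows=42)

    def test_empty_results_give_header_only_table(self):
        tab = mediation_table([])
        assert len(tab) == 0
        assert "estimate" in tab.columns

    def test_degenerate_draws_collapse_interval(self):
        tab = mediation_table([self._degenerate_result()])
        assert (tab.ci_low == tab.ci_high).all()
        assert tab.estimate.iloc[0] == pytest.approx(1.2)

    def test_round_trip_through_csv(self, tmp_path):
        tab = mediation_table([self._degenerate_result()])
        path = tmp_path / "table.csv"
        tab.to_csv(path, index=False)
        back = pd.read_csv(path)
        pd.testing.assert_frame_equal(back, tab)


def test_spec_requires_mediators():
    with pytest.raises(ConfigurationError):
        MediationSpec(mediators=())
    with pytest.raises(ConfigurationError):
        MediationSpec(mediators=("knowhow",), pairing="inverse")
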