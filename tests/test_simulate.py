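import numpy as np
import pandas as pd
import pytest

from trialmed.config import MEDIATORS, default_config
from trialmed.errors import SequencingError
from trialmed.simulate import (
    apply_missingness,
    generate_baseline,
    generate_mediators,
    generate_outcomes,
    randomize,
    simulate_trial,
)


class TestBaseline:
    def test_age_moments_match_targets_despite_truncation(self, cfg):
        df = generate_baseline(cfg.replace(n=100_000), seed=1)
        assert df.age.mean() == pytest.approx(45.4, abs=0.2)
        assert df.age.std() == pytest.approx(14.0, abs=0.2)
        assert df.age.min() >= 18.0

    def test_empty_dataset(self, cfg):
        df = generate_baseline(cfg.replace(n=0), seed=1)
        assert len(df) == 0

    def test_determinism(self, cfg):
        a = generate_baseline(cfg, seed=5)
        b = generate_baseline(cfg, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_ranges(self, cfg):
        df = generate_baseline(cfg.replace(n=5000), seed=2)
        assert df.ftnd.between(0, 10).all()
        assert (df.cigs_per_week >= 1).all()
        for m in MEDIATORS:
            assert df[f"{m}_0"].between(1, 10).all()


class TestRandomize:
    def test_forced_balance_single_block(self, cfg):
        df = generate_baseline(cfg.replace(n=2, surgery_frac=0.0), seed=3)
        out = randomize(df, block_sizes=(2,), seed=0)
        assert sorted(out.group) == ["control", "intervention"]

    @pytest.mark.parametrize("n", [7, 50, 1012])
    def test_imbalance_bounded_by_half_max_block(self, cfg, n):
        df = generate_baseline(cfg.replace(n=n), seed=4)
        for seed in range(10):
            out = randomize(df, block_sizes=(2, 4), seed=seed)
            for _, stratum in out.groupby("version"):
                n_i = (stratum.group == "intervention").sum()
                n_c = (stratum.group == "control").sum()
                assert abs(n_i - n_c) <= 2  # max(block_sizes) / 2

    def test_positionwise_allocation_probability_is_half(self, cfg):
        """Over many replicates every enrolment position is assigned to the
        intervention with probability 1/2."""
        n, reps = 200, 3000
        df = generate_baseline(cfg.replace(n=n), seed=6)
        counts = np.zeros(n)
        for seed in range(reps):
            out = randomize(df, block_sizes=(2, 4), seed=seed)
            counts += (out.group == "intervention").to_numpy()
        p = counts / reps
        assert np.abs(p - 0.5).max() < 0.035  # ~3.8 binomial sd


class TestMediators:
    def test_requires_randomisation_first(self, cfg):
        df = generate_baseline(cfg.replace(n=10), seed=1)
        with pytest.raises(SequencingError):
            generate_mediators(df, cfg, seed=1)

    def test_null_arm_effect_gives_no_group_difference(self, cfg):
        null = cfg.replace(
            n=50_000,
            arm_effect={m: {1: 0.0, 3: 0.0, 6: 0.0} for m in MEDIATORS},
        )
        df = randomize(generate_baseline(null, seed=7), seed=7)
        df = generate_mediators(df, null, seed=7)
        for m in MEDIATORS:
            g = df.groupby("group")[f"{m}_1"]
            z = (g.mean().diff().iloc[-1]) / g.std().mean() * np.sqrt(len(df) / 4)
            assert abs(z) < 4

    def test_positive_arm_effect_raises_intervention_mean(self, cfg):
        df = randomize(generate_baseline(cfg.replace(n=30_000), seed=8), seed=8)
        df = generate_mediators(df, cfg, seed=8)
        means = df.groupby("group").knowhow_1.mean()
        assert means["intervention"] > means["control"]

    def test_default_trajectories_qualitative(self, cfg):
        """Know-how/confidence diverge between arms after month 1 while
        importance stays flat and high in both arms."""
        big = cfg.replace(n=30_000)
        df = randomize(generate_baseline(big, seed=9), seed=9)
        df = generate_mediators(df, big, seed=9)
        g = df.groupby("group")
        for m in ("knowhow", "confidence"):
            for t in (1, 3, 6):
                diff = g[f"{m}_{t}"].mean().loc["intervention"] - g[f"{m}_{t}"].mean().loc["control"]
                assert diff > 0.1
        for t in (1, 3, 6):
            imp = g[f"importance_{t}"].mean()
            # importance stays near ceiling in both arms; any arm gap is small
            assert abs(imp["intervention"] - imp["control"]) < 0.15
            assert imp.min() > 8.0

    def test_optional_rounding_gives_integer_scores(self, cfg):
        rounded = cfg.replace(n=500, round_mediators=True)
        df = randomize(generate_baseline(rounded, seed=20), seed=20)
        df = generate_mediators(df, rounded, seed=20)
        for m in MEDIATORS:
            vals = df[f"{m}_1"]
            assert np.allclose(vals, np.round(vals))
            assert vals.between(1, 10).all()

    def test_range_invariant(self, trial_complete):
        for m in MEDIATORS:
            for t in (1, 3, 6):
                assert trial_complete[f"{m}_{t}"].between(1, 10).all()


class TestOutcomes:
    def test_null_effects_give_unit_odds_ratio(self, cfg):
        null = cfg.copy()
        null = null.replace(n=100_000)
        for key in null.outcome_params:
            null.outcome_params[key].theta_A = 0.0
            null.outcome_params[key].b = {m: 0.0 for m in MEDIATORS}
        df = simulate_trial(null, seed=10, with_missingness=False)
        p = df.groupby("group").prolonged_3.mean()
        odds = p / (1 - p)
        assert odds["intervention"] / odds["control"] == pytest.approx(1.0, abs=0.06)

    def test_intercept_monotonically_raises_control_rate(self, cfg):
        rates = []
        for theta_0 in (-2.0, -1.0, 0.0):
            c = cfg.replace(n=20_000)
            c.outcome_params["prolonged_3"].theta_0 = theta_0
            df = simulate_trial(c, seed=12, with_missingness=False)
            rates.append(df[df.group == "control"].prolonged_3.mean())
        assert rates[0] < rates[1] < rates[2]


class TestMissingness:
    def test_no_missingness_limit(self, cfg):
        c = cfg.copy()
        for t in c.response_params.med_intercept:
            c.response_params.med_intercept[t] = {"intervention": 30.0, "control": 30.0}
        for t in c.response_params.out_intercept:
            c.response_params.out_intercept[t] = {"intervention": 30.0, "control": 30.0}
        df = simulate_trial(c, seed=14)
        assert df.filter(like="responded").to_numpy().all()
        assert not df[[f"{m}_{t}" for m in MEDIATORS for t in (1, 3, 6)]].isna().any().any()

    def test_masking_consistent_with_indicators(self, trial_missing):
        for t in (1, 3, 6):
            resp = trial_missing[f"responded_med_{t}"] == 1
            for m in MEDIATORS:
                assert (trial_missing[f"{m}_{t}"].notna() == resp).all()

    def test_masking_leaves_retained_values_unchanged(self, cfg):
        full = simulate_trial(cfg, seed=15, with_missingness=False)
        # same seed path: regenerate with missingness and compare retained cells
        masked = apply_missingness(full, cfg, seed=99)
        for m in MEDIATORS:
            keep = masked[f"{m}_1"].notna()
            assert np.allclose(masked.loc[keep, f"{m}_1"], full.loc[keep, f"{m}_1"])

    def test_one_month_response_rates_lower_in_intervention(self, cfg):
        df = simulate_trial(cfg.replace(n=20_000), seed=16)
        rates = df.groupby("group").responded_med_1.mean()
        assert rates["intervention"] == pytest.approx(0.40, abs=0.02)
        assert rates["control"] == pytest.approx(0.61, abs=0.02)

    def test_attrition_model_recovers_ftnd_interaction_sign(self, cfg):
        """Refitting a frequentist response model on generated data recovers
        the negative FTND slope in the intervention arm at 1 month."""
        import statsmodels.api as sm

        df = simulate_trial(cfg.replace(n=30_000), seed=17)
        arm = (df.group == "intervention").astype(float)
        ftnd_z = (df.ftnd - df.ftnd.mean()) / df.ftnd.std()
        age_z = (df.age - df.age.mean()) / df.age.std()
        X = sm.add_constant(np.column_stack([arm, age_z, ftnd_z, ftnd_z * arm]))
        res = sm.Logit(df.responded_med_1, X).fit(disp=0)
        assert res.params.iloc[4] < -0.2  # ftnd x intervention
        assert res.params.iloc[2] > 0.2  # age


def test_end_to_end_determinism(cfg):
    a = simulate_trial(cfg, seed=21)
    b = simulate_trial(cfg, seed=21)
    pd.testing.assert_frame_equal(a, b)
    c = simulate_trial(cfg, seed=22)
    assert not a.equals(c)
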