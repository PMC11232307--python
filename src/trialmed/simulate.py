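"""Seeded synthetic-trial generation.

Builds participant-level datasets with the causal structure the mediation
analysis assumes: randomisation -> mediators -> outcomes, plus a
missing-at-random attrition layer.  Every stage takes an explicit seed (or
:class:`numpy.random.Generator`) and is deterministic given it.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .config import (
    MEDIATORS,
    MEDIATOR_INTERVALS,
    OUTCOME_INTERVALS,
    PRIOR_MEDIATOR_INTERVAL,
    GeneratorConfig,
    truncated_normal_parent_params,
)
from .errors import SequencingError


def as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ----------------------------------------------------------------------
# covariate helpers (shared with the oracle)
# ----------------------------------------------------------------------

def covariate_design(df: pd.DataFrame, config: GeneratorConfig) -> dict[str, np.ndarray]:
    """Generator-side covariate codings: indicators and z-scores against the
    *configured* (population) moments, not sample moments."""
    return {
        "sex": (df["sex"].to_numpy() == "woman").astype(float),
        "version": (df["version"].to_numpy() == "surgery").astype(float),
        "age_z": (df["age"].to_numpy(float) - config.age_mean) / config.age_sd,
        "ftnd_z": (df["ftnd"].to_numpy(float) - config.ftnd_mean) / config.ftnd_sd,
    }


def arm_indicator(df: pd.DataFrame) -> np.ndarray:
    group = df["group"]
    if group.isna().any():
        raise SequencingError("group assignment missing: run randomize first")
    return (group.to_numpy() == "intervention").astype(float)


def _exchangeable_chol(k: int, corr: float) -> np.ndarray:
    cov = np.full((k, k), corr)
    np.fill_diagonal(cov, 1.0)
    return np.linalg.cholesky(cov)


# ----------------------------------------------------------------------
# generation stages
# ----------------------------------------------------------------------

def generate_baseline(config: GeneratorConfig, seed=None) -> pd.DataFrame:
    """Draw pre-randomisation fields for ``config.n`` participants."""
    config.validate()
    rng = as_rng(seed)
    n = config.n

    sex = np.where(rng.random(n) < config.prop_woman, "woman", "man")
    version = np.where(rng.random(n) < config.surgery_frac, "surgery", "general")

    mu, sigma = truncated_normal_parent_params(
        config.age_mean, config.age_sd, config.age_min
    )
    a = (config.age_min - mu) / sigma
    age = stats.truncnorm.rvs(a, np.inf, loc=mu, scale=sigma, size=n, random_state=rng)

    ftnd = np.clip(
        np.round(rng.normal(config.ftnd_mean, config.ftnd_sd, size=n)), 0, 10
    ).astype(int)

    log_sd = np.sqrt(np.log1p((config.cigs_per_week_sd / config.cigs_per_week_mean) ** 2))
    log_mu = np.log(config.cigs_per_week_mean) - 0.5 * log_sd**2
    cigs = np.maximum(rng.lognormal(log_mu, log_sd, size=n), 1.0)

    chol = _exchangeable_chol(len(MEDIATORS), config.baseline_mediator_corr)
    z = rng.standard_normal((n, len(MEDIATORS))) @ chol.T
    base = {}
    for j, m in enumerate(MEDIATORS):
        vals = config.mediator_baseline_mean[m] + config.mediator_baseline_sd[m] * z[:, j]
        if config.round_mediators:
            vals = np.round(vals)
        base[f"{m}_0"] = np.clip(vals, 1.0, 10.0)

    df = pd.DataFrame(
        {
            "id": [f"P{i:06d}" for i in range(n)],
            "sex": sex,
            "age": age,
            "version": version,
            "ftnd": ftnd,
            "cigs_per_week": cigs,
            **base,
        }
    )
    df["group"] = pd.Series([pd.NA] * n, dtype="object")
    return df


def randomize(df: pd.DataFrame, block_sizes=(2, 4), seed=None) -> pd.DataFrame:
    """Stratified permuted-block randomisation.

    Within each intervention-version stratum, allocation proceeds in blocks
    whose lengths are drawn uniformly from ``block_sizes``; each block is a
    random permutation of half intervention / half control.  The final
    (possibly truncated) block is the only source of imbalance, bounded by
    ``max(block_sizes) / 2``.
    """
    rng = as_rng(seed)
    block_sizes = tuple(int(b) for b in block_sizes)
    if any(b <= 0 or b % 2 for b in block_sizes):
        raise ValueError(f"block sizes must be positive and even, got {block_sizes}")
    df = df.copy()
    group = np.empty(len(df), dtype=object)
    for _, idx in df.groupby("version", sort=True).indices.items():
        n_s = len(idx)
        alloc: list[int] = []
        while len(alloc) < n_s:
            size = int(rng.choice(block_sizes))
            block = np.repeat([1, 0], size // 2)
            alloc.extend(rng.permutation(block).tolist())
        arm01 = np.asarray(alloc[:n_s])
        group[idx] = np.where(arm01 == 1, "intervention", "control")
    df["group"] = group
    return df


def mediator_potential(
    df: pd.DataFrame,
    config: GeneratorConfig,
    interval: int,
    arm01: np.ndarray,
    eps: np.ndarray,
) -> dict[str, np.ndarray]:
    """Potential mediator values at ``interval`` given arm and standard-normal
    noise ``eps`` of shape (n, 3).  Shared noise across arms gives common
    random numbers for counterfactual contrasts."""
    cov = covariate_design(df, config)
    chol = _exchangeable_chol(len(MEDIATORS), config.residual_corr)
    corr_eps = eps @ chol.T
    out = {}
    for j, m in enumerate(MEDIATORS):
        mean = config.mediator_baseline_mean[m]
        sd = config.mediator_baseline_sd[m]
        coefs = config.mediator_covariate_coef[m]
        loc = (
            mean
            + config.rho[m] * (df[f"{m}_0"].to_numpy(float) - mean)
            + sum(coefs[c] * cov[c] for c in coefs)
            + config.arm_effect[m][interval] * sd * arm01
        )
        vals = loc + config.mediator_residual_sd(m) * corr_eps[:, j]
        if config.round_mediators:
            vals = np.round(vals)
        out[m] = np.clip(vals, 1.0, 10.0)
    return out


def generate_mediators(df: pd.DataFrame, config: GeneratorConfig, seed=None) -> pd.DataFrame:
    """Add mediator trajectories at 1/3/6 months (requires assigned groups)."""
    rng = as_rng(seed)
    arm01 = arm_indicator(df)
    df = df.copy()
    for t in MEDIATOR_INTERVALS:
        eps = rng.standard_normal((len(df), len(MEDIATORS)))
        vals = mediator_potential(df, config, t, arm01, eps)
        for m in MEDIATORS:
            df[f"{m}_{t}"] = vals[m]
    return df


def outcome_probability(
    df: pd.DataFrame,
    config: GeneratorConfig,
    outcome_key: str,
    arm01: np.ndarray | None = None,
    mediator_values: dict[str, np.ndarray] | None = None,
) -> np.ndarray:
    """True conditional abstinence probability under the generator.

    ``outcome_key`` is e.g. ``"prolonged_3"``.  ``mediator_values`` (raw
    scale, at the causally prior interval) and ``arm01`` may be overridden
    to evaluate counterfactual compositions.
    """
    params = config.outcome_params[outcome_key]
    interval = int(outcome_key.rsplit("_", 1)[1])
    t_med = PRIOR_MEDIATOR_INTERVAL[interval]
    if arm01 is None:
        arm01 = arm_indicator(df)
    cov = covariate_design(df, config)
    eta = params.theta_0 + params.theta_A * arm01
    for c, coef in params.covariate_coef.items():
        eta = eta + coef * cov[c]
    for m in MEDIATORS:
        raw = (
            mediator_values[m]
            if mediator_values is not None
            else df[f"{m}_{t_med}"].to_numpy(float)
        )
        z = (raw - config.mediator_baseline_mean[m]) / config.mediator_baseline_sd[m]
        eta = eta + params.b[m] * z
    return expit(eta)


def generate_outcomes(df: pd.DataFrame, config: GeneratorConfig, seed=None) -> pd.DataFrame:
    """Draw binary abstinence outcomes from the true logistic models."""
    rng = as_rng(seed)
    missing = [
        f"{m}_{t}" for t in MEDIATOR_INTERVALS for m in MEDIATORS if f"{m}_{t}" not in df
    ]
    if missing:
        raise SequencingError("mediators not generated yet: run generate_mediators first")
    df = df.copy()
    for key in config.outcome_params:
        p = outcome_probability(df, config, key)
        df[key] = rng.binomial(1, p).astype(float)
    return df


def apply_missingness(df: pd.DataFrame, config: GeneratorConfig, seed=None) -> pd.DataFrame:
    """Draw response indicators from the MAR attrition models and mask values.

    Mediator questionnaires (all three items together) can be missed at
    1/3/6 months; outcome questionnaires (both abstinence definitions) at
    3/6 months.  Baseline fields are never masked.
    """
    rng = as_rng(seed)
    rp = config.response_params
    arm01 = arm_indicator(df)
    cov = covariate_design(df, config)
    df = df.copy()
    for t in MEDIATOR_INTERVALS:
        b0 = np.where(
            arm01 == 1, rp.med_intercept[t]["intervention"], rp.med_intercept[t]["control"]
        )
        eta = b0 + rp.age_slope * cov["age_z"]
        if t == 1:
            eta = eta + rp.ftnd_intervention_slope_1m * cov["ftnd_z"] * arm01
        resp = rng.binomial(1, expit(eta))
        df[f"responded_med_{t}"] = resp
        for m in MEDIATORS:
            df.loc[resp == 0, f"{m}_{t}"] = np.nan
    for t in OUTCOME_INTERVALS:
        b0 = np.where(
            arm01 == 1, rp.out_intercept[t]["intervention"], rp.out_intercept[t]["control"]
        )
        resp = rng.binomial(1, expit(b0 + rp.age_slope * cov["age_z"]))
        df[f"responded_out_{t}"] = resp
        for name in ("prolonged", "pp"):
            df.loc[resp == 0, f"{name}_{t}"] = np.nan
    return df


def simulate_trial(
    config: GeneratorConfig, seed=None, with_missingness: bool = True
) -> pd.DataFrame:
    """End-to-end simulation: baseline -> randomise -> mediators -> outcomes
    [-> attrition].  Per-stage seeds are spawned from ``seed`` so stages stay
    individually reproducible."""
    ss = np.random.SeedSequence(seed)
    s_base, s_rand, s_med, s_out, s_miss = ss.spawn(5)
    df = generate_baseline(config, np.random.default_rng(s_base))
    df = randomize(df, config.block_sizes, np.random.default_rng(s_rand))
    df = generate_mediators(df, config, np.random.default_rng(s_med))
    df = generate_outcomes(df, config, np.random.default_rng(s_out))
    if with_missingness:
        df = apply_missingness(df, config, np.random.default_rng(s_miss))
    else:
        for t in MEDIATOR_INTERVALS:
            df[f"responded_med_{t}"] = 1
        for t in OUTCOME_INTERVALS:
            df[f"responded_out_{t}"] = 1
    return df
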