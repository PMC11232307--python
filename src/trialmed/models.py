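"""Analysis-side model fitting: standardised-mediator linear models,
abstinence-outcome logistic models, total-effect models and attrition
models, with posterior summaries in the trial's reporting format
(posterior median, 2.5%/97.5% percentiles, posterior probability of
direction).

All models share one adjustment set: arm, sex, age, intervention version,
baseline FTND, and the baseline value of each mediator entering the model.
Continuous covariates are standardised before entering so the
standard-normal effect priors have a meaningful scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import MEDIATORS, PRIOR_MEDIATOR_INTERVAL
from .errors import (
    DegenerateDataError,
    InsufficientDataError,
)
from .glm import (
    BayesianLinearRegression,
    BayesianLogisticRegression,
    HierarchicalScaleLogisticRegression,
    PosteriorDraws,
)

ADJUSTMENT_COVARIATES = ("sex", "age_z", "version", "ftnd_z")


# ----------------------------------------------------------------------
# standardisation
# ----------------------------------------------------------------------

def standardize_mediator(values, reference_values):
    """Standardise ``values`` by the mean/sd of ``reference_values``.

    The reference is the set of available observations at the interval in
    question, both arms pooled; sd uses the n-1 denominator.  Returns
    ``(standardised, mean, sd)`` so the same transform can be reapplied to
    counterfactual predictions.
    """
    ref = np.asarray(reference_values, dtype=float)
    ref = ref[np.isfinite(ref)]
    if ref.size < 2:
        raise DegenerateDataError("need at least two reference values to standardise")
    mean = float(ref.mean())
    sd = float(ref.std(ddof=1))
    if sd == 0.0:
        raise DegenerateDataError("reference values are constant; sd = 0")
    return (np.asarray(values, dtype=float) - mean) / sd, mean, sd


# ----------------------------------------------------------------------
# summaries
# ----------------------------------------------------------------------

@dataclass
class EffectSummary:
    """Posterior median, 95% compatibility interval and direction probability."""

    estimate: float
    ci_low: float
    ci_high: float
    prob_direction: float
    scale: str  # standardised_difference | log_odds | odds_ratio

    def __post_init__(self):
        if not self.ci_low <= self.estimate <= self.ci_high:
            raise ValueError("summary ordering violated: ci_low <= estimate <= ci_high")
        if not 0.0 <= self.prob_direction <= 1.0:
            raise ValueError("prob_direction must be in [0, 1]")


def summarize(draws, transform="identity", scale=None) -> EffectSummary:
    """Median and 2.5/97.5 percentiles of (optionally exponentiated) draws.

    ``prob_direction`` is the fraction of draws above the null value: 0 on
    the identity scale, 1 after an exp transform (odds ratios).  Percentiles
    use linear interpolation.
    """
    draws = np.asarray(draws, dtype=float)
    if draws.size == 0:
        raise ValueError("cannot summarise empty draws")
    if transform == "exp":
        draws = np.exp(draws)
        null = 1.0
        scale = scale or "odds_ratio"
    elif transform == "identity":
        null = 1.0 if scale == "odds_ratio" else 0.0
        scale = scale or "standardised_difference"
    else:
        raise ValueError(f"unknown transform {transform!r}")
    lo, med, hi = np.percentile(draws, [2.5, 50.0, 97.5])
    return EffectSummary(
        estimate=float(med),
        ci_low=float(lo),
        ci_high=float(hi),
        prob_direction=float(np.mean(draws > null)),
        scale=scale,
    )


# ----------------------------------------------------------------------
# design construction
# ----------------------------------------------------------------------

@dataclass
class ModelFit:
    """A fitted model plus everything needed to reuse or audit it: the
    estimator, posterior draws, term names, the standardisation transforms
    applied, and the exact rows used (complete-case reproducibility)."""

    model: object
    draws: PosteriorDraws
    terms: list[str]
    transforms: dict[str, tuple[float, float]]
    rows: pd.Index
    response: str

    def coef(self, name):
        return self.draws.coef(name)


def _complete_rows(data: pd.DataFrame, columns) -> pd.Index:
    return data.index[data[list(columns)].notna().all(axis=1)]


def build_design(data: pd.DataFrame, terms, transforms):
    """Design matrix for the shared covariate coding.

    ``terms`` may contain: ``arm``, ``sex``, ``version``, ``age_z``,
    ``ftnd_z`` and ``z(<column>)`` entries for standardised mediator
    columns.  ``transforms`` maps a raw column name to its (mean, sd); it is
    filled in for any z-term not already present (so a shared transform can
    be passed between mediator and outcome fits).
    """
    cols = []
    for term in terms:
        if term == "arm":
            cols.append((data["group"] == "intervention").astype(float).to_numpy())
        elif term == "sex":
            cols.append((data["sex"] == "woman").astype(float).to_numpy())
        elif term == "version":
            cols.append((data["version"] == "surgery").astype(float).to_numpy())
        elif term in ("age_z", "ftnd_z"):
            raw = term[:-2]
            if raw not in transforms:
                _, mean, sd = standardize_mediator(data[raw], data[raw])
                transforms[raw] = (mean, sd)
            mean, sd = transforms[raw]
            cols.append((data[raw].to_numpy(float) - mean) / sd)
        elif term.startswith("z(") and term.endswith(")"):
            raw = term[2:-1]
            if raw not in transforms:
                _, mean, sd = standardize_mediator(data[raw], data[raw])
                transforms[raw] = (mean, sd)
            mean, sd = transforms[raw]
            cols.append((data[raw].to_numpy(float) - mean) / sd)
        elif term in data.columns:
            cols.append(data[term].to_numpy(float))
        else:
            raise ValueError(f"unknown design term {term!r}")
    return np.column_stack(cols) if cols else np.empty((len(data), 0))


def _attach_rows(fit_model, rows) -> PosteriorDraws:
    post = fit_model.posterior_
    post.rows = rows
    return post


# ----------------------------------------------------------------------
# model-level operations
# ----------------------------------------------------------------------

def fit_mediator_model(
    data: pd.DataFrame,
    mediator: str,
    interval: int,
    *,
    min_rows: int = 25,
    transforms: dict | None = None,
    rows: pd.Index | None = None,
    random_state=None,
    **sampler_kwargs,
) -> ModelFit:
    """Bayesian linear regression of the standardised mediator at ``interval``
    on arm plus the adjustment set (complete cases)."""
    if mediator not in MEDIATORS:
        raise ValueError(f"unknown mediator {mediator!r}")
    m_col = f"{mediator}_{interval}"
    base_col = f"{mediator}_0"
    needed = ["group", "sex", "age", "version", "ftnd", base_col, m_col]
    if rows is None:
        rows = _complete_rows(data, needed)
    if len(rows) < min_rows:
        raise InsufficientDataError(
            f"only {len(rows)} complete rows for {mediator} at {interval} months "
            f"(minimum {min_rows})"
        )
    sub = data.loc[rows]
    transforms = {} if transforms is None else transforms
    if m_col not in transforms:
        _, mean, sd = standardize_mediator(sub[m_col], sub[m_col])
        transforms[m_col] = (mean, sd)
    mean, sd = transforms[m_col]
    y = (sub[m_col].to_numpy(float) - mean) / sd
    terms = ["arm", *ADJUSTMENT_COVARIATES, f"z({base_col})"]
    X = build_design(sub, terms, transforms)
    model = BayesianLinearRegression(random_state=random_state, **sampler_kwargs)
    model.fit(X, y, coef_names=terms)
    return ModelFit(model, _attach_rows(model, rows), terms, transforms, rows, m_col)


def fit_outcome_model(
    data: pd.DataFrame,
    outcome: str,
    outcome_interval: int,
    mediator_set=MEDIATORS,
    mediator_interval: int | None = None,
    *,
    min_rows: int = 25,
    transforms: dict | None = None,
    rows: pd.Index | None = None,
    random_state=None,
    **sampler_kwargs,
) -> ModelFit:
    """Bayesian logistic regression of a binary abstinence outcome on arm,
    the standardised mediator(s) at the causally prior interval, and the
    adjustment set (complete cases)."""
    mediator_set = tuple(mediator_set)
    if mediator_interval is None:
        mediator_interval = PRIOR_MEDIATOR_INTERVAL[outcome_interval]
    out_col = f"{outcome}_{outcome_interval}"
    med_cols = [f"{m}_{mediator_interval}" for m in mediator_set]
    base_cols = [f"{m}_0" for m in mediator_set]
    needed = ["group", "sex", "age", "version", "ftnd", out_col, *med_cols, *base_cols]
    if rows is None:
        rows = _complete_rows(data, needed)
    if len(rows) < min_rows:
        raise InsufficientDataError(
            f"only {len(rows)} complete rows for {out_col} with mediators at "
            f"{mediator_interval} months (minimum {min_rows})"
        )
    sub = data.loc[rows]
    transforms = {} if transforms is None else transforms
    terms = [
        "arm",
        *(f"z({c})" for c in med_cols),
        *ADJUSTMENT_COVARIATES,
        *(f"z({c})" for c in base_cols),
    ]
    X = build_design(sub, terms, transforms)
    y = sub[out_col].to_numpy(float)
    model = BayesianLogisticRegression(random_state=random_state, **sampler_kwargs)
    model.fit(X, y, coef_names=terms)
    return ModelFit(model, _attach_rows(model, rows), terms, transforms, rows, out_col)


def mediation_available_rows(
    data: pd.DataFrame, outcome: str, outcome_interval: int, mediator_set=MEDIATORS
) -> pd.Index:
    """Rows usable by a mediation analysis: arm, adjustment set, mediators at
    the causally prior interval, their baselines and the outcome all observed."""
    t_med = PRIOR_MEDIATOR_INTERVAL[outcome_interval]
    needed = (
        ["group", "sex", "age", "version", "ftnd", f"{outcome}_{outcome_interval}"]
        + [f"{m}_{t_med}" for m in mediator_set]
        + [f"{m}_0" for m in mediator_set]
    )
    return _complete_rows(data, needed)


def fit_total_effect(
    data: pd.DataFrame,
    outcome: str,
    outcome_interval: int,
    subsample_rule=None,
    *,
    min_rows: int = 25,
    random_state=None,
    **sampler_kwargs,
):
    """Adjusted total-effect model (no mediators): logistic regression of the
    outcome on arm plus the adjustment set.

    ``subsample_rule`` optionally restricts the rows, e.g. to participants
    with mediation data available (the attrition sensitivity comparison);
    it may be a callable ``data -> Index`` or an explicit Index.

    Returns ``(EffectSummary on the odds-ratio scale, ModelFit)``.  The
    summary is the covariate-averaged marginal odds ratio: per posterior
    draw, predicted probabilities with arm set to 1 and to 0 are averaged
    over the analysis rows and turned into an OR — the same marginalisation
    convention the mediation estimator uses, and the estimand the causal
    oracle computes.  The conditional arm log-odds coefficient remains
    available from the returned fit.
    """
    out_col = f"{outcome}_{outcome_interval}"
    needed = ["group", "sex", "age", "version", "ftnd", out_col]
    rows = _complete_rows(data, needed)
    if subsample_rule is not None:
        extra = subsample_rule(data) if callable(subsample_rule) else pd.Index(subsample_rule)
        rows = rows.intersection(extra)
    if len(rows) < min_rows:
        raise InsufficientDataError(
            f"only {len(rows)} usable rows for total effect on {out_col}"
        )
    sub = data.loc[rows]
    transforms: dict = {}
    terms = ["arm", *ADJUSTMENT_COVARIATES]
    X = build_design(sub, terms, transforms)
    y = sub[out_col].to_numpy(float)
    model = BayesianLogisticRegression(random_state=random_state, **sampler_kwargs)
    model.fit(X, y, coef_names=terms)
    fit = ModelFit(model, _attach_rows(model, rows), terms, transforms, rows, out_col)

    arm_idx = terms.index("arm")
    X1 = X.copy()
    X1[:, arm_idx] = 1.0
    X0 = X.copy()
    X0[:, arm_idx] = 0.0
    p1 = model.predict_proba_draws(X1).mean(axis=0)
    p0 = model.predict_proba_draws(X0).mean(axis=0)
    or_draws = (p1 / (1 - p1)) / (p0 / (1 - p0))
    return summarize(or_draws, scale="odds_ratio"), fit


def fit_attrition_model(
    data: pd.DataFrame,
    interval: int,
    response_field: str,
    *,
    random_state=None,
    n_draws: int = 2000,
    extra_covariates=(),
    **sampler_kwargs,
):
    """Hierarchical logistic attrition model with arm interactions.

    Response (1 = responded) is regressed on baseline covariates, arm, and
    arm x covariate interactions; coefficients get Cauchy priors with a
    common scale under a half-normal hyperprior.  Returns ``(ModelFit,
    arm_effects)`` where ``arm_effects[arm][covariate]`` is an
    :class:`EffectSummary` of that covariate's effect within the arm.
    """
    y_all = data[response_field]
    if y_all.isna().any():
        raise ValueError(f"{response_field} must be observed for every row")
    if y_all.nunique() < 2:
        raise DegenerateDataError(f"{response_field} is constant; attrition model undefined")

    covs = ["sex", "age_z", "version", "ftnd_z"] + [f"z({m}_0)" for m in MEDIATORS]
    covs += list(extra_covariates)
    rows = _complete_rows(data, ["group", "sex", "age", "version", "ftnd"])
    sub = data.loc[rows]
    transforms: dict = {}
    # centred design: covariates and the arm indicator are centred before
    # interactions are formed, which decorrelates main effects from their
    # interactions (the coordinate-wise sampler mixes poorly otherwise).
    # Coefficient meaning: main effect = covariate effect at the average arm
    # mix; arm-specific effects are recovered below.
    X_main = build_design(sub, covs, transforms)
    X_main = X_main - X_main.mean(axis=0, keepdims=True)
    arm = build_design(sub, ["arm"], transforms)[:, 0]
    arm_mean = arm.mean()
    arm_c = arm - arm_mean
    X = np.column_stack([arm_c[:, None], X_main, X_main * arm_c[:, None]])
    terms = ["arm", *covs, *(f"arm:{c}" for c in covs)]
    model = HierarchicalScaleLogisticRegression(
        random_state=random_state, n_draws=n_draws, **sampler_kwargs
    )
    model.fit(X, sub[response_field].to_numpy(float), coef_names=terms)
    fit = ModelFit(
        model, _attach_rows(model, rows), terms, transforms, rows, response_field
    )
    arm_effects = {"control": {}, "intervention": {}}
    for c in covs:
        main = fit.coef(c)
        inter = fit.coef(f"arm:{c}")
        arm_effects["control"][c] = summarize(main - arm_mean * inter, scale="log_odds")
        arm_effects["intervention"][c] = summarize(
            main + (1.0 - arm_mean) * inter, scale="log_odds"
        )
    return fit, arm_effects
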