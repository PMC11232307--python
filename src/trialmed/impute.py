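"""Multiple imputation by chained equations (MICE) and Bayesian pooling.

Sensitivity analysis for the complete-case ("available data") analyses:
mediator scores are imputed by predictive mean matching (5 donors) and
binary abstinence outcomes by approximate-Bayesian logistic draws, cycling
variables in ascending-missingness order.  Observed values are never
modified.  Pooling of Bayesian fits across completed datasets concatenates
their posterior draws, which propagates within- plus between-imputation
uncertainty.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.base import BaseEstimator

from .config import MEDIATORS, MEDIATOR_INTERVALS, OUTCOME_INTERVALS
from .errors import ConfigurationError
from .glm import PosteriorDraws

#: analysis variables eligible for imputation, with their imputation method
DEFAULT_METHODS = {
    **{f"{m}_{t}": "pmm" for t in MEDIATOR_INTERVALS for m in MEDIATORS},
    **{f"{o}_{t}": "logreg" for t in OUTCOME_INTERVALS for o in ("prolonged", "pp")},
}

#: always-observed predictors entering every imputation model
BASELINE_PREDICTORS = [
    "arm",
    "sex01",
    "version01",
    "age",
    "ftnd",
    "cigs_per_week",
    "importance_0",
    "knowhow_0",
    "confidence_0",
]


@dataclass
class ImputationSet:
    """m completed datasets plus the recipe that produced them."""

    datasets: list[pd.DataFrame]
    methods: dict[str, str]
    n_iter: int
    seed: object = None

    def __post_init__(self):
        for ds in self.datasets:
            cols = [c for c in self.methods if c in ds.columns]
            if ds[cols].isna().any().any():
                raise ValueError("completed dataset still contains missing analysis fields")

    @property
    def m(self) -> int:
        return len(self.datasets)


def _ridge_logistic_draw(X, y, rng, ridge=0.01, n_irls=30):
    """Approximate posterior draw of logistic coefficients via IRLS + Laplace.

    The ridge term acts as a weak normal prior and keeps the fit defined
    under separation inside chained cycles.
    """
    p = X.shape[1]
    beta = np.zeros(p)
    XtX_prior = ridge * np.eye(p)
    for _ in range(n_irls):
        eta = X @ beta
        mu = expit(eta)
        w = np.clip(mu * (1 - mu), 1e-6, None)
        H = X.T @ (X * w[:, None]) + XtX_prior
        grad = X.T @ (y - mu) - ridge * beta
        step = np.linalg.solve(H, grad)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-8:
            break
    H = X.T @ (X * np.clip(expit(X @ beta) * (1 - expit(X @ beta)), 1e-6, None)[:, None])
    H += XtX_prior
    cov = np.linalg.inv(H)
    chol = np.linalg.cholesky(0.5 * (cov + cov.T) + 1e-12 * np.eye(p))
    return beta + chol @ rng.standard_normal(p)


def _bayes_linear_draw(X, y, rng, ridge=1e-6):
    """Posterior draw (beta, and point predictions) for a vague-prior linear
    model: sigma^2 from the scaled inverse-chi-square, beta from its normal."""
    n, p = X.shape
    XtX = X.T @ X + ridge * np.eye(p)
    beta_hat = np.linalg.solve(XtX, X.T @ y)
    resid = y - X @ beta_hat
    dof = max(n - p, 1)
    sigma2 = resid @ resid / rng.chisquare(dof)
    cov = sigma2 * np.linalg.inv(XtX)
    chol = np.linalg.cholesky(0.5 * (cov + cov.T) + 1e-12 * np.eye(p))
    beta_draw = beta_hat + chol @ rng.standard_normal(p)
    return beta_hat, beta_draw


class ChainedEquationsImputer(BaseEstimator):
    """MICE transformer producing ``m`` completed datasets.

    Continuous mediators use type-1 predictive mean matching (donor pool
    ``pmm_donors``); binary outcomes use Bayesian logistic draws.  Within a
    cycle each variable is regressed on the baseline covariates, arm, and
    every other analysis variable (current completed values), which keeps
    the imputation models congenial with the analysis models.
    """

    def __init__(self, m=20, n_iter=20, pmm_donors=5, methods=None, random_state=None):
        self.m = m
        self.n_iter = n_iter
        self.pmm_donors = pmm_donors
        self.methods = methods
        self.random_state = random_state

    def fit(self, data: pd.DataFrame, y=None):
        methods = dict(self.methods or DEFAULT_METHODS)
        methods = {k: v for k, v in methods.items() if k in data.columns}
        fully_missing = [c for c in methods if data[c].notna().sum() == 0]
        if fully_missing:
            raise ConfigurationError(
                f"cannot impute variables with no observed values: {fully_missing}"
            )
        self.methods_ = methods
        self.missing_counts_ = {c: int(data[c].isna().sum()) for c in methods}
        # ascending-missingness visit order
        self.visit_order_ = sorted(methods, key=lambda c: self.missing_counts_[c])
        return self

    def transform(self, data: pd.DataFrame) -> ImputationSet:
        work_base = data.copy()
        work_base["arm"] = (work_base["group"] == "intervention").astype(float)
        work_base["sex01"] = (work_base["sex"] == "woman").astype(float)
        work_base["version01"] = (work_base["version"] == "surgery").astype(float)

        ss = np.random.SeedSequence(self.random_state)
        datasets = []
        for child in ss.spawn(self.m):
            rng = np.random.default_rng(child)
            completed = self._single_imputation(work_base, rng)
            datasets.append(completed.drop(columns=["arm", "sex01", "version01"]))
        return ImputationSet(
            datasets=datasets, methods=dict(self.methods_), n_iter=self.n_iter,
            seed=self.random_state,
        )

    def fit_transform(self, data: pd.DataFrame, y=None) -> ImputationSet:
        return self.fit(data).transform(data)

    # ------------------------------------------------------------------
    def _single_imputation(self, data: pd.DataFrame, rng) -> pd.DataFrame:
        work = data.copy()
        obs_mask = {c: work[c].notna().to_numpy() for c in self.methods_}
        # initial fill: random draws from the observed values
        for c in self.visit_order_:
            n_mis = (~obs_mask[c]).sum()
            if n_mis:
                donors = work.loc[obs_mask[c], c].to_numpy()
                work.loc[~obs_mask[c], c] = rng.choice(donors, size=n_mis)
        if all(obs_mask[c].all() for c in self.visit_order_):
            return work

        for _ in range(self.n_iter):
            for c in self.visit_order_:
                mis = ~obs_mask[c]
                if not mis.any():
                    continue
                predictors = BASELINE_PREDICTORS + [
                    v for v in self.visit_order_ if v != c
                ]
                X = np.column_stack(
                    [np.ones(len(work))]
                    + [work[p].to_numpy(float) for p in predictors]
                )
                y = work[c].to_numpy(float)
                if self.methods_[c] == "pmm":
                    beta_hat, beta_draw = _bayes_linear_draw(X[obs_mask[c]], y[obs_mask[c]], rng)
                    pred_obs = X[obs_mask[c]] @ beta_hat
                    pred_mis = X[mis] @ beta_draw
                    obs_vals = y[obs_mask[c]]
                    k = min(self.pmm_donors, len(obs_vals))
                    dist = np.abs(pred_mis[:, None] - pred_obs[None, :])
                    donor_idx = np.argpartition(dist, k - 1, axis=1)[:, :k]
                    pick = donor_idx[np.arange(len(pred_mis)), rng.integers(0, k, len(pred_mis))]
                    work.loc[mis, c] = obs_vals[pick]
                else:  # logreg
                    beta = _ridge_logistic_draw(X[obs_mask[c]], y[obs_mask[c]], rng)
                    p_mis = expit(X[mis] @ beta)
                    work.loc[mis, c] = rng.binomial(1, p_mis).astype(float)
        return work


def mice_impute(data, m=20, n_iter=20, methods=None, seed=None) -> ImputationSet:
    """Functional wrapper over :class:`ChainedEquationsImputer`."""
    return ChainedEquationsImputer(
        m=m, n_iter=n_iter, methods=methods, random_state=seed
    ).fit_transform(data)


def pool_posteriors(fits: list[PosteriorDraws]) -> PosteriorDraws:
    """Pool Bayesian fits across imputations by concatenating their draws.

    The mixture posterior reflects within- plus between-imputation
    uncertainty; summaries are then computed as for a single fit.
    """
    if not fits:
        raise ValueError("no fits to pool")
    names = fits[0].names
    for f in fits[1:]:
        if f.names != names:
            raise ValueError("cannot pool fits with different coefficients")
    draws = np.concatenate([f.draws for f in fits], axis=0)
    aux = {}
    for key in fits[0].aux:
        aux[key] = np.concatenate([f.aux[key] for f in fits], axis=0)
    diagnostics = {
        "pooled_from": len(fits),
        "rhat_max": max(f.diagnostics.get("rhat_max", np.nan) for f in fits),
        "flagged": any(f.diagnostics.get("flagged", False) for f in fits),
    }
    return PosteriorDraws(
        names=list(names), draws=draws, aux=aux, diagnostics=diagnostics,
        n_obs=fits[0].n_obs,
    )
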