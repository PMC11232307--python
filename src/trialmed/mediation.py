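"""Counterfactual mediation: natural direct and indirect effect odds ratios.

The estimator combines a Bayesian linear model for each standardised
mediator with a Bayesian logistic model for the outcome.  Per posterior
draw, the marginal counterfactual probabilities

    p[a, a'] = E_x[ P(Y(a, M(a')) = 1 | x) ]

are computed by integrating the conditional-normal mediator law (arm a')
against the logistic outcome model (arm a), averaging over the observed
covariate rows of the analysis sample.  Odds-ratio draws follow:

* pure NDE   = odds(p[1,0]) / odds(p[0,0])
* pure NIE   = odds(p[0,1]) / odds(p[0,0])
* total NDE  = odds(p[1,1]) / odds(p[0,1])
* total NIE  = odds(p[1,1]) / odds(p[1,0])
* TE         = odds(p[1,1]) / odds(p[0,0])

The headline pairing reports the *pure* effects (mediator held at its
control-arm law for the direct effect; treatment held at control for the
indirect effect).  The complementary (total) pairing is always computed as
well because it is the one that satisfies the exact per-draw decomposition
TE = total NDE x pure NIE = pure NDE x total NIE.

Integration is Gauss-Hermite quadrature for a single mediator and common-
random-number Monte Carlo for the joint model (mediators conditionally
independent given covariates by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.polynomial.hermite import hermgauss
from scipy.special import expit
from sklearn.base import BaseEstimator

from .config import MEDIATORS, PRIOR_MEDIATOR_INTERVAL
from .errors import AlignmentError, ConfigurationError, ConvergenceError
from .models import (
    EffectSummary,
    ModelFit,
    fit_mediator_model,
    fit_outcome_model,
    mediation_available_rows,
    summarize,
)

_PAIRINGS = ("pure", "total")


@dataclass
class MediationSpec:
    """What to mediate: outcome, intervals, mediator set, pairing, integration."""

    outcome: str = "prolonged"
    outcome_interval: int = 3
    mediators: tuple[str, ...] = MEDIATORS
    pairing: str = "pure"
    method: str | None = None  # gauss_hermite | monte_carlo | None = auto
    size: int | None = None  # nodes (GH) or draws per row (MC)

    def __post_init__(self):
        self.mediators = tuple(self.mediators)
        if not self.mediators:
            raise ConfigurationError("mediator set must be non-empty")
        if self.pairing not in _PAIRINGS:
            raise ConfigurationError(f"pairing must be one of {_PAIRINGS}")
        if self.method is None:
            self.method = "gauss_hermite" if len(self.mediators) == 1 else "monte_carlo"
        if self.size is None:
            self.size = 32 if self.method == "gauss_hermite" else 20
        if self.size < 1:
            raise ConfigurationError("integration size must be >= 1")

    @property
    def mediator_interval(self) -> int:
        return PRIOR_MEDIATOR_INTERVAL[self.outcome_interval]


@dataclass
class MediationResult:
    """Paired NDE/NIE/TE summaries (headline pairing) plus all OR draws."""

    spec: MediationSpec
    nde: EffectSummary
    nie: EffectSummary
    te: EffectSummary
    n_rows: int
    or_draws: dict[str, np.ndarray] = field(default_factory=dict)
    summaries: dict[str, EffectSummary] = field(default_factory=dict)


# ----------------------------------------------------------------------
# integration machinery
# ----------------------------------------------------------------------

class _CounterfactualEngine:
    """Precomputes per-draw pieces shared by the four compositions."""

    def __init__(self, outcome_fit, mediator_fits, data, spec, n_draws=1000, seed=None):
        self.spec = spec
        mediators = spec.mediators
        t = spec.mediator_interval
        self.med_cols = [f"{m}_{t}" for m in mediators]

        rows = outcome_fit.rows
        for m, fit in mediator_fits.items():
            if not fit.rows.equals(rows):
                raise AlignmentError(
                    f"mediator fit for {m} uses different rows than the outcome fit"
                )
            col = f"{m}_{t}"
            if not np.allclose(fit.transforms[col], outcome_fit.transforms[col]):
                raise AlignmentError(f"standardisation transforms differ for {col}")
        sub = data.loc[rows]
        self.n_rows = len(sub)

        # thin all posteriors to a common number of integration draws
        avail = min(
            outcome_fit.draws.n_draws, *(f.draws.n_draws for f in mediator_fits.values())
        )
        n_draws = min(n_draws, avail)
        idx = np.linspace(0, avail - 1, n_draws).astype(int)
        self.n_draws = n_draws

        # outcome model pieces
        oc = outcome_fit.draws.draws[idx]
        names = outcome_fit.draws.names
        self.out_intercept = oc[:, names.index("intercept")]
        self.out_arm = oc[:, names.index("arm")]
        self.b = np.column_stack([oc[:, names.index(f"z({c})")] for c in self.med_cols])
        other_terms = [
            tname
            for tname in outcome_fit.terms
            if tname != "arm" and tname not in {f"z({c})" for c in self.med_cols}
        ]
        from .models import build_design

        X_other = build_design(sub, other_terms, dict(outcome_fit.transforms))
        beta_other = np.column_stack(
            [oc[:, names.index(tname)] for tname in other_terms]
        ) if other_terms else np.zeros((n_draws, 0))
        # (n_rows, n_draws)
        self.eta_cov = self.out_intercept[None, :] + X_other @ beta_other.T

        # mediator conditional laws on the z scale: mu(row, draw; arm)
        self.mu0, self.arm_shift, self.sigma = {}, {}, {}
        for m in mediators:
            fit = mediator_fits[m]
            dr = fit.draws.draws[idx]
            mnames = fit.draws.names
            m_other = [tname for tname in fit.terms if tname != "arm"]
            Xm = build_design(sub, m_other, dict(fit.transforms))
            beta_m = (
                np.column_stack([dr[:, mnames.index(tname)] for tname in m_other])
                if m_other
                else np.zeros((n_draws, 0))
            )
            self.mu0[m] = dr[:, mnames.index("intercept")][None, :] + Xm @ beta_m.T
            self.arm_shift[m] = dr[:, mnames.index("arm")]
            self.sigma[m] = fit.model.sigma_draws_[idx]
            if not np.all(np.isfinite(self.mu0[m])):
                raise ValueError(f"non-finite conditional means for mediator {m}")

        if spec.method == "monte_carlo":
            rng = np.random.default_rng(seed)
            # one epsilon per (row, integration draw, mediator), shared across
            # compositions and posterior draws: common random numbers
            self.eps = rng.standard_normal((self.n_rows, spec.size, len(mediators)))
        else:
            nodes, weights = hermgauss(spec.size)
            self.gh_nodes = np.sqrt(2.0) * nodes
            self.gh_weights = weights / np.sqrt(np.pi)

    def marginal_probability(self, a_direct, a_mediator, chunk=16):
        """Per-posterior-draw marginal probability of the composition."""
        spec = self.spec
        mediators = spec.mediators
        out = np.empty(self.n_draws)
        for lo in range(0, self.n_draws, chunk):
            sl = slice(lo, min(lo + chunk, self.n_draws))
            eta0 = (
                self.eta_cov[:, sl] + self.out_arm[sl][None, :] * float(a_direct)
            )  # (n, c)
            if spec.method == "gauss_hermite":
                m = mediators[0]
                mu = self.mu0[m][:, sl] + self.arm_shift[m][sl][None, :] * float(a_mediator)
                sigma = self.sigma[m][sl]
                b = self.b[sl, 0]
                p = np.zeros_like(eta0)
                for x_k, w_k in zip(self.gh_nodes, self.gh_weights):
                    p += w_k * expit(eta0 + b[None, :] * (mu + sigma[None, :] * x_k))
                out[sl] = p.mean(axis=0)
            else:
                eta = eta0[:, None, :]  # (n, 1, c)
                acc = np.zeros((self.n_rows, spec.size, sl.stop - sl.start))
                acc += eta
                for j, m in enumerate(mediators):
                    mu = (
                        self.mu0[m][:, sl]
                        + self.arm_shift[m][sl][None, :] * float(a_mediator)
                    )
                    z = mu[:, None, :] + self.sigma[m][sl][None, None, :] * self.eps[
                        :, :, j, None
                    ]
                    acc += self.b[sl, j][None, None, :] * z
                out[sl] = expit(acc).mean(axis=(0, 1))
        return out


def counterfactual_risk(
    outcome_fit: ModelFit,
    mediator_fits: dict[str, ModelFit],
    data: pd.DataFrame,
    a_direct: int,
    a_mediator: int,
    spec: MediationSpec | None = None,
    n_draws: int = 1000,
    seed=None,
) -> np.ndarray:
    """Marginal counterfactual probability p[a_direct, M(a_mediator)] per draw."""
    if spec is None:
        spec = MediationSpec(mediators=tuple(mediator_fits))
    engine = _CounterfactualEngine(outcome_fit, mediator_fits, data, spec, n_draws, seed)
    return engine.marginal_probability(a_direct, a_mediator)


def _odds(p):
    return p / (1.0 - p)


def natural_effects(
    mediator_fits: dict[str, ModelFit],
    outcome_fit: ModelFit,
    data: pd.DataFrame,
    spec: MediationSpec,
    n_draws: int = 1000,
    seed=None,
) -> MediationResult:
    """Natural direct/indirect/total effect ORs from fitted component models.

    All five odds-ratio families are derived per posterior draw from the
    same four marginal probabilities, so the exact decomposition identities
    hold draw by draw.  Summaries are direct percentiles of the OR draws.
    """
    engine = _CounterfactualEngine(outcome_fit, mediator_fits, data, spec, n_draws, seed)
    p = {
        (a, ap): engine.marginal_probability(a, ap)
        for a in (0, 1)
        for ap in (0, 1)
    }
    or_draws = {
        "nde_pure": _odds(p[1, 0]) / _odds(p[0, 0]),
        "nie_pure": _odds(p[0, 1]) / _odds(p[0, 0]),
        "nde_total": _odds(p[1, 1]) / _odds(p[0, 1]),
        "nie_total": _odds(p[1, 1]) / _odds(p[1, 0]),
        "te": _odds(p[1, 1]) / _odds(p[0, 0]),
    }
    for key, probs in p.items():
        or_draws[f"p{key[0]}{key[1]}"] = probs
    summaries = {
        k: summarize(or_draws[k], scale="odds_ratio")
        for k in ("nde_pure", "nie_pure", "nde_total", "nie_total", "te")
    }
    suffix = "pure" if spec.pairing == "pure" else "total"
    return MediationResult(
        spec=spec,
        nde=summaries[f"nde_{suffix}"],
        nie=summaries[f"nie_{suffix}"],
        te=summaries["te"],
        n_rows=engine.n_rows,
        or_draws=or_draws,
        summaries=summaries,
    )


def joint_natural_effects(
    mediator_fits: dict[str, ModelFit],
    outcome_fit: ModelFit,
    data: pd.DataFrame,
    spec: MediationSpec | None = None,
    n_draws: int = 1000,
    seed=None,
) -> MediationResult:
    """Joint-model natural effects: the NIE shifts the whole mediator vector
    from its control-arm law to its intervention-arm law simultaneously."""
    if spec is None:
        spec = MediationSpec(mediators=MEDIATORS)
    if set(spec.mediators) != set(mediator_fits):
        raise AlignmentError("joint spec mediators must match the supplied fits")
    return natural_effects(mediator_fits, outcome_fit, data, spec, n_draws, seed)


# ----------------------------------------------------------------------
# sklearn-style front end
# ----------------------------------------------------------------------

class NaturalEffects(BaseEstimator):
    """End-to-end mediation estimator for a participant-level dataset.

    ``fit`` selects the complete-case analysis rows, fits the mediator
    model(s) and the outcome model on those shared rows with shared
    standardisation transforms, and integrates them into natural-effect
    odds ratios.  Fitted attributes: ``nde_``, ``nie_``, ``te_``
    (:class:`EffectSummary`) and ``result_`` (:class:`MediationResult`).
    """

    def __init__(
        self,
        outcome="prolonged",
        outcome_interval=3,
        mediators=MEDIATORS,
        pairing="pure",
        method=None,
        size=None,
        n_integration_draws=1000,
        min_rows=25,
        check_diagnostics=True,
        sampler_params=None,
        random_state=None,
    ):
        self.outcome = outcome
        self.outcome_interval = outcome_interval
        self.mediators = mediators
        self.pairing = pairing
        self.method = method
        self.size = size
        self.n_integration_draws = n_integration_draws
        self.min_rows = min_rows
        self.check_diagnostics = check_diagnostics
        self.sampler_params = sampler_params
        self.random_state = random_state

    def fit(self, data: pd.DataFrame, y=None):
        spec = MediationSpec(
            outcome=self.outcome,
            outcome_interval=self.outcome_interval,
            mediators=tuple(self.mediators),
            pairing=self.pairing,
            method=self.method,
            size=self.size,
        )
        ss = np.random.SeedSequence(self.random_state)
        seeds = ss.generate_state(len(spec.mediators) + 2)
        sampler = dict(self.sampler_params or {})

        rows = mediation_available_rows(
            data, spec.outcome, spec.outcome_interval, spec.mediators
        )
        transforms: dict = {}
        mediator_fits = {}
        for i, m in enumerate(spec.mediators):
            mediator_fits[m] = fit_mediator_model(
                data,
                m,
                spec.mediator_interval,
                min_rows=self.min_rows,
                transforms=transforms,
                rows=rows,
                random_state=int(seeds[i]),
                **sampler,
            )
        outcome_fit = fit_outcome_model(
            data,
            spec.outcome,
            spec.outcome_interval,
            spec.mediators,
            min_rows=self.min_rows,
            transforms=transforms,
            rows=rows,
            random_state=int(seeds[-2]),
            **sampler,
        )
        if self.check_diagnostics:
            for name, fit in {**mediator_fits, "outcome": outcome_fit}.items():
                if fit.draws.diagnostics.get("flagged"):
                    raise ConvergenceError(
                        f"{name} model failed the convergence gate "
                        f"(rhat_max={fit.draws.diagnostics['rhat_max']:.4f})"
                    )
        self.mediator_fits_ = mediator_fits
        self.outcome_fit_ = outcome_fit
        self.rows_ = rows
        self.result_ = natural_effects(
            mediator_fits,
            outcome_fit,
            data,
            spec,
            n_draws=self.n_integration_draws,
            seed=int(seeds[-1]),
        )
        self.nde_ = self.result_.nde
        self.nie_ = self.result_.nie
        self.te_ = self.result_.te
        return self


# ----------------------------------------------------------------------
# reporting
# ----------------------------------------------------------------------

_TABLE_COLUMNS = [
    "outcome",
    "outcome_interval",
    "mediator_interval",
    "block",
    "effect",
    "estimate",
    "ci_low",
    "ci_high",
    "pr_gt_1",
    "n_rows",
]


def mediation_table(results, outcome=None) -> pd.DataFrame:
    """Trial-style mediation table: one NIE and one NDE row per mediator block.

    ``results`` is an iterable of :class:`MediationResult`.  An incomplete
    set still yields a (partial) table.
    """
    rows = []
    for res in results:
        if outcome is not None and res.spec.outcome != outcome:
            continue
        block = (
            "all_three" if set(res.spec.mediators) == set(MEDIATORS)
            else "+".join(res.spec.mediators)
        )
        for effect, summ in (("nie", res.nie), ("nde", res.nde), ("te", res.te)):
            rows.append(
                {
                    "outcome": res.spec.outcome,
                    "outcome_interval": res.spec.outcome_interval,
                    "mediator_interval": res.spec.mediator_interval,
                    "block": block,
                    "effect": effect,
                    "estimate": summ.estimate,
                    "ci_low": summ.ci_low,
                    "ci_high": summ.ci_high,
                    "pr_gt_1": summ.prob_direction,
                    "n_rows": res.n_rows,
                }
            )
    return pd.DataFrame(rows, columns=_TABLE_COLUMNS)
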