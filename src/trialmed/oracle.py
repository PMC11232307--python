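"""Brute-force counterfactual oracle for the synthetic generator.

Because the generator's true mediator and outcome models are known, the
natural direct/indirect/total effect odds ratios can be computed to Monte
Carlo precision by simulating both potential mediator vectors M(0) and M(1)
for a large synthetic population (with common random numbers) and averaging
the true outcome probabilities under the four compositions Y(a, M(a')).
This gives an independent ground truth against which the Bayesian
estimation pipeline is validated.

Terminology: with p[a, a'] the marginal probability of Y(a, M(a')),

* pure NDE  = odds(p[1,0]) / odds(p[0,0])   (mediators held at their control law)
* pure NIE  = odds(p[0,1]) / odds(p[0,0])   (mediator shift with treatment at control)
* total NDE = odds(p[1,1]) / odds(p[0,1])
* total NIE = odds(p[1,1]) / odds(p[1,0])
* TE        = odds(p[1,1]) / odds(p[0,0])

TE = total NDE x pure NIE = pure NDE x total NIE exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .config import MEDIATORS, PRIOR_MEDIATOR_INTERVAL, GeneratorConfig
from .errors import CalibrationError, ConfigurationError
from .simulate import covariate_design, generate_baseline, mediator_potential


def odds(p):
    p = np.asarray(p, dtype=float)
    return p / (1.0 - p)


@dataclass
class TrueEffects:
    """Ground-truth odds ratios with Monte Carlo standard errors."""

    or_nde: float  # pure NDE (paper pairing)
    or_nie: float  # pure NIE (paper pairing)
    or_te: float
    or_nde_total: float
    or_nie_total: float
    mc_se: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        for name in ("or_nde", "or_nie", "or_te", "or_nde_total", "or_nie_total"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


class CompositionEvaluator:
    """Row-level probabilities of the four compositions Y(a, M(a')).

    Simulates one synthetic population (baseline covariates + potential
    mediator values under both arms, common random numbers) once; outcome
    coefficients can then be re-evaluated cheaply, which makes calibration
    searches inexpensive.

    Mediators outside ``mediator_set`` follow the *direct* arm, i.e. they
    are treated as part of the non-mediated pathway.
    """

    def __init__(self, config, outcome, interval, mediator_set=None, n_mc=200_000, seed=0):
        if n_mc <= 0:
            raise ConfigurationError(f"n_mc must be positive, got {n_mc}")
        self.config = config
        self.key = f"{outcome}_{interval}"
        if self.key not in config.outcome_params:
            raise ConfigurationError(f"unknown outcome {self.key!r}")
        self.params = config.outcome_params[self.key]
        self.mediator_set = tuple(mediator_set) if mediator_set else MEDIATORS
        unknown = set(self.mediator_set) - set(MEDIATORS)
        if unknown:
            raise ConfigurationError(f"unknown mediators: {sorted(unknown)}")
        t_med = PRIOR_MEDIATOR_INTERVAL[interval]

        rng = np.random.default_rng(seed)
        df = generate_baseline(config.replace(n=int(n_mc)), rng)
        eps = rng.standard_normal((int(n_mc), len(MEDIATORS)))
        zeros = np.zeros(int(n_mc))
        ones = np.ones(int(n_mc))
        pot = {
            0: mediator_potential(df, config, t_med, zeros, eps),
            1: mediator_potential(df, config, t_med, ones, eps),
        }
        self.z = {
            a: {
                m: (pot[a][m] - config.mediator_baseline_mean[m])
                / config.mediator_baseline_sd[m]
                for m in MEDIATORS
            }
            for a in (0, 1)
        }
        cov = covariate_design(df, config)
        self.eta_cov = self.params.theta_0 + sum(
            coef * cov[c] for c, coef in self.params.covariate_coef.items()
        )
        self.n_mc = int(n_mc)

    def row_probs(self, a_direct, a_mediator, theta_A=None, b_scale=1.0):
        theta_A = self.params.theta_A if theta_A is None else theta_A
        eta = self.eta_cov + theta_A * float(a_direct)
        for m in MEDIATORS:
            src = a_mediator if m in self.mediator_set else a_direct
            coef = self.params.b[m] * (b_scale if m in self.mediator_set else 1.0)
            if coef != 0.0:
                eta = eta + coef * self.z[src][m]
        return expit(eta)

    def marginal_probs(self, theta_A=None, b_scale=1.0):
        return {
            (a, ap): float(self.row_probs(a, ap, theta_A, b_scale).mean())
            for a in (0, 1)
            for ap in (0, 1)
        }


def _effects_from_probs(p) -> dict[str, float]:
    return {
        "or_nde": float(odds(p[1, 0]) / odds(p[0, 0])),
        "or_nie": float(odds(p[0, 1]) / odds(p[0, 0])),
        "or_te": float(odds(p[1, 1]) / odds(p[0, 0])),
        "or_nde_total": float(odds(p[1, 1]) / odds(p[0, 1])),
        "or_nie_total": float(odds(p[1, 1]) / odds(p[1, 0])),
    }


def oracle_true_effects(
    config: GeneratorConfig,
    outcome: str = "prolonged",
    interval: int = 3,
    mediator_set=None,
    n_mc: int = 1_000_000,
    seed=0,
    n_batches: int = 20,
) -> TrueEffects:
    """Ground-truth NDE/NIE/TE odds ratios by brute-force simulation.

    Monte Carlo standard errors come from splitting the population into
    ``n_batches`` replicate batches.
    """
    ev = CompositionEvaluator(config, outcome, interval, mediator_set, n_mc, seed)
    rows = {(a, ap): ev.row_probs(a, ap) for a in (0, 1) for ap in (0, 1)}
    point = _effects_from_probs({k: v.mean() for k, v in rows.items()})

    bounds = np.linspace(0, ev.n_mc, n_batches + 1).astype(int)
    batch_effects = {name: [] for name in point}
    for i in range(n_batches):
        sl = slice(bounds[i], bounds[i + 1])
        eff = _effects_from_probs({k: v[sl].mean() for k, v in rows.items()})
        for name, val in eff.items():
            batch_effects[name].append(val)
    mc_se = {
        name: float(np.std(vals, ddof=1) / np.sqrt(n_batches))
        for name, vals in batch_effects.items()
    }
    return TrueEffects(**point, mc_se=mc_se)


# ----------------------------------------------------------------------
# calibration
# ----------------------------------------------------------------------

_QUANTITIES = ("or_nie", "or_nde", "or_te", "mediator_effect")


def realized_mediator_effect(
    config: GeneratorConfig, mediator: str, interval: int, n_mc: int = 200_000, seed=0
) -> float:
    """True standardised arm effect on a mediator after clipping.

    Difference in potential means divided by the pooled sd of the mixture of
    both potential distributions, i.e. the estimand targeted by a
    standardised-mediator regression on a 1:1 trial.
    """
    rng = np.random.default_rng(seed)
    df = generate_baseline(config.replace(n=int(n_mc)), rng)
    eps = rng.standard_normal((int(n_mc), len(MEDIATORS)))
    m0 = mediator_potential(df, config, interval, np.zeros(int(n_mc)), eps)[mediator]
    m1 = mediator_potential(df, config, interval, np.ones(int(n_mc)), eps)[mediator]
    pooled_sd = np.std(np.concatenate([m0, m1]), ddof=1)
    return float((m1.mean() - m0.mean()) / pooled_sd)


def _bracketed_root(g, target, x0, step, max_abs, tol, label):
    """Root of g(x) = target for monotone g, walking a geometrically growing
    bracket out from ``x0``."""
    from scipy.optimize import brentq

    f0 = g(x0) - target
    if abs(f0) < 1e-12:
        return float(x0)
    f_probe = g(x0 + step) - target
    if f0 * f_probe <= 0:
        lo, hi = x0, x0 + step
    else:
        slope = f_probe - f0
        if slope == 0:
            raise CalibrationError(f"{label}: quantity does not respond to the coefficient")
        d = abs(step) * np.sign(slope) * np.sign(-f0)
        x, fx = x0, f0
        while True:
            x_new = x + d
            if abs(x_new) > max_abs:
                raise CalibrationError(
                    f"target {target} for {label} unreachable within |x| <= {max_abs} "
                    f"(last bracket [{x:.4g}, {x_new:.4g}], g({x:.4g})={fx + target:.4g})"
                )
            f_new = g(x_new) - target
            if fx * f_new <= 0:
                lo, hi = x, x_new
                break
            x, fx, d = x_new, f_new, d * 2.0
    root = brentq(lambda v: g(v) - target, lo, hi, xtol=1e-7, rtol=8.9e-16)
    if abs(g(root) - target) > tol:
        raise CalibrationError(
            f"calibration of {label} converged to {g(root):.4g}, "
            f"outside tolerance {tol} of target {target}"
        )
    return float(root)


def calibrate_to_target(
    config: GeneratorConfig,
    quantity: str,
    target_value: float,
    tol: float = 0.01,
    *,
    outcome: str = "prolonged",
    interval: int = 3,
    mediator_set=None,
    mediator: str | None = None,
    n_mc: int = 400_000,
    seed=0,
) -> GeneratorConfig:
    """Adjust one generator coefficient so a true causal quantity hits a target.

    * ``or_nie``: scales the mediator->outcome coefficients of ``mediator_set``.
    * ``or_nde`` / ``or_te``: searches the direct effect ``theta_A``.
    * ``mediator_effect``: searches ``arm_effect[mediator][interval]`` so the
      *realised* (post-clipping) standardised arm effect hits the target.

    The search is a monotone bracketing root find evaluated on one fixed
    synthetic population (common random numbers), so it is deterministic
    given ``seed``.
    """
    if quantity not in _QUANTITIES:
        raise ConfigurationError(f"unsupported quantity {quantity!r}")

    if quantity == "mediator_effect":
        if mediator is None:
            raise ConfigurationError("mediator_effect calibration needs a mediator name")
        # here ``interval`` is the mediator measurement interval (1, 3 or 6)

        def g(a):
            new = _with_arm_effect(config, mediator, interval, a)
            return realized_mediator_effect(new, mediator, interval, n_mc, seed)

        root = _bracketed_root(
            g, target_value, 0.0, 0.5, 16.0, tol, f"arm effect on {mediator}@{interval}m"
        )
        return _with_arm_effect(config, mediator, interval, root)

    if target_value <= 0:
        raise ConfigurationError("odds-ratio targets must be positive")
    ev = CompositionEvaluator(config, outcome, interval, mediator_set, n_mc, seed)
    key = ev.key

    if quantity == "or_nie":
        base_b = {m: ev.params.b[m] for m in ev.mediator_set}
        if all(v == 0 for v in base_b.values()):
            raise ConfigurationError(
                "or_nie calibration scales existing b coefficients; "
                f"all are zero for {ev.mediator_set}"
            )

        def g(s):
            p = ev.marginal_probs(b_scale=s)
            return _effects_from_probs(p)["or_nie"]

        root = _bracketed_root(g, target_value, 0.0, 1.0, 64.0, tol, f"NIE({key})")
        new = config.copy()
        for m in ev.mediator_set:
            new.outcome_params[key].b[m] = base_b[m] * root
        return new

    # or_nde / or_te: search theta_A
    def g(theta):
        p = ev.marginal_probs(theta_A=theta)
        return _effects_from_probs(p)[quantity]

    root = _bracketed_root(
        g, target_value, ev.params.theta_A, 1.0, 12.0, tol, f"{quantity}({key})"
    )
    new = config.copy()
    new.outcome_params[key].theta_A = float(root)
    return new


def _with_arm_effect(config, mediator, interval, value) -> GeneratorConfig:
    new = config.copy()
    new.arm_effect[mediator][interval] = float(value)
    return new
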