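"""Configuration of the synthetic two-arm trial generator.

The generator emulates a 1:1 randomised controlled trial of a digital
smoking-cessation intervention: baseline covariates match the trial's
published baseline table, three self-rated mediators (importance, know-how,
confidence; 1-10 scales) are measured at baseline and 1/3/6 months, and two
binary abstinence outcomes (prolonged abstinence and 4-week point
prevalence) are observed at 3 and 6 months.  Attrition follows the
missing-at-random structure reported by the trial's attrition analyses:
older participants respond more, and at the 1-month follow-up higher
nicotine dependence predicts non-response in the intervention arm only.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import yaml
from numpy.polynomial.hermite_e import hermegauss
from scipy import optimize, stats

from .errors import ConfigurationError

MEDIATORS = ("importance", "knowhow", "confidence")
MEDIATOR_INTERVALS = (1, 3, 6)
OUTCOME_NAMES = ("prolonged", "pp")
OUTCOME_INTERVALS = (3, 6)
#: outcome column -> mediator interval that is causally prior to it
PRIOR_MEDIATOR_INTERVAL = {3: 1, 6: 3}

ARMS = ("intervention", "control")


@dataclass
class OutcomeParams:
    """True logistic model for one binary abstinence outcome.

    ``b`` holds log-odds coefficients per 1 SD of each mediator measured at
    the causally prior interval (1 month for 3-month outcomes, 3 months for
    6-month outcomes).  ``theta_0`` controls the control-arm abstinence
    rate; ``theta_A`` is the direct (non-mediated) log-odds effect of the
    intervention.
    """

    theta_0: float
    theta_A: float
    b: dict[str, float]
    covariate_coef: dict[str, float] = field(
        default_factory=lambda: {"sex": 0.0, "age_z": 0.1, "version": 0.1, "ftnd_z": -0.25}
    )


@dataclass
class ResponseParams:
    """True logistic response (non-attrition) models.

    One model per follow-up questionnaire: mediator questionnaires at
    1/3/6 months, outcome questionnaires at 3/6 months.  Each has
    arm-specific intercepts, a shared positive age slope, and (for the
    1-month mediator questionnaire only) a negative FTND slope in the
    intervention arm.
    """

    med_intercept: dict[int, dict[str, float]]
    out_intercept: dict[int, dict[str, float]]
    age_slope: float = 0.4
    ftnd_intervention_slope_1m: float = -0.35


@dataclass
class GeneratorConfig:
    """All true parameters of the synthetic-trial data-generating process."""

    n: int = 1012
    # --- baseline covariates ---
    prop_woman: float = 0.81
    age_mean: float = 45.4
    age_sd: float = 14.0
    age_min: float = 18.0
    ftnd_mean: float = 5.0
    ftnd_sd: float = 2.2
    surgery_frac: float = 0.062
    cigs_per_week_mean: float = 101.0
    cigs_per_week_sd: float = 46.2
    mediator_baseline_mean: dict[str, float] = field(
        default_factory=lambda: {"importance": 9.4, "knowhow": 5.5, "confidence": 6.2}
    )
    mediator_baseline_sd: dict[str, float] = field(
        default_factory=lambda: {"importance": 1.3, "knowhow": 2.6, "confidence": 2.5}
    )
    #: exchangeable correlation of the three latent baseline mediator scores
    baseline_mediator_corr: float = 0.3
    # --- mediator trajectories ---
    #: standardised treatment effect on each mediator at each interval
    arm_effect: dict[str, dict[int, float]] = field(
        default_factory=lambda: {
            "importance": {1: -0.04, 3: 0.13, 6: 0.10},
            "knowhow": {1: 0.55, 3: 0.47, 6: 0.47},
            "confidence": {1: 0.30, 3: 0.23, 6: 0.32},
        }
    )
    #: raw-scale carry-over of the (centred) baseline score
    rho: dict[str, float] = field(
        default_factory=lambda: {"importance": 0.5, "knowhow": 0.5, "confidence": 0.5}
    )
    mediator_covariate_coef: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "importance": {"sex": 0.0, "age_z": 0.0, "version": 0.0, "ftnd_z": 0.0},
            "knowhow": {"sex": 0.0, "age_z": 0.1, "version": 0.0, "ftnd_z": -0.1},
            "confidence": {"sex": 0.0, "age_z": 0.1, "version": 0.0, "ftnd_z": -0.1},
        }
    )
    #: correlation of mediator residuals within an interval (0 = independent)
    residual_corr: float = 0.0
    round_mediators: bool = False
    # --- outcomes ---
    outcome_params: dict[str, OutcomeParams] = field(
        default_factory=lambda: {
            "prolonged_3": OutcomeParams(
                theta_0=-1.35, theta_A=0.30,
                b={"importance": 0.30, "knowhow": 0.45, "confidence": 0.35},
            ),
            "prolonged_6": OutcomeParams(
                theta_0=-1.45, theta_A=0.45,
                b={"importance": 0.30, "knowhow": 0.40, "confidence": 0.30},
            ),
            "pp_3": OutcomeParams(
                theta_0=-1.60, theta_A=0.25,
                b={"importance": 0.25, "knowhow": 0.35, "confidence": 0.25},
            ),
            "pp_6": OutcomeParams(
                theta_0=-1.70, theta_A=0.10,
                b={"importance": 0.25, "knowhow": 0.35, "confidence": 0.25},
            ),
        }
    )
    # --- missingness ---
    response_params: ResponseParams | None = None
    # --- randomisation ---
    block_sizes: tuple[int, ...] = (2, 4)

    def __post_init__(self):
        if self.response_params is None:
            self.response_params = default_response_params(
                age_slope=0.4, ftnd_slope=-0.35
            )
        self.validate()

    # ------------------------------------------------------------------
    def validate(self) -> None:
        """Raise :class:`ConfigurationError` on invalid parameter values."""
        if self.n < 0:
            raise ConfigurationError(f"n must be >= 0, got {self.n}")
        for name, val in [
            ("age_sd", self.age_sd),
            ("ftnd_sd", self.ftnd_sd),
            ("cigs_per_week_sd", self.cigs_per_week_sd),
        ]:
            if val <= 0:
                raise ConfigurationError(f"{name} must be > 0, got {val}")
        for frac_name, frac in [
            ("prop_woman", self.prop_woman),
            ("surgery_frac", self.surgery_frac),
        ]:
            if not 0.0 <= frac <= 1.0:
                raise ConfigurationError(f"{frac_name} must be in [0, 1], got {frac}")
        for m in MEDIATORS:
            if self.mediator_baseline_sd[m] <= 0:
                raise ConfigurationError(f"baseline sd for {m} must be > 0")
        if not self.block_sizes:
            raise ConfigurationError("block_sizes must be non-empty")
        if any(b <= 0 or b % 2 for b in self.block_sizes):
            raise ConfigurationError(
                f"block sizes must be positive and even, got {self.block_sizes}"
            )
        if not -1.0 < self.residual_corr < 1.0:
            raise ConfigurationError("residual_corr must be in (-1, 1)")
        if not -1.0 < self.baseline_mediator_corr < 1.0:
            raise ConfigurationError("baseline_mediator_corr must be in (-1, 1)")

    # ------------------------------------------------------------------
    def mediator_residual_sd(self, mediator: str) -> float:
        """Residual sd keeping the marginal control-arm sd at its baseline value.

        The trajectory model is
        ``M_t = mean + rho * (M_0 - mean) + coef @ x + a_t * sd * A + eps``;
        the residual variance absorbs what carry-over and covariates do not
        explain of the configured marginal variance.
        """
        sd = self.mediator_baseline_sd[mediator]
        coefs = self.mediator_covariate_coef[mediator]
        # sex and version are Bernoulli; age_z/ftnd_z approximately unit variance
        cov_var = (
            coefs["age_z"] ** 2
            + coefs["ftnd_z"] ** 2
            + coefs["sex"] ** 2 * self.prop_woman * (1 - self.prop_woman)
            + coefs["version"] ** 2 * self.surgery_frac * (1 - self.surgery_frac)
        )
        resid_var = sd**2 * (1 - self.rho[mediator] ** 2) - cov_var
        if resid_var <= 0:
            raise ConfigurationError(
                f"carry-over/covariate variance for {mediator} exceeds its marginal variance"
            )
        return float(np.sqrt(resid_var))

    # ------------------------------------------------------------------
    def replace(self, **changes) -> "GeneratorConfig":
        return dataclasses.replace(self, **changes)

    def copy(self) -> "GeneratorConfig":
        d = dataclasses.asdict(self)
        return _config_from_dict(d)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path) -> None:
        d = self.to_dict()
        d["block_sizes"] = list(d["block_sizes"])
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path, encoding="utf-8") as fh:
            d = yaml.safe_load(fh)
        return _config_from_dict(d)


def _config_from_dict(d: dict) -> GeneratorConfig:
    d = dict(d)
    # sidecar files may carry run metadata (seed, missingness flag) on top of
    # the generator parameters; ignore anything that is not a config field
    known = {f.name for f in dataclasses.fields(GeneratorConfig)}
    d = {k: v for k, v in d.items() if k in known}
    d["block_sizes"] = tuple(d["block_sizes"])
    d["outcome_params"] = {
        k: OutcomeParams(**v) if isinstance(v, dict) else v
        for k, v in d["outcome_params"].items()
    }
    # YAML round-trips dict keys as they were written; interval keys may
    # come back as ints already, but normalise defensively.
    rp = d["response_params"]
    if isinstance(rp, dict):
        d["response_params"] = ResponseParams(
            med_intercept={int(k): dict(v) for k, v in rp["med_intercept"].items()},
            out_intercept={int(k): dict(v) for k, v in rp["out_intercept"].items()},
            age_slope=rp["age_slope"],
            ftnd_intervention_slope_1m=rp["ftnd_intervention_slope_1m"],
        )
    d["arm_effect"] = {m: {int(t): v for t, v in d["arm_effect"][m].items()} for m in d["arm_effect"]}
    return GeneratorConfig(**d)


# ----------------------------------------------------------------------
# calibration helpers used when building the default configuration
# ----------------------------------------------------------------------

def truncated_normal_parent_params(
    target_mean: float, target_sd: float, lower: float
) -> tuple[float, float]:
    """Parent (mu, sigma) of a left-truncated normal with given truncated moments.

    Truncating N(mu, sigma) at ``lower`` inflates the mean and shrinks the
    sd, so drawing from N(target_mean, target_sd) truncated at ``lower``
    would *not* reproduce the target summary statistics.  This solves the
    two-parameter inverse problem instead.
    """

    def moments(params):
        mu, log_sigma = params
        sigma = np.exp(log_sigma)
        a = (lower - mu) / sigma
        mean, var = stats.truncnorm.stats(a, np.inf, loc=mu, scale=sigma, moments="mv")
        return [mean - target_mean, np.sqrt(var) - target_sd]

    sol = optimize.fsolve(moments, [target_mean, np.log(target_sd)], full_output=False)
    mu, sigma = float(sol[0]), float(np.exp(sol[1]))
    return mu, sigma


def _marginal_response_rate(intercept, age_slope, ftnd_slope, n_nodes=40):
    """E[expit(intercept + age_slope*Z1 + ftnd_slope*Z2)] for iid standard normal Z."""
    x, w = hermegauss(n_nodes)
    w = w / w.sum()
    if ftnd_slope == 0.0:
        eta = intercept + age_slope * x
        return float(w @ (1.0 / (1.0 + np.exp(-eta))))
    eta = intercept + age_slope * x[:, None] + ftnd_slope * x[None, :]
    p = 1.0 / (1.0 + np.exp(-eta))
    return float(w @ p @ w)


def solve_response_intercept(target_rate, age_slope, ftnd_slope=0.0):
    """Intercept whose marginal response probability equals ``target_rate``."""
    if not 0.0 < target_rate < 1.0:
        raise ConfigurationError("target response rate must be in (0, 1)")
    return float(
        optimize.brentq(
            lambda b0: _marginal_response_rate(b0, age_slope, ftnd_slope) - target_rate,
            -15.0,
            15.0,
        )
    )


#: arm-specific mediator-questionnaire response rates reported by the trial
MEDIATOR_RESPONSE_RATES = {
    1: {"intervention": 0.40, "control": 0.61},
    3: {"intervention": 0.41, "control": 0.47},
    6: {"intervention": 0.36, "control": 0.42},
}
#: outcome follow-up used phone-call rescue, so response was higher; the trial
#: does not print these rates and they are free defaults.
OUTCOME_RESPONSE_RATES = {
    3: {"intervention": 0.70, "control": 0.70},
    6: {"intervention": 0.66, "control": 0.66},
}


def default_response_params(age_slope=0.4, ftnd_slope=-0.35) -> ResponseParams:
    """Response models calibrated to the reported follow-up rates.

    Intercepts are solved so each arm's *marginal* response probability
    matches its target despite the covariate slopes.
    """
    med = {}
    for t, rates in MEDIATOR_RESPONSE_RATES.items():
        med[t] = {}
        for arm, rate in rates.items():
            fslope = ftnd_slope if (t == 1 and arm == "intervention") else 0.0
            med[t][arm] = solve_response_intercept(rate, age_slope, fslope)
    out = {
        t: {arm: solve_response_intercept(r, age_slope) for arm, r in rates.items()}
        for t, rates in OUTCOME_RESPONSE_RATES.items()
    }
    return ResponseParams(
        med_intercept=med,
        out_intercept=out,
        age_slope=age_slope,
        ftnd_intervention_slope_1m=ftnd_slope,
    )


def default_config(n: int = 1012) -> GeneratorConfig:
    """Default study conditions: the calibrated synthetic counterpart of the trial."""
    return GeneratorConfig(n=n)
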