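"""End-to-end analysis runs: simulate/load -> mediator effects -> mediation
-> attrition -> total-effect comparison -> imputation sensitivity -> report.

A run is driven by a :class:`RunConfig`, writes every table under one output
directory, logs one line per stage (inputs, row counts, seeds), and is
deterministic given its master seed: per-stage seeds are spawned from it by
fixed offsets.  Completed stages are reused on rerun when their inputs are
unchanged (CSV plus matching stage manifest)."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import zlib

import numpy as np
import pandas as pd
import yaml

from .config import MEDIATOR_INTERVALS, MEDIATORS, GeneratorConfig, default_config
from .errors import ConvergenceError
from .glm import PosteriorDraws
from .impute import ChainedEquationsImputer, pool_posteriors
from .io import read_dataset, write_dataset
from .mediation import NaturalEffects, mediation_table
from .models import (
    fit_attrition_model,
    fit_mediator_model,
    fit_total_effect,
    mediation_available_rows,
    summarize,
)

log = logging.getLogger("trialmed")


@dataclass
class RunConfig:
    """Everything needed to reproduce an analysis run."""

    out_dir: str
    seed: int = 0
    data_path: str | None = None
    generator: GeneratorConfig | None = None
    outcomes: tuple[str, ...] = ("prolonged", "pp")
    outcome_intervals: tuple[int, ...] = (3, 6)
    pairing: str = "pure"
    single_mediator_blocks: bool = True
    sampler_params: dict = field(default_factory=dict)
    n_integration_draws: int = 1000
    attrition_intervals: tuple[int, ...] = MEDIATOR_INTERVALS
    impute: bool = True
    impute_m: int = 20
    impute_iters: int = 20
    allow_flagged: bool = False

    def __post_init__(self):
        if self.generator is None and self.data_path is None:
            self.generator = default_config()

    def to_yaml(self, path):
        d = dataclasses.asdict(self)
        if self.generator is not None:
            d["generator"] = self.generator.to_dict()
            d["generator"]["block_sizes"] = list(self.generator.block_sizes)
        for key in ("outcomes", "outcome_intervals", "attrition_intervals"):
            d[key] = list(d[key])
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            d = yaml.safe_load(fh)
        if d.get("generator") is not None:
            from .config import _config_from_dict

            d["generator"] = _config_from_dict(d["generator"])
        for key in ("outcomes", "outcome_intervals", "attrition_intervals"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def digest(self) -> str:
        d = dataclasses.asdict(self)
        d.pop("out_dir", None)
        return hashlib.sha256(json.dumps(d, sort_keys=True, default=str).encode()).hexdigest()[:16]


@dataclass
class RunReport:
    """All tables produced by one run, plus the manifest tying them together."""

    mediator_effects: pd.DataFrame
    mediation: pd.DataFrame
    attrition: pd.DataFrame
    total_effects: pd.DataFrame
    imputation: pd.DataFrame | None
    diagnostics: pd.DataFrame
    manifest: dict


def _stage_seed(master: int, offset) -> int:
    """Deterministic per-stage seed (process-independent: labels are hashed
    with crc32, never the salted built-in hash)."""
    if isinstance(offset, str):
        offset = zlib.crc32(offset.encode())
    return int(np.random.SeedSequence([master, int(offset)]).generate_state(1)[0] % (2**31))


class _Stages:
    """Stage runner with CSV-level caching keyed on the config digest."""

    def __init__(self, config: RunConfig):
        self.config = config
        self.out = Path(config.out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.digest = config.digest()
        self.diag_rows = []
        self.manifest = {"seed": config.seed, "digest": self.digest, "stages": {}}

    def cached(self, name):
        path = self.out / f"{name}.csv"
        meta = self.out / f"{name}.stage.yaml"
        if path.exists() and meta.exists():
            with open(meta, encoding="utf-8") as fh:
                stage_meta = yaml.safe_load(fh)
            if stage_meta.get("digest") == self.digest:
                log.info("stage %s: reusing cached output", name)
                return pd.read_csv(path)
        return None

    def store(self, name, df: pd.DataFrame, **meta):
        path = self.out / f"{name}.csv"
        df.to_csv(path, index=False)
        with open(self.out / f"{name}.stage.yaml", "w", encoding="utf-8") as fh:
            yaml.safe_dump({"digest": self.digest, **meta}, fh, sort_keys=True)
        self.manifest["stages"][name] = {"rows": len(df), **meta}
        return df

    def record_fit(self, stage, label, draws: PosteriorDraws):
        d = draws.diagnostics
        self.diag_rows.append(
            {
                "stage": stage,
                "model": label,
                "rhat_max": d.get("rhat_max"),
                "ess_min": d.get("ess_min"),
                "accept_rate": d.get("accept_rate"),
                "divergences": d.get("divergences", 0),
                "flagged": d.get("flagged", False),
                "n_obs": draws.n_obs,
            }
        )
        if d.get("flagged") and not self.config.allow_flagged:
            raise ConvergenceError(
                f"stage {stage}: fit {label} failed the diagnostics gate "
                f"(rhat_max={d.get('rhat_max'):.4f}); rerun with allow_flagged to override"
            )


def run(config: RunConfig) -> RunReport:
    """Execute the full analysis and write all tables under ``config.out_dir``."""
    st = _Stages(config)
    seed = config.seed
    sampler = dict(config.sampler_params)

    # -- stage: data ---------------------------------------------------
    data_file = st.out / "data.csv"
    if config.data_path is not None:
        data = read_dataset(config.data_path)
        log.info("stage data: loaded %d rows from %s", len(data), config.data_path)
    else:
        cached = data_file.exists() and st.cached("data_meta") is not None
        if cached:
            data = read_dataset(data_file)
        else:
            from .simulate import simulate_trial

            data = simulate_trial(config.generator, seed=_stage_seed(seed, 1))
            write_dataset(data, data_file)
            config.generator.to_yaml(st.out / "generator.yaml")
            st.store("data_meta", pd.DataFrame({"n": [len(data)]}))
        log.info("stage data: %d simulated rows", len(data))

    # -- stage: mediator effects (trial Table-3 style) ------------------
    med_table = st.cached("mediator_effects")
    if med_table is None:
        rows = []
        for m in MEDIATORS:
            for t in MEDIATOR_INTERVALS:
                fit = fit_mediator_model(
                    data, m, t, random_state=_stage_seed(seed, f"mediator:{m}:{t}"),
                    **sampler,
                )
                st.record_fit("mediator_effects", f"{m}_{t}", fit.draws)
                summ = summarize(fit.coef("arm"))
                rows.append(
                    {
                        "mediator": m,
                        "interval": t,
                        "estimate": summ.estimate,
                        "ci_low": summ.ci_low,
                        "ci_high": summ.ci_high,
                        "pr_gt_0": summ.prob_direction,
                        "n_rows": len(fit.rows),
                    }
                )
        med_table = st.store("mediator_effects", pd.DataFrame(rows))
    log.info("stage mediator_effects: %d rows", len(med_table))

    # -- stage: mediation ----------------------------------------------
    mediation_df = st.cached("mediation")
    if mediation_df is None:
        results = []
        blocks = [MEDIATORS]
        if config.single_mediator_blocks:
            blocks += [(m,) for m in MEDIATORS]
        for outcome in config.outcomes:
            for t_out in config.outcome_intervals:
                for block in blocks:
                    est = NaturalEffects(
                        outcome=outcome,
                        outcome_interval=t_out,
                        mediators=block,
                        pairing=config.pairing,
                        n_integration_draws=config.n_integration_draws,
                        check_diagnostics=False,
                        sampler_params=sampler,
                        random_state=_stage_seed(seed, f"mediation:{outcome}:{t_out}:{'+'.join(block)}"),
                    ).fit(data)
                    for m, f in est.mediator_fits_.items():
                        st.record_fit("mediation", f"{outcome}_{t_out}:{'+'.join(block)}:{m}", f.draws)
                    st.record_fit(
                        "mediation", f"{outcome}_{t_out}:{'+'.join(block)}:outcome",
                        est.outcome_fit_.draws,
                    )
                    results.append(est.result_)
        mediation_df = st.store("mediation", mediation_table(results))
    log.info("stage mediation: %d rows", len(mediation_df))

    # -- stage: attrition ----------------------------------------------
    attrition_df = st.cached("attrition")
    if attrition_df is None:
        rows = []
        for t in config.attrition_intervals:
            fit, arm_effects = fit_attrition_model(
                data, t, f"responded_med_{t}",
                random_state=_stage_seed(seed, 300 + t), **sampler,
            )
            st.record_fit("attrition", f"responded_med_{t}", fit.draws)
            for arm, effects in arm_effects.items():
                for cov, summ in effects.items():
                    rows.append(
                        {
                            "interval": t,
                            "arm": arm,
                            "covariate": cov,
                            "estimate": summ.estimate,
                            "ci_low": summ.ci_low,
                            "ci_high": summ.ci_high,
                            "pr_gt_0": summ.prob_direction,
                        }
                    )
        attrition_df = st.store("attrition", pd.DataFrame(rows))
    log.info("stage attrition: %d rows", len(attrition_df))

    # -- stage: total effects (full vs mediation-available) -------------
    total_df = st.cached("total_effects")
    if total_df is None:
        rows = []
        for outcome in config.outcomes:
            for t_out in config.outcome_intervals:
                for sample_name, rule in [
                    ("full", None),
                    (
                        "mediation_available",
                        lambda d, o=outcome, t=t_out: mediation_available_rows(d, o, t),
                    ),
                ]:
                    summ, fit = fit_total_effect(
                        data, outcome, t_out, subsample_rule=rule,
                        random_state=_stage_seed(seed, f"total:{outcome}:{t_out}:{sample_name}"),
                        **sampler,
                    )
                    st.record_fit("total_effects", f"{outcome}_{t_out}:{sample_name}", fit.draws)
                    rows.append(
                        {
                            "outcome": outcome,
                            "outcome_interval": t_out,
                            "sample": sample_name,
                            "or_estimate": summ.estimate,
                            "ci_low": summ.ci_low,
                            "ci_high": summ.ci_high,
                            "pr_gt_1": summ.prob_direction,
                            "n_rows": len(fit.rows),
                        }
                    )
        total_df = st.store("total_effects", pd.DataFrame(rows))
    log.info("stage total_effects: %d rows", len(total_df))

    # -- stage: imputation sensitivity ----------------------------------
    imputation_df = None
    if config.impute:
        imputation_df = st.cached("imputation")
        if imputation_df is None:
            imputer = ChainedEquationsImputer(
                m=config.impute_m, n_iter=config.impute_iters,
                random_state=_stage_seed(seed, 500),
            )
            imp = imputer.fit_transform(data)
            rows = []
            for outcome in config.outcomes:
                for t_out in config.outcome_intervals:
                    # compare on the conditional arm-coefficient scale, which
                    # is what draw-level pooling across imputations supports
                    _, cc_fit = fit_total_effect(
                        data, outcome, t_out,
                        random_state=_stage_seed(seed, 510), **sampler,
                    )
                    cc_summ = summarize(cc_fit.coef("arm"), transform="exp")
                    fits = []
                    for i, ds in enumerate(imp.datasets):
                        _, fit = fit_total_effect(
                            ds, outcome, t_out,
                            random_state=_stage_seed(seed, 520 + i), **sampler,
                        )
                        fits.append(fit.draws)
                    pooled = pool_posteriors(fits)
                    pooled_summ = summarize(
                        pooled.draws[:, pooled.names.index("arm")], transform="exp"
                    )
                    for name, summ in [
                        ("complete_case", cc_summ),
                        ("imputed_pooled", pooled_summ),
                    ]:
                        rows.append(
                            {
                                "outcome": outcome,
                                "outcome_interval": t_out,
                                "analysis": name,
                                "or_estimate": summ.estimate,
                                "ci_low": summ.ci_low,
                                "ci_high": summ.ci_high,
                            }
                        )
            imputation_df = st.store(
                "imputation", pd.DataFrame(rows), m=config.impute_m,
                iters=config.impute_iters,
            )
        log.info("stage imputation: %d rows", len(imputation_df))

    diagnostics = pd.DataFrame(st.diag_rows)
    diagnostics.to_csv(st.out / "diagnostics.csv", index=False)
    report = RunReport(
        mediator_effects=med_table,
        mediation=mediation_df,
        attrition=attrition_df,
        total_effects=total_df,
        imputation=imputation_df,
        diagnostics=diagnostics,
        manifest=st.manifest,
    )
    write_report(report, st.out)
    return report


def write_report(report: RunReport, out_dir) -> None:
    """Write the report tables plus a human-readable summary and manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.mediator_effects.to_csv(out / "mediator_effects.csv", index=False)
    report.mediation.to_csv(out / "mediation.csv", index=False)
    report.attrition.to_csv(out / "attrition.csv", index=False)
    report.total_effects.to_csv(out / "total_effects.csv", index=False)
    if report.imputation is not None:
        report.imputation.to_csv(out / "imputation.csv", index=False)
    with open(out / "manifest.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(report.manifest, fh, sort_keys=True)
    lines = ["trialmed run summary", "====================", ""]
    lines.append("Adjusted standardised treatment effects on mediators:")
    for _, r in report.mediator_effects.iterrows():
        lines.append(
            f"  {r.mediator:<11s} {int(r.interval)}m: {r.estimate:+.2f} "
            f"({r.ci_low:+.2f}; {r.ci_high:+.2f})  Pr(>0)={r.pr_gt_0:.1%}"
        )
    lines.append("")
    lines.append("Natural effects (odds ratios):")
    for _, r in report.mediation.iterrows():
        lines.append(
            f"  {r.outcome}@{int(r.outcome_interval)}m via {r.block} "
            f"[{int(r.mediator_interval)}m] {r.effect.upper():<3s}: {r.estimate:.2f} "
            f"({r.ci_low:.2f}; {r.ci_high:.2f})  Pr(OR>1)={r.pr_gt_1:.1%}"
        )
    with open(out / "summary.txt", "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")
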