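"""Reading, validating and writing participant-level trial datasets.

The on-disk format is a comma-separated text file with a header row, UTF-8,
missing values as empty fields.  Validation enforces the participant-record
invariants (ranges, category levels, and the "value present iff response
indicator is 1" consistency rule) and reports offending rows by number.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .config import MEDIATORS, MEDIATOR_INTERVALS, OUTCOME_INTERVALS
from .errors import DataValidationError

SCHEMA_COLUMNS = (
    ["id", "sex", "age", "version", "ftnd", "cigs_per_week"]
    + [f"{m}_0" for m in MEDIATORS]
    + ["group"]
    + [f"{m}_{t}" for t in MEDIATOR_INTERVALS for m in MEDIATORS]
    + [f"{o}_{t}" for t in OUTCOME_INTERVALS for o in ("prolonged", "pp")]
    + [f"responded_med_{t}" for t in MEDIATOR_INTERVALS]
    + [f"responded_out_{t}" for t in OUTCOME_INTERVALS]
)

_CATEGORY_LEVELS = {
    "sex": {"woman", "man"},
    "version": {"general", "surgery"},
    "group": {"intervention", "control"},
}

_MAX_REPORTED = 20


def _rows_str(mask) -> str:
    rows = list(np.flatnonzero(np.asarray(mask)))
    head = ", ".join(str(r) for r in rows[:5])
    more = f" (+{len(rows) - 5} more)" if len(rows) > 5 else ""
    return head + more


def validate_dataset(df: pd.DataFrame) -> None:
    """Raise :class:`DataValidationError` listing every schema violation."""
    problems = []
    missing_cols = [c for c in SCHEMA_COLUMNS if c not in df.columns]
    if missing_cols:
        raise DataValidationError([f"missing columns: {missing_cols}"])

    for col, levels in _CATEGORY_LEVELS.items():
        bad = ~df[col].isin(levels)
        if bad.any():
            problems.append(f"{col} outside {sorted(levels)} at rows {_rows_str(bad)}")

    for col, lo, hi in [("age", 18.0, np.inf), ("cigs_per_week", 1.0, np.inf), ("ftnd", 0, 10)]:
        vals = df[col]
        bad = vals.isna() | (vals < lo) | (vals > hi)
        if bad.any():
            problems.append(f"{col} outside [{lo}, {hi}] or missing at rows {_rows_str(bad)}")

    med_cols = [f"{m}_0" for m in MEDIATORS] + [
        f"{m}_{t}" for t in MEDIATOR_INTERVALS for m in MEDIATORS
    ]
    for col in med_cols:
        vals = df[col]
        bad = vals.notna() & ((vals < 1.0) | (vals > 10.0))
        if bad.any():
            problems.append(f"{col} outside [1, 10] at rows {_rows_str(bad)}")
        if col.endswith("_0") and vals.isna().any():
            problems.append(f"baseline {col} missing at rows {_rows_str(vals.isna())}")

    binary_cols = [f"{o}_{t}" for t in OUTCOME_INTERVALS for o in ("prolonged", "pp")]
    for col in binary_cols:
        vals = df[col]
        bad = vals.notna() & ~vals.isin([0.0, 1.0])
        if bad.any():
            problems.append(f"{col} must be 0/1 at rows {_rows_str(bad)}")

    for t in MEDIATOR_INTERVALS:
        resp = df[f"responded_med_{t}"]
        bad_resp = ~resp.isin([0, 1])
        if bad_resp.any():
            problems.append(f"responded_med_{t} must be 0/1 at rows {_rows_str(bad_resp)}")
        for m in MEDIATORS:
            col = f"{m}_{t}"
            mism = (df[col].notna() & (resp == 0)) | (df[col].isna() & (resp == 1))
            if mism.any():
                problems.append(
                    f"{col} presence inconsistent with responded_med_{t} "
                    f"at rows {_rows_str(mism)}"
                )
    for t in OUTCOME_INTERVALS:
        resp = df[f"responded_out_{t}"]
        bad_resp = ~resp.isin([0, 1])
        if bad_resp.any():
            problems.append(f"responded_out_{t} must be 0/1 at rows {_rows_str(bad_resp)}")
        for o in ("prolonged", "pp"):
            col = f"{o}_{t}"
            mism = (df[col].notna() & (resp == 0)) | (df[col].isna() & (resp == 1))
            if mism.any():
                problems.append(
                    f"{col} presence inconsistent with responded_out_{t} "
                    f"at rows {_rows_str(mism)}"
                )

    if problems:
        raise DataValidationError(problems[:_MAX_REPORTED])


def write_dataset(df: pd.DataFrame, path) -> None:
    """Write a participant dataset as CSV (missing values as empty fields)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, columns=[c for c in SCHEMA_COLUMNS if c in df.columns])


def read_dataset(path, validate: bool = True) -> pd.DataFrame:
    """Read and (by default) validate a participant dataset."""
    df = pd.read_csv(path, dtype={"id": str, "sex": str, "version": str, "group": str})
    if validate:
        validate_dataset(df)
    return df


# ----------------------------------------------------------------------
# fit artifacts
# ----------------------------------------------------------------------

def save_fit(fit, out_dir) -> None:
    """Serialise a :class:`~trialmed.models.ModelFit` as a directory:
    coefficient draws as CSV plus a YAML manifest (terms, transforms,
    diagnostics, rows used)."""
    import yaml

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    draws = pd.DataFrame(fit.draws.draws, columns=fit.draws.names)
    for name, arr in fit.draws.aux.items():
        draws[f"aux_{name}"] = arr
    draws.to_csv(out_dir / "draws.csv", index=False)
    pd.Series(list(fit.rows)).to_csv(out_dir / "rows.csv", index=False, header=["row"])
    manifest = {
        "response": fit.response,
        "terms": list(fit.terms),
        "transforms": {k: [float(v[0]), float(v[1])] for k, v in fit.transforms.items()},
        "n_obs": int(fit.draws.n_obs),
        "diagnostics": {
            k: (float(v) if isinstance(v, (int, float, np.floating)) else v)
            for k, v in fit.draws.diagnostics.items()
            if not isinstance(v, dict)
        },
    }
    with open(out_dir / "manifest.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
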