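"""Waveform estimation error metrics and condition summaries.

Accuracy is quantified per subject, condition and output variable by the
normalized root-mean-square error (NRMSE, percent): the RMSE between the
estimated and actual 101-point waveform divided by the peak-to-peak range
of the actual waveform.  For each subject and variable, every condition's
NRMSE is also expressed as a ratio to the same subject's NRMSE under
perfect alignment (ZERO), so the ZERO-condition ratio is exactly 1 with
zero spread across subjects.  Ratios are computed per subject before any
averaging.

Normalization by the ACTUAL waveform's range is the default (the
dominant convention); normalizing by the estimate's range is available
for sensitivity checks.  Summary SDs use the n-1 (sample) denominator.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import layout
from .estimator import LOOCVResult

__all__ = [
    "nrmse",
    "evaluate_loocv",
    "ratio_to_zero",
    "summarize",
    "write_report",
]

ZERO_LABEL = "ZERO"


def nrmse(actual: np.ndarray, estimated: np.ndarray,
          normalize_by: str = "actual") -> float:
    """NRMSE between two 101-point waveforms, in percent.

    Returns NaN when the normalizing waveform has zero peak-to-peak range
    (the error is undefined there); callers flag and exclude such records.
    """
    actual = np.asarray(actual, dtype=float)
    estimated = np.asarray(estimated, dtype=float)
    if actual.shape != estimated.shape:
        raise ValueError("waveforms must have equal shapes")
    if normalize_by not in ("actual", "estimated"):
        raise ValueError("normalize_by must be 'actual' or 'estimated'")
    ref = actual if normalize_by == "actual" else estimated
    rng = float(ref.max() - ref.min())
    if rng <= 0.0:
        return float("nan")
    rmse = float(np.sqrt(np.mean((estimated - actual) ** 2)))
    return 100.0 * rmse / rng


def evaluate_loocv(result: LOOCVResult, normalize_by: str = "actual") -> pd.DataFrame:
    """Long-format NRMSE records: one row per subject x condition x variable.

    Columns: subject_id, condition, variable, nrmse, ratio_to_zero,
    undefined (True where the NRMSE or its ZERO reference is undefined).
    """
    n = len(result.subject_ids)
    labels = [c.label for c in result.conditions]
    if ZERO_LABEL not in labels:
        raise ValueError("LOOCV result lacks a ZERO condition")

    actual = result.actual.reshape(n, layout.N_OUTPUT_VARIABLES, layout.N_POINTS)
    records = []
    for label in labels:
        est = result.predictions[label].reshape(
            n, layout.N_OUTPUT_VARIABLES, layout.N_POINTS
        )
        for s in range(n):
            for v, variable in enumerate(layout.OUTPUT_VARIABLES):
                records.append(
                    (result.subject_ids[s], label, variable,
                     nrmse(actual[s, v], est[s, v], normalize_by))
                )
    df = pd.DataFrame(records,
                      columns=["subject_id", "condition", "variable", "nrmse"])
    return ratio_to_zero(df)


def ratio_to_zero(records: pd.DataFrame) -> pd.DataFrame:
    """Attach per-subject ratios of each condition's NRMSE to ZERO's.

    The ratio is computed within each (subject, variable) pair before any
    averaging.  Records with an undefined NRMSE, or whose ZERO reference
    is undefined or zero, are flagged ``undefined`` and carry a NaN ratio.
    """
    df = records.copy()
    zero = (
        df[df["condition"] == ZERO_LABEL]
        .set_index(["subject_id", "variable"])["nrmse"]
    )
    if zero.empty:
        raise ValueError("no ZERO-condition records present")
    ref = df.set_index(["subject_id", "variable"]).index.map(zero)
    ref = np.asarray(ref, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = df["nrmse"].to_numpy(float) / ref
    df["ratio_to_zero"] = ratio
    df["undefined"] = (
        ~np.isfinite(df["nrmse"].to_numpy(float)) | ~np.isfinite(ratio)
    )
    # exact unity for ZERO rows (guards against 0/0 and rounding)
    is_zero = (df["condition"] == ZERO_LABEL).to_numpy()
    ok = is_zero & ~df["undefined"].to_numpy()
    df.loc[ok, "ratio_to_zero"] = 1.0
    return df


def summarize(records: pd.DataFrame) -> pd.DataFrame:
    """Mean and sample SD of NRMSE and ratio per variable x condition.

    Undefined records are excluded (their count is reported in the
    ``n_undefined`` column).  With fewer than two subjects the SDs are NaN.
    """
    df = records[~records["undefined"]] if "undefined" in records else records
    grouped = df.groupby(["variable", "condition"], sort=False)
    out = grouped.agg(
        nrmse_mean=("nrmse", "mean"),
        nrmse_sd=("nrmse", lambda x: x.std(ddof=1)),
        ratio_mean=("ratio_to_zero", "mean"),
        ratio_sd=("ratio_to_zero", lambda x: x.std(ddof=1)),
        n_subjects=("nrmse", "size"),
    ).reset_index()
    if "undefined" in records:
        n_undef = (
            records[records["undefined"]]
            .groupby(["variable", "condition"], sort=False)
            .size()
        )
        out["n_undefined"] = [
            int(n_undef.get((v, c), 0))
            for v, c in zip(out["variable"], out["condition"])
        ]
    else:
        out["n_undefined"] = 0
    return out


def _wide_table(summary: pd.DataFrame, variables, conditions) -> pd.DataFrame:
    """Rows = variables; column pairs = condition mean/SD for NRMSE and ratio."""
    sub = summary.set_index(["variable", "condition"])
    rows = []
    for variable in variables:
        row: dict[str, float | str] = {"variable": variable}
        for cond in conditions:
            cell = sub.loc[(variable, cond)]
            row[f"{cond}_nrmse_mean"] = cell["nrmse_mean"]
            row[f"{cond}_nrmse_sd"] = cell["nrmse_sd"]
            row[f"{cond}_ratio_mean"] = cell["ratio_mean"]
            row[f"{cond}_ratio_sd"] = cell["ratio_sd"]
        rows.append(row)
    return pd.DataFrame(rows)


def write_report(
    summary: pd.DataFrame,
    directory,
    conditions: list[str] | None = None,
    manifest: dict | None = None,
    float_format: str = "%.6g",
) -> dict[str, Path]:
    """Write angle and moment summary tables plus a run manifest.

    ``angles.csv`` has 12 variable rows, ``moments.csv`` 9; each has one
    mean/SD column pair per condition for both NRMSE and ratio.  The
    manifest records the configuration and per-fold diagnostics supplied
    by the caller.  Identical inputs produce byte-identical files.
    """
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    if conditions is None:
        conditions = list(dict.fromkeys(summary["condition"]))
    paths = {}
    for name, variables in (
        ("angles", layout.ANGLE_VARIABLES),
        ("moments", layout.MOMENT_VARIABLES),
    ):
        table = _wide_table(summary, variables, conditions)
        path = d / f"{name}.csv"
        table.to_csv(path, index=False, float_format=float_format)
        paths[name] = path
    mpath = d / "manifest.json"
    mpath.write_text(json.dumps(manifest or {}, indent=2, sort_keys=True))
    paths["manifest"] = mpath
    return paths
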