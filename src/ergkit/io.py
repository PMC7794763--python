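"""Delimited-text I/O for ERG data.

Three table kinds are handled, all as plain-text and all validated on read:

* **sweep tables** — long-format CSV of raw stimulus-locked voltage traces,
  one row per sample: ``animal_id, eye, luminance_log, trial, time_ms,
  voltage_uV``.  Time zero is stimulus onset; pretrial samples carry
  negative ``time_ms``, which makes the pretrial-baseline window a pure
  time query.
* **feature tables** — one row per (animal, eye, luminance) holding the
  extracted waveform features (a-/b-wave amplitude and implicit time, OP1–OP4
  implicit times and amplitudes) plus provenance columns.  Written as TSV
  with a fixed column order, 6-significant-digit formatting and a
  deterministic row sort so repeated writes are byte-identical.
* **summary tables** — printed per-group summary statistics (mean, SEM, n)
  for factorial re-analysis, as CSV.

Missing values (e.g. an OP that was not detected) are encoded as *empty*
fields, never 0, so downstream statistics can drop them.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd


class ValidationError(ValueError):
    """A table failed schema or invariant validation."""


class MissingColumnError(ValidationError):
    pass


class NonMonotoneTimeError(ValidationError):
    """Time samples are not strictly increasing within a trial."""


class NonUniformSamplingError(ValidationError):
    """Sampling interval varies within a trial beyond tolerance."""


class MissingPretrialError(ValidationError):
    """A trial has no samples before stimulus onset (time_ms < 0)."""


class IncompleteCrossingError(ValidationError):
    """A factorial analysis was requested on an incomplete factor crossing."""


#: required sweep CSV columns
SWEEP_COLUMNS = ["animal_id", "eye", "luminance_log", "trial", "time_ms", "voltage_uV"]

#: fixed feature-TSV column order
FEATURE_COLUMNS = [
    "animal_id",
    "eye",
    "luminance_log",
    "baseline_uV",
    "a_amp_uV",
    "a_implicit_ms",
    "b_amp_uV",
    "b_implicit_ms",
    "op1_implicit_ms",
    "op2_implicit_ms",
    "op3_implicit_ms",
    "op4_implicit_ms",
    "op1_amp_uV",
    "op2_amp_uV",
    "op3_amp_uV",
    "op4_amp_uV",
    "n_trials",
    "filter_cutoff_hz",
    "filter_order",
    "a_fallback",
]

SUMMARY_COLUMNS = ["variable", "units", "factor_a", "factor_b", "mean", "sem", "n"]

#: tolerance on sampling-interval jitter, in ms
SAMPLING_TOLERANCE_MS = 1e-9

VALID_EYES = {"left", "right"}

_TRIAL_KEY = ["animal_id", "eye", "luminance_log", "trial"]


def validate_sweeps(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a sweep table in memory; returns the (unmodified) frame.

    Raises a named :class:`ValidationError` subclass on the first violated
    invariant: missing column, unknown eye label, non-monotone time,
    non-uniform sampling, or absent pretrial window.
    """
    missing = [c for c in SWEEP_COLUMNS if c not in df.columns]
    if missing:
        raise MissingColumnError(f"missing column(s): {', '.join(missing)}")
    bad_eyes = set(df["eye"].unique()) - VALID_EYES
    if bad_eyes:
        raise ValidationError(f"unknown eye label(s): {sorted(bad_eyes)}")
    if (df["trial"] < 1).any():
        raise ValidationError("trial indices must be >= 1")
    for key, g in df.groupby(_TRIAL_KEY, sort=False):
        t = g["time_ms"].to_numpy(float)
        dt = np.diff(t)
        if len(t) < 2 or (dt <= 0).any():
            raise NonMonotoneTimeError(f"non-monotone time in trial {key}")
        if dt.max() - dt.min() > SAMPLING_TOLERANCE_MS:
            raise NonUniformSamplingError(f"non-uniform sampling in trial {key}")
        if t[0] >= 0:
            raise MissingPretrialError(f"no pretrial window (time_ms < 0) in trial {key}")
    return df


def read_sweeps(path: str | Path, dialect: dict | None = None) -> pd.DataFrame:
    """Read and validate a long-format sweep CSV.

    ``dialect`` may carry ``{"delimiter": ...}``; parsing is column-order
    independent and locale-independent (decimal point only).
    """
    delimiter = (dialect or {}).get("delimiter", ",")
    df = pd.read_csv(path, sep=delimiter)
    df = validate_sweeps(df)
    return df[SWEEP_COLUMNS].copy()


def _format_cell(value, col: str) -> str:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return ""  # missing, never 0
    if col in ("animal_id", "eye"):
        return str(value)
    if col in ("n_trials", "filter_order", "a_fallback"):
        return str(int(value))
    return f"{float(value):.6g}"


def write_features(features: pd.DataFrame, path: str | Path) -> None:
    """Write a feature table as deterministic TSV.

    Fixed column order, 6-significant-digit floats, rows sorted by
    (animal_id, eye, luminance_log); two writes of equal tables are
    byte-identical.  Missing features become empty cells.
    """
    missing = [c for c in FEATURE_COLUMNS if c not in features.columns]
    if missing:
        raise MissingColumnError(f"feature table missing column(s): {', '.join(missing)}")
    df = features.sort_values(["animal_id", "eye", "luminance_log"], kind="mergesort")
    lines = ["\t".join(FEATURE_COLUMNS)]
    for _, row in df.iterrows():
        lines.append("\t".join(_format_cell(row[c], c) for c in FEATURE_COLUMNS))
    Path(path).write_text("\n".join(lines) + "\n")


def read_features(path: str | Path) -> pd.DataFrame:
    """Read a feature TSV written by :func:`write_features`."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in FEATURE_COLUMNS if c not in df.columns]
    if missing:
        raise MissingColumnError(f"feature table missing column(s): {', '.join(missing)}")
    return df[FEATURE_COLUMNS]


def validate_summary(df: pd.DataFrame, require_crossing: bool = False) -> pd.DataFrame:
    missing = [c for c in ("factor_a", "factor_b", "mean", "sem", "n") if c not in df.columns]
    if missing:
        raise MissingColumnError(f"summary table missing column(s): {', '.join(missing)}")
    if (df["n"] < 2).any():
        raise ValidationError("summary n must be >= 2 in every cell")
    if (df["n"] != df["n"].astype(int)).any():
        raise ValidationError("summary n must be integer")
    if (df["sem"] <= 0).any():
        raise ValidationError("summary sem must be > 0")
    if require_crossing:
        for var, g in (
            df.groupby("variable", sort=False) if "variable" in df.columns else [(None, df)]
        ):
            a_levels = sorted(g["factor_a"].unique())
            b_levels = sorted(g["factor_b"].unique())
            cells = set(zip(g["factor_a"], g["factor_b"]))
            wanted = {(a, b) for a in a_levels for b in b_levels}
            if cells != wanted or len(g) != len(wanted):
                raise IncompleteCrossingError(
                    f"incomplete factor crossing{'' if var is None else f' for {var!r}'}"
                )
    return df


def read_summary(path: str | Path, require_crossing: bool = False) -> pd.DataFrame:
    """Read a printed-summary CSV (mean, SEM, n per factor cell).

    With ``require_crossing=True`` the table must contain every combination
    of the two factor levels exactly once (per variable), as a factorial
    ANOVA needs.
    """
    df = pd.read_csv(path)
    return validate_summary(df, require_crossing=require_crossing)
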