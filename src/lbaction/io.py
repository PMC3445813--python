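"""Trial-table readers/writers and run manifests.

Trial tables are TSV with columns ``trial_index, onset_s, trial_type,
condition, valid_actions, previous_action, response, rt_s,
first_action_trial``.  Times are seconds; a ``rt_ms`` column is accepted
and converted on ingest.  Omissions carry an empty response and RT; null
events an empty condition and valid-action set.  Action ids are 0-3 and
valid sets serialise as comma-joined ids (e.g. ``0,2,3``).
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import TRIAL_COLUMNS, parse_actions
from . import __version__ as _pkg_version

logger = logging.getLogger("lbaction")

__all__ = ["read_trial_table", "write_trial_table", "write_manifest", "sha256_of"]

REQUIRED_COLUMNS = [
    "trial_type",
    "condition",
    "valid_actions",
    "previous_action",
    "response",
    "rt_s",
]


def write_trial_table(trials: pd.DataFrame, path) -> None:
    """Write a trial table as TSV at fixed precision (lossless round-trip
    at 6 decimal places)."""
    out = trials.copy()
    if "first_action_trial" in out.columns:
        out["first_action_trial"] = out["first_action_trial"].astype(int)
    out.to_csv(path, sep="\t", index=False, float_format="%.6f", na_rep="")


def read_trial_table(path) -> pd.DataFrame:
    """Read and validate a trial table.

    Unknown columns are tolerated with a warning; missing required columns
    are fatal.  Rows whose response lies outside the valid-action set are
    flagged in a ``commission_error`` column (the fitter excludes them)
    and their count logged.  Schema violations are reported with row
    numbers.
    """
    # keep_default_na=False: "null" is a real trial-type token, not NaN
    df = pd.read_csv(
        path,
        sep="\t",
        dtype=str,
        keep_default_na=False,
        na_values=[""],
    )
    for col in ("trial_index", "onset_s", "rt_ms", "rt_s", "first_action_trial"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    if "rt_ms" in df.columns and "rt_s" not in df.columns:
        df["rt_s"] = df["rt_ms"].astype(float) / 1000.0
        df = df.drop(columns=["rt_ms"])
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    known = set(TRIAL_COLUMNS) | {"commission_error"}
    unknown = [c for c in df.columns if c not in known]
    if unknown:
        warnings.warn(f"{path}: ignoring unknown columns {unknown}", stacklevel=2)
    if "trial_index" not in df.columns:
        df["trial_index"] = np.arange(len(df))
    if "onset_s" not in df.columns:
        df["onset_s"] = np.nan
    if "first_action_trial" not in df.columns:
        df["first_action_trial"] = False
    df["first_action_trial"] = df["first_action_trial"].fillna(0).astype(bool)
    df["condition"] = df["condition"].fillna("")
    df["valid_actions"] = df["valid_actions"].fillna("")
    for col in ("previous_action", "response"):
        df[col] = pd.array(
            pd.to_numeric(df[col], errors="coerce").round(), dtype="Int64"
        )
    df["rt_s"] = pd.to_numeric(df["rt_s"], errors="coerce")

    bad_type = df.index[~df["trial_type"].isin(["choice", "specified", "null"])]
    if len(bad_type):
        raise ValueError(
            f"{path}: invalid trial_type at rows {list(bad_type[:10])}"
        )
    action = df["trial_type"] != "null"
    bad_cond = df.index[action & (df["condition"] == "")]
    if len(bad_cond):
        raise ValueError(f"{path}: action trials without condition at rows {list(bad_cond[:10])}")

    commission = np.zeros(len(df), dtype=bool)
    for i in df.index[action & df["response"].notna()]:
        if int(df.at[i, "response"]) not in parse_actions(df.at[i, "valid_actions"]):
            commission[i] = True
    df["commission_error"] = commission
    if commission.any():
        logger.info("%s: %d commission-error trials flagged", path, int(commission.sum()))
        # the fitter drops them; keep rows so counts remain auditable
        df.loc[commission, "response"] = pd.NA
        df.loc[commission, "rt_s"] = np.nan
    df["condition"] = df["condition"].replace("", np.nan)
    return df


def sha256_of(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(out_dir, config: dict, seeds: dict, inputs: list | None = None) -> Path:
    """Write a reproducibility manifest (config, seeds, package version and
    input checksums) alongside a run's outputs."""
    out_dir = Path(out_dir)
    manifest = {
        "package": "lbaction",
        "version": _pkg_version,
        "config": config,
        "seeds": seeds,
        "inputs": {str(p): sha256_of(p) for p in (inputs or [])},
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return path
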