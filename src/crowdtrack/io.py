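"""Readers and writers for the three CSV schemas and run manifests.

All files are comma-separated UTF-8 with a mandatory header row and '.'
decimals.  POSIX timestamps are decimal seconds.  Empty fields mark
absent positions (crosshair/cursor hidden during the stimulus, target
absent outside it).

* frame log  -- ``t_posix, crosshairX_px, crosshairY_px, cursorX_px,
  cursorY_px, targetX_px, targetY_px, bold, epoch`` (one row per 60 Hz
  display frame),
* gaze log   -- ``t_posix, gazeX_px, gazeY_px`` (one row per 10 ms
  tracker sample),
* threshold table -- ``observer, method, meridian, session,
  threshold_deg`` plus optional ``log10_threshold, posterior_sd``.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "FRAME_COLUMNS",
    "GAZE_COLUMNS",
    "THRESHOLD_COLUMNS",
    "read_frame_log",
    "write_frame_log",
    "read_gaze_log",
    "write_gaze_log",
    "read_threshold_table",
    "write_threshold_table",
    "write_manifest",
]

logger = logging.getLogger(__name__)

FRAME_COLUMNS = [
    "t_posix",
    "crosshairX_px",
    "crosshairY_px",
    "cursorX_px",
    "cursorY_px",
    "targetX_px",
    "targetY_px",
    "bold",
    "epoch",
]
GAZE_COLUMNS = ["t_posix", "gazeX_px", "gazeY_px"]
THRESHOLD_COLUMNS = ["observer", "method", "meridian", "session", "threshold_deg"]

#: nominal tracker sampling interval and accepted slack
NOMINAL_GAZE_DT_S = 0.010
GAZE_DT_SLACK = 0.20


def _require_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")


def write_frame_log(frames: pd.DataFrame, path) -> None:
    frames[FRAME_COLUMNS].to_csv(path, index=False)


def read_frame_log(path) -> pd.DataFrame:
    """Typed frame log; validates the schema and timestamp monotonicity."""
    df = pd.read_csv(path)
    _require_columns(df, FRAME_COLUMNS, path)
    t = df["t_posix"].to_numpy(dtype=float)
    if np.isnan(t).any():
        line = int(np.flatnonzero(np.isnan(t))[0]) + 2  # +1 header, +1 one-based
        raise ValueError(f"{path}: unparseable timestamp at line {line}")
    if np.any(np.diff(t) < 0):
        raise ValueError(f"{path}: timestamps are not nondecreasing")
    df["bold"] = df["bold"].astype(int)
    return df[FRAME_COLUMNS]


def write_gaze_log(gaze: pd.DataFrame, path) -> None:
    gaze[GAZE_COLUMNS].to_csv(path, index=False)


def read_gaze_log(path) -> pd.DataFrame:
    """Typed gaze log; a violated 10 ms cadence is logged, not fatal."""
    df = pd.read_csv(path)
    _require_columns(df, GAZE_COLUMNS, path)
    bad = df[GAZE_COLUMNS].isna().any(axis=1)
    if bad.any():
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 2
        raise ValueError(f"{path}: unparseable row at line {line}")
    t = df["t_posix"].to_numpy(dtype=float)
    if np.any(np.diff(t) < 0):
        raise ValueError(f"{path}: timestamps are not nondecreasing")
    if len(t) > 1:
        median_dt = float(np.median(np.diff(t)))
        if abs(median_dt - NOMINAL_GAZE_DT_S) > GAZE_DT_SLACK * NOMINAL_GAZE_DT_S:
            logger.warning(
                "%s: median inter-sample gap %.4f s deviates from the nominal "
                "%.3f s by more than %d%%",
                path,
                median_dt,
                NOMINAL_GAZE_DT_S,
                int(GAZE_DT_SLACK * 100),
            )
    return df[GAZE_COLUMNS]


def write_threshold_table(table: pd.DataFrame, path) -> None:
    cols = THRESHOLD_COLUMNS + [
        c for c in ("log10_threshold", "posterior_sd") if c in table.columns
    ]
    table[cols].to_csv(path, index=False)


def read_threshold_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, THRESHOLD_COLUMNS, path)
    if (df["threshold_deg"] <= 0).any():
        raise ValueError(f"{path}: thresholds must be positive")
    return df


def write_manifest(path, *, config_hash: str, seed: int, files: list[str]) -> None:
    """Record what a run produced, for byte-level reproducibility checks."""
    from . import __version__

    manifest = {
        "config_sha256": config_hash,
        "seed": int(seed),
        "package_version": __version__,
        "files": sorted(files),
    }
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")


def sha256_of_config(payload: dict) -> str:
    """Stable hash of a configuration dict (canonical JSON)."""
    canon = json.dumps(payload, sort_keys=True, separators=(",", ":"), default=str)
    return hashlib.sha256(canon.encode()).hexdigest()
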