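"""Trial-table and configuration readers/writers.

Trial data travels as delimited text (CSV) with the header
``subject_id, group, trial, phase, u, c, y``. ``u`` and ``y`` are binary
(``y`` may be empty for unplayed trials), ``c`` lies strictly in (0, 1) and
``phase`` is ``stable`` or ``volatile``. Configs are YAML or JSON.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = ["read_trials", "write_trials", "load_config", "save_json",
           "config_hash"]

REQUIRED_COLUMNS = ("subject_id", "group", "trial", "phase", "u", "c", "y")


def _check_binary(df, col, allow_na=False):
    vals = df[col]
    mask = vals.isna()
    if mask.any() and not allow_na:
        bad = df.index[mask][0]
        raise ValueError(f"column {col!r} has a missing value at row {bad}")
    ok = mask | vals.isin([0, 1])
    if not ok.all():
        bad = df.index[~ok][0]
        raise ValueError(
            f"column {col!r} must be binary; row {bad} has {vals[bad]!r}")


def read_trials(path) -> dict:
    """Read and validate a trial CSV; returns {subject_id: DataFrame}."""
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")
    _check_binary(df, "u")
    _check_binary(df, "y", allow_na=True)
    c = df["c"].to_numpy(dtype=float)
    if np.any((c <= 0) | (c >= 1)):
        bad = int(np.argwhere((c <= 0) | (c >= 1))[0][0])
        raise ValueError(f"column 'c' must lie in (0, 1); row {bad} has "
                         f"{c[bad]!r}")
    bad_phase = ~df["phase"].isin(["stable", "volatile"])
    if bad_phase.any():
        bad = df.index[bad_phase][0]
        raise ValueError(f"unknown phase at row {bad}: {df['phase'][bad]!r}")
    return {sid: g.reset_index(drop=True)
            for sid, g in df.groupby("subject_id", sort=False)}


def write_trials(trials: pd.DataFrame, path) -> None:
    """Write a trial table (columns per :data:`REQUIRED_COLUMNS`) to CSV."""
    trials.loc[:, list(REQUIRED_COLUMNS)].to_csv(path, index=False)


def load_config(path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        return yaml.safe_load(text)
    return json.loads(text)


def save_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_jsonify))


def _jsonify(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, pd.DataFrame):
        return x.to_dict(orient="records")
    raise TypeError(f"not JSON-serializable: {type(x)}")


def config_hash(config: dict) -> str:
    """Stable short hash of a config dict, recorded with run artifacts."""
    blob = json.dumps(config, sort_keys=True, default=_jsonify).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
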