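"""Typed readers and writers for the package's on-disk dialects.

* Trial tables: tab-delimited with a header row, columns exactly the
  trial-record fields, times in seconds with 3 decimals.
* Conductance traces: one CSV per participant with columns
  ``time_s, conductance_uS`` plus a JSON sidecar carrying the sampling
  rate and participant id.
* Gamble choices: tab-delimited (participant_id, gain, loss, accepted).

Readers validate the domain row by row and report the first offending
line number; writes followed by reads round-trip losslessly on the
documented precision.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .config import INCENTIVE_LEVELS
from .errors import FormatError, ParseError
from .scr import SCRRecording

__all__ = [
    "write_trials", "read_trials",
    "write_trace", "read_trace",
    "write_choices", "read_choices",
]

TRIAL_COLUMNS = [
    "participant_id", "run", "block_index", "condition", "incentive",
    "incentive_onset", "incentive_duration", "task_onset", "task_duration",
    "iti_duration", "outcome",
]
_TIME_COLUMNS = ["incentive_onset", "incentive_duration", "task_onset",
                 "task_duration", "iti_duration"]


def write_trials(trials: pd.DataFrame, path) -> None:
    """Write a trial table as tab-delimited text, times to 3 decimals."""
    out = trials[TRIAL_COLUMNS].copy()
    for col in _TIME_COLUMNS:
        out[col] = out[col].map(lambda v: f"{v:.3f}")
    out.to_csv(path, sep="\t", index=False)


def read_trials(path) -> pd.DataFrame:
    """Read and validate a tab-delimited trial table.

    Raises :class:`ParseError` naming the first offending line (1-based,
    counting the header) for domain violations: incentive off the grid,
    unknown condition or outcome, durations out of range, or onsets that
    fail to increase strictly within a run.
    """
    df = pd.read_csv(path, sep="\t")
    missing = set(TRIAL_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")

    def bad(mask, message):
        if mask.any():
            line = int(np.flatnonzero(mask.to_numpy())[0]) + 2
            raise ParseError(f"{path}:{line}: {message}")

    bad(~df["incentive"].isin(INCENTIVE_LEVELS),
        f"incentive not in {INCENTIVE_LEVELS}")
    bad(~df["condition"].isin(["baseline", "reappraisal"]), "unknown condition")
    bad(~df["outcome"].isin(["success", "failure"]), "unknown outcome")
    bad((df["incentive_duration"] < 2 - 1e-9) | (df["incentive_duration"] > 5 + 1e-9),
        "incentive_duration outside [2, 5] s")
    bad((df["iti_duration"] < 1 - 1e-9) | (df["iti_duration"] > 7 + 1e-9),
        "iti_duration outside [1, 7] s")
    for col in _TIME_COLUMNS:
        bad(~np.isfinite(df[col]), f"non-finite {col}")
    for (pid, run), grp in df.groupby(["participant_id", "run"], sort=False):
        onsets = grp["incentive_onset"].to_numpy()
        if np.any(np.diff(onsets) <= 0):
            j = int(np.flatnonzero(np.diff(onsets) <= 0)[0]) + 1
            line = int(grp.index[j]) + 2
            raise ParseError(
                f"{path}:{line}: onsets not strictly increasing within run "
                f"({pid}, run {run})")
    df["incentive"] = df["incentive"].astype(int)
    return df


def write_trace(rec: SCRRecording, csv_path, sidecar_path=None) -> None:
    """Write a conductance trace as CSV plus a JSON sidecar."""
    csv_path = Path(csv_path)
    if sidecar_path is None:
        sidecar_path = csv_path.with_suffix(".json")
    t = rec.times
    pd.DataFrame({"time_s": t, "conductance_uS": rec.samples}).to_csv(
        csv_path, index=False, float_format="%.6f")
    with open(sidecar_path, "w") as fh:
        json.dump({"participant_id": rec.participant_id,
                   "sampling_rate": rec.sampling_rate}, fh)
        fh.write("\n")


def read_trace(csv_path, sidecar_path=None) -> SCRRecording:
    """Read a trace CSV (+ sidecar); non-finite samples are a format error."""
    csv_path = Path(csv_path)
    if sidecar_path is None:
        sidecar_path = csv_path.with_suffix(".json")
    df = pd.read_csv(csv_path)
    if not {"time_s", "conductance_uS"} <= set(df.columns):
        raise FormatError(f"{csv_path}: expected columns time_s, conductance_uS")
    samples = df["conductance_uS"].to_numpy(dtype=float)
    if not np.all(np.isfinite(samples)):
        j = int(np.flatnonzero(~np.isfinite(samples))[0]) + 2
        raise FormatError(f"{csv_path}:{j}: non-finite conductance sample")
    with open(sidecar_path) as fh:
        meta = json.load(fh)
    rate = float(meta["sampling_rate"])
    t = df["time_s"].to_numpy(dtype=float)
    if len(t) > 1 and abs((t[1] - t[0]) - 1.0 / rate) > 1e-6:
        raise FormatError(
            f"{csv_path}: time step {t[1] - t[0]:.6f} s does not match the "
            f"sidecar sampling_rate {rate} Hz")
    return SCRRecording(participant_id=str(meta["participant_id"]),
                        sampling_rate=rate, samples=samples)


def write_choices(choices: pd.DataFrame, path) -> None:
    choices.to_csv(path, sep="\t", index=False)


def read_choices(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = {"participant_id", "gain", "loss", "accepted"} - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    for col in ("gain", "loss"):
        m = ~(df[col] > 0)
        if m.any():
            line = int(np.flatnonzero(m.to_numpy())[0]) + 2
            raise ParseError(f"{path}:{line}: {col} must be strictly positive")
    df["accepted"] = df["accepted"].astype(bool)
    return df
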