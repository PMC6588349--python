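"""Tidy-table input/output for all pipeline stages.

All interchange is plain comma-separated text with a header row, '.' decimal,
UTF-8.  Schemas:

* trace tables:        trace_id, time_s, intensity [, channel]
* FRET series:         time_s, donor, acceptor
* epoch tables:        label, start_s, end_s, drug, concentration_uM
* dose-response:       concentration_uM, response, replicate
* quench trials:       time_ms, fluorescence, trial_id, quencher

Rows are validated at load (monotone time, finite values) and malformed
input is rejected with the offending location.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .photobleach import IntensityTrace
from .fret import FretSeries
from .simulate import Epoch

TRACE_COLUMNS = ["trace_id", "time_s", "intensity"]
FRET_COLUMNS = ["time_s", "donor", "acceptor"]
EPOCH_COLUMNS = ["label", "start_s", "end_s", "drug", "concentration_uM"]
DOSE_COLUMNS = ["concentration_uM", "response", "replicate"]
QUENCH_COLUMNS = ["time_ms", "fluorescence", "trial_id", "quencher"]


def _require_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")


def _check_finite(df: pd.DataFrame, cols: list[str], path) -> None:
    for col in cols:
        bad = ~np.isfinite(df[col].to_numpy(dtype=float))
        if bad.any():
            line = int(np.flatnonzero(bad)[0]) + 2  # header + 1-based
            raise ValueError(f"{path}: non-finite value in '{col}' at line {line}")


def read_trace_table(path) -> list[IntensityTrace]:
    """Read per-spot intensity traces from a tidy table."""
    df = pd.read_csv(path)
    _require_columns(df, TRACE_COLUMNS, path)
    _check_finite(df, ["time_s", "intensity"], path)
    traces = []
    for tid, group in df.groupby("trace_id", sort=False):
        t = group["time_s"].to_numpy(dtype=float)
        if np.any(np.diff(t) <= 0):
            first_bad = int(group.index[np.flatnonzero(np.diff(t) <= 0)[0] + 1]) + 2
        # IntensityTrace re-validates; report line numbers here
            raise ValueError(
                f"{path}: time_s not strictly increasing for trace {tid!r} "
                f"near line {first_bad}"
            )
        channel = str(group["channel"].iloc[0]) if "channel" in group else ""
        traces.append(IntensityTrace(str(tid), t,
                                     group["intensity"].to_numpy(dtype=float),
                                     channel))
    if not traces:
        raise ValueError(f"{path}: no traces found")
    return traces


def write_trace_table(traces: list[IntensityTrace], path) -> None:
    frames = []
    for tr in traces:
        frame = pd.DataFrame({
            "trace_id": tr.trace_id, "time_s": tr.time_s,
            "intensity": tr.intensity,
        })
        if tr.channel:
            frame["channel"] = tr.channel
        frames.append(frame)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_epoch_table(path) -> tuple[Epoch, ...]:
    df = pd.read_csv(path)
    _require_columns(df, ["label", "start_s", "end_s", "drug"], path)
    return tuple(
        Epoch(str(row.label), float(row.start_s), float(row.end_s),
              str(row.drug),
              float(getattr(row, "concentration_uM", 0.0)))
        for row in df.itertuples()
    )


def read_fret_series(path, epochs_path=None) -> FretSeries:
    df = pd.read_csv(path)
    _require_columns(df, FRET_COLUMNS, path)
    _check_finite(df, FRET_COLUMNS, path)
    epochs = read_epoch_table(epochs_path) if epochs_path else ()
    return FretSeries(df["time_s"].to_numpy(dtype=float),
                      df["donor"].to_numpy(dtype=float),
                      df["acceptor"].to_numpy(dtype=float), epochs)


def read_dose_response(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, ["concentration_uM", "response"], path)
    _check_finite(df, ["concentration_uM", "response"], path)
    return df


def read_quench_trials(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, QUENCH_COLUMNS, path)
    _check_finite(df, ["time_ms", "fluorescence"], path)
    if df["quencher"].dtype == object:
        df["quencher"] = df["quencher"].astype(str).str.lower().isin(
            ["true", "1", "yes"])
    return df


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
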