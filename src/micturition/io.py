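"""Delimited-table I/O shared by the simulator, generator and analyses.

Traces are written as UTF-8 CSV with a header row and '#'-prefixed
metadata lines (sampling rate, units), so a written trace round-trips
losslessly.  Spike trains are two-column (unit_id, time_s) tables or
one-time-per-line files.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .cystometry import EMGTrace, PressureTrace
from .ephys import SpikeTrain

__all__ = [
    "write_table",
    "read_table",
    "write_trace",
    "read_trace",
    "write_spikes",
    "read_spikes",
    "load_config",
    "save_config",
]


def write_table(path, df: pd.DataFrame, meta: Optional[dict] = None) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for k, v in (meta or {}).items():
            fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, index=False)


def read_table(path) -> tuple[pd.DataFrame, dict]:
    path = Path(path)
    meta: dict = {}
    lines = []
    with open(path, encoding="utf-8") as fh:
        for i, line in enumerate(fh):
            if line.startswith("#"):
                body = line[1:].strip()
                if ":" in body:
                    k, v = body.split(":", 1)
                    meta[k.strip()] = v.strip()
                continue
            lines.append(line)
    if not lines or all(not ln.strip() for ln in lines):
        raise ValueError(f"{path}: empty input file")
    try:
        df = pd.read_csv(_io.StringIO("".join(lines)))
    except Exception as exc:  # malformed header/body
        raise ValueError(f"{path}: cannot parse table ({exc})") from exc
    return df, meta


def write_trace(path, trace) -> None:
    """Write a pressure or EMG trace (time_s, value columns + rate metadata)."""
    if isinstance(trace, PressureTrace):
        col, units = "pressure_mmHg", "mmHg"
    elif isinstance(trace, EMGTrace):
        col, units = "emg_au", "a.u."
    else:
        raise TypeError("expected a PressureTrace or EMGTrace")
    df = pd.DataFrame({"time_s": trace.times, col: trace.samples})
    write_table(path, df, meta={"sampling_rate_hz": repr(trace.rate), "units": units})


def read_trace(path):
    """Read a trace written by :func:`write_trace`; validates monotone time."""
    df, meta = read_table(path)
    if "time_s" not in df.columns or len(df.columns) < 2:
        raise ValueError(f"{path}: missing time_s/value columns")
    t = df["time_s"].to_numpy()
    if len(t) == 0:
        raise ValueError(f"{path}: empty trace")
    bad = np.flatnonzero(np.diff(t) <= 0)
    if len(bad):
        raise ValueError(f"{path}: non-monotone time at data line {bad[0] + 2}")
    rate = float(meta.get("sampling_rate_hz", 1.0 / np.median(np.diff(t)) if len(t) > 1 else 1.0))
    col = [c for c in df.columns if c != "time_s"][0]
    cls = PressureTrace if col.startswith("pressure") else EMGTrace
    return cls(rate=rate, samples=df[col].to_numpy(), t0=float(t[0]))


def write_spikes(path, trains: list) -> None:
    rows = [
        {"unit_id": tr.unit_id, "time_s": t}
        for tr in trains
        for t in tr.times
    ]
    df = pd.DataFrame(rows, columns=["unit_id", "time_s"])
    durs = {tr.unit_id: tr.duration for tr in trains}
    write_table(path, df, meta={"durations_s": yaml.safe_dump(durs, default_flow_style=True).strip()})


def read_spikes(path) -> list:
    df, meta = read_table(path)
    durs = yaml.safe_load(meta.get("durations_s", "{}")) or {}
    trains = []
    for uid, g in df.groupby("unit_id", sort=True):
        times = g["time_s"].to_numpy()
        trains.append(
            SpikeTrain(times=times, duration=float(durs.get(uid, times.max() if len(times) else 0.0)), unit_id=str(uid))
        )
    return trains


def load_config(path) -> dict:
    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if cfg is None:
        return {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg


def save_config(path, cfg: dict) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
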