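"""Delimited-text trace I/O and JSON fit reports.

Traces are plain delimited text with a ``time`` column plus one or two
channel columns (``475nm``, ``525nm``, or ``ratio``); header names declare
the channels, and time is in seconds.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .stopped_flow import DecayTrace, ExponentialFit

__all__ = ["read_trace", "read_channel_pair", "write_trace", "write_fit_report"]

_CHANNELS = ("475nm", "525nm", "ratio")


def write_trace(trace: DecayTrace, path, sep: str = ",") -> None:
    df = pd.DataFrame({"time": trace.time, trace.channel: trace.signal})
    df.to_csv(path, sep=sep, index=False)
    sidecar = Path(path).with_suffix(Path(path).suffix + ".json")
    meta = {"channel": trace.channel, "n_injections": trace.n_injections,
            "start_offset": trace.start_offset, **trace.meta}
    sidecar.write_text(json.dumps(meta, indent=2, default=float))


def _load(path, sep):
    df = pd.read_csv(path, sep=sep)
    df.columns = [c.strip().lower().replace(" ", "") for c in df.columns]
    if "time" not in df.columns:
        raise ValueError(f"{path}: no 'time' column (found {list(df.columns)})")
    return df


def read_trace(path, sep: str = ",", channel: str | None = None,
               n_injections: int = 1, start_offset: float = 0.0) -> DecayTrace:
    """Read a single-channel (or ratio) trace from delimited text."""
    df = _load(path, sep)
    channels = [c for c in df.columns if c != "time"]
    if channel is None:
        if len(channels) != 1:
            raise ValueError(
                f"{path}: expected one channel column, found {channels}; "
                "pass channel= to choose"
            )
        channel = channels[0]
    return DecayTrace(df["time"].to_numpy(float), df[channel].to_numpy(float),
                      channel=channel, n_injections=n_injections,
                      start_offset=start_offset, meta={"path": str(path)})


def read_channel_pair(path, sep: str = ",", n_injections: int = 1,
                      start_offset: float = 0.0):
    """Read a two-channel trace file; returns (trace525, trace475)."""
    df = _load(path, sep)
    for ch in ("525nm", "475nm"):
        if ch not in df.columns:
            raise ValueError(f"{path}: missing channel column {ch!r}")
    t = df["time"].to_numpy(float)
    mk = lambda ch: DecayTrace(t.copy(), df[ch].to_numpy(float), channel=ch,
                               n_injections=n_injections,
                               start_offset=start_offset,
                               meta={"path": str(path)})
    return mk("525nm"), mk("475nm")


def write_fit_report(fit: ExponentialFit, path, residuals=None,
                     constraints_from: str | None = None) -> None:
    """JSON fit report (parameters, uncertainties, flags, provenance of any
    constrained parameters); optional CSV residuals alongside."""
    report = fit.to_dict()
    if constraints_from is not None:
        report["constraints_from"] = constraints_from
    Path(path).write_text(json.dumps(report, indent=2, default=float))
    if residuals is not None:
        t, r = residuals
        pd.DataFrame({"time": t, "residual": r}).to_csv(
            Path(path).with_suffix(".residuals.csv"), index=False)
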