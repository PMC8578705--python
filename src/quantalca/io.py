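"""Delimited-text I/O with ``#``-prefixed metadata headers.

All files are comma-separated with a header row; metadata (parameters,
seed, tool version) travels in leading ``# key: value`` comment lines so
every output is self-describing and reproducible.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from quantalca.analysis import FluorescenceTrace

__all__ = [
    "write_table", "read_table", "write_trace", "read_trace",
]


def _jsonify(value):
    if isinstance(value, (np.integer,)):
        return int(value)
    if isinstance(value, (np.floating,)):
        return float(value)
    if isinstance(value, np.ndarray):
        return value.tolist()
    return value


def write_table(path, df: pd.DataFrame, metadata: dict | None = None,
                overwrite: bool = False) -> None:
    """Write a DataFrame as CSV with ``# key: json`` metadata lines."""
    path = Path(path)
    if path.exists() and not overwrite:
        raise FileExistsError(f"{path} exists; pass overwrite=True to replace")
    with open(path, "w") as fh:
        for key, value in (metadata or {}).items():
            fh.write(f"# {key}: {json.dumps(_jsonify(value))}\n")
        df.to_csv(fh, index=False)


def read_table(path) -> tuple[pd.DataFrame, dict]:
    """Read a CSV written by :func:`write_table`; returns (table, metadata)."""
    metadata: dict = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            body = line[1:].strip()
            if ":" in body:
                key, _, raw = body.partition(":")
                try:
                    metadata[key.strip()] = json.loads(raw.strip())
                except json.JSONDecodeError:
                    metadata[key.strip()] = raw.strip()
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh)
    return df, metadata


def write_trace(path, trace: FluorescenceTrace, metadata: dict | None = None,
                overwrite: bool = False, column: str = "fluorescence") -> None:
    """Write a fluorescence trace with its annotations in the metadata."""
    meta = dict(metadata or {})
    meta["annotations"] = {k: _jsonify(v) for k, v in trace.annotations.items()}
    if trace.calibration is not None:
        meta["calibration"] = list(trace.calibration)
    df = pd.DataFrame({"time_s": trace.times, column: trace.values})
    write_table(path, df, meta, overwrite=overwrite)


def read_trace(path) -> tuple[FluorescenceTrace, dict]:
    """Read a trace file; annotation/calibration metadata is restored."""
    df, meta = read_table(path)
    if "time_s" not in df.columns or df.shape[1] < 2:
        raise ValueError(f"{path}: expected columns time_s plus one trace "
                         f"column, got {list(df.columns)}")
    value_col = [c for c in df.columns if c != "time_s"][0]
    calibration = meta.get("calibration")
    trace = FluorescenceTrace(
        times=df["time_s"].to_numpy(),
        values=df[value_col].to_numpy(),
        annotations=meta.get("annotations", {}),
        calibration=tuple(calibration) if calibration else None,
    )
    return trace, meta
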