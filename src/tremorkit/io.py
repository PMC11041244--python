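"""Plain-text file dialects: pen traces, accelerometer streams, manifests.

Pen trace: UTF-8 CSV, header ``t,x,y,pen``; t seconds (strictly monotone),
x/y pixels, pen in {0,1}.  Accel stream: header ``t,ax,ay,az``; t seconds at
a nominal 128 Hz, axes in g.  Manifest: ``participant,task,condition,
repetition,pen_file,accel_file`` with paths relative to the manifest.
Feature/metric tables carry the pipeline config hash in a leading comment
line so that tables from different configurations cannot be mixed.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .core import ACCEL_FS, AccelStream, PenTrace

__all__ = [
    "read_pen_trace",
    "write_pen_trace",
    "read_accel_stream",
    "write_accel_stream",
    "read_manifest",
    "write_table",
    "read_table",
]

_FLOAT_FMT = "%.10g"


class ParseError(ValueError):
    """Malformed input file; the message names the first offending line."""


def _read_csv(path, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ParseError(f"{path}: file is empty")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    if df.empty:
        raise ParseError(f"{path}: no data rows")
    return df


def read_pen_trace(path, **meta) -> PenTrace:
    """Parse and validate a pen-trace CSV.

    Raises :class:`ParseError` naming the first offending data line (1-based
    file line numbers, header = line 1) for non-monotone timestamps, invalid
    pen states, or non-finite samples.
    """
    path = Path(path)
    df = _read_csv(path, ["t", "x", "y", "pen"])
    t = df["t"].to_numpy(float)
    bad = np.flatnonzero(~np.isfinite(df[["t", "x", "y"]].to_numpy(float)).all(axis=1))
    if len(bad):
        raise ParseError(f"{path}: non-finite value at line {bad[0] + 2}")
    dec = np.flatnonzero(np.diff(t) <= 0)
    if len(dec):
        raise ParseError(f"{path}: non-increasing timestamp at line {dec[0] + 3}")
    pen = df["pen"].to_numpy()
    badpen = np.flatnonzero(~np.isin(pen, (0, 1)))
    if len(badpen):
        raise ParseError(f"{path}: pen state not in {{0,1}} at line {badpen[0] + 2}")
    return PenTrace(t=t, x=df["x"].to_numpy(float), y=df["y"].to_numpy(float),
                    pen=pen.astype(int), **meta)


def write_pen_trace(trace: PenTrace, path) -> None:
    trace.to_dataframe().to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_accel_stream(path, expected_fs: float = ACCEL_FS, tol: float = 0.01, **meta) -> AccelStream:
    """Parse and validate an accelerometer CSV.

    Validates near-constant sampling at ``expected_fs`` (median interval
    within ``tol`` relative); a stream at a different rate raises
    :class:`ParseError`.  NaN samples are rejected with their line number.
    """
    path = Path(path)
    df = _read_csv(path, ["t", "ax", "ay", "az"])
    arr = df[["ax", "ay", "az"]].to_numpy(float)
    bad = np.flatnonzero(~np.isfinite(arr).all(axis=1))
    if len(bad):
        raise ParseError(f"{path}: non-finite sample at line {bad[0] + 2}")
    t = df["t"].to_numpy(float)
    dec = np.flatnonzero(np.diff(t) <= 0)
    if len(dec):
        raise ParseError(f"{path}: non-increasing timestamp at line {dec[0] + 3}")
    if len(t) > 1:
        fs_obs = 1.0 / np.median(np.diff(t))
        if abs(fs_obs - expected_fs) / expected_fs > tol:
            raise ParseError(
                f"{path}: sampling rate {fs_obs:.1f} Hz differs from expected "
                f"{expected_fs:g} Hz by more than {tol:.0%}"
            )
    return AccelStream(t=t, axes=arr, fs=expected_fs, **meta)


def write_accel_stream(stream: AccelStream, path) -> None:
    stream.to_dataframe().to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_manifest(path) -> pd.DataFrame:
    """Read a run manifest and check referenced files exist and keys are unique."""
    path = Path(path)
    df = _read_csv(path, ["participant", "task", "condition", "repetition",
                          "pen_file", "accel_file"])
    keys = df[["participant", "task", "condition", "repetition"]]
    if keys.duplicated().any():
        dup = keys[keys.duplicated()].iloc[0].to_dict()
        raise ParseError(f"{path}: duplicate manifest key {dup}")
    root = path.parent
    for col in ("pen_file", "accel_file"):
        for f in df[col]:
            if not (root / f).exists():
                raise ParseError(f"{path}: referenced file does not exist: {f}")
    return df


def write_table(df: pd.DataFrame, path, config_hash: str | None = None) -> None:
    """Write a metrics/features/results table, embedding the config hash."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        if config_hash:
            fh.write(f"# config_hash={config_hash}\n")
        df.to_csv(fh, index=False, float_format=_FLOAT_FMT)


def read_table(path, expect_hash: str | None = None) -> pd.DataFrame:
    """Read a table written by :func:`write_table`, checking the config hash."""
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
    file_hash = None
    if first.startswith("# config_hash="):
        file_hash = first.strip().split("=", 1)[1]
    if expect_hash is not None:
        if file_hash is None:
            warnings.warn(f"{path}: table carries no config hash", stacklevel=2)
        elif file_hash != expect_hash:
            raise ValueError(
                f"{path}: config hash {file_hash} does not match expected {expect_hash}; "
                "refusing to mix tables from different configurations"
            )
    return pd.read_csv(path, comment="#")
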