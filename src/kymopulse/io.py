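"""Readers and writers for the formats the pipeline touches.

Kymographs come in as single-channel TIFF images or CSV matrices; time
series and tip traces as CSV. Everything is converted to float on read.
Orientation is normalized so the cell occupies low column indices (the
first frame's left 10% of columns is at least as bright as its right
10%); a flip, if applied, is recorded on the returned object.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .types import GrowthSeries, Kymograph, RawSeries, TipTrace, UniformSeries


def _orient(values: np.ndarray) -> tuple[np.ndarray, bool]:
    n_px = values.shape[1]
    k = max(1, n_px // 10)
    first = float(np.mean(values[0, :k]))
    last = float(np.mean(values[0, -k:]))
    if last > first:
        return values[:, ::-1].copy(), True
    return values, False


def read_kymograph(
    path: str | Path,
    dt: float,
    dx: float,
    channel: str = "",
    n_frames: int | None = None,
) -> Kymograph:
    """Read a kymograph from TIFF or CSV and normalize its orientation.

    Rows are assumed to be frames (time) and columns pixels (space). If
    ``n_frames`` is given and only the other dimension matches it, the
    matrix is transposed (ImageJ's Multiple Kymograph emits space x time).

    Raises
    ------
    ValueError
        On empty or non-numeric content.
    """
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        values = np.asarray(tifffile.imread(path), dtype=float)
    else:
        try:
            values = np.loadtxt(path, delimiter=",", dtype=float, ndmin=2)
        except ValueError as exc:
            raise ValueError(f"non-numeric content in {path}: {exc}") from exc
    if values.size == 0:
        raise ValueError(f"empty matrix in {path}")
    if values.ndim != 2:
        raise ValueError(f"expected a 2-D matrix in {path}, got ndim={values.ndim}")
    if n_frames is not None and values.shape[0] != n_frames:
        if values.shape[1] == n_frames:
            values = values.T
        else:
            raise ValueError(
                f"neither dimension of {values.shape} matches n_frames={n_frames}"
            )
    values, flipped = _orient(values)
    return Kymograph(values=values, dt=dt, dx=dx, channel=channel, flipped=flipped)


def write_kymograph(kymo: Kymograph, path: str | Path) -> None:
    """Write a kymograph to TIFF (bit-exact float) or CSV."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        tifffile.imwrite(path, kymo.values)
    else:
        np.savetxt(path, kymo.values, delimiter=",", fmt="%.17g")


def read_series(
    path: str | Path,
    time_col: str = "time_s",
    value_col: str = "value",
    units: str = "",
) -> RawSeries:
    """Read a (time, value) CSV into a time-sorted RawSeries.

    Duplicate timestamps are collapsed by their mean.
    """
    df = pd.read_csv(path)
    for col in (time_col, value_col):
        if col not in df.columns:
            raise ValueError(f"column {col!r} missing from {path}")
    df = df[[time_col, value_col]].dropna()
    df = df.groupby(time_col, as_index=False).mean().sort_values(time_col)
    if len(df) < 4:
        raise ValueError(f"need at least 4 samples, got {len(df)}")
    return RawSeries(
        t=df[time_col].to_numpy(float), v=df[value_col].to_numpy(float), units=units
    )


def write_series(rs: RawSeries | UniformSeries, path: str | Path) -> None:
    t = rs.t
    df = pd.DataFrame({"time_s": t, "value": rs.v})
    df.to_csv(path, index=False, float_format="%.12g")


def read_tip_trace(path: str | Path, dx: float, dt: float | None = None) -> TipTrace:
    """Read an externally produced tip trace CSV (frame, position_px)."""
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    fcol = cols.get("frame", df.columns[0])
    pcol = cols.get("position_px", df.columns[1])
    frames = df[fcol].to_numpy(float)
    t = frames * dt if dt is not None else frames
    return TipTrace(t=t, pos_px=df[pcol].to_numpy(float), dx=dx, method="external")


def write_tip_trace(trace: TipTrace, path: str | Path) -> None:
    pd.DataFrame(
        {
            "time_s": trace.t,
            "position_px": trace.pos_px,
            "position_um": trace.pos_um,
            "method": trace.method,
            "smoothed": trace.smoothed,
        }
    ).to_csv(path, index=False, float_format="%.12g")


def write_growth(gs: GrowthSeries, path: str | Path) -> None:
    pd.DataFrame({"time_s": gs.t, "rate_um_min": gs.rate}).to_csv(
        path, index=False, float_format="%.12g"
    )


def write_ridges(points: np.ndarray, path: str | Path) -> None:
    """Write a ridge table with columns time_s, period_s, power, amplitude."""
    pd.DataFrame(
        np.asarray(points, dtype=float).reshape(-1, 4),
        columns=["time_s", "period_s", "power", "amplitude"],
    ).to_csv(path, index=False, float_format="%.12g")


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_json_default) + "\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.bool_,)):
        return bool(o)
    raise TypeError(f"not JSON serializable: {type(o)}")
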