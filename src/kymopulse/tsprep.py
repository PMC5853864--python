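"""Pre-filtering of raw time series: regular sampling and outlier repair.

Most downstream spectral methods require a homogeneous sampling rate, but
experimental series (ion-selective probe exports in particular) rarely
have one. ``regularize`` interpolates a series onto a regular grid with a
degree-2 loess fit; ``remove_outliers`` flags gross deviations from a
running median in MAD units and restores them from a local regression,
optionally also scanning autoregressive innovations for additive-outlier
and level-shift patterns. Level shifts are reported but never corrected:
an abrupt persistent change may be biology, not artefact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import median_filter

from ._loess import loess
from .types import RawSeries, UniformSeries


@dataclass
class OutlierReport:
    """Audit record of outlier handling: index, type, original, replacement."""

    index: np.ndarray
    kind: list[str]  # "additive" or "level_shift"
    original: np.ndarray
    replaced: np.ndarray
    method: str
    mad_k: float


def regularize(
    rs: RawSeries,
    dt_target: float | None = None,
    span: float = 0.05,
) -> UniformSeries:
    """Resample a raw series onto a regular grid by local quadratic regression.

    ``dt_target`` defaults to the median observed time step. The loess
    fit (degree 2, tricube weights, ``span`` fraction of the data per
    local fit) is evaluated on the grid covering [min t, max t]; missing
    values are excluded from the fit.
    """
    if len(rs) < 10:
        raise ValueError("need at least 10 samples to regularize")
    steps = np.diff(rs.t)
    if dt_target is None:
        dt_target = float(np.median(steps))
    if not dt_target > 0:
        raise ValueError("dt_target must be positive")
    t0 = float(rs.t[0])
    n = int(np.floor((rs.t[-1] - t0) / dt_target)) + 1
    grid = t0 + np.arange(n) * dt_target
    # ensure each local fit spans enough points
    span = max(span, 7.0 / len(rs))
    v = loess(rs.t, rs.v, grid, span=min(span, 1.0), degree=2)
    return UniformSeries(t0=t0, dt=dt_target, v=v, units=rs.units)


def remove_outliers(
    us: UniformSeries,
    mad_k: float = 5.0,
    method: str = "mad",
    window: int = 11,
) -> tuple[UniformSeries, OutlierReport]:
    """Detect gross outliers and restore them from the local structure.

    ``mad`` method: points whose residual from a running median (window
    ``window`` samples) exceeds ``mad_k`` times the MAD of the residuals
    are flagged as additive outliers and replaced by a local quadratic
    regression prediction from the unflagged points. ``model`` method:
    additionally fits a low-order
    autoregression to the MAD-cleaned series and scans its standardized
    innovations for additive-outlier and level-shift signatures; level
    shifts are reported but left in place.
    """
    if us.n < 20:
        raise ValueError("need at least 20 samples")
    v = us.v.copy()
    med = median_filter(v, size=window, mode="nearest")
    resid = v - med
    mad = float(np.median(np.abs(resid - np.median(resid)))) * 1.4826
    if mad == 0:
        mad = float(np.std(resid)) or 1e-12
    flagged = np.abs(resid) > mad_k * mad
    if flagged.mean() > 0.5:
        raise ValueError("most points flagged: mad_k too small for this series")
    idx = list(np.nonzero(flagged)[0])
    kinds = ["additive"] * len(idx)
    if idx:
        t = us.t
        good = ~flagged
        span = min(1.0, max(15.0 / good.sum(), 9.0 / good.sum()))
        v[flagged] = loess(t[good], v[good], t[flagged], span=span, degree=2)

    if method == "model":
        for i in _scan_level_shifts(v, mad_k):
            if i not in idx:
                idx.append(i)
                kinds.append("level_shift")
    elif method != "mad":
        raise ValueError(f"unknown method {method!r}")

    if idx:
        order = np.argsort(idx)
        idx_arr = np.asarray(idx, dtype=int)[order]
        kinds = [kinds[i] for i in order]
    else:
        idx_arr = np.array([], dtype=int)
    report = OutlierReport(
        index=idx_arr,
        kind=kinds,
        original=us.v[idx_arr].copy(),
        replaced=v[idx_arr].copy(),
        method=method,
        mad_k=mad_k,
    )
    return UniformSeries(t0=us.t0, dt=us.dt, v=v, units=us.units), report


def remove_outliers_raw(
    rs: RawSeries, mad_k: float = 5.0, window: int = 11
) -> tuple[RawSeries, OutlierReport]:
    """MAD-based additive-outlier repair on a raw (possibly irregular) series.

    Same flagging rule as :func:`remove_outliers`, applied in sample
    order before any interpolation — gross spikes must be repaired
    before loess regularization, which would otherwise smear them into
    their neighbours and below the detection threshold.
    """
    if len(rs) < 20:
        raise ValueError("need at least 20 samples")
    v = rs.v.copy()
    med = median_filter(v, size=window, mode="nearest")
    resid = v - med
    mad = float(np.median(np.abs(resid - np.median(resid)))) * 1.4826
    if mad == 0:
        mad = float(np.std(resid)) or 1e-12
    flagged = np.abs(resid) > mad_k * mad
    if flagged.mean() > 0.5:
        raise ValueError("most points flagged: mad_k too small for this series")
    idx = np.nonzero(flagged)[0]
    if idx.size:
        good = ~flagged
        span = min(1.0, 15.0 / good.sum())
        v[flagged] = loess(rs.t[good], v[good], rs.t[flagged], span=span, degree=2)
    report = OutlierReport(
        index=idx,
        kind=["additive"] * idx.size,
        original=rs.v[idx].copy(),
        replaced=v[idx].copy(),
        method="mad_raw",
        mad_k=mad_k,
    )
    return RawSeries(t=rs.t, v=v, units=rs.units), report


def prepare(
    rs: RawSeries,
    dt_target: float | None = None,
    span: float = 0.05,
    mad_k: float = 5.0,
    fix_outliers: bool = True,
) -> tuple[UniformSeries, OutlierReport | None]:
    """Standard pre-filtering chain: repair gross outliers, then regularize."""
    report = None
    if fix_outliers:
        rs, report = remove_outliers_raw(rs, mad_k=mad_k)
    return regularize(rs, dt_target=dt_target, span=span), report


def _scan_level_shifts(v: np.ndarray, k: float) -> list[int]:
    """Indices where the series mean shifts persistently (CUSUM-style scan
    of AR(1) innovations): candidate level-shift points."""
    x = v - v.mean()
    if x.size < 30 or np.allclose(x, 0):
        return []
    phi = float(np.corrcoef(x[:-1], x[1:])[0, 1])
    phi = np.clip(phi, -0.99, 0.99)
    innov = x[1:] - phi * x[:-1]
    s = np.std(innov) or 1e-12
    z = innov / s
    out: list[int] = []
    half = 8
    for i in np.nonzero(np.abs(z) > k)[0]:
        j = i + 1  # innovation i belongs to sample i+1
        lo = max(0, j - half)
        hi = min(v.size, j + half)
        if j - lo < 3 or hi - j < 3:
            continue
        before, after = v[lo:j], v[j:hi]
        if abs(after.mean() - before.mean()) > k * 0.5 * s:
            out.append(int(j))
    return out
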