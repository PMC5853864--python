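"""Tip localization on kymographs.

Two per-frame detectors are provided. The *threshold* method returns the
boundary pixel where the fluorescence last exceeds a threshold when
scanning from the background toward the cell; its resolution is limited
to whole pixels. The featured *regression* method fits an ordinary
least-squares line to the sharpest part of the edge in a lightly smoothed
profile and returns the real-valued position where that line crosses a
reference level, giving subpixel resolution. Traces can be smoothed with
a local quadratic fit, and differenced into growth-rate series.
"""

from __future__ import annotations

import numpy as np

from ._loess import loess
from .types import GrowthSeries, Kymograph, TipTrace


def detect_tip_threshold(profile: np.ndarray, threshold: float) -> float:
    """Boundary pixel index where the profile last meets ``threshold``.

    Scanning from the background (high indices) toward the cell, the
    returned index is the largest ``p`` with ``profile[p] >= threshold``
    — i.e. every pixel beyond it is below threshold. NaN when no pixel
    meets the threshold.
    """
    profile = np.asarray(profile, dtype=float)
    above = np.nonzero(profile >= threshold)[0]
    if above.size == 0:
        return float("nan")
    return float(above[-1])


def default_threshold(profile: np.ndarray) -> float:
    """Midpoint between the 10th and 99th intensity percentiles of a frame."""
    lo, hi = np.nanpercentile(profile, [10, 99])
    return 0.5 * (lo + hi)


def _moving_average(x: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return x.astype(float)
    kernel = np.ones(window) / window
    pad = window // 2
    xp = np.pad(x.astype(float), pad, mode="edge")
    out = np.convolve(xp, kernel, mode="same")[pad : pad + x.size]
    return out


def detect_tip_regression(
    profile: np.ndarray,
    presmooth_window: int = 3,
    fit_halfwidth: int = 2,
    ref_level: float = 0.0,
) -> float:
    """Subpixel tip position from a line fit at the sharpest edge slope.

    Steps: (1) lightly smooth the profile (moving average of
    ``presmooth_window`` px); (2) fit an OLS line through the smoothed
    intensities in every sliding window of half-width ``fit_halfwidth``
    between the profile maximum and the background side, and keep the
    window whose fitted slope is the sharpest descent (ties break toward
    the background side); (3) return the real-valued position where that
    line crosses ``ref_level`` (the frame's background estimate; 0 after
    background subtraction).

    Returns NaN when no window has a descending fitted slope.
    """
    profile = np.asarray(profile, dtype=float)
    n = profile.size
    win = 2 * fit_halfwidth + 1
    if n < win:
        raise ValueError("profile shorter than the fit window")
    sm = _moving_average(profile, presmooth_window)
    # sliding OLS slope and mean over centred windows of width `win`
    k = np.arange(-fit_halfwidth, fit_halfwidth + 1, dtype=float)
    sxx = float(np.sum(k**2))
    slopes = np.convolve(sm, -k / sxx, mode="valid")  # slope at centre c
    means = np.convolve(sm, np.ones(win) / win, mode="valid")
    centers = np.arange(fit_halfwidth, n - fit_halfwidth)
    start = int(np.argmax(sm))
    use = centers >= start
    if not use.any():
        use = np.ones_like(use, dtype=bool)
    smin = slopes[use].min()
    if smin >= 0:
        return float("nan")
    cand = np.nonzero(use & (slopes == smin))[0]
    i = int(cand[-1])  # most distal tie
    slope, c = slopes[i], centers[i]
    # line through (c, means[i]) with the fitted slope
    return float(c + (ref_level - means[i]) / slope)


def detect_tip(
    kymo: Kymograph,
    method: str = "regression",
    threshold: float | None = None,
    presmooth_window: int = 3,
    fit_halfwidth: int = 2,
    ref_level: float | None = None,
    bg_quantile: float = 0.5,
) -> TipTrace:
    """Run a per-frame tip detector over every frame of a kymograph.

    For the regression method, ``ref_level`` defaults per frame to the
    midpoint between the plateau estimate (median of the first 10% of
    columns, cell side) and the background estimate (median of the last
    10%). A mid-edge crossing level keeps the line-crossing inside the
    fit window, so slope noise is not amplified by extrapolation, and it
    is unbiased for a symmetric edge; pass ``ref_level`` explicitly
    (e.g. a measured background cut-off, or 0 after background
    subtraction) to localize the edge foot instead.
    """
    values = kymo.values
    pos = np.empty(kymo.n_frames)
    k = max(1, kymo.n_px // 10)
    for i in range(kymo.n_frames):
        profile = values[i]
        if method == "threshold":
            thr = default_threshold(profile) if threshold is None else threshold
            pos[i] = detect_tip_threshold(profile, thr)
        elif method == "regression":
            if ref_level is None:
                bg = float(np.median(profile[-k:]))
                plateau = float(np.median(profile[:k]))
                ref = 0.5 * (bg + plateau)
            else:
                ref = ref_level
            pos[i] = detect_tip_regression(
                profile, presmooth_window, fit_halfwidth, ref
            )
        else:
            raise ValueError(f"unknown method {method!r}")
    pos = np.where((pos >= 0) & (pos <= kymo.n_px - 1), pos, np.nan)
    return TipTrace(t=kymo.times, pos_px=pos, dx=kymo.dx, method=method)


def strongest_channel(*kymos: Kymograph) -> Kymograph:
    """The channel with the highest median intensity (used for detection)."""
    return max(kymos, key=lambda k: float(np.median(k.values)))


def smooth_trace(trace: TipTrace, span: float | None = None) -> TipTrace:
    """Smooth a tip trace with a local quadratic (loess) fit.

    The default span covers about 20 points of the series — small, on the
    assumption that the tip makes no sudden jumps, so as not to flatten
    genuine high-frequency growth oscillations. Missing frames are filled
    by the local fit.
    """
    good = np.isfinite(trace.pos_px)
    if good.sum() < 10:
        raise ValueError("need at least 10 non-missing points to smooth")
    if span is None:
        span = min(1.0, 20.0 / good.sum())
    sm = loess(trace.t[good], trace.pos_px[good], trace.t, span, degree=2)
    return TipTrace(
        t=trace.t, pos_px=sm, dx=trace.dx, method=trace.method, smoothed=True
    )


def growth_rate(trace: TipTrace, dx: float | None = None, dt: float | None = None) -> GrowthSeries:
    """First-difference growth rate in µm/min, timestamped at midpoints.

    rate_i = (pos_px[i+1] - pos_px[i]) * dx / dt * 60.
    """
    if dx is None:
        dx = trace.dx
    if dt is None:
        dts = np.diff(trace.t)
        dt = float(dts[0])
        if not np.allclose(dts, dt):
            raise ValueError("trace must be uniform in time")
    rate = np.diff(trace.pos_px) * dx / dt * 60.0
    t_mid = 0.5 * (trace.t[:-1] + trace.t[1:])
    return GrowthSeries(t=t_mid, rate=rate)
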