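"""Synthetic kymographs and time series with known ground truth.

The generators emulate the study conditions the downstream estimators are
built for: a bright cell body ending in a near-sigmoid edge onto a dark
background, a tip trajectory combining steady elongation with a sinusoidal
oscillation, spectrally co-registered ratiometric channel pairs with
distinct background levels, photobleaching drift, additive noise,
occasional gross outliers, and series pairs sharing a period at a fixed
lag. Every generator is a pure function of its parameters and seed and
returns the ground truth needed to score the estimators.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import Kymograph, RawSeries


@dataclass
class KymoGroundTruth:
    """True quantities behind a simulated kymograph."""

    tip_px: np.ndarray          # true subpixel tip position per frame
    period_s: float
    amp_um: float
    v_um_min: float
    bg: dict[str, float]        # true background level per channel
    ratio_field: np.ndarray | None = None  # true ratio per (frame, px), NaN outside cell
    edge_width_px: float = 1.0


@dataclass
class SeriesGroundTruth:
    """True quantities behind a simulated series pair."""

    period_s: float
    amp: float
    lag_s: float
    clean_x: np.ndarray
    clean_y: np.ndarray
    outlier_idx: np.ndarray
    outlier_sign: np.ndarray


def _logistic(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))


def tip_trajectory(
    n_frames: int, dt: float, dx: float, x0: float, v: float, period: float, amp: float
) -> np.ndarray:
    """True tip position (px): x0 + (v/60)*t/dx + (amp/dx)*sin(2*pi*t/period)."""
    t = np.arange(n_frames) * dt
    return x0 + (v / 60.0) * t / dx + (amp / dx) * np.sin(2 * np.pi * t / period)


def simulate_kymograph(
    n_frames: int = 256,
    n_px: int = 200,
    dt: float = 4.0,
    dx: float = 0.22,
    v: float = 1.5,
    period: float = 48.0,
    amp: float = 0.4,
    edge_width: float = 1.0,
    plateau: float = 1000.0,
    bg_level: float = 100.0,
    noise_sd: float = 0.0,
    bleach_rate: float = 0.0,
    x0: float | None = None,
    bump_amp: float = 0.0,
    bump_width: float = 4.0,
    poisson: bool = False,
    channel: str = "",
    seed: int = 0,
) -> tuple[Kymograph, KymoGroundTruth]:
    """Simulate a single-channel kymograph of a growing, oscillating tip.

    The per-frame profile is a logistic edge from plateau (cell, low
    indices) to background (high indices), centred on the true tip
    position; the plateau decays exponentially with ``bleach_rate`` per
    frame. ``bump_amp`` adds a tip-focused Gaussian intensity bump (the
    "strong channel" look). Noise is additive Gaussian by default; with
    ``poisson=True`` intensities are Poisson-resampled instead.

    Defaults emulate a typical acquisition: 4 s frames, 0.22 µm pixels,
    ~1.5 µm/min mean growth with a 48 s, 0.4 µm oscillation, and a
    diffraction-limited (1 px scale) edge.
    """
    if not plateau > bg_level:
        raise ValueError("plateau must exceed bg_level")
    if edge_width < 1:
        raise ValueError("edge_width must be >= 1 px")
    rng = np.random.default_rng(seed)
    if x0 is None:
        x0 = 0.1 * n_px
    tip = tip_trajectory(n_frames, dt, dx, x0, v, period, amp)
    if tip.min() < 2 or tip.max() > n_px - 3:
        raise ValueError("tip trajectory leaves the field of view")
    p = np.arange(n_px)
    frames = np.arange(n_frames)
    plat = bg_level + (plateau - bg_level) * np.exp(-bleach_rate * frames)
    signal = _logistic((tip[:, None] - p[None, :]) / edge_width)
    values = bg_level + (plat[:, None] - bg_level) * signal
    if bump_amp > 0:
        values += bump_amp * np.exp(
            -0.5 * ((p[None, :] - tip[:, None]) / bump_width) ** 2
        ) * signal
    if poisson:
        values = rng.poisson(np.maximum(values, 0)).astype(float)
    if noise_sd > 0:
        values = values + rng.normal(0.0, noise_sd, values.shape)
    kymo = Kymograph(values=values, dt=dt, dx=dx, channel=channel)
    truth = KymoGroundTruth(
        tip_px=tip,
        period_s=period,
        amp_um=amp,
        v_um_min=v,
        bg={channel or "signal": bg_level},
        edge_width_px=edge_width,
    )
    return kymo, truth


def simulate_ratiometric_pair(
    n_frames: int = 256,
    n_px: int = 256,
    dt: float = 4.0,
    dx: float = 0.22,
    v: float = 1.5,
    period: float = 48.0,
    amp: float = 0.4,
    edge_width: float = 1.0,
    cfp_plateau: float = 500.0,
    bgY: float = 150.0,
    bgC: float = 80.0,
    ratio_tip: float = 1.5,
    ratio_shank: float = 1.0,
    ratio_decay_um: float = 3.0,
    ratio_osc_amp: float = 0.0,
    noise_sd: float = 0.0,
    bleach_rate: float = 0.0,
    x0: float | None = None,
    seed: int = 0,
) -> tuple[Kymograph, Kymograph, KymoGroundTruth]:
    """Simulate a co-registered YFP/CFP pair with distinct backgrounds.

    The CFP channel carries the geometric signal S (logistic edge times
    bleach); the YFP channel is built as ``bgY + ratio_field * S`` so that
    ``(YFP - bgY) / (CFP - bgC) == ratio_field`` exactly in the noiseless
    case. The true ratio decays from ``ratio_tip`` at the apex to
    ``ratio_shank`` with length scale ``ratio_decay_um`` (a tip-focused
    gradient); ``ratio_osc_amp`` adds a tip-localized oscillation of the
    ratio in phase with growth.
    """
    rng = np.random.default_rng(seed)
    if x0 is None:
        # long tube: leave >= ~20 µm of shank behind the tip at frame 0
        x0 = 0.4 * n_px
    tip = tip_trajectory(n_frames, dt, dx, x0, v, period, amp)
    if tip.min() < 2 or tip.max() > n_px - 3:
        raise ValueError("tip trajectory leaves the field of view")
    p = np.arange(n_px)
    frames = np.arange(n_frames)
    t = frames * dt
    plat = (cfp_plateau - bgC) * np.exp(-bleach_rate * frames)
    S = plat[:, None] * _logistic((tip[:, None] - p[None, :]) / edge_width)
    dist_um = (tip[:, None] - p[None, :]) * dx  # >0 inside the cell
    ratio_field = ratio_shank + (ratio_tip - ratio_shank) * np.exp(
        -np.maximum(dist_um, 0.0) / ratio_decay_um
    )
    if ratio_osc_amp > 0:
        ratio_field = ratio_field + (
            ratio_osc_amp
            * np.sin(2 * np.pi * t / period)[:, None]
            * np.exp(-np.maximum(dist_um, 0.0) / ratio_decay_um)
        )
    cfp_vals = bgC + S
    yfp_vals = bgY + ratio_field * S
    if noise_sd > 0:
        cfp_vals = cfp_vals + rng.normal(0.0, noise_sd, cfp_vals.shape)
        yfp_vals = yfp_vals + rng.normal(0.0, noise_sd, yfp_vals.shape)
    truth_ratio = np.where(dist_um > 0, ratio_field, np.nan)
    yfp = Kymograph(values=yfp_vals, dt=dt, dx=dx, channel="YFP")
    cfp = Kymograph(values=cfp_vals, dt=dt, dx=dx, channel="CFP")
    truth = KymoGroundTruth(
        tip_px=tip,
        period_s=period,
        amp_um=amp,
        v_um_min=v,
        bg={"YFP": bgY, "CFP": bgC},
        ratio_field=truth_ratio,
        edge_width_px=edge_width,
    )
    return yfp, cfp, truth


def simulate_series_pair(
    n: int = 512,
    dt: float = 4.0,
    period: float = 48.0,
    amp: float = 1.0,
    lag: float = 4.0,
    ar1: float = 0.5,
    noise_sd: float = 0.2,
    n_outliers: int = 0,
    outlier_mag: float = 10.0,
    trend: tuple[float, ...] = (0.0,),
    jitter: float = 0.0,
    units: str = "",
    seed: int = 0,
) -> tuple[RawSeries, RawSeries, SeriesGroundTruth]:
    """Simulate two series sharing a sinusoid, the second delayed by ``lag``.

    x(t) = trend(t) + amp*sin(2*pi*t/period) + AR(1) noise;
    y(t) = trend(t) + amp*sin(2*pi*(t-lag)/period) + independent AR(1)
    noise. ``jitter`` perturbs the sample times of both series
    independently (uniform, +-jitter seconds) to emulate heterogeneous
    sampling. ``n_outliers`` gross outliers of magnitude +-outlier_mag
    (half adding, half subtracting) are injected into x at seeded
    positions away from the series ends.
    """
    if abs(ar1) >= 1:
        raise ValueError("|ar1| must be < 1")
    if lag >= period:
        raise ValueError("lag must be smaller than the period")
    rng = np.random.default_rng(seed)
    t = np.arange(n) * dt
    tx, ty = t.copy(), t.copy()
    if jitter > 0:
        tx = np.sort(t + rng.uniform(-jitter, jitter, n))
        ty = np.sort(t + rng.uniform(-jitter, jitter, n))
        tx, ty = _force_increasing(tx), _force_increasing(ty)
    trend_poly = np.polynomial.Polynomial(trend)

    def _ar1_noise() -> np.ndarray:
        if noise_sd == 0:
            return np.zeros(n)
        e = rng.normal(0.0, noise_sd * np.sqrt(1 - ar1**2), n)
        out = np.empty(n)
        out[0] = rng.normal(0.0, noise_sd)
        for i in range(1, n):
            out[i] = ar1 * out[i - 1] + e[i]
        return out

    clean_x = trend_poly(tx) + amp * np.sin(2 * np.pi * tx / period)
    clean_y = trend_poly(ty) + amp * np.sin(2 * np.pi * (ty - lag) / period)
    x = clean_x + _ar1_noise()
    y = clean_y + _ar1_noise()
    if n_outliers > 0:
        idx = rng.choice(np.arange(n // 10, n - n // 10), n_outliers, replace=False)
        sign = np.resize([1.0, -1.0], n_outliers)
        x[idx] += sign * outlier_mag
    else:
        idx = np.array([], dtype=int)
        sign = np.array([])
    truth = SeriesGroundTruth(
        period_s=period,
        amp=amp,
        lag_s=lag,
        clean_x=clean_x,
        clean_y=clean_y,
        outlier_idx=np.sort(idx),
        outlier_sign=sign[np.argsort(idx)] if n_outliers else sign,
    )
    return (
        RawSeries(t=tx, v=x, units=units),
        RawSeries(t=ty, v=y, units=units),
        truth,
    )


def _force_increasing(t: np.ndarray) -> np.ndarray:
    eps = 1e-9
    out = t.copy()
    for i in range(1, out.size):
        if out[i] <= out[i - 1]:
            out[i] = out[i - 1] + eps
    return out


def add_stripe_artifact(
    kymo: Kymograph, frame0: int, n_stripe_frames: int, magnitude: float
) -> Kymograph:
    """Add a bright horizontal block (refocusing/'kink' artefact) to a kymograph."""
    values = kymo.values.copy()
    values[frame0 : frame0 + n_stripe_frames, :] += magnitude
    return Kymograph(
        values=values, dt=kymo.dt, dx=kymo.dx, channel=kymo.channel, flipped=kymo.flipped
    )
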