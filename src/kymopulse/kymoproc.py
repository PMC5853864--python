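"""Kymograph processing: background, ratio, tip alignment, extraction.

Background is estimated from the pixels beyond the tip in every frame and
summarized by a tail quantile (default 99%); the cut-off is subtracted
per channel before forming the YFP/CFP ratio. Rows are then resampled
onto a distance-from-tip grid so that fluorescence series can be pulled
at fixed distances (tip, shank, or a scan along the tube). A separable
2-D discrete wavelet filter removes stripes, blocks, and slow drift from
single-channel kymographs.
"""

from __future__ import annotations

import numpy as np
import pywt

from .types import AlignedKymograph, BackgroundEstimate, Kymograph, RawSeries, TipTrace


def estimate_background(
    kymo: Kymograph,
    trace: TipTrace,
    margin_px: int = 3,
    quantile: float = 0.99,
) -> BackgroundEstimate:
    """Pool pixels strictly beyond tip+margin in every frame; take a tail quantile.

    The margin keeps the blurred edge out of the background sample.
    Frames whose tip estimate is missing, or that leave no room beyond
    the margin, contribute no samples; it is an error only if no frame
    does.
    """
    samples = []
    for i in range(kymo.n_frames):
        tip = trace.pos_px[i]
        if not np.isfinite(tip):
            continue
        start = int(np.ceil(tip)) + margin_px + 1
        if start < kymo.n_px:
            samples.append(kymo.values[i, start:])
    if not samples:
        raise ValueError("background region empty in every frame")
    pooled = np.concatenate(samples)
    cutoff = float(np.quantile(pooled, quantile))
    return BackgroundEstimate(samples=pooled, cutoff=cutoff, quantile=quantile)


def ratio_kymograph(
    yfp: Kymograph,
    cfp: Kymograph,
    bgY: float,
    bgC: float,
    floor: float = 1.0,
) -> Kymograph:
    """Background-subtracted ratio (YFP-bgY)/(CFP-bgC), masked where dim.

    Elements where the denominator CFP-bgC does not exceed ``floor`` are
    NaN, preventing ratio blow-up outside the cell.
    """
    if yfp.values.shape != cfp.values.shape:
        raise ValueError("channel shape mismatch")
    den = cfp.values - bgC
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(den > floor, (yfp.values - bgY) / den, np.nan)
    return Kymograph(values=ratio, dt=yfp.dt, dx=yfp.dx, channel="ratio")


def align_to_tip(kymo: Kymograph, trace: TipTrace) -> AlignedKymograph:
    """Resample each row onto a distance-from-tip grid (linear interpolation).

    Column k of the output holds the intensity at distance ``k*dx`` from
    the frame's (subpixel) tip estimate, oriented tip -> shank. Bins that
    fall outside the row, and frames with a missing tip, are NaN.
    """
    n_frames, n_px = kymo.values.shape
    dist_px = np.arange(n_px, dtype=float)
    out = np.full((n_frames, n_px), np.nan)
    px = np.arange(n_px, dtype=float)
    for i in range(n_frames):
        tip = trace.pos_px[i]
        if not np.isfinite(tip):
            continue
        sample_at = tip - dist_px  # walking from the tip into the cell
        inside = (sample_at >= 0) & (sample_at <= n_px - 1)
        row = kymo.values[i]
        if np.isnan(row).any():
            good = np.isfinite(row)
            if good.sum() < 2:
                continue
            vals = np.interp(sample_at[inside], px[good], row[good])
        else:
            vals = np.interp(sample_at[inside], px, row)
        out[i, inside] = vals
    return AlignedKymograph(values=out, dist_um=dist_px * kymo.dx, dt=kymo.dt)


def extract_region_series(
    ak: AlignedKymograph,
    center_um: float,
    width_um: float,
    stat: str = "median",
) -> RawSeries:
    """Per-frame summary of columns within width_um of center_um from the tip."""
    lo, hi = center_um - width_um / 2, center_um + width_um / 2
    cols = np.nonzero((ak.dist_um >= lo) & (ak.dist_um <= hi))[0]
    if cols.size == 0:
        raise ValueError(
            f"no distance bins in [{lo:.3g}, {hi:.3g}] µm (grid max "
            f"{ak.dist_um.max():.3g})"
        )
    block = ak.values[:, cols]
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        if stat == "median":
            v = np.nanmedian(block, axis=1)
        elif stat == "mean":
            v = np.nanmean(block, axis=1)
        else:
            raise ValueError(f"unknown stat {stat!r}")
    return RawSeries(t=ak.times, v=v)


def tip_shank_gradient(tip: RawSeries, shank: RawSeries) -> RawSeries:
    """Normalized tip-focused gradient (tip - shank)/shank per frame."""
    if tip.t.shape != shank.t.shape or not np.allclose(tip.t, shank.t):
        raise ValueError("tip and shank series must share a time base")
    if np.any(shank.v <= 0):
        raise ValueError("shank values must be positive for the normalized gradient")
    return RawSeries(t=tip.t, v=(tip.v - shank.v) / shank.v)


def scan_series_along_tube(
    ak: AlignedKymograph,
    start_um: float,
    stop_um: float,
    step_um: float,
    width_um: float,
    stat: str = "median",
) -> list[tuple[float, RawSeries]]:
    """Series at evenly spaced centres from tip to shank."""
    if not start_um < stop_um:
        raise ValueError("start_um must be < stop_um")
    centers = np.arange(start_um, stop_um + 1e-9, step_um)
    return [(float(c), extract_region_series(ak, c, width_um, stat)) for c in centers]


def filter_kymograph_2d(
    kymo: Kymograph,
    drop_fine_levels: int = 1,
    drop_coarse_levels: int = 1,
    wavelet: str = "sym4",
    level: int | None = None,
    drop_uniform: bool = True,
) -> Kymograph:
    """Band-limit a kymograph with a separable 2-D discrete wavelet transform.

    The matrix is decomposed to ``level`` scales (sym4, symmetric
    boundary) and reconstructed with the finest ``drop_fine_levels``
    detail scales zeroed and, when ``drop_coarse_levels`` > 0, the
    coarsest ``drop_coarse_levels`` detail scales *and* the smooth
    approximation zeroed. Dropping fine scales removes pixel noise;
    dropping coarse scales plus the smooth removes slow trends.

    Spatially uniform intensity transients — refocusing blocks,
    photobleaching steps, illumination 'kinks', all constant across a
    row — load exclusively the spatial-approximation x temporal-detail
    subbands. When trend removal is requested (``drop_coarse_levels`` >
    0) and ``drop_uniform`` is set, those subbands are zeroed at every
    level, removing such stripes at all temporal scales while leaving
    spatially structured signal untouched. With both drop counts at 0
    the transform is the identity.
    """
    values = kymo.values
    if level is None:
        level = min(
            pywt.dwtn_max_level(values.shape, wavelet), 5
        )
    if drop_fine_levels + drop_coarse_levels > level:
        raise ValueError(
            f"dropping {drop_fine_levels}+{drop_coarse_levels} levels exceeds "
            f"decomposition depth {level}"
        )
    coeffs = pywt.wavedec2(values, wavelet, mode="symmetric", level=level)
    # coeffs = [cA_L, (H_L, V_L, D_L), ..., (H_1, V_1, D_1)];
    # H = temporal detail x spatial approximation (row-constant structure)
    if drop_coarse_levels > 0:
        coeffs[0] = np.zeros_like(coeffs[0])
        for j in range(1, 1 + drop_coarse_levels):
            coeffs[j] = tuple(np.zeros_like(c) for c in coeffs[j])
        if drop_uniform:
            for j in range(1, len(coeffs)):
                h, v_, d_ = coeffs[j]
                coeffs[j] = (np.zeros_like(h), v_, d_)
    for j in range(len(coeffs) - drop_fine_levels, len(coeffs)):
        if j >= 1:
            coeffs[j] = tuple(np.zeros_like(c) for c in coeffs[j])
    rec = pywt.waverec2(coeffs, wavelet, mode="symmetric")
    rec = rec[: values.shape[0], : values.shape[1]]
    return Kymograph(
        values=rec, dt=kymo.dt, dx=kymo.dx, channel=kymo.channel, flipped=kymo.flipped
    )
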