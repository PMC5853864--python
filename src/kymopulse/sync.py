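"""Cross-wavelet synchronization between two concurrent series.

Two series measured simultaneously (e.g. growth rate and extracellular
proton flux) are matched onto a common regular grid and band-filtered,
then combined as W_xy = W_x * conj(W_y). Regions of high joint power
reveal shared periodicity; the argument of W_xy is the local phase
difference Delta_phi = phi_x - phi_y, which at a given period P converts
to a time delay Delta_phi / (2*pi) * P. Sign convention, printed in
every output header: positive delay (and positive phase) means the FIRST
series leads — it occurs before the second.

Joint significance uses the distribution of the product of two chi-square
backgrounds: under independent red-noise nulls, |W_xy| exceeds
sigma_x*sigma_y*sqrt(Px*Py)*Z/2 with probability alpha, where Z solves
Z*K1(Z) = alpha (K1 the modified Bessel function; Z = 3.999 at alpha =
0.05, the standard tabulated value).
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import brentq
from scipy.special import k1

from . import tsprep, wavelets
from .types import CrossSpectrum, CwtSpectrum, DelaySeries, RawSeries, RidgeSet, UniformSeries

SIGN_CONVENTION = "positive delay: first series leads (occurs before) the second"


def match_series(
    a: RawSeries,
    b: RawSeries,
    dt_target: float | None = None,
    period_min: float = 16.0,
    period_max: float = 128.0,
    span: float = 0.05,
    n_levels: int | None = None,
) -> tuple[UniformSeries, UniformSeries]:
    """Regularize two series onto one grid over their overlap, then band-filter.

    Both series are loess-interpolated onto the identical regular grid
    covering the time overlap (step ``dt_target``, default the coarser of
    the two median steps) and band-filtered to the shared period band by
    multiresolution selection.
    """
    lo = max(a.t[0], b.t[0])
    hi = min(a.t[-1], b.t[-1])
    if hi <= lo:
        raise ValueError("series do not overlap in time")
    if dt_target is None:
        dt_target = float(
            max(np.median(np.diff(a.t)), np.median(np.diff(b.t)))
        )
    n = int(np.floor((hi - lo) / dt_target)) + 1
    if n < 32:
        raise ValueError(f"overlap holds only {n} samples at dt={dt_target}")
    grid = lo + np.arange(n) * dt_target

    out = []
    for rs in (a, b):
        from ._loess import loess

        sp = max(span, 7.0 / len(rs))
        v = loess(rs.t, rs.v, grid, span=min(sp, 1.0), degree=2)
        us = UniformSeries(t0=lo, dt=dt_target, v=v, units=rs.units)
        if n_levels is None:
            J = min(int(np.log2(n)) - 2, int(np.ceil(np.log2(period_max / dt_target))))
        else:
            J = n_levels
        d = wavelets.mra(us, n_levels=max(J, 3))
        filt, _ = wavelets.bandpass(d, period_min, period_max, t0=lo)
        out.append(filt)
    return out[0], out[1]


def _cross_quantile(alpha: float) -> float:
    """Z with P(|W_xy| normalized > Z) = alpha: solves Z*K1(Z) = alpha."""
    return float(brentq(lambda z: z * k1(z) - alpha, 1e-6, 50.0))


def xwt(
    a: UniformSeries,
    b: UniformSeries,
    dj: float = 1 / 12,
    s0: float | None = None,
    J: int | None = None,
    omega0: float = 6.0,
    alpha: float = 0.05,
) -> CrossSpectrum:
    """Cross-wavelet transform W_a * conj(W_b) with joint significance."""
    if a.n != b.n or a.dt != b.dt or a.t0 != b.t0:
        raise ValueError("series must share one time grid")
    sa = wavelets.cwt(a, dj=dj, s0=s0, J=J, omega0=omega0)
    sb = wavelets.cwt(b, dj=dj, s0=s0, J=J, omega0=omega0)
    Wxy = sa.W * np.conj(sb.W)
    xpower = np.abs(Wxy)
    phase = np.angle(Wxy)
    Pa = wavelets.red_noise_spectrum(sa.ar1, sa.periods, sa.dt)
    Pb = wavelets.red_noise_spectrum(sb.ar1, sb.periods, sb.dt)
    Z = _cross_quantile(alpha)
    level = np.sqrt(sa.var * sb.var) * np.sqrt(Pa * Pb) * Z / 2
    signif = xpower > level[:, None]
    return CrossSpectrum(
        xpower=xpower,
        phase=phase,
        periods=sa.periods,
        times=sa.times,
        coi=sa.coi,
        Wxy=Wxy,
        scales=sa.scales,
        dt=sa.dt,
        omega0=omega0,
        signif=signif,
        alpha=alpha,
    )


def _as_cwt_view(xs: CrossSpectrum) -> CwtSpectrum:
    """Present cross power as a CwtSpectrum so the single-series
    peak-finder can extract joint ridges."""
    return CwtSpectrum(
        power=xs.xpower,
        periods=xs.periods,
        times=xs.times,
        coi=xs.coi,
        W=np.sqrt(xs.Wxy + 0j),
        scales=xs.scales,
        dt=xs.dt,
        omega0=xs.omega0,
        var=1.0,
        ar1=0.0,
        signif=xs.signif,
        alpha=xs.alpha,
    )


def joint_ridges(
    xs: CrossSpectrum, min_power_frac: float = 0.01, max_per_time: int = 1
) -> RidgeSet:
    """Ridges of the cross power surface (same peak-finder as single series)."""
    return wavelets.extract_ridges(
        _as_cwt_view(xs), min_power_frac=min_power_frac, max_per_time=max_per_time
    )


def phase_to_delay(xs: CrossSpectrum, ridges: RidgeSet) -> DelaySeries:
    """Convert joint-ridge phases to per-time delays.

    delay = Delta_phi / (2*pi) * period, wrapped into (-period/2,
    period/2]. Positive delay: the first series leads.
    """
    pts = ridges.points
    if pts.shape[0] == 0:
        return DelaySeries(
            t=np.array([]), delay=np.array([]), period_at=np.array([]), relamp=np.array([])
        )
    t_idx = np.searchsorted(xs.times, pts[:, 0])
    p_idx = np.array(
        [int(np.argmin(np.abs(xs.periods - p))) for p in pts[:, 1]]
    )
    phi = xs.phase[p_idx, np.clip(t_idx, 0, xs.times.size - 1)]
    period = pts[:, 1]
    delay = phi / (2 * np.pi) * period
    half = period / 2
    delay = np.where(delay > half, delay - period, delay)
    delay = np.where(delay <= -half, delay + period, delay)
    relamp = pts[:, 2] / pts[:, 2].max()
    return DelaySeries(t=pts[:, 0], delay=delay, period_at=period, relamp=relamp)


def circular_mean_resultant(phases: np.ndarray) -> tuple[float, float]:
    """Circular mean angle and resultant length R of a phase sample."""
    z = np.mean(np.exp(1j * np.asarray(phases)))
    return float(np.angle(z)), float(np.abs(z))


def phase_histogram(
    xs: CrossSpectrum, ridges: RidgeSet, n_bins: int = 16
) -> dict:
    """Binned circular distribution of joint-ridge phases.

    Returns bin edges/counts plus the circular mean and resultant length
    R (1 for perfectly locked phases, ~0 for uniform).
    """
    pts = ridges.points
    if pts.shape[0] < 10:
        raise ValueError("need at least 10 ridge points for a phase histogram")
    t_idx = np.clip(np.searchsorted(xs.times, pts[:, 0]), 0, xs.times.size - 1)
    p_idx = np.array([int(np.argmin(np.abs(xs.periods - p))) for p in pts[:, 1]])
    phases = xs.phase[p_idx, t_idx]
    edges = np.linspace(-np.pi, np.pi, n_bins + 1)
    counts, _ = np.histogram(phases, bins=edges)
    mean, R = circular_mean_resultant(phases)
    return {
        "bin_edges": edges,
        "counts": counts,
        "circular_mean": mean,
        "resultant_length": R,
        "n": int(phases.size),
        "phases": phases,
        "sign_convention": SIGN_CONVENTION,
    }


def synchrony_flag(
    xs: CrossSpectrum,
    ridges: RidgeSet,
    window: float = 60.0,
    tol: float = 0.5,
    min_signif_frac: float = 0.8,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-window synchronization flags.

    A window is synchronized when the circular SD of its joint-ridge
    phases is below ``tol`` radians and joint ridges (which are by
    construction significant and outside the cone) cover more than
    ``min_signif_frac`` of the window's time points. Only ridge points
    with period at most ``window/2`` count: a window shorter than two
    cycles cannot attest a stable phase relationship, and long-period
    cross-power patches of independent noise would otherwise pass.
    Returns (window start times, boolean flags).
    """
    t0, t1 = xs.times[0], xs.times[-1]
    starts = np.arange(t0, t1, window)
    pts = ridges.points
    if pts.shape[0]:
        pts = pts[pts[:, 1] <= window / 2]
    if pts.shape[0]:
        t_idx = np.clip(np.searchsorted(xs.times, pts[:, 0]), 0, xs.times.size - 1)
        p_idx = np.array([int(np.argmin(np.abs(xs.periods - p))) for p in pts[:, 1]])
        phases_all = xs.phase[p_idx, t_idx]
    flags = np.zeros(starts.size, dtype=bool)
    for w, ws in enumerate(starts):
        we = ws + window
        in_w = (xs.times >= ws) & (xs.times < we)
        if in_w.sum() == 0 or pts.shape[0] == 0:
            continue
        sel = (pts[:, 0] >= ws) & (pts[:, 0] < we)
        coverage = np.unique(pts[sel, 0]).size / in_w.sum()
        if sel.sum() < 3:
            continue
        _, R = circular_mean_resultant(phases_all[sel])
        circ_sd = np.sqrt(max(0.0, -2 * np.log(max(R, 1e-12))))
        flags[w] = (circ_sd < tol) and (coverage > min_signif_frac)
    return starts, flags
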