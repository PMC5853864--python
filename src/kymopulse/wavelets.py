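"""Discrete multiresolution band filtering and continuous Morlet spectra.

The discrete side uses a shift-invariant (stationary) wavelet transform
to split a series additively into dyadic detail bands D_j, each with
nominal period band (2^j*dt, 2^(j+1)*dt], plus a smooth trend S_J;
selecting bands acts as a band-pass filter that simultaneously smooths
(discarding fine details) and detrends (discarding the smooth and coarse
details).

The continuous side implements the Morlet (omega0 = 6) wavelet transform
on log-spaced scales with the standard FFT algorithm, normalized so that
the expected power of white noise equals the series variance at every
scale. Significance is tested pointwise against a variance-matched
red-noise (lag-1 autoregressive) background spectrum scaled by chi-square
quantiles; the cone of influence marks the periods at which wavelet
e-folding reaches the series edge. Wavelet ridges — per-time local power
maxima across scale, restricted to significant cells outside the cone —
give time-resolved period and amplitude estimates.
"""

from __future__ import annotations

import numpy as np
import pywt
from scipy import stats as sstats

from .types import CwtSpectrum, MraDecomposition, RidgeSet, UniformSeries

DEFAULT_FILTER = "sym4"  # 8-tap least-asymmetric


# ---------------------------------------------------------------------------
# discrete multiresolution analysis

def mra(
    us: UniformSeries, n_levels: int = 5, filter: str = DEFAULT_FILTER
) -> MraDecomposition:
    """Additive shift-invariant multiresolution analysis.

    The input is reflection-padded to a multiple of 2^n_levels (the
    stationary transform requires it), decomposed, and trimmed back.
    Detail level j captures the nominal period band (2^j*dt, 2^(j+1)*dt].
    """
    n = us.n
    if n < 2**n_levels:
        raise ValueError(f"n_levels={n_levels} too deep for n={n}")
    block = 2**n_levels
    n_pad = int(np.ceil(n / block)) * block
    pad = n_pad - n
    x = np.concatenate([us.v, us.v[-2 : -2 - pad : -1]]) if pad else us.v
    comps = pywt.mra(x, filter, level=n_levels, transform="swt")
    # pywt orders [S_J, D_J, ..., D_1]; store D_1..D_J
    smooth = comps[0][:n]
    details = [comps[-(j)][:n] for j in range(1, n_levels + 1)]
    return MraDecomposition(details=details, smooth=smooth, dt=us.dt, filter=filter)


def select_levels(
    d: MraDecomposition, period_min: float, period_max: float
) -> list[int]:
    """Detail levels (1-based) whose nominal band intersects the open band.

    Level j is kept iff 2^j*dt < period_max and 2^(j+1)*dt > period_min,
    so a band whose lower edge coincides with a level's upper band edge
    does not drag that level in.
    """
    out = [
        j
        for j in range(1, d.n_levels + 1)
        if 2.0**j * d.dt < period_max and 2.0 ** (j + 1) * d.dt > period_min
    ]
    return out


def bandpass(
    d: MraDecomposition,
    period_min: float,
    period_max: float,
    keep_trend: bool = False,
    t0: float = 0.0,
) -> tuple[UniformSeries, UniformSeries]:
    """Sum the detail levels inside a period band; return (filtered, trend).

    The trend is the smooth plus every detail level coarser than the
    band; it is added back into the filtered series when ``keep_trend``.
    """
    levels = select_levels(d, period_min, period_max)
    if not levels:
        raise ValueError(
            f"no detail level overlaps [{period_min}, {period_max}] s at dt={d.dt}"
        )
    filt = np.sum([d.details[j - 1] for j in levels], axis=0)
    coarse = [j for j in range(max(levels) + 1, d.n_levels + 1)]
    trend = d.smooth + (
        np.sum([d.details[j - 1] for j in coarse], axis=0) if coarse else 0.0
    )
    if keep_trend:
        filt = filt + trend
    return (
        UniformSeries(t0=t0, dt=d.dt, v=filt),
        UniformSeries(t0=t0, dt=d.dt, v=trend),
    )


# ---------------------------------------------------------------------------
# continuous Morlet transform

def _morlet_fourier_factor(omega0: float) -> float:
    return 4 * np.pi / (omega0 + np.sqrt(2 + omega0**2))


def _lag1_autocorr(x: np.ndarray) -> float:
    """Lag-1 autocorrelation after removing a linear trend."""
    t = np.arange(x.size)
    x = x - np.polyval(np.polyfit(t, x, 1), t)
    denom = float(np.dot(x, x))
    if denom == 0:
        return 0.0
    return float(np.clip(np.dot(x[:-1], x[1:]) / denom, -0.999, 0.999))


def cwt(
    us: UniformSeries,
    dj: float = 1 / 12,
    s0: float | None = None,
    J: int | None = None,
    omega0: float = 6.0,
) -> CwtSpectrum:
    """Continuous Morlet wavelet transform on log-spaced scales.

    Scales are ``s0 * 2**(j*dj)``, ``j = 0..J``, by default from 2*dt up
    to the scale whose Fourier-equivalent period is a quarter of the
    series length. The series is zero-padded to the next power of two;
    the cone of influence (``coi``, in period units) makes the resulting
    edge effects explicit. The caller is expected to have detrended /
    band-filtered the input.
    """
    x = us.v
    n = x.size
    if n < 32:
        raise ValueError("need at least 32 samples for the continuous transform")
    dt = us.dt
    ff = _morlet_fourier_factor(omega0)
    if s0 is None:
        s0 = 2 * dt
    if J is None:
        s_max = (n * dt / 4) / ff
        J = max(1, int(np.ceil(np.log2(s_max / s0) / dj)))
    scales = s0 * 2.0 ** (dj * np.arange(J + 1))
    var = float(np.var(x))
    ar1 = _lag1_autocorr(x)

    x0 = x - x.mean()
    n_pad = int(2 ** np.ceil(np.log2(n)))
    xp = np.concatenate([x0, np.zeros(n_pad - n)])
    k = np.fft.fftfreq(n_pad, d=dt) * 2 * np.pi  # angular frequencies
    xhat = np.fft.fft(xp)
    W = np.empty((scales.size, n), dtype=complex)
    pos = k > 0
    for i, s in enumerate(scales):
        psi_hat = np.zeros(n_pad)
        psi_hat[pos] = (
            np.sqrt(2 * np.pi * s / dt)
            * np.pi**-0.25
            * np.exp(-0.5 * (s * k[pos] - omega0) ** 2)
        )
        W[i] = np.fft.ifft(xhat * psi_hat)[:n]
    periods = ff * scales
    t_rel = np.minimum(np.arange(n), np.arange(n)[::-1]) * dt
    coi = ff / np.sqrt(2) * np.maximum(t_rel, dt * 1e-6)
    return CwtSpectrum(
        power=np.abs(W) ** 2,
        periods=periods,
        times=us.t,
        coi=coi,
        W=W,
        scales=scales,
        dt=dt,
        omega0=omega0,
        var=var,
        ar1=ar1,
    )


def red_noise_spectrum(ar1: float, periods: np.ndarray, dt: float) -> np.ndarray:
    """Normalized lag-1 autoregressive background spectrum at the given periods."""
    freq = dt / periods  # cycles per sample
    return (1 - ar1**2) / (1 + ar1**2 - 2 * ar1 * np.cos(2 * np.pi * freq))


def significance(spec: CwtSpectrum, alpha: float = 0.05) -> CwtSpectrum:
    """Pointwise red-noise significance mask at level ``alpha``.

    Power is compared to the variance-matched autoregressive background
    spectrum scaled by the chi-square(2) quantile at 1-alpha: under the
    null each |W|^2 is background * chi2_2 / 2.
    """
    Pk = red_noise_spectrum(spec.ar1, spec.periods, spec.dt)
    threshold = spec.var * Pk * sstats.chi2.ppf(1 - alpha, 2) / 2
    spec.signif = spec.power > threshold[:, None]
    spec.alpha = alpha
    return spec


def _morlet_amplitude(W_abs: np.ndarray, scales: np.ndarray, dt: float) -> np.ndarray:
    """Oscillation envelope implied by a Morlet coefficient magnitude.

    For x = A*sin(2*pi*t/P), |W| at the matching scale is
    (A/2) * pi^(-1/4) * sqrt(2*pi*s/dt), so A = 2*|W|*pi^(1/4) /
    sqrt(2*pi*s/dt).
    """
    return 2 * W_abs * np.pi**0.25 / np.sqrt(2 * np.pi * scales / dt)


def extract_ridges(
    spec: CwtSpectrum,
    min_power_frac: float = 0.01,
    max_per_time: int = 2,
) -> RidgeSet:
    """Per-time local maxima of power along the period axis.

    Candidates must be significant, outside the cone of influence, and
    carry at least ``min_power_frac`` of the global power maximum; at
    most ``max_per_time`` ridges (highest power first) are kept per time
    point.
    """
    if spec.signif is None:
        raise ValueError("run significance() before ridge extraction")
    P = spec.power
    n_s, n_t = P.shape
    inside = spec.periods[:, None] <= spec.coi[None, :]
    ok = spec.signif & inside
    gmax = P.max() if P.size else 0.0
    ok &= P >= min_power_frac * gmax
    # local maxima along the period axis
    local = np.ones_like(P, dtype=bool)
    local[1:, :] &= P[1:, :] >= P[:-1, :]
    local[:-1, :] &= P[:-1, :] > P[1:, :]
    cand = ok & local
    points = []
    amps = _morlet_amplitude(np.abs(spec.W), spec.scales[:, None] * np.ones((1, n_t)), spec.dt)
    for j in range(n_t):
        rows = np.nonzero(cand[:, j])[0]
        if rows.size == 0:
            continue
        rows = rows[np.argsort(P[rows, j])[::-1][:max_per_time]]
        for i in rows:
            points.append((spec.times[j], spec.periods[i], P[i, j], amps[i, j]))
    valid = spec.coi >= spec.periods.min()
    return RidgeSet(
        points=np.asarray(points, dtype=float).reshape(-1, 4),
        times=spec.times,
        valid_times=valid,
    )


def detection_proportion(ridges: RidgeSet, spec: CwtSpectrum | None = None) -> float:
    """Fraction of trustworthy (outside-cone) time points with >= 1 ridge."""
    valid = ridges.valid_times
    if valid.sum() == 0:
        return 0.0
    return float((ridges.has_ridge() & valid).sum() / valid.sum())


def link_ridges(ridges: RidgeSet, dj: float = 1 / 12, max_jump_steps: int = 2) -> list[np.ndarray]:
    """Greedy nearest-period linking of ridge points into bouts.

    Consecutive-time ridge points are chained when their log2-period jump
    is at most ``max_jump_steps`` scale steps; maximal chains (bouts) are
    returned as arrays of point indices.
    """
    pts = ridges.points
    if pts.shape[0] == 0:
        return []
    order = np.lexsort((pts[:, 1], pts[:, 0]))
    times = np.unique(pts[order, 0])
    tstep = np.min(np.diff(times)) if times.size > 1 else 0
    chains: list[list[int]] = []
    open_chains: list[list[int]] = []
    for tval in times:
        idx_now = order[pts[order, 0] == tval]
        used = set()
        new_open = []
        for ch in open_chains:
            last = pts[ch[-1]]
            if tval - last[0] > 1.5 * tstep:
                chains.append(ch)
                continue
            best, best_d = None, np.inf
            for i in idx_now:
                if i in used:
                    continue
                dlog = abs(np.log2(pts[i, 1]) - np.log2(last[1]))
                if dlog <= max_jump_steps * dj and dlog < best_d:
                    best, best_d = i, dlog
            if best is None:
                chains.append(ch)
            else:
                used.add(best)
                new_open.append(ch + [best])
        for i in idx_now:
            if i not in used:
                new_open.append([i])
        open_chains = new_open
    chains.extend(open_chains)
    return [np.asarray(c) for c in chains]
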