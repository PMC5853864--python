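"""Shared container types for the pipeline.

All containers are plain dataclasses over numpy arrays. Conventions:

* kymographs are indexed ``(frame, pixel)`` — rows are time, columns space;
* after orientation normalization the cell sits at low column indices and
  the background at high ones;
* coordinates are 0-based with pixel centres at integer positions, so a
  subpixel tip location is a real number on that grid;
* internal units are seconds and micrometres; growth rates are reported in
  µm/min.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class Kymograph:
    """A time x space fluorescence matrix with acquisition calibration.

    Parameters
    ----------
    values : ndarray, shape (n_frames, n_px)
        Fluorescence intensities, arbitrary units, float.
    dt : float
        Frame interval in seconds.
    dx : float
        Pixel size in micrometres.
    channel : str
        Channel label, e.g. ``"YFP"``, ``"CFP"``, ``"ratio"``.
    flipped : bool
        True if columns were reversed on read to put the cell at low
        indices.
    """

    values: np.ndarray
    dt: float
    dx: float
    channel: str = ""
    flipped: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.size == 0:
            raise ValueError("kymograph values must be a non-empty 2-D matrix")
        if not (self.dt > 0 and self.dx > 0):
            raise ValueError("dt and dx must be positive")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_px(self) -> int:
        return self.values.shape[1]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.dt


@dataclass
class RawSeries:
    """A possibly irregularly sampled time series.

    ``t`` is strictly increasing, in seconds; ``v`` carries the declared
    ``units`` (µm/min, pmol cm^-2 s^-1, ratio units, ...).
    """

    t: np.ndarray
    v: np.ndarray
    units: str = ""

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.t.shape != self.v.shape or self.t.ndim != 1:
            raise ValueError("t and v must be 1-D arrays of equal length")
        if self.t.size >= 2 and not np.all(np.diff(self.t) > 0):
            raise ValueError("t must be strictly increasing")

    def __len__(self) -> int:
        return self.t.size


@dataclass
class UniformSeries:
    """A regularly sampled series with implied times ``t0 + i*dt``."""

    t0: float
    dt: float
    v: np.ndarray
    units: str = ""

    def __post_init__(self) -> None:
        self.v = np.asarray(self.v, dtype=float)
        if self.v.ndim != 1:
            raise ValueError("v must be 1-D")
        if not self.dt > 0:
            raise ValueError("dt must be positive")

    @property
    def n(self) -> int:
        return self.v.size

    @property
    def t(self) -> np.ndarray:
        return self.t0 + np.arange(self.n) * self.dt

    def __len__(self) -> int:
        return self.v.size


@dataclass
class TipTrace:
    """Per-frame tip position estimates.

    ``pos_px`` is real-valued for the regression method and integer-valued
    (stored as float) for the threshold method; missing detections are NaN.
    """

    t: np.ndarray
    pos_px: np.ndarray
    dx: float
    method: str = "regression"
    smoothed: bool = False

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.pos_px = np.asarray(self.pos_px, dtype=float)
        if self.t.shape != self.pos_px.shape:
            raise ValueError("t and pos_px must have equal length")

    @property
    def pos_um(self) -> np.ndarray:
        return self.pos_px * self.dx

    def __len__(self) -> int:
        return self.t.size


@dataclass
class GrowthSeries:
    """Growth-rate series in µm/min, timestamped at frame midpoints."""

    t: np.ndarray
    rate: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.rate = np.asarray(self.rate, dtype=float)

    def __len__(self) -> int:
        return self.t.size


@dataclass
class AlignedKymograph:
    """Kymograph resampled to fixed distances from the tip.

    Column ``k`` holds, in every frame, the intensity at distance
    ``dist_um[k]`` from that frame's tip estimate (0 at the tip, increasing
    into the cell). Bins beyond a row's extent are NaN.
    """

    values: np.ndarray
    dist_um: np.ndarray
    dt: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.dist_um = np.asarray(self.dist_um, dtype=float)

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.values.shape[0]) * self.dt


@dataclass
class BackgroundEstimate:
    """Background intensity distribution and its quantile cut-off."""

    samples: np.ndarray
    cutoff: float
    quantile: float


@dataclass
class MraDecomposition:
    """Additive multiresolution decomposition of a uniform series.

    ``details[j-1]`` is detail level D_j with nominal period band
    ``(2^j*dt, 2^(j+1)*dt]`` seconds; ``smooth`` is the residual trend S_J.
    The levels and the smooth sum back to the input.
    """

    details: list[np.ndarray]
    smooth: np.ndarray
    dt: float
    filter: str

    @property
    def n_levels(self) -> int:
        return len(self.details)

    def band(self, level: int) -> tuple[float, float]:
        """Nominal period band (lo, hi] in seconds of detail level `level` (1-based)."""
        return (2.0**level * self.dt, 2.0 ** (level + 1) * self.dt)

    def reconstruct(self) -> np.ndarray:
        return np.sum(self.details, axis=0) + self.smooth


@dataclass
class CwtSpectrum:
    """Continuous Morlet wavelet power over (period, time).

    ``power[i, j]`` is |W|^2 at ``periods[i]``, ``times[j]``. ``coi`` gives
    the largest trustworthy period at each time; ``signif`` is the boolean
    red-noise significance mask (None until tested); ``ar1`` is the lag-1
    autocorrelation used for the red-noise null.
    """

    power: np.ndarray
    periods: np.ndarray
    times: np.ndarray
    coi: np.ndarray
    W: np.ndarray
    scales: np.ndarray
    dt: float
    omega0: float
    var: float
    ar1: float
    signif: np.ndarray | None = None
    alpha: float | None = None


@dataclass
class RidgeSet:
    """Per-time local power maxima (wavelet ridges).

    Each row of ``points`` is (time_s, period_s, power, amplitude); the
    amplitude is the oscillation envelope implied by the Morlet coefficient
    magnitude.
    """

    points: np.ndarray  # shape (n, 4)
    times: np.ndarray   # full time grid of the parent spectrum
    valid_times: np.ndarray  # boolean: time points outside the coi

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 4)

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    def has_ridge(self) -> np.ndarray:
        """Boolean per time point of the parent grid: at least one ridge."""
        out = np.zeros(self.times.size, dtype=bool)
        if self.n_points:
            idx = np.searchsorted(self.times, self.points[:, 0])
            idx = np.clip(idx, 0, self.times.size - 1)
            out[idx] = True
        return out


@dataclass
class CrossSpectrum:
    """Cross-wavelet transform of two series on a shared grid.

    ``xpower`` is |W_xy|; ``phase`` is the local phase difference
    phi_x - phi_y in (-pi, pi]. Positive phase at a period P means the
    first series leads the second there.
    """

    xpower: np.ndarray
    phase: np.ndarray
    periods: np.ndarray
    times: np.ndarray
    coi: np.ndarray
    Wxy: np.ndarray
    scales: np.ndarray
    dt: float
    omega0: float
    signif: np.ndarray | None = None
    alpha: float | None = None


@dataclass
class DelaySeries:
    """Time-resolved delay between two series at the joint-ridge period.

    Positive delay means the first series leads (occurs before) the
    second. ``relamp`` is cross power normalized by its maximum.
    """

    t: np.ndarray
    delay: np.ndarray
    period_at: np.ndarray
    relamp: np.ndarray


@dataclass
class MixtureFit:
    """Two-component univariate Gaussian mixture summary."""

    means: np.ndarray
    sds: np.ndarray
    weights: np.ndarray
    main: int
    loglik: float
    seed: int

    @property
    def main_mean(self) -> float:
        return float(self.means[self.main])

    @property
    def main_sd(self) -> float:
        return float(self.sds[self.main])


@dataclass
class PairedDetectionTable:
    """2x2 paired detection counts over shared time points."""

    both: int
    a_only: int
    b_only: int
    neither: int

    @property
    def total(self) -> int:
        return self.both + self.a_only + self.b_only + self.neither
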