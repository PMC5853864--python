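# Methods

This note documents the models, estimators, numerical choices, and
default parameters behind kymopulse, and what the synthetic study
conditions do and do not establish about real data.

## Kymograph model and coordinates

A kymograph is a matrix indexed `(frame, pixel)`: each row is the
fluorescence profile along a line through the cell midline at one time
point. Calibration is `dt` (frame interval, seconds) and `dx` (pixel
size, micrometres). Pixels are 0-based with centres on integers;
subpixel positions are real numbers on this grid. On read, orientation
is normalized so the cell occupies low column indices (first frame: the
left 10% of columns must be at least as bright as the right 10%,
otherwise columns are reversed and the flip recorded). If a
space × time matrix is supplied (ImageJ Multiple Kymograph), it is
transposed when the caller states the frame count. Intensities are
arbitrary; everything is float internally.

## Tip detection

**Threshold method (comparison baseline).** Scanning from background
toward the cell, the boundary pixel is the largest index whose
intensity meets the threshold (default: midpoint of the 10th and 99th
intensity percentiles of the frame). Resolution is one pixel, so the
error cannot fall below the quantization floor 1/√12 ≈ 0.29 px, and the
differenced growth rate inherits step artefacts.

**Regression method (featured).** The profile is lightly smoothed
(moving average, default 3 px). An ordinary least-squares line is
fitted in every sliding window of half-width `fit_halfwidth` (default
2 px, i.e. 5-px windows) between the profile maximum and the background
side; the window whose fitted slope is the steepest descent wins (ties
break toward the background). The tip estimate is where that line
crosses a reference level. Evaluating the fitted slope in whole windows
rather than picking the most negative single first-difference is what
makes the edge localization robust at realistic noise: a pointwise pick
is dominated by single-pixel noise excursions at contrast-to-noise 10.

*Reference level.* When tracking a kymograph the default crossing level
is the frame's mid-edge level — the midpoint of the plateau estimate
(median of the first 10% of columns) and the background estimate
(median of the last 10%). A mid-edge crossing keeps the intersection
inside the fit window, so slope noise is not amplified by
extrapolation, and it is unbiased for a symmetric edge. Passing
`ref_level` explicitly localizes any other landmark: with `ref_level`
at background (0 after background subtraction), the estimator returns
the tangent's background-contact point, which for a logistic edge of
centre `c` and scale `w` is exactly `c + 2w`. Landmark choices shift
all frames by a constant, which cancels in growth-rate and oscillation
analysis; tracking precision is therefore quoted as RMSE after removing
the mean offset.

*Precision.* On the standard synthetic condition (logistic edge of
scale 1 px, contrast-to-noise 10, 1000 frames) the regression detector
attains ≈ 0.28 px RMSE versus ≈ 0.50 px for thresholding. For
comparison, the maximum-likelihood bound for this condition is
≈ 0.25 px, so the line fit operates near the information limit. The
bound scales as √w with edge scale: no estimator can deliver
subpixel-floor precision from a heavily blurred edge at this noise
level.

**Trace smoothing.** A tricube-weighted local quadratic (loess,
degree 2) smooths the trace on the assumption that the tip makes no
sudden jumps; the default span covers ≈ 20 points so that genuine
oscillations are attenuated as little as possible. Smoothing always
trades amplitude for noise: the amplitude of the smoothed trace is
non-increasing in the span, and the tests verify this monotonicity.
Missing frames are filled by the local fit.

**Growth rate.** First differences, `(x̂_{i+1} − x̂_i)·dx/dt·60`
µm/min, timestamped at frame midpoints.

## Ratiometric processing

Tip detection runs on the strongest channel (highest median intensity);
the same trace serves both channels, which are assumed co-registered as
acquired. Background samples are all pixels beyond `tip + margin`
(default margin 3 px, excluding the blurred edge) pooled over frames;
the subtraction value is the tail quantile (default 99%) of that
distribution, deliberately sitting above the background mean so that
residual background maps to ≈ 0 after subtraction. The ratio
`(YFP − bg_Y)/(CFP − bg_C)` is computed only where the denominator
exceeds a floor (default 1 intensity unit); other elements propagate as
missing.

Alignment resamples each row by linear interpolation onto the distance
grid `d_k = k·dx` from the frame's subpixel tip estimate, oriented
tip → shank; region series take the per-frame median (or mean) over a
width window. Defaults for the tip/shank contrast: ~1.1 µm windows at
2.2 µm and 19.4 µm. The distance step equals `dx` — no resampling finer
than acquisition.

**2-D wavelet filter.** Single-channel kymographs can be cleaned with a
separable 2-D discrete wavelet decomposition (8-tap least-asymmetric
filter, symmetric boundary). Fine detail scales (default 1) remove
pixel noise; when trend removal is requested, the coarsest scales plus
the smooth are zeroed, and additionally the spatially-uniform subband
family (spatial approximation × temporal detail) at every level. The
latter is the exact home of row-constant artefacts — refocusing blocks,
bleaching ramps and steps, illumination "kinks" — which are temporally
broadband and therefore not removable by coarse-scale zeroing alone.
The cost is insensitivity to truly space-uniform signal, which in a
tip-aligned kymograph is not where the biology lives.

## Series preparation

`regularize` interpolates a possibly irregular series onto a regular
grid (default step: median observed step) with loess (degree 2, tricube
weights); local quadratics reproduce polynomials up to degree 2 exactly
and commute with affine transforms of the values.

`remove_outliers` flags points whose residual from a running median
(window 11) exceeds `mad_k` (default 5) times the MAD of the residuals,
and restores them from a local quadratic fit through the unflagged
points. Gross spikes must be repaired *before* loess regularization —
interpolation smears a spike across its neighbourhood and below the
detection threshold — so the standard chain (`prepare`, and the `prep`
CLI) runs the MAD repair on the raw samples first. The `model` method
additionally scans standardized AR(1) innovations for level shifts;
shifts are reported but never corrected, because an abrupt persistent
change in a live-cell series may be biology rather than artefact. With
more than half the points flagged the call errors out (`mad_k` too
small).

## Discrete multiresolution band filter

The shift-invariant (stationary/maximal-overlap style) transform with
the 8-tap least-asymmetric filter decomposes a series additively into
detail levels `D_j` — nominal period band `(2^j·dt, 2^{j+1}·dt]` — plus
a smooth trend; additivity holds to 1e-8 or better. The input is
reflection-padded to a multiple of `2^J` and trimmed after.

Band selection keeps level `j` iff `2^j·dt < period_max` **and**
`2^{j+1}·dt > period_min`. The strict inequalities matter: at dt = 4 s
the band 16–128 s selects levels {2, 3, 4} — level 1's band (8, 16] s
touches 16 s only at its closed upper edge and is excluded — while
8–128 s selects {1, 2, 3, 4}. The excluded coarse levels plus the
smooth are returned as the trend, which downstream regime
classification uses as the growth baseline.

## Continuous Morlet spectrum

Morlet wavelet with ω₀ = 6; scales `s_j = s0·2^{j·dj}` with dj = 1/12
(12 scales per octave), s0 = 2·dt, and the largest scale chosen so the
Fourier-equivalent period (`4π/(ω₀+√(2+ω₀²)) ≈ 1.033` times the scale)
reaches a quarter of the series length. The transform is computed by
FFT on a zero-padded (next power of two) mean-removed series, with the
wavelet normalized to unit total spectral energy so that the expected
power of white noise equals the series variance at every scale. The
cone of influence is the e-folding distance √2·s converted to period
units; everything above the cone at a given time is untrusted.

Significance is pointwise: `|W|²` is compared with `σ²·P_k·χ²₂(1−α)/2`,
where `P_k` is the normalized AR(1) spectrum at the scale's frequency
and the lag-1 coefficient is estimated from the (linearly detrended)
series. Calibration is verified by simulation: on AR(1) noise with
φ = 0.7, the significant area outside the cone is 5.0 ± 2% at α = 0.05
over 50 replicates.

Ridges are per-time local maxima of power along the period axis,
restricted to significant cells outside the cone and to at least
`min_power_frac` (default 1%) of the global maximum, keeping at most
`max_per_time` (default 2) by power. The amplitude attached to each
ridge point inverts the Morlet response of a pure sinusoid,
`A = 2·|W|·π^{1/4}/√(2πs/dt)`, giving the oscillation envelope in the
series' units; raw power is reported alongside. Detected periods are
quantized to the scale grid, i.e. accurate to one scale step
(2^{1/12} ≈ 6%). The detection proportion is the fraction of
outside-cone time points carrying at least one ridge. Ridge points link
into bouts by greedy nearest-period matching with a maximum jump of two
scale steps between consecutive times.

## Cross-wavelet analysis

`match_series` regularizes both series onto one grid over their time
overlap (default step: the coarser of the two median steps) and
band-filters both with the shared band (default 16–128 s). The cross
transform is `W_xy = W_x·conj(W_y)`; its modulus is joint power and its
argument the phase difference Δφ = φ_x − φ_y. Sign convention, printed
in every output: **positive phase/delay means the first series leads
(occurs before) the second**; delay = Δφ/(2π)·P wrapped to
(−P/2, P/2]. Swapping the inputs negates phase and delay exactly.

Joint significance compares `|W_xy|` with
`σ_x·σ_y·√(P_x·P_y)·Z_α/2`, where `Z_α` solves `Z·K₁(Z) = α` (K₁ the
modified Bessel function) — the analytic tail of the square root of a
product of two independent χ²₂ variables; at α = 0.05, Z = 3.999.
Calibration on independent AR(1) pairs gives ≈ 5% significant area
outside the cone. Joint ridges reuse the single-series peak-finder on
cross power; delays are evaluated at joint-ridge points (the
all-significant-cells alternative is a matter of selecting ridges with
a larger `max_per_time`).

Synchrony windows: a window (default 120 s) is flagged synchronized
when the circular SD of its joint-ridge phases is below `tol` (default
0.5 rad) and joint ridges cover more than 80% of its time points. Only
ridge periods at most half the window length count — a window shorter
than two cycles cannot attest phase stability, and long-period
cross-power patches of independent red noise (the known weakness of
cross-wavelet versus coherence analysis) would otherwise inflate the
false-positive rate. Wavelet coherence is deliberately out of scope.

## Summary statistics

- **Two-component Gaussian mixture** (EM, seeded multi-start via
  scikit-learn, default 10 starts): the reported summary is the mean
  and SD of the larger-weight ("main") component, ties broken toward
  the smaller SD. Constant data errors out with advice to use
  descriptive statistics. Note that ridge periods from a single short
  series are quantized to the scale grid; the mixture summary is meant
  for period/delay samples pooled across cells or long recordings.
- **Welch's t-test** with Welch–Satterthwaite degrees of freedom,
  Bonferroni adjustment `p_adj = min(1, m·p)`, and the confidence
  interval of the mean difference at the Welch df. Simulated coverage
  of the 95% interval is 95 ± 2%.
- **McNemar's test** on 2×2 paired detection tables:
  `(|b−c|−1)²/(b+c)` with continuity correction (default; conservative)
  or `(b−c)²/(b+c)` without, p from χ²₁; for fewer than 25 discordant
  pairs an exact two-sided binomial p is reported as well. No
  discordance returns χ² = 0, p = 1 by convention.
- **Tracking noise** is the SD (plus a kernel density estimate) of the
  finest multiresolution detail band of a growth-rate series — for
  white noise this band carries half the variance, so the statistic
  reads ≈ σ·√0.5.
- **Growth regimes** classify the band-filter trend (not the raw rate)
  as growing (> 2 µm/min), non-growing (< 0.5 µm/min), or intermediate
  (excluded from contrasts).

## Synthetic study conditions

The generators are pure functions of their parameters and seed and
return the ground truth needed to score every estimator.

- **Kymograph**: logistic edge from plateau to background centred on
  the trajectory `x(t) = x0 + (v/60)·t/dx + (amp/dx)·sin(2πt/period)`;
  optional exponential photobleaching of the plateau, tip-focused
  Gaussian intensity bump, additive Gaussian noise (Poisson available),
  stripe/block artefacts for the 2-D filter. Defaults: dt = 4 s,
  dx = 0.22 µm, 1.5 µm/min growth, 48 s / 0.4 µm oscillation, edge
  scale 1 px. The edge scale reflects a diffraction-limited edge at
  this sampling (a logistic scale w maps to a Gaussian blur of
  ≈ 1.8·w px); it also matters quantitatively — the localization bound
  grows as √w, and subpixel-floor precision at contrast-to-noise 10 is
  achievable only for a sharp edge.
- **Ratiometric pair**: the CFP channel carries the geometry; YFP is
  built as `bg_Y + ratio_field·(CFP − bg_C)` so the true ratio is
  recovered exactly in the noiseless case. The ratio field decays from
  tip (default 1.5) to shank (1.0) with a 3 µm length scale, optionally
  oscillating at the tip.
- **Series pair**: shared sinusoid with the second series delayed by a
  fixed lag, independent AR(1) noise in each, optional polynomial
  trend, sampling-time jitter, and seeded ±`outlier_mag` spikes (half
  adding, half subtracting).
- **Method-comparison condition**: the oscillation-detection comparison
  uses a 700-frame kymograph with a 0.06 µm oscillation — chosen so the
  growth-rate oscillation (~0.5 µm/min) sits near the per-frame
  tracking noise, the regime where detection sensitivity actually
  differs between methods. With the standard 0.4 µm amplitude all
  methods detect essentially always and no ordering exists.

What the passing tests show: the estimators are correct and calibrated
under additive Gaussian/AR(1) noise with an idealized logistic edge and
stationary backgrounds. What they do not show: robustness to organelle
motion across the midline, non-stationary backgrounds, strong
photobleaching of the ratio pair, chromatic misregistration, or the
template-matching behaviour of commercial trackers — external traces
can be imported for such comparisons but are not modelled.

## Numerical choices and degenerate inputs

- Loess: k-nearest-neighbour tricube weights, weighted least squares via
  `lstsq`; a span that selects fewer than degree + 3 points errors out;
  exact-duplicate evaluation points fall back to the local mean.
- Threshold detector returns missing (NaN) when no pixel meets the
  threshold; the regression detector returns missing when no window has
  a descending fitted slope. Missing frames propagate (excluded from
  background estimation, NaN columns in alignment) rather than raising.
- Stationary-transform padding is reflective; CWT padding is zeros
  (edge effects are declared via the cone rather than hidden).
- Ridge ties at equal power: highest power first, then scale order;
  steepest-slope ties in tip detection: the most distal window.
- The cross-wavelet quantile solves `Z·K₁(Z) = α` by Brent's method on
  [1e-6, 50].
- Problem sizes in the test suite and acceptance script (256–1000
  frames, 50-replicate calibrations) were chosen as the smallest that
  estimate each quantity stably; all randomness is seeded.

## Known limitations

- The tip detector assumes a single bright-to-dark edge; profiles with
  internal dark gaps (vacuoles crossing the midline) can mislocate the
  steepest-slope window.
- Cross-wavelet significance tests joint *power*, not correlation; one
  strong series can produce significant joint cells (mitigated, not
  eliminated, by the synchrony-window period rule). Wavelet coherence
  would be the stricter instrument.
- Detected periods are quantized to the scale grid (6% at the default
  dj); period summaries from a single short series inherit that
  granularity.
- Level shifts are only reported, never repaired; series with genuine
  regime changes should be segmented by the user before spectral
  summary.
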