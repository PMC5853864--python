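# kymopulse

Analysis of oscillations in tip-growing cells (pollen tubes, root hairs,
fungal hyphae) from kymographs and companion time series: subpixel tip
tracking, ratiometric Ca²⁺ kymograph processing, wavelet band filtering,
time-resolved period/amplitude estimation, and cross-wavelet phase/delay
analysis between concurrently measured processes (growth rate, cytosolic
Ca²⁺, extracellular H⁺ flux).

## Who this is for

Labs that image growing cells along a midline (ImageJ-style kymographs:
one spatial line per frame, stacked over time) and/or record ion fluxes
with self-referencing microelectrodes, and want quantitative,
reproducible answers to: how fast is the cell growing, does growth (or
Ca²⁺, or H⁺ flux) oscillate, with what time-varying period and
amplitude, and are two processes synchronized — and with what lag?

## The methods in brief

**Subpixel tip detection.** Each kymograph row is a fluorescence profile
with a sharp descent from the bright cell body to the dark background at
the tip. A simple intensity threshold locates the tip only to whole
pixels (quantization floor ≈ 1/√12 ≈ 0.29 px). The featured estimator
fits an ordinary least-squares line to the steepest descending stretch of
a lightly smoothed profile and reports the real-valued position where the
line crosses a reference level: for a profile `F(p)` and fitted line
`ℓ(p) = a + b·p` on the sharpest-slope window, the tip estimate is
`x̂ = (ref − a)/b`. On synthetic edges at contrast-to-noise 10 this
tracks the true tip with RMSE < 0.3 px per frame. Growth rate follows by
first differences, `v_i = (x̂_{i+1} − x̂_i)·dx/dt·60` (µm/min).

**Ratiometric processing.** Background is estimated per channel from all
pixels beyond the tip and summarized by a tail quantile (default 99%);
the ratio is `(YFP − bg_Y)/(CFP − bg_C)`. Rows are resampled onto a
distance-from-tip grid so fluorescence series can be extracted at fixed
distances (e.g. median of a ~1.1 µm window at 2.2 µm for "tip" and
19.4 µm for "shank"), plus the normalized tip-focused gradient
`(tip − shank)/shank`.

**Wavelet filtering and spectra.** A shift-invariant discrete wavelet
multiresolution analysis splits a series additively into dyadic detail
bands `D_j` (nominal periods `(2^j·dt, 2^{j+1}·dt]`) plus a smooth
trend; band selection acts as a band-pass filter (e.g. 16–128 s at
dt = 4 s keeps levels 2–4). The filtered series then goes through a
Morlet (ω₀ = 6) continuous wavelet transform; power is tested pointwise
against a variance-matched red-noise (AR(1)) background via χ²
quantiles, edge effects are delimited by the cone of influence, and
wavelet ridges (per-time power maxima across scale) give the
instantaneous period and amplitude.

**Synchronization.** Two series on a shared grid combine as
`W_xy = W_x·conj(W_y)`; the argument of `W_xy` is the local phase
difference Δφ = φ_x − φ_y, converted at period P to a time delay
`Δφ/(2π)·P`, wrapped to (−P/2, P/2]. Positive delay means the first
series leads. Circular statistics of ridge phases summarize phase
locking; windows are flagged synchronized when ridge phases are stable
and joint ridges cover the window.

**Summaries.** Pooled period/delay distributions are summarized by the
dominant component of a two-component Gaussian mixture; group contrasts
use Welch's t-test with Bonferroni adjustment; paired method comparisons
of oscillation detection use McNemar's test; tracking noise is the
standard deviation of the finest multiresolution band of the growth-rate
series.

## Worked example

Simulate a noisy oscillating kymograph (400 frames, 4 s interval,
0.22 µm pixels, 48 s / 0.4 µm oscillation on 1.5 µm/min growth,
contrast-to-noise 10), track the tip, and analyze the growth rate:

```sh
kymopulse simulate --kind kymo --n-frames 400 --amp 0.4 --noise-sd 90 --seed 7 --out-dir data
kymopulse tip data/kymograph.csv --dt 4 --dx 0.22 --no-smooth --out-dir track
kymopulse analyze track/growth_rate.csv --time-col time_s --value-col rate_um_min \
    --max-ridges 1 --out-dir spectra
```

`spectra/analysis.json`:

```json
{
  "detection_proportion": 0.9287531806615776,
  "n_ridge_points": 365,
  "ar1": 0.860708454555772,
  "alpha": 0.05
}
```

A significant periodic component is present in 93% of the trustworthy
(outside-cone) time points. The ridge table starts:

```
time_s,period_s,power,amplitude
70,46.7502187895,21.4118249147,1.46134204236
74,46.7502187895,22.2276612783,1.48892191521
78,46.7502187895,22.9879691603,1.51417245043
```

The detected period sits on the log-spaced scale grid (12 scales per
octave), so the 48 s rhythm lands on the nearest scale bins, 46.75 s and
49.53 s — within one scale step of truth. The amplitude column is the
oscillation envelope in the series' own units (here µm/min; the injected
rate oscillation has amplitude `0.4·2π/48·60 ≈ 3.1` µm/min peak, and the
band-filtered envelope fluctuates below that).

Cross-wavelet delay analysis between two concurrent series follows the
same pattern (`kymopulse sync a.csv b.csv`), writing a per-time delay
table and a circular phase histogram; every delay output states the sign
convention (positive = first series leads).

## Layout

- `src/kymopulse/io.py` — TIFF/CSV readers and writers, orientation normalization
- `src/kymopulse/synthetic.py` — ground-truth generators for every stage
- `src/kymopulse/tipdetect.py` — threshold and regression tip detectors, trace smoothing, growth rate
- `src/kymopulse/kymoproc.py` — background, ratio, tip alignment, region series, 2-D wavelet filter
- `src/kymopulse/tsprep.py` — loess regularization and outlier repair
- `src/kymopulse/wavelets.py` — multiresolution band filter; Morlet CWT, significance, ridges
- `src/kymopulse/sync.py` — cross-wavelet transform, phase/delay, synchrony windows
- `src/kymopulse/stats.py` — mixture summaries, Welch/Bonferroni, McNemar, tracking noise
- `src/kymopulse/cli.py` — `kymopulse` command group

See `docs/methods.md` for model details, parameter defaults, and known
limitations.
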