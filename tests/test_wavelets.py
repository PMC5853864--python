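import numpy as np
import pytest

from conftest import ar1_series
from kymopulse import wavelets
from kymopulse.types import UniformSeries


def _us(v, dt=4.0, t0=0.0):
    return UniformSeries(t0=t0, dt=dt, v=np.asarray(v, float))


class TestMra:
    def test_additivity(self):
        rng = np.random.default_rng(0)
        for n in (100, 256, 313):
            us = _us(rng.normal(0, 1, n))
            d = wavelets.mra(us, n_levels=5)
            np.testing.assert_allclose(d.reconstruct(), us.v, atol=1e-8)

    def test_constant_input(self):
        d = wavelets.mra(_us(np.full(64, 3.3)), n_levels=4)
        for det in d.details:
            np.testing.assert_allclose(det, 0.0, atol=1e-8)
        np.testing.assert_allclose(d.smooth, 3.3, atol=1e-8)

    def test_sinusoid_energy_in_matching_band(self):
        # 48 s period at dt 4 s falls in D3's nominal band (32, 64] s
        t = np.arange(256) * 4.0
        d = wavelets.mra(_us(np.sin(2 * np.pi * t / 48)), n_levels=5)
        energies = [np.sum(det**2) for det in d.details]
        assert energies[2] / sum(energies) >= 0.70

    def test_too_deep_raises(self):
        with pytest.raises(ValueError):
            wavelets.mra(_us(np.zeros(30)), n_levels=5)


class TestBandpass:
    def test_band_level_selection(self):
        d = wavelets.mra(_us(np.random.default_rng(0).normal(0, 1, 256)), n_levels=5)
        assert wavelets.select_levels(d, 16, 128) == [2, 3, 4]
        assert wavelets.select_levels(d, 8, 128) == [1, 2, 3, 4]

    def test_full_band_plus_trend_is_identity(self):
        rng = np.random.default_rng(1)
        us = _us(rng.normal(0, 1, 128))
        d = wavelets.mra(us, n_levels=4)
        filt, trend = wavelets.bandpass(d, 2 * 4.0, 2**5 * 4.0, keep_trend=True)
        np.testing.assert_allclose(filt.v, us.v, atol=1e-8)

    def test_empty_band_raises(self):
        d = wavelets.mra(_us(np.zeros(128)), n_levels=4)
        with pytest.raises(ValueError):
            wavelets.bandpass(d, 1.0, 2.0)

    def test_filtered_plus_trend_partition(self):
        rng = np.random.default_rng(2)
        us = _us(rng.normal(0, 1, 256))
        d = wavelets.mra(us, n_levels=5)
        filt, trend = wavelets.bandpass(d, 16, 128)
        fine = d.details[0]  # level 1 excluded from the 16-128 s band
        np.testing.assert_allclose(filt.v + trend.v + fine, us.v, atol=1e-8)


class TestCwt:
    def test_sinusoid_peak_period(self):
        t = np.arange(256) * 4.0
        spec = wavelets.cwt(_us(np.sin(2 * np.pi * t / 48)))
        peak = spec.periods[np.argmax(spec.power.mean(axis=1))]
        step = 2 ** (1 / 12)
        assert 48 / step <= peak <= 48 * step

    def test_white_noise_flat_mid_scales(self):
        reps = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            spec = wavelets.cwt(_us(rng.normal(0, 1, 256)))
            reps.append(spec.power.mean(axis=1))
        mean_power = np.mean(reps, axis=0)
        mid = (spec.periods > 4 * spec.dt) & (spec.periods < 32 * spec.dt)
        ratio = mean_power[mid].max() / mean_power[mid].min()
        assert ratio < 1.6

    def test_amplitude_scaling_power_quadruples(self):
        t = np.arange(128) * 4.0
        x = np.sin(2 * np.pi * t / 40)
        s1 = wavelets.cwt(_us(x))
        s2 = wavelets.cwt(_us(2 * x))
        np.testing.assert_allclose(s2.power, 4 * s1.power, rtol=1e-9)

    def test_coi_smallest_at_ends(self):
        spec = wavelets.cwt(_us(np.random.default_rng(0).normal(0, 1, 64)))
        assert spec.coi[0] < spec.coi[len(spec.coi) // 2]
        assert spec.coi[-1] < spec.coi[len(spec.coi) // 2]


class TestSignificance:
    def test_ar1_null_calibration(self):
        """Significant area outside the coi is ~alpha under the red-noise
        null (50 seeded replicates)."""
        fracs = []
        for rep in range(50):
            rng = np.random.default_rng(100 + rep)
            us = _us(ar1_series(256, 0.7, 1.0, rng))
            spec = wavelets.significance(wavelets.cwt(us), alpha=0.05)
            inside = spec.periods[:, None] <= spec.coi[None, :]
            fracs.append((spec.signif & inside).sum() / inside.sum())
        assert np.mean(fracs) == pytest.approx(0.05, abs=0.02)

    def test_embedded_sinusoid_power(self):
        """A sinusoid at SNR 3 in autoregressive noise is significant at
        its period for >= 90% of out-of-cone time points."""
        rng = np.random.default_rng(7)
        t = np.arange(256) * 4.0
        x = 3.0 * np.sin(2 * np.pi * t / 48) + ar1_series(256, 0.5, 1.0, rng)
        spec = wavelets.significance(wavelets.cwt(_us(x)), alpha=0.05)
        row = int(np.argmin(np.abs(spec.periods - 48)))
        ok = spec.coi >= spec.periods[row]
        assert spec.signif[row, ok].mean() >= 0.9

    def test_alpha_one_everything_significant(self):
        spec = wavelets.cwt(_us(np.random.default_rng(0).normal(0, 1, 64)))
        spec = wavelets.significance(spec, alpha=1.0 - 1e-12)
        assert spec.signif.mean() > 0.99


class TestRidges:
    def _sin_spec(self, n=400, period=48.0, noise=0.2, seed=2):
        rng = np.random.default_rng(seed)
        t = np.arange(n) * 4.0
        x = np.sin(2 * np.pi * t / period) + rng.normal(0, noise, n)
        return wavelets.significance(wavelets.cwt(_us(x)), 0.05)

    def test_single_sinusoid_one_ridge_per_interior_time(self):
        spec = self._sin_spec()
        r = wavelets.extract_ridges(spec, max_per_time=3)
        times, counts = np.unique(r.points[:, 0], return_counts=True)
        interior = (times > 200) & (times < spec.times[-1] - 200)
        assert np.all(counts[interior] == 1)
        err = np.abs(r.points[:, 1] - 48.0) / 48.0
        assert np.median(err) < 2 ** (1 / 12) - 1

    def test_ridge_amplitude_estimates_envelope(self):
        spec = self._sin_spec(noise=0.05)
        r = wavelets.extract_ridges(spec)
        assert np.median(r.points[:, 3]) == pytest.approx(1.0, rel=0.15)

    def test_two_superposed_sinusoids(self):
        rng = np.random.default_rng(3)
        t = np.arange(512) * 4.0
        x = np.sin(2 * np.pi * t / 20) + np.sin(2 * np.pi * t / 60) + rng.normal(0, 0.1, 512)
        spec = wavelets.significance(wavelets.cwt(_us(x)), 0.05)
        r = wavelets.extract_ridges(spec, max_per_time=2)
        interior = (r.points[:, 0] > 300) & (r.points[:, 0] < t[-1] - 300)
        pts = r.points[interior]
        near20 = np.abs(pts[:, 1] - 20) / 20 < 0.15
        near60 = np.abs(pts[:, 1] - 60) / 60 < 0.15
        assert near20.sum() > 100 and near60.sum() > 100

    def test_noise_only_no_ridges_everywhere(self):
        rng = np.random.default_rng(4)
        spec = wavelets.significance(wavelets.cwt(_us(rng.normal(0, 1, 256))), 1e-7)
        r = wavelets.extract_ridges(spec)
        assert wavelets.detection_proportion(r) < 0.05

    def test_detection_proportion_bounds(self):
        spec = self._sin_spec()
        r = wavelets.extract_ridges(spec)
        assert 0.8 <= wavelets.detection_proportion(r) <= 1.0


class TestChirp:
    def _chirp_ridges(self):
        n = 512
        t = np.arange(n) * 4.0
        f0, f1 = 1 / 60, 1 / 20
        T = t[-1]
        phase = 2 * np.pi * (f0 * t + (f1 - f0) * t**2 / (2 * T))
        spec = wavelets.significance(wavelets.cwt(_us(np.sin(phase))), 0.05)
        r = wavelets.extract_ridges(spec, max_per_time=1)
        inst = 1 / (f0 + (f1 - f0) * t / T)
        return t, r, inst

    def test_chirp_ridge_monotone_nonincreasing(self):
        t, r, _ = self._chirp_ridges()
        sel = (r.points[:, 0] > t[40]) & (r.points[:, 0] < t[-40])
        pp = r.points[sel]
        assert np.all(np.diff(pp[:, 1]) <= 1e-9)

    def test_chirp_tracks_instantaneous_period_within_15pct(self):
        t, r, inst = self._chirp_ridges()
        sel = (r.points[:, 0] > t[40]) & (r.points[:, 0] < t[-40])
        pp = r.points[sel]
        rel = np.abs(pp[:, 1] - np.interp(pp[:, 0], t, inst)) / np.interp(pp[:, 0], t, inst)
        assert rel.max() < 0.15


def test_ridge_linking_single_bout():
    t = np.arange(300) * 4.0
    x = np.sin(2 * np.pi * t / 48)
    spec = wavelets.significance(wavelets.cwt(_us(x)), 0.05)
    r = wavelets.extract_ridges(spec, max_per_time=1)
    bouts = wavelets.link_ridges(r)
    assert len(bouts) >= 1
    assert max(len(b) for b in bouts) > 0.8 * np.unique(r.points[:, 0]).size
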