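import numpy as np
import pytest

from kymopulse import kymoproc, synthetic, tipdetect
from kymopulse.types import Kymograph, RawSeries, TipTrace


def _const_trace(n_frames, pos, dx=0.22, dt=4.0):
    return TipTrace(t=np.arange(n_frames) * dt, pos_px=np.full(n_frames, float(pos)), dx=dx)


class TestBackground:
    def test_constant_background_cutoff(self):
        vals = np.full((5, 50), 5.0)
        k = Kymograph(values=vals, dt=1.0, dx=1.0)
        be = kymoproc.estimate_background(k, _const_trace(5, 10))
        assert be.cutoff == 5.0

    def test_uniform_background_order_statistic(self):
        rng = np.random.default_rng(0)
        vals = rng.uniform(0, 1, (100, 1010))
        k = Kymograph(values=vals, dt=1.0, dx=1.0)
        be = kymoproc.estimate_background(k, _const_trace(100, 5), quantile=0.99)
        assert be.cutoff == pytest.approx(0.99, abs=0.01)
        assert be.samples.size >= 1e5

    def test_tip_at_last_column_contributes_nothing(self):
        vals = np.full((3, 20), 2.0)
        trace = TipTrace(t=np.arange(3.0), pos_px=np.array([5.0, 19.0, 5.0]), dx=1.0)
        k = Kymograph(values=vals, dt=1.0, dx=1.0)
        be = kymoproc.estimate_background(k, trace)
        assert be.samples.size == 2 * (20 - (5 + 3 + 1))
        with pytest.raises(ValueError, match="empty"):
            kymoproc.estimate_background(k, _const_trace(3, 19))

    def test_separation_property_snr10(self):
        """Background and within-cell intensities overlap < 1% at SNR 10,
        so the 99% cutoff separates them."""
        yfp, cfp, truth = synthetic.simulate_ratiometric_pair(noise_sd=42.0, seed=2)
        trace = tipdetect.detect_tip(tipdetect.strongest_channel(yfp, cfp), "regression")
        be = kymoproc.estimate_background(cfp, trace)
        cell = cfp.values[:, :40].ravel()  # deep inside the cell
        assert np.mean(cell < be.cutoff) < 0.01
        assert be.cutoff > np.quantile(be.samples, 0.5)

    def test_channel_specific_cutoffs_differ(self, ratio_pair_clean):
        yfp, cfp, truth = ratio_pair_clean
        trace = tipdetect.detect_tip(yfp, "regression")
        bY = kymoproc.estimate_background(yfp, trace).cutoff
        bC = kymoproc.estimate_background(cfp, trace).cutoff
        assert abs((bY - bC) - (truth.bg["YFP"] - truth.bg["CFP"])) < 5.0


class TestRatio:
    def test_simple_arithmetic(self):
        y = Kymograph(values=np.full((2, 3), 200.0), dt=1, dx=1)
        c = Kymograph(values=np.full((2, 3), 150.0), dt=1, dx=1)
        r = kymoproc.ratio_kymograph(y, c, 100.0, 50.0)
        np.testing.assert_allclose(r.values, 1.0)

    def test_dim_denominator_masked(self):
        y = Kymograph(values=np.full((1, 2), 200.0), dt=1, dx=1)
        c = Kymograph(values=np.array([[150.0, 50.5]]), dt=1, dx=1)
        r = kymoproc.ratio_kymograph(y, c, 100.0, 50.0, floor=1.0)
        assert np.isfinite(r.values[0, 0]) and np.isnan(r.values[0, 1])

    def test_recovers_generated_ratio_field(self, ratio_pair_clean):
        yfp, cfp, truth = ratio_pair_clean
        r = kymoproc.ratio_kymograph(yfp, cfp, truth.bg["YFP"], truth.bg["CFP"])
        ok = np.isfinite(r.values) & np.isfinite(truth.ratio_field)
        np.testing.assert_allclose(r.values[ok], truth.ratio_field[ok], rtol=1e-9)

    def test_shape_mismatch(self):
        y = Kymograph(values=np.zeros((2, 3)), dt=1, dx=1)
        c = Kymograph(values=np.zeros((2, 4)), dt=1, dx=1)
        with pytest.raises(ValueError):
            kymoproc.ratio_kymograph(y, c, 0, 0)


class TestAlignment:
    def test_constant_profile_constant_aligned(self):
        k = Kymograph(values=np.full((4, 30), 7.0), dt=1.0, dx=0.5)
        ak = kymoproc.align_to_tip(k, _const_trace(4, 20, dx=0.5, dt=1.0))
        got = ak.values[:, :21]
        np.testing.assert_allclose(got, 7.0)

    def test_integer_trace_is_index_shift(self):
        rng = np.random.default_rng(1)
        vals = rng.uniform(0, 1, (3, 25))
        k = Kymograph(values=vals, dt=1.0, dx=1.0)
        trace = TipTrace(t=np.arange(3.0), pos_px=np.array([20.0, 18.0, 15.0]), dx=1.0)
        ak = kymoproc.align_to_tip(k, trace)
        for i, tip in enumerate([20, 18, 15]):
            np.testing.assert_allclose(ak.values[i, : tip + 1], vals[i, tip::-1])

    def test_tip_bump_stays_at_zero_distance(self):
        kymo, truth = synthetic.simulate_kymograph(
            n_frames=64, n_px=220, noise_sd=0.0, bump_amp=400.0, seed=0
        )
        trace = TipTrace(t=kymo.times, pos_px=truth.tip_px, dx=kymo.dx)
        ak = kymoproc.align_to_tip(kymo, trace)
        col0 = ak.values[:, 0]
        assert np.ptp(col0) < 0.05 * col0.mean()  # bump pinned to the tip column


class TestRegionSeries:
    def test_constant_matrix_constant_series(self):
        k = Kymograph(values=np.full((6, 40), 3.0), dt=2.0, dx=0.5)
        ak = kymoproc.align_to_tip(k, _const_trace(6, 35, dx=0.5, dt=2.0))
        s = kymoproc.extract_region_series(ak, 5.0, 1.0)
        np.testing.assert_allclose(s.v, 3.0)

    def test_single_column_when_width_below_dx(self):
        k = Kymograph(values=np.tile(np.arange(40.0), (3, 1)), dt=1.0, dx=0.5)
        ak = kymoproc.align_to_tip(k, _const_trace(3, 35, dx=0.5, dt=1.0))
        s = kymoproc.extract_region_series(ak, 2.0, 0.2)
        np.testing.assert_allclose(s.v, 31.0)  # tip 35 minus 4 px

    def test_tip_exceeds_shank_on_gradient_phantom(self, ratio_pair_clean):
        yfp, cfp, truth = ratio_pair_clean
        trace = tipdetect.detect_tip(yfp, "regression")
        r = kymoproc.ratio_kymograph(yfp, cfp, truth.bg["YFP"], truth.bg["CFP"])
        ak = kymoproc.align_to_tip(r, trace)
        tip_s = kymoproc.extract_region_series(ak, 2.2, 1.1)
        shank_s = kymoproc.extract_region_series(ak, 19.4, 1.1)
        assert np.all(tip_s.v > shank_s.v)
        grad = kymoproc.tip_shank_gradient(tip_s, shank_s)
        assert np.all(grad.v > 0)

    def test_gradient_arithmetic(self):
        t = np.arange(3.0)
        tip_s = RawSeries(t=t, v=np.array([1.0, 2.0, 3.0]))
        shank = RawSeries(t=t, v=np.array([1.0, 1.0, 1.5]))
        g = kymoproc.tip_shank_gradient(tip_s, shank)
        np.testing.assert_allclose(g.v, [0.0, 1.0, 1.0])

    def test_scan_along_tube_decaying_oscillation(self):
        yfp, cfp, truth = synthetic.simulate_ratiometric_pair(
            noise_sd=0.0, ratio_osc_amp=0.3, ratio_decay_um=5.0, seed=3
        )
        trace = tipdetect.detect_tip(yfp, "regression")
        r = kymoproc.ratio_kymograph(yfp, cfp, truth.bg["YFP"], truth.bg["CFP"])
        ak = kymoproc.align_to_tip(r, trace)
        series = kymoproc.scan_series_along_tube(ak, 1.5, 21.5, 1.5, 1.1)
        amps = [np.ptp(s.v - np.median(s.v)) for _, s in series]
        assert amps[0] > 3 * amps[-1]  # oscillation decays tip -> shank


class TestFilter2D:
    def test_identity_when_dropping_nothing(self):
        kymo, _ = synthetic.simulate_kymograph(n_frames=64, n_px=96, noise_sd=20.0, seed=5)
        out = kymoproc.filter_kymograph_2d(kymo, 0, 0)
        np.testing.assert_allclose(out.values, kymo.values, atol=1e-8)

    def test_stripe_artifact_power_reduced_10x(self):
        kymo, _ = synthetic.simulate_kymograph(n_frames=128, n_px=128, noise_sd=0.0, seed=0)
        striped = synthetic.add_stripe_artifact(kymo, 60, 6, 300.0)
        f_clean = kymoproc.filter_kymograph_2d(kymo, 1, 1)
        f_striped = kymoproc.filter_kymograph_2d(striped, 1, 1)
        resid = f_striped.values - f_clean.values
        injected = striped.values - kymo.values
        assert np.sum(resid**2) < 0.1 * np.sum(injected**2)

    def test_bleaching_ramp_detrended(self):
        kymo, _ = synthetic.simulate_kymograph(
            n_frames=128, n_px=128, noise_sd=0.0, bleach_rate=0.004, seed=0
        )
        out = kymoproc.filter_kymograph_2d(kymo, 1, 1)
        fm = out.values.mean(axis=1)
        slope = np.polyfit(np.arange(fm.size), fm, 1)[0]
        raw_slope = np.polyfit(np.arange(fm.size), kymo.values.mean(axis=1), 1)[0]
        assert abs(slope) < 0.01 * abs(raw_slope)

    def test_too_many_levels_raises(self):
        kymo, _ = synthetic.simulate_kymograph(n_frames=64, n_px=64, seed=0)
        with pytest.raises(ValueError, match="exceeds"):
            kymoproc.filter_kymograph_2d(kymo, 4, 4, level=5)
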