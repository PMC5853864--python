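import numpy as np
import pytest

from kymopulse import synthetic, tipdetect


@pytest.fixture(scope="session")
def snr10_kymo():
    """1000-frame kymograph of a stationary oscillating tip at SNR 10
    ((plateau - background) / noise_sd = 10), sub-integer true positions."""
    return synthetic.simulate_kymograph(
        n_frames=1000, n_px=100, v=0.0, amp=0.4, x0=40.0,
        plateau=1000.0, bg_level=100.0, noise_sd=90.0, seed=1,
    )


@pytest.fixture(scope="session")
def growing_kymo():
    """Growing, oscillating kymograph at SNR 10 (standard tracking set)."""
    return synthetic.simulate_kymograph(
        n_frames=300, n_px=200, v=1.5, amp=0.4, noise_sd=90.0, seed=2
    )


@pytest.fixture(scope="session")
def ratio_pair_clean():
    """Noiseless co-registered YFP/CFP pair with a tip-focused gradient."""
    return synthetic.simulate_ratiometric_pair(noise_sd=0.0, seed=1)


@pytest.fixture(scope="session")
def series_pair_lagged():
    """Series pair sharing a 48 s sinusoid, second delayed by 4 s."""
    return synthetic.simulate_series_pair(
        n=400, dt=4.0, period=48.0, amp=1.0, lag=4.0, ar1=0.4,
        noise_sd=0.33, seed=5,
    )


@pytest.fixture(scope="session")
def snr10_traces(snr10_kymo):
    kymo, truth = snr10_kymo
    reg = tipdetect.detect_tip(kymo, "regression")
    thr = tipdetect.detect_tip(kymo, "threshold")
    return reg, thr, truth


def ar1_series(n, phi, sd, rng):
    e = rng.normal(0.0, sd * np.sqrt(1 - phi**2), n)
    x = np.empty(n)
    x[0] = rng.normal(0.0, sd)
    for i in range(1, n):
        x[i] = phi * x[i - 1] + e[i]
    return x
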