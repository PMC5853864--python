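"""Summary statistics for oscillation studies.

Period and delay distributions pooled across cells are typically
bimodal (a dominant oscillatory mode plus a minor one), so they are
summarized by the larger-weight component of a two-component Gaussian
mixture. Group comparisons use Welch's unequal-variance t-test with
Bonferroni adjustment; paired detection comparisons between tracking
methods use McNemar's test on 2x2 contingency tables; tracking noise is
quantified as the finest multiresolution detail band of a growth-rate
series.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sstats
from sklearn.mixture import GaussianMixture

from . import wavelets
from .types import (
    GrowthSeries,
    MixtureFit,
    PairedDetectionTable,
    RidgeSet,
    UniformSeries,
)


def fit_gmm2(values: np.ndarray, seed: int = 0, n_starts: int = 10) -> MixtureFit:
    """Two-component univariate Gaussian mixture by seeded multi-start EM.

    The reported summary is the mean and SD of the *main* component — the
    one with the larger weight (ties break toward the smaller SD).
    """
    x = np.asarray(values, dtype=float).ravel()
    x = x[np.isfinite(x)]
    if x.size < 20:
        raise ValueError("need at least 20 finite values to fit a mixture")
    if np.ptp(x) == 0:
        raise ValueError("degenerate (constant) data: use descriptive statistics")
    gm = GaussianMixture(
        n_components=2,
        covariance_type="full",
        n_init=n_starts,
        random_state=seed,
        reg_covar=1e-6,
    ).fit(x[:, None])
    means = gm.means_.ravel()
    sds = np.sqrt(gm.covariances_.ravel())
    weights = gm.weights_.ravel()
    if np.isclose(weights[0], weights[1]):
        main = int(np.argmin(sds))
    else:
        main = int(np.argmax(weights))
    return MixtureFit(
        means=means,
        sds=sds,
        weights=weights,
        main=main,
        loglik=float(gm.score(x[:, None]) * x.size),
        seed=seed,
    )


def classify_growth_regime(
    trend: GrowthSeries | np.ndarray, hi: float = 2.0, lo: float = 0.5
) -> np.ndarray:
    """Label each time point of a growth trend as a growth regime.

    ``growing`` above ``hi`` µm/min, ``non_growing`` below ``lo``, and
    ``intermediate`` between (excluded from group comparisons). The
    trend should be the low-frequency baseline from the multiresolution
    band filter, not the raw rate.
    """
    if hi <= lo:
        raise ValueError("hi must exceed lo")
    r = trend.rate if isinstance(trend, GrowthSeries) else np.asarray(trend, float)
    labels = np.full(r.shape, "intermediate", dtype=object)
    labels[r > hi] = "growing"
    labels[r < lo] = "non_growing"
    return labels


def welch_bonferroni(
    groups: list[tuple[np.ndarray, np.ndarray]],
    m: int | None = None,
    conf: float = 0.95,
) -> list[dict]:
    """Welch's t-test per comparison with Bonferroni-adjusted p-values.

    Each entry of ``groups`` is a pair of samples. Returns, per pair:
    t, Welch-Satterthwaite df, p_adj = min(1, m*p), the mean difference,
    and its confidence interval at level ``conf``.
    """
    if m is None:
        m = len(groups)
    out = []
    for a, b in groups:
        a = np.asarray(a, float)
        b = np.asarray(b, float)
        if a.size < 2 or b.size < 2:
            raise ValueError("each group needs at least 2 samples")
        va, vb = a.var(ddof=1), b.var(ddof=1)
        if va == 0 and vb == 0:
            raise ValueError("zero variance in both groups")
        na, nb = a.size, b.size
        se2 = va / na + vb / nb
        t = (a.mean() - b.mean()) / np.sqrt(se2)
        df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
        p = 2 * sstats.t.sf(abs(t), df)
        tcrit = sstats.t.ppf(0.5 + conf / 2, df)
        diff = a.mean() - b.mean()
        out.append(
            {
                "t": float(t),
                "df": float(df),
                "p": float(p),
                "p_adj": float(min(1.0, m * p)),
                "mean_diff": float(diff),
                "ci_low": float(diff - tcrit * np.sqrt(se2)),
                "ci_high": float(diff + tcrit * np.sqrt(se2)),
            }
        )
    return out


def mcnemar(tab: PairedDetectionTable, correction: bool = True) -> dict:
    """McNemar's paired proportion test on a 2x2 detection table.

    chi2 = (|b-c|-1)^2/(b+c) with continuity correction (default) or
    (b-c)^2/(b+c) without; p from chi-square with 1 df. When the
    discordant count b+c < 25 an exact two-sided binomial p is also
    reported. b+c = 0 returns chi2 = 0, p = 1 by convention.
    """
    b, c = tab.a_only, tab.b_only
    n_disc = b + c
    if n_disc == 0:
        return {"chi2": 0.0, "p": 1.0, "p_exact": 1.0, "b": b, "c": c}
    if correction:
        chi2 = (abs(b - c) - 1) ** 2 / n_disc
    else:
        chi2 = (b - c) ** 2 / n_disc
    p = float(sstats.chi2.sf(chi2, 1))
    result = {"chi2": float(chi2), "p": p, "b": b, "c": c}
    if n_disc < 25:
        p_exact = min(1.0, 2 * float(sstats.binom.sf(max(b, c) - 1, n_disc, 0.5)))
        result["p_exact"] = p_exact
    return result


def noise_band_density(rate: GrowthSeries, filter: str = wavelets.DEFAULT_FILTER) -> dict:
    """Tracking-noise summary: the finest multiresolution detail band.

    The finest detail level D_1 of the growth-rate series isolates
    fluctuations faster than any plausible growth oscillation; its
    standard deviation, and a kernel density estimate of its values,
    quantify tracking noise for comparing detection methods.
    """
    r = rate.rate
    if r.size < 32:
        raise ValueError("need at least 32 samples")
    dts = np.diff(rate.t)
    us = UniformSeries(t0=float(rate.t[0]), dt=float(dts[0]), v=r)
    d = wavelets.mra(us, n_levels=min(5, int(np.log2(r.size))), filter=filter)
    d1 = d.details[0]
    kde = sstats.gaussian_kde(d1)
    grid = np.linspace(d1.min() - 3 * d1.std(), d1.max() + 3 * d1.std(), 256)
    return {
        "sd": float(np.std(d1)),
        "density_x": grid,
        "density_y": kde(grid),
        "values": d1,
    }


def compare_detection(
    ridgesA: RidgeSet, ridgesB: RidgeSet
) -> PairedDetectionTable:
    """Cross-tabulate per-time detection of two methods on one grid.

    Only time points trustworthy (outside the cone of influence) in both
    spectra are compared.
    """
    if ridgesA.times.size != ridgesB.times.size or not np.allclose(
        ridgesA.times, ridgesB.times
    ):
        raise ValueError("ridge sets are not on the same time grid")
    valid = ridgesA.valid_times & ridgesB.valid_times
    a = ridgesA.has_ridge()[valid]
    b = ridgesB.has_ridge()[valid]
    return PairedDetectionTable(
        both=int(np.sum(a & b)),
        a_only=int(np.sum(a & ~b)),
        b_only=int(np.sum(~a & b)),
        neither=int(np.sum(~a & ~b)),
    )
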