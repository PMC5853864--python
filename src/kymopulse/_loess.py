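"""Local polynomial regression (loess) with tricube weights.

Degree-2 local fits are needed both for trace smoothing and for
regularizing irregularly sampled series onto a uniform grid, so the
solver lives here. statsmodels' lowess is local-linear only, hence the
in-package implementation.
"""

from __future__ import annotations

import numpy as np

_MIN_PTS = 5  # a local quadratic needs > 3 points to be over-determined


def loess(
    t: np.ndarray,
    v: np.ndarray,
    t_eval: np.ndarray,
    span: float,
    degree: int = 2,
) -> np.ndarray:
    """Evaluate a tricube-weighted local polynomial fit of ``v`` on ``t``.

    Parameters
    ----------
    t, v : 1-D arrays
        Sample locations and values. NaN values are excluded.
    t_eval : 1-D array
        Locations at which to evaluate the smooth.
    span : float
        Fraction of the data used in each local fit, in (0, 1].
    degree : int
        Local polynomial degree (default 2).

    Returns
    -------
    ndarray of fitted values at ``t_eval``.
    """
    t = np.asarray(t, dtype=float)
    v = np.asarray(v, dtype=float)
    keep = np.isfinite(t) & np.isfinite(v)
    t, v = t[keep], v[keep]
    n = t.size
    if not 0 < span <= 1:
        raise ValueError("span must be in (0, 1]")
    k = int(np.ceil(span * n))
    if k < max(_MIN_PTS, degree + 2):
        raise ValueError(
            f"span {span} selects {k} points; the local degree-{degree} fit "
            "is under-determined"
        )
    order = np.argsort(t)
    t, v = t[order], v[order]

    t_eval = np.atleast_1d(np.asarray(t_eval, dtype=float))
    out = np.empty(t_eval.size)
    for i, x0 in enumerate(t_eval):
        d = np.abs(t - x0)
        # k nearest neighbours; bandwidth = distance to the k-th
        idx = np.argpartition(d, k - 1)[:k]
        h = d[idx].max()
        if h == 0:
            out[i] = v[idx][d[idx] == 0].mean()
            continue
        u = d[idx] / h
        w = (1 - u**3) ** 3
        w[u >= 1] = 0
        # guard: at least degree+1 strictly positive weights
        if np.count_nonzero(w > 0) <= degree:
            w = np.maximum(w, 1e-12)
        tc = t[idx] - x0
        X = np.vander(tc, degree + 1, increasing=True)
        sw = np.sqrt(w)
        beta, *_ = np.linalg.lstsq(X * sw[:, None], v[idx] * sw, rcond=None)
        out[i] = beta[0]
    return out
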