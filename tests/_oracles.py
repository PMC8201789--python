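"""Independent oracles used by the test suite.

These deliberately avoid the package's optimisation path: the
two-parameter WLS objective is minimised by exhaustive evaluation on a
dense (cs, d') grid using only the closed-form sum-of-squares algebra.
"""

from __future__ import annotations

import numpy as np


def grid_search_two_param(
    speeds: np.ndarray,
    dependent: np.ndarray,
    weights: np.ndarray,
    formulation: str,
    cs_grid: np.ndarray,
    dprime_grid: np.ndarray,
) -> tuple[float, float, float]:
    """Exhaustive WLS grid minimiser for the two-parameter model.

    For each cs the model is linear in d' (t = d' a(s), a = 1/(s - cs);
    distance multiplies a by s), so the weighted SSE over the whole
    (cs, d') grid expands to C - 2 d' S1(cs) + d'^2 S2(cs) and is
    evaluated without loops.

    Returns (cs, d_prime, weighted_sse) at the grid minimum.
    """
    s = np.asarray(speeds, float)
    y = np.asarray(dependent, float)
    w = np.asarray(weights, float)
    cs = np.asarray(cs_grid, float)[:, None]  # (ncs, 1)
    a = 1.0 / (s[None, :] - cs)  # (ncs, n)
    if formulation == "ds":
        a = a * s[None, :]
    S1 = (w * y * a).sum(axis=1)  # (ncs,)
    S2 = (w * a * a).sum(axis=1)
    C = float((w * y * y).sum())
    dp = np.asarray(dprime_grid, float)[None, :]  # (1, ndp)
    sse = C - 2.0 * dp * S1[:, None] + dp**2 * S2[:, None]
    i, j = np.unravel_index(np.argmin(sse), sse.shape)
    return float(cs_grid[i]), float(dprime_grid[j]), float(sse[i, j])


def ols_slope_intercept(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Closed-form simple OLS (normal equations written out by hand)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xm, ym = x.mean(), y.mean()
    slope = float(((x - xm) * (y - ym)).sum() / ((x - xm) ** 2).sum())
    return slope, float(ym - slope * xm)
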