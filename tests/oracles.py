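"""Independent reference implementations used to cross-check the estimators.

These deliberately avoid the package's own linear algebra: the weighted
percentile is computed by explicit enumeration of the percentile positions and
the weighted regressions by scalar normal-equation sums (Cramer's rule) and by
statsmodels WLS, so agreement is a genuine dual-route check.
"""

from __future__ import annotations

import numpy as np


def weighted_percentile_oracle(ratios, weights, q: float = 50.0) -> float:
    """Brute-force interpolated weighted percentile.

    Orders the ratio estimates ascending, places the j-th at percentile
    100*(S_j - W_j/2) with normalised weights, and linearly interpolates
    between the two bracketing positions (clamping at the extremes).
    """
    pairs = sorted(zip(ratios, weights), key=lambda p: p[0])
    total = sum(w for _, w in pairs)
    positions = []
    running = 0.0
    for r, w in pairs:
        wn = w / total
        running += wn
        positions.append((100.0 * (running - wn / 2.0), r))
    if q <= positions[0][0]:
        return positions[0][1]
    if q >= positions[-1][0]:
        return positions[-1][1]
    for (p_lo, r_lo), (p_hi, r_hi) in zip(positions, positions[1:]):
        if p_lo <= q <= p_hi:
            return r_lo + (r_hi - r_lo) * (q - p_lo) / (p_hi - p_lo)
    raise AssertionError("unreachable")


def ivw_oracle(e, d, se_d) -> tuple[float, float]:
    """IVW beta and SE by direct evaluation of the closed-form sums."""
    num = den = 0.0
    for ek, dk, sk in zip(e, d, se_d):
        num += ek * dk / sk**2
        den += ek**2 / sk**2
    return num / den, den**-0.5


def egger_oracle(e, d, se_d) -> tuple[float, float, float, float]:
    """Weighted-normal-equations Egger fit via Cramer's rule.

    Orientation (E >= 0) applied first; returns (intercept, slope,
    intercept_se, slope_se) with the residual scale factor floored at 1.
    """
    e = np.asarray(e, dtype=float)
    d = np.asarray(d, dtype=float)
    w = 1.0 / np.asarray(se_d, dtype=float) ** 2
    sign = np.where(e < 0, -1.0, 1.0)
    e, d = e * sign, d * sign

    s_w = float(np.sum(w))
    s_we = float(np.sum(w * e))
    s_wee = float(np.sum(w * e * e))
    s_wd = float(np.sum(w * d))
    s_wed = float(np.sum(w * e * d))
    det = s_w * s_wee - s_we**2
    intercept = (s_wee * s_wd - s_we * s_wed) / det
    slope = (s_w * s_wed - s_we * s_wd) / det

    resid = d - intercept - slope * e
    phi = max(1.0, float(np.sum(w * resid**2)) / (len(e) - 2))
    intercept_se = float(np.sqrt(phi * s_wee / det))
    slope_se = float(np.sqrt(phi * s_w / det))
    return intercept, slope, intercept_se, slope_se


def wls_statsmodels(x, y, w, add_intercept: bool):
    """statsmodels WLS point estimates (library route of the dual check)."""
    import statsmodels.api as sm

    design = sm.add_constant(np.asarray(x, float)) if add_intercept else np.asarray(x, float)
    fit = sm.WLS(np.asarray(y, float), design, weights=np.asarray(w, float)).fit()
    return np.atleast_1d(fit.params)
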