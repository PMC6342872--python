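"""Causal-effect estimators for two-sample Mendelian randomisation.

Implements the Wald ratio, the inverse-variance-weighted (IVW) combination,
the weighted-median estimator and Egger regression, together with
instrument-strength diagnostics (variance explained and F-statistic).

All estimators operate on a :class:`~mrmediate.summary_io.HarmonisedSet` whose
rows carry the gene-exposure beta ``E_k`` (SE ``se_exp``) and gene-outcome
beta ``D_k`` (SE ``se_out``) aligned to one effect allele.  Per-SNP ratio
estimates are weighted by the first-order ratio variance ``se_out**2 / E_k**2``
throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .summary_io import HarmonisedSet, InstrumentSet

__all__ = [
    "MRResult",
    "InstrumentStrength",
    "wald_ratio",
    "ivw",
    "weighted_median",
    "egger",
    "instrument_strength",
]

Z_95 = 1.959963984540054  # standard-normal 97.5% quantile


def _two_sided_p(beta: float, se: float) -> float:
    if se == 0:
        return 0.0 if beta != 0 else 1.0
    return float(2.0 * stats.norm.sf(abs(beta) / se))


@dataclass
class MRResult:
    """A causal-effect estimate with SE, 95% CI and p-value.

    ``beta`` is in outcome units per exposure unit (log-odds for binary
    outcomes).  The intercept fields are populated only for ``egger_slope``.
    ``or_scale`` holds ``(OR, OR ci_low, OR ci_high)`` when the outcome is
    binary; it is a presentation layer over the log-odds fields.
    """

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float
    n_snps: int
    exposure: str = ""
    outcome: str = ""
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_p: float | None = None
    or_scale: tuple[float, float, float] | None = None

    def with_or_scale(self) -> "MRResult":
        """Attach the exponentiated (odds-ratio) presentation of the estimate."""
        self.or_scale = (
            math.exp(self.beta),
            math.exp(self.ci_low),
            math.exp(self.ci_high),
        )
        return self

    def to_dict(self) -> dict:
        d = {
            "method": self.method,
            "exposure": self.exposure,
            "outcome": self.outcome,
            "n_snps": self.n_snps,
            "beta": self.beta,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "pvalue": self.pvalue,
        }
        if self.intercept is not None:
            d.update(
                intercept=self.intercept,
                intercept_se=self.intercept_se,
                intercept_p=self.intercept_p,
            )
        if self.or_scale is not None:
            d.update(
                odds_ratio=self.or_scale[0],
                or_ci_low=self.or_scale[1],
                or_ci_high=self.or_scale[2],
            )
        return d


@dataclass
class InstrumentStrength:
    """Variance explained by an instrument set and the implied F-statistic."""

    r_squared: float
    f_statistic: float
    n_snps: int
    n_sample: int
    coverage: float = 1.0  # fraction of SNPs with usable eaf
    skipped: list[str] = field(default_factory=list)


def _result(
    method: str, beta: float, se: float, n_snps: int, h: HarmonisedSet | None = None, **kw
) -> MRResult:
    res = MRResult(
        method=method,
        beta=float(beta),
        se=float(se),
        ci_low=float(beta - Z_95 * se),
        ci_high=float(beta + Z_95 * se),
        pvalue=_two_sided_p(beta, se),
        n_snps=n_snps,
        exposure=h.exposure_name if h else "",
        outcome=h.outcome_name if h else "",
        **kw,
    )
    return res


def wald_ratio(beta_exp: float, se_exp: float, beta_out: float, se_out: float) -> MRResult:
    """Single-SNP causal estimate ``D/E`` with first-order SE ``se_out/|E|``."""
    if beta_exp == 0:
        raise ZeroDivisionError("gene-exposure beta is zero; Wald ratio undefined")
    beta = beta_out / beta_exp
    se = se_out / abs(beta_exp)
    return _result("wald", beta, se, 1)


def ivw(h: HarmonisedSet) -> MRResult:
    """Inverse-variance-weighted estimate.

    beta = sum(E_k D_k / s_Dk^2) / sum(E_k^2 / s_Dk^2), fixed-effect
    SE = sqrt(1 / sum(E_k^2 / s_Dk^2)); equivalent to weighting per-SNP Wald
    ratios by the inverse first-order ratio variance.
    """
    if len(h) < 1:
        raise ValueError("ivw requires at least one SNP")
    e, d, sd = h.beta_exp, h.beta_out, h.se_out
    w = sd**-2.0
    denom = float(np.sum(e**2 * w))
    beta = float(np.sum(e * d * w)) / denom
    se = math.sqrt(1.0 / denom)
    return _result("ivw", beta, se, len(h), h)


def _weighted_median_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    """50th weighted percentile with linear interpolation.

    The j-th ordered ratio sits at percentile ``100 * (S_j - W_j / 2)`` where
    ``S_j`` is the cumulative normalised weight; the estimate interpolates
    between the two ratios whose percentiles bracket 50.
    """
    order = np.argsort(ratios)
    r = ratios[order]
    w = weights[order].astype(float)
    w /= w.sum()
    p = 100.0 * (np.cumsum(w) - 0.5 * w)
    return float(np.interp(50.0, p, r))


def _weighted_median_rows(ratios: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Vectorised row-wise weighted median for the bootstrap (rows x SNPs)."""
    order = np.argsort(ratios, axis=1)
    r = np.take_along_axis(ratios, order, axis=1)
    w = np.take_along_axis(weights, order, axis=1)
    w = w / w.sum(axis=1, keepdims=True)
    p = np.cumsum(w, axis=1) - 0.5 * w
    k = r.shape[1]
    idx = np.clip((p < 0.5).sum(axis=1), 1, k - 1)
    take = lambda a, i: np.take_along_axis(a, i[:, None], axis=1)[:, 0]
    p_lo, p_hi = take(p, idx - 1), take(p, idx)
    r_lo, r_hi = take(r, idx - 1), take(r, idx)
    est = r_lo + (r_hi - r_lo) * (0.5 - p_lo) / (p_hi - p_lo)
    return np.where(p[:, 0] >= 0.5, r[:, 0], est)


def weighted_median(
    h: HarmonisedSet,
    n_boot: int = 1000,
    seed: int | None = None,
    boot_center: str = "fitted",
) -> MRResult:
    """Weighted-median causal estimate with parametric-bootstrap SE.

    Per-SNP ratio estimates are ordered ascending and weighted by the inverse
    first-order ratio variance (``E_k^2 / se_out_k^2``, normalised to sum 1);
    the estimate is the interpolated 50th weighted percentile.  The SE is the
    standard deviation of the estimate over ``n_boot`` parametric resamples of
    the exposure and outcome betas; ``seed`` is mandatory.

    ``boot_center="fitted"`` (default) resamples the outcome betas around the
    fitted values ``beta_hat * E_k``, which calibrates the CI when instruments
    are valid; ``"observed"`` resamples around the observed outcome betas,
    which double-counts their noise and yields mildly conservative intervals.
    """
    if len(h) < 3:
        raise ValueError("weighted_median requires at least 3 SNPs")
    if seed is None:
        raise ValueError("weighted_median requires an explicit seed for the bootstrap")
    if boot_center not in ("fitted", "observed"):
        raise ValueError("boot_center must be 'fitted' or 'observed'")
    e, se_e, d, se_d = h.beta_exp, h.se_exp, h.beta_out, h.se_out
    beta = _weighted_median_point(d / e, e**2 / se_d**2)

    rng = np.random.default_rng(seed)
    eb = rng.normal(e, se_e, size=(n_boot, len(h)))
    d_center = beta * e if boot_center == "fitted" else d
    db = rng.normal(d_center, se_d, size=(n_boot, len(h)))
    with np.errstate(divide="ignore", invalid="ignore"):
        boots = _weighted_median_rows(db / eb, eb**2 / se_d**2)
    se = float(np.std(boots[np.isfinite(boots)], ddof=1))
    return _result("weighted_median", beta, se, len(h), h)


def _wls(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Weighted least squares via the normal equations.

    Returns (coefficients, unscaled covariance (X'WX)^-1, weighted RSS).
    """
    xtw = x.T * w
    xtwx = xtw @ x
    cov = np.linalg.inv(xtwx)
    coef = cov @ (xtw @ y)
    resid = y - x @ coef
    rss = float(np.sum(w * resid**2))
    return coef, cov, rss


def egger(h: HarmonisedSet, constrain_intercept: bool = False) -> MRResult:
    """Egger regression of outcome betas on exposure betas with a free intercept.

    Rows are first re-oriented so every exposure beta is non-negative (the
    outcome beta sign is flipped in tandem); the regression weights are
    ``1 / se_out^2``.  The residual-variance scale factor multiplies the
    coefficient SEs with a floor of 1 (under-dispersion is not allowed) and
    p-values use a standard-normal reference.  A non-zero intercept indicates
    directional pleiotropy.  With ``constrain_intercept=True`` the fit goes
    through the origin and the slope coincides with the IVW estimate.
    """
    k = len(h)
    if k < 3:
        raise ValueError("egger requires at least 3 SNPs")
    sign = np.where(h.beta_exp < 0, -1.0, 1.0)
    e = h.beta_exp * sign
    d = h.beta_out * sign
    w = h.se_out**-2.0
    if np.ptp(e) == 0 and not constrain_intercept:
        raise ValueError("egger slope unidentifiable: all exposure betas identical")

    if constrain_intercept:
        x = e[:, None]
    else:
        x = np.column_stack([np.ones(k), e])
    coef, cov, rss = _wls(x, d, w)
    dof = k - x.shape[1]
    phi = max(1.0, rss / dof) if dof > 0 else 1.0
    ses = np.sqrt(np.diag(cov) * phi)

    if constrain_intercept:
        return _result("egger_slope", coef[0], ses[0], k, h)
    return _result(
        "egger_slope",
        coef[1],
        ses[1],
        k,
        h,
        intercept=float(coef[0]),
        intercept_se=float(ses[0]),
        intercept_p=_two_sided_p(float(coef[0]), float(ses[0])),
    )


def instrument_strength(instruments: InstrumentSet, n_sample: int) -> InstrumentStrength:
    """Variance in the (standardised) trait explained by independent SNPs.

    Each SNP contributes ``2 p (1 - p) beta^2`` where ``p`` is its effect-allele
    frequency; the F-statistic is ``((n - k - 1) / k) * R^2 / (1 - R^2)``.
    SNPs with missing eaf are skipped and reported in the coverage fraction.
    """
    r2 = 0.0
    used = 0
    skipped: list[str] = []
    for rec in instruments.records:
        if rec.eaf is None:
            skipped.append(rec.variant_id)
            continue
        r2 += 2.0 * rec.eaf * (1.0 - rec.eaf) * rec.beta**2
        used += 1
    if used == 0:
        raise ValueError("no SNPs with effect-allele frequency; cannot compute R^2")
    f = ((n_sample - used - 1) / used) * (r2 / (1.0 - r2)) if r2 < 1.0 else math.inf
    return InstrumentStrength(
        r_squared=r2,
        f_statistic=max(0.0, f),
        n_snps=used,
        n_sample=n_sample,
        coverage=used / len(instruments.records),
        skipped=skipped,
    )
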