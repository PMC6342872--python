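"""Multivariable IVW adjustment and mediation-proportion calculation.

The direct (mediator-adjusted) effect of the exposure on the outcome comes
from a weighted regression of the per-SNP outcome betas on the exposure and
mediator betas jointly; the proportion mediated is the relative attenuation
of the total effect.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Collection, Mapping

import numpy as np
from scipy import stats

from .estimators import Z_95, MRResult, _two_sided_p, _wls
from .summary_io import HarmonisedSet

__all__ = [
    "MVMRResult",
    "MediationResult",
    "BinaryMediatorError",
    "mvmr_ivw",
    "proportion_mediated",
    "mediator_triage",
    "TriageDecision",
]

#: default attenuation formula: 1 - beta_direct / beta_total, as a percentage
DEFAULT_FORMULA_TAG = "difference_of_effects:1_minus_direct_over_total_pct"


class BinaryMediatorError(ValueError):
    """Proportion mediated is not defined for a dichotomised mediator."""


@dataclass
class MVMRResult:
    """Exposure effect on the outcome conditional on one or more mediators."""

    exposure_name: str
    outcome_name: str
    mediator_names: list[str]
    direct_beta: float
    direct_se: float
    direct_ci_low: float
    direct_ci_high: float
    direct_p: float
    mediator_effects: dict[str, tuple[float, float, float]]  # name -> (beta, se, p)
    n_snps: int
    dropped_mediators: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "exposure": self.exposure_name,
            "outcome": self.outcome_name,
            "mediators": list(self.mediator_names),
            "n_snps": self.n_snps,
            "direct_beta": self.direct_beta,
            "direct_se": self.direct_se,
            "direct_ci_low": self.direct_ci_low,
            "direct_ci_high": self.direct_ci_high,
            "direct_p": self.direct_p,
            "mediator_effects": {
                m: {"beta": b, "se": s, "pvalue": p}
                for m, (b, s, p) in self.mediator_effects.items()
            },
            "dropped_mediators": list(self.dropped_mediators),
        }


@dataclass
class MediationResult:
    total_beta: float
    direct_beta: float
    proportion_mediated: float  # percent; may fall outside [0, 100]
    formula_tag: str = DEFAULT_FORMULA_TAG

    def to_dict(self) -> dict:
        return {
            "total_beta": self.total_beta,
            "direct_beta": self.direct_beta,
            "proportion_mediated_pct": self.proportion_mediated,
            "formula_tag": self.formula_tag,
        }


def mvmr_ivw(h: HarmonisedSet) -> MVMRResult:
    """Multivariable IVW: regress outcome betas on exposure + mediator betas.

    Weighted least squares with weights ``1 / se_out^2`` and no intercept; the
    coefficient on the exposure column is the direct effect.  Mediator columns
    that are identically zero carry no information and are dropped (logged in
    ``dropped_mediators``) so the fit collapses exactly to univariable IVW;
    any other rank deficiency is fatal and names the collinear columns.
    """
    k = len(h)
    names = list(h.mediator_names)
    m = h.mediator_matrix() if names else np.empty((k, 0))
    keep = [j for j in range(len(names)) if np.any(m[:, j] != 0.0)]
    dropped = [names[j] for j in range(len(names)) if j not in keep]
    names = [names[j] for j in keep]
    m = m[:, keep]

    if k <= 1 + len(names):
        raise ValueError(
            f"mvmr_ivw needs more SNPs ({k}) than regressors ({1 + len(names)})"
        )
    x = np.column_stack([h.beta_exp, m])
    w = h.se_out**-2.0
    xw = x * np.sqrt(w)[:, None]
    if np.linalg.matrix_rank(xw) < x.shape[1]:
        # identify offending columns via near-zero R diagonal of a QR factorisation
        diag = np.abs(np.diag(np.linalg.qr(xw, mode="r")))
        labels = [h.exposure_name] + names
        bad = [labels[j] for j in range(len(labels)) if diag[j] < 1e-10 * diag.max()]
        raise ValueError(f"rank-deficient multivariable design; collinear columns: {bad}")

    coef, cov, _ = _wls(x, h.beta_out, w)
    ses = np.sqrt(np.diag(cov))
    med_effects = {
        name: (float(coef[1 + j]), float(ses[1 + j]), _two_sided_p(coef[1 + j], ses[1 + j]))
        for j, name in enumerate(names)
    }
    beta, se = float(coef[0]), float(ses[0])
    return MVMRResult(
        exposure_name=h.exposure_name,
        outcome_name=h.outcome_name,
        mediator_names=names,
        direct_beta=beta,
        direct_se=se,
        direct_ci_low=beta - Z_95 * se,
        direct_ci_high=beta + Z_95 * se,
        direct_p=_two_sided_p(beta, se),
        mediator_effects=med_effects,
        n_snps=k,
        dropped_mediators=dropped,
    )


def proportion_mediated(
    total: MRResult,
    direct: MVMRResult,
    binary_mediators: Collection[str] = (),
) -> MediationResult:
    """Proportion of the total effect explained by the adjusted-for mediators.

    Default formula: ``100 * (1 - beta_direct / beta_total)``, computed on the
    estimation scale (log-odds for binary outcomes).  Refuses dichotomised
    mediators, for which the attenuation formula has no proportion
    interpretation.
    """
    binary = sorted(set(direct.mediator_names) & set(binary_mediators))
    if binary:
        raise BinaryMediatorError(
            f"proportion mediated is not assessed for dichotomised mediator(s) {binary}"
        )
    if total.beta == 0:
        raise ZeroDivisionError("total effect is zero; proportion mediated undefined")
    prop = 100.0 * (1.0 - direct.direct_beta / total.beta)
    return MediationResult(
        total_beta=total.beta,
        direct_beta=direct.direct_beta,
        proportion_mediated=prop,
        formula_tag=DEFAULT_FORMULA_TAG,
    )


@dataclass
class TriageDecision:
    mediator: str
    status: str  # "pass" | "fail" | "not_evaluable"
    reasons: list[str] = field(default_factory=list)


_METHODS = ("ivw", "weighted_median", "egger_slope")


def _step_support(results: Mapping[str, MRResult]) -> list[str]:
    """Reasons this step fails to support a causal effect (empty = supported)."""
    missing = [m for m in _METHODS if m not in results]
    if missing:
        return [f"missing:{','.join(missing)}"]
    reasons = []
    signs = {np.sign(results[m].beta) for m in _METHODS}
    if len(signs) != 1 or signs == {0.0}:
        reasons.append("discordant_signs")
    for m in ("ivw", "weighted_median"):
        r = results[m]
        if r.ci_low <= 0.0 <= r.ci_high:
            reasons.append(f"{m}_ci_includes_null")
    return reasons


def mediator_triage(
    step_one: Mapping[str, Mapping[str, MRResult]],
    step_two: Mapping[str, Mapping[str, MRResult]],
) -> tuple[list[str], dict[str, TriageDecision]]:
    """Select mediators with causal support in both steps.

    A candidate passes iff, for exposure->mediator (step one) and
    mediator->outcome (step two): the IVW, weighted-median and Egger point
    estimates agree in sign and the IVW and weighted-median 95% CIs exclude
    zero.  The Egger CI may include zero provided its point estimate is
    sign-concordant.  Candidates with missing method results are marked
    ``not_evaluable``.
    """
    decisions: dict[str, TriageDecision] = {}
    for name in step_one:
        reasons = [f"step1_{r}" for r in _step_support(step_one[name])]
        reasons += [f"step2_{r}" for r in _step_support(step_two.get(name, {}))]
        if name not in step_two:
            reasons.append("step2_missing")
        if any("missing" in r for r in reasons):
            status = "not_evaluable"
        elif reasons:
            status = "fail"
        else:
            status = "pass"
        decisions[name] = TriageDecision(mediator=name, status=status, reasons=reasons)
    passed = [n for n, d in decisions.items() if d.status == "pass"]
    return passed, decisions
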