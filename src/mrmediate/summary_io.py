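"""Reading, validation and allele harmonisation of GWAS summary-association tables.

A summary-association table holds one row per SNP with the per-allele effect
(beta), its standard error and optionally the effect-allele frequency, p-value
and sample size.  Two-sample Mendelian randomisation requires the gene-exposure
and gene-outcome associations to be expressed relative to the *same* effect
allele for every SNP; :func:`harmonise` performs that alignment and logs every
exclusion it makes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "VariantAssociation",
    "InstrumentSet",
    "HarmonisedRow",
    "HarmonisedSet",
    "HarmonisationError",
    "read_association_table",
    "write_association_table",
    "harmonise",
    "rescale_estimate",
]

VALID_ALLELES = frozenset({"A", "C", "G", "T"})
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: logical -> default file column names
DEFAULT_COLUMNS = {
    "variant_id": "variant_id",
    "effect_allele": "effect_allele",
    "other_allele": "other_allele",
    "eaf": "eaf",
    "beta": "beta",
    "se": "se",
    "pvalue": "pvalue",
    "n": "n",
}

_OPTIONAL = ("eaf", "pvalue", "n")


class HarmonisationError(RuntimeError):
    """No SNPs survived harmonisation; carries the exclusion log."""

    def __init__(self, message: str, exclusion_log: list[tuple[str, str]]):
        super().__init__(message)
        self.exclusion_log = exclusion_log


@dataclass(frozen=True)
class VariantAssociation:
    """One SNP's summary association with one trait.

    ``beta`` is the mean change in the trait per additional copy of
    ``effect_allele`` (log-odds for binary traits); ``se`` is its standard
    error.  ``eaf`` is the effect-allele frequency.
    """

    variant_id: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    eaf: float | None = None
    pvalue: float | None = None
    n: float | None = None

    def invalid_reason(self) -> str | None:
        """Return an exclusion reason, or ``None`` when the record is valid."""
        if self.effect_allele not in VALID_ALLELES or self.other_allele not in VALID_ALLELES:
            return "malformed_allele"
        if self.effect_allele == self.other_allele:
            return "identical_alleles"
        if not math.isfinite(self.beta):
            return "missing_beta"
        if not math.isfinite(self.se) or self.se <= 0:
            return "nonpositive_se"
        if self.eaf is not None and not (0.0 < self.eaf < 1.0):
            return "eaf_out_of_range"
        if self.pvalue is not None and not (0.0 < self.pvalue <= 1.0):
            return "pvalue_out_of_range"
        return None

    @property
    def is_palindromic(self) -> bool:
        return COMPLEMENT[self.effect_allele] == self.other_allele

    def flipped(self) -> "VariantAssociation":
        """The same association expressed relative to the other allele."""
        return replace(
            self,
            effect_allele=self.other_allele,
            other_allele=self.effect_allele,
            beta=-self.beta,
            eaf=None if self.eaf is None else 1.0 - self.eaf,
        )


@dataclass
class InstrumentSet:
    """A named collection of variant associations for one trait."""

    trait_name: str
    records: list[VariantAssociation]
    trait_type: str = "continuous"
    unit_label: str = ""
    exclusions: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.trait_type not in ("continuous", "binary"):
            raise ValueError(f"trait_type must be continuous or binary, got {self.trait_type!r}")
        if self.trait_type == "binary" and not self.unit_label:
            self.unit_label = "log-odds"
        ids = [r.variant_id for r in self.records]
        if len(ids) != len(set(ids)):
            dup = sorted({v for v in ids if ids.count(v) > 1})
            raise ValueError(f"duplicate variant ids in {self.trait_name}: {dup[:5]}")

    def __len__(self) -> int:
        return len(self.records)

    def by_id(self) -> dict[str, VariantAssociation]:
        return {r.variant_id: r for r in self.records}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "variant_id": r.variant_id,
                "effect_allele": r.effect_allele,
                "other_allele": r.other_allele,
                "eaf": r.eaf,
                "beta": r.beta,
                "se": r.se,
                "pvalue": r.pvalue,
                "n": r.n,
            }
            for r in self.records
        ]
        return pd.DataFrame(rows, columns=list(DEFAULT_COLUMNS))


@dataclass(frozen=True)
class HarmonisedRow:
    """Exposure/outcome (and mediator) betas aligned to one effect allele."""

    variant_id: str
    effect_allele: str
    other_allele: str
    beta_exp: float
    se_exp: float
    beta_out: float
    se_out: float
    eaf_exp: float | None = None
    mediators: Mapping[str, tuple[float, float]] = field(default_factory=dict)


@dataclass
class HarmonisedSet:
    """Per-SNP aligned summary statistics ready for estimation."""

    exposure_name: str
    outcome_name: str
    rows: list[HarmonisedRow]
    mediator_names: list[str] = field(default_factory=list)
    exclusion_log: list[tuple[str, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.rows)

    @property
    def beta_exp(self) -> np.ndarray:
        return np.array([r.beta_exp for r in self.rows], dtype=float)

    @property
    def se_exp(self) -> np.ndarray:
        return np.array([r.se_exp for r in self.rows], dtype=float)

    @property
    def beta_out(self) -> np.ndarray:
        return np.array([r.beta_out for r in self.rows], dtype=float)

    @property
    def se_out(self) -> np.ndarray:
        return np.array([r.se_out for r in self.rows], dtype=float)

    def mediator_matrix(self) -> np.ndarray:
        """SNP x mediator matrix of aligned mediator betas."""
        return np.array(
            [[r.mediators[m][0] for m in self.mediator_names] for r in self.rows], dtype=float
        ).reshape(len(self.rows), len(self.mediator_names))

    def to_frame(self) -> pd.DataFrame:
        data: dict[str, list] = {
            "variant_id": [r.variant_id for r in self.rows],
            "effect_allele": [r.effect_allele for r in self.rows],
            "other_allele": [r.other_allele for r in self.rows],
            "eaf_exp": [r.eaf_exp for r in self.rows],
            "beta_exp": [r.beta_exp for r in self.rows],
            "se_exp": [r.se_exp for r in self.rows],
            "beta_out": [r.beta_out for r in self.rows],
            "se_out": [r.se_out for r in self.rows],
        }
        for m in self.mediator_names:
            data[f"beta_{m}"] = [r.mediators[m][0] for r in self.rows]
            data[f"se_{m}"] = [r.mediators[m][1] for r in self.rows]
        return pd.DataFrame(data)

    def write(self, path: str | Path, exclusions_path: str | Path | None = None) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)
        if exclusions_path is not None:
            pd.DataFrame(self.exclusion_log, columns=["variant_id", "reason"]).to_csv(
                exclusions_path, sep="\t", index=False
            )


def _coerce_float(value) -> float | None:
    if value is None:
        return None
    try:
        f = float(value)
    except (TypeError, ValueError):
        return None
    return f if math.isfinite(f) else None


def read_association_table(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    *,
    trait_name: str | None = None,
    trait_type: str = "continuous",
    unit_label: str = "",
) -> InstrumentSet:
    """Read a TSV/CSV summary-association table into an :class:`InstrumentSet`.

    ``column_map`` maps the logical names of :data:`DEFAULT_COLUMNS` to the
    file's actual column names.  Rows violating record invariants (e.g.
    ``se <= 0``) are routed to ``InstrumentSet.exclusions`` with a reason, not
    silently dropped.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    frame = pd.read_csv(path, sep=sep)
    cols = dict(DEFAULT_COLUMNS)
    if column_map:
        cols.update(column_map)
    for logical in ("variant_id", "effect_allele", "other_allele", "beta", "se"):
        if cols[logical] not in frame.columns:
            raise ValueError(f"required column {cols[logical]!r} ({logical}) missing in {path}")

    records: list[VariantAssociation] = []
    exclusions: list[tuple[str, str]] = []
    for _, row in frame.iterrows():
        vid = str(row[cols["variant_id"]])
        optional = {
            k: _coerce_float(row[cols[k]]) if cols[k] in frame.columns else None for k in _OPTIONAL
        }
        beta = _coerce_float(row[cols["beta"]])
        se = _coerce_float(row[cols["se"]])
        rec = VariantAssociation(
            variant_id=vid,
            effect_allele=str(row[cols["effect_allele"]]).strip().upper(),
            other_allele=str(row[cols["other_allele"]]).strip().upper(),
            beta=math.nan if beta is None else beta,
            se=math.nan if se is None else se,
            **optional,
        )
        reason = rec.invalid_reason()
        if reason is None:
            records.append(rec)
        else:
            exclusions.append((vid, reason))
    return InstrumentSet(
        trait_name=trait_name or path.stem,
        records=records,
        trait_type=trait_type,
        unit_label=unit_label,
        exclusions=exclusions,
    )


def write_association_table(instruments: InstrumentSet, path: str | Path) -> None:
    """Write an instrument set in the TSV dialect :func:`read_association_table` reads."""
    instruments.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")


def _align_to(
    exposure: VariantAssociation, other: VariantAssociation
) -> tuple[VariantAssociation | None, str]:
    """Re-express ``other`` relative to the exposure's effect allele.

    Returns ``(aligned record, tag)`` where the tag is one of ``direct``,
    ``swapped``, ``strand``, ``strand_swapped`` or ``mismatch``.
    """
    ea, oa = exposure.effect_allele, exposure.other_allele
    if other.effect_allele == ea and other.other_allele == oa:
        return other, "direct"
    if other.effect_allele == oa and other.other_allele == ea:
        return other.flipped(), "swapped"
    cea, coa = COMPLEMENT[other.effect_allele], COMPLEMENT[other.other_allele]
    if cea == ea and coa == oa:
        return replace(other, effect_allele=cea, other_allele=coa), "strand"
    if cea == oa and coa == ea:
        return replace(other, effect_allele=cea, other_allele=coa).flipped(), "strand_swapped"
    return None, "mismatch"


def _eaf_inside(eaf: float | None, window: tuple[float, float]) -> bool:
    return eaf is None or (window[0] < eaf < window[1])


def _align_palindromic(
    exposure: VariantAssociation,
    other: VariantAssociation,
    policy: str,
    window: tuple[float, float],
) -> tuple[VariantAssociation | None, str | None]:
    """Handle an A/T or C/G SNP per policy; returns (aligned, exclusion reason)."""
    if policy == "drop_all":
        return None, "palindromic"
    aligned, tag = _align_to(exposure, other)
    if aligned is None:
        return None, "allele_mismatch"
    if policy == "keep":
        return aligned, None
    if policy != "drop_ambiguous":
        raise ValueError(f"unknown palindrome_policy {policy!r}")
    if _eaf_inside(exposure.eaf, window) or _eaf_inside(aligned.eaf, window):
        return None, "palindromic_ambiguous"
    # Frequencies are informative: a strand flip shows up as eaf on opposite
    # sides of 0.5, in which case the label-based alignment must be reversed.
    if (exposure.eaf - 0.5) * (aligned.eaf - 0.5) < 0:
        aligned = aligned.flipped()
    return aligned, None


def harmonise(
    exposure: InstrumentSet,
    outcome: InstrumentSet,
    palindrome_policy: str = "drop_ambiguous",
    eaf_ambiguity_window: tuple[float, float] = (0.42, 0.58),
    mediators: Mapping[str, InstrumentSet] | None = None,
) -> HarmonisedSet:
    """Match exposure and outcome (and mediator) associations on variant id and
    align them to the exposure's effect allele.

    When the outcome record's alleles are swapped relative to the exposure the
    outcome beta sign is flipped and its eaf replaced by ``1 - eaf``.
    Palindromic SNPs (A/T, C/G) are handled per ``palindrome_policy``:
    ``drop_ambiguous`` drops them iff either side's eaf is missing or falls
    inside ``eaf_ambiguity_window``; ``drop_all`` drops every palindromic SNP;
    ``keep`` aligns by allele labels alone.  Unmatched or invalid SNPs are
    logged, never silently dropped.
    """
    if not exposure.records or not outcome.records:
        raise ValueError("exposure and outcome sets must be non-empty")
    mediators = mediators or {}
    out_by_id = outcome.by_id()
    med_by_id = {name: s.by_id() for name, s in mediators.items()}

    rows: list[HarmonisedRow] = []
    log: list[tuple[str, str]] = []
    for exp in exposure.records:
        vid = exp.variant_id
        out = out_by_id.get(vid)
        if out is None:
            log.append((vid, f"missing_in_{outcome.trait_name}"))
            continue
        if exp.is_palindromic:
            aligned, reason = _align_palindromic(exp, out, palindrome_policy, eaf_ambiguity_window)
        else:
            aligned, tag = _align_to(exp, out)
            reason = "allele_mismatch" if aligned is None else None
        if aligned is None:
            log.append((vid, reason or "allele_mismatch"))
            continue

        med_values: dict[str, tuple[float, float]] = {}
        failed = None
        for name in mediators:
            rec = med_by_id[name].get(vid)
            if rec is None:
                failed = f"missing_in_{name}"
                break
            if exp.is_palindromic:
                arec, mreason = _align_palindromic(
                    exp, rec, palindrome_policy, eaf_ambiguity_window
                )
                if arec is None:
                    failed = f"{mreason}_in_{name}"
                    break
            else:
                arec, _ = _align_to(exp, rec)
                if arec is None:
                    failed = f"allele_mismatch_in_{name}"
                    break
            med_values[name] = (arec.beta, arec.se)
        if failed is not None:
            log.append((vid, failed))
            continue

        rows.append(
            HarmonisedRow(
                variant_id=vid,
                effect_allele=exp.effect_allele,
                other_allele=exp.other_allele,
                beta_exp=exp.beta,
                se_exp=exp.se,
                beta_out=aligned.beta,
                se_out=aligned.se,
                eaf_exp=exp.eaf,
                mediators=med_values,
            )
        )

    if not rows:
        raise HarmonisationError(
            f"no SNPs survived harmonisation of {exposure.trait_name} vs {outcome.trait_name}",
            log,
        )
    return HarmonisedSet(
        exposure_name=exposure.trait_name,
        outcome_name=outcome.trait_name,
        rows=rows,
        mediator_names=list(mediators),
        exclusion_log=log,
    )


def rescale_estimate(beta: float, se: float, factor: float) -> tuple[float, float]:
    """Rescale a point estimate and its SE by a positive unit-conversion factor.

    The p-value is unaffected since beta and SE scale together (e.g. HbA1c
    effects in % multiply by 10.929 to give IFCC mmol/mol).
    """
    if not factor > 0:
        raise ValueError(f"conversion factor must be positive, got {factor}")
    return beta * factor, se * factor
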