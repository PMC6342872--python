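"""Orchestration of the full two-step analysis.

Order of play: instrument-strength diagnostics, bidirectional screen among all
traits, step one (exposure -> mediators, three methods), step two (mediators ->
outcome), mediator triage, then multivariable mediation models.  Every number
lands both in human-readable TSV tables and a machine-readable JSON bundle
containing identical values, plus a run log recording seeds, policies and
exclusions.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import yaml

from .estimators import MRResult, egger, instrument_strength, ivw, weighted_median
from .mediation import (
    BinaryMediatorError,
    MediationResult,
    MVMRResult,
    mediator_triage,
    mvmr_ivw,
    proportion_mediated,
)
from .summary_io import HarmonisedSet, InstrumentSet, harmonise, read_association_table

__all__ = [
    "TraitSpec",
    "StudyConfig",
    "ScreenResult",
    "ReportBundle",
    "bidirectional_screen",
    "run_two_step",
]


def _stars(p: float) -> str:
    return "***" if p < 0.001 else "**" if p < 0.01 else "*" if p < 0.05 else ""


@dataclass
class TraitSpec:
    """One trait's files: its own instruments and its full association table."""

    name: str
    trait_type: str = "continuous"
    unit_label: str = ""
    instrument_file: str | None = None
    association_file: str | None = None


@dataclass
class StudyConfig:
    exposure: str
    outcome: str
    traits: list[TraitSpec]
    mediators: list[str] = field(default_factory=list)
    seed: int = 0
    n_boot: int = 1000
    palindrome_policy: str = "drop_ambiguous"
    eaf_ambiguity_window: tuple[float, float] = (0.42, 0.58)
    out_dir: str = "results"
    base_dir: Path = field(default_factory=Path)

    def __post_init__(self) -> None:
        names = {t.name for t in self.traits}
        for required in (self.exposure, self.outcome, *self.mediators):
            if required not in names:
                raise ValueError(f"trait {required!r} not declared in config traits")
        self.base_dir = Path(self.base_dir)
        self.eaf_ambiguity_window = tuple(self.eaf_ambiguity_window)  # type: ignore[assignment]

    def trait(self, name: str) -> TraitSpec:
        for t in self.traits:
            if t.name == name:
                return t
        raise KeyError(name)

    def _resolve(self, rel: str) -> Path:
        p = Path(rel)
        return p if p.is_absolute() else self.base_dir / p

    def load_instruments(self, name: str) -> InstrumentSet | None:
        t = self.trait(name)
        if t.instrument_file is None:
            return None
        return read_association_table(
            self._resolve(t.instrument_file),
            trait_name=name,
            trait_type=t.trait_type,
            unit_label=t.unit_label,
        )

    def load_associations(self, name: str) -> InstrumentSet:
        t = self.trait(name)
        if t.association_file is None:
            raise ValueError(f"trait {name!r} has no association file")
        return read_association_table(
            self._resolve(t.association_file),
            trait_name=name,
            trait_type=t.trait_type,
            unit_label=t.unit_label,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        path = Path(path)
        raw = yaml.safe_load(path.read_text())
        traits = [
            TraitSpec(
                name=t["name"],
                trait_type=t.get("type", "continuous"),
                unit_label=t.get("unit", ""),
                instrument_file=t.get("instruments"),
                association_file=t.get("associations"),
            )
            for t in raw["traits"]
        ]
        return cls(
            exposure=raw["exposure"],
            outcome=raw["outcome"],
            mediators=list(raw.get("mediators", [])),
            traits=traits,
            seed=int(raw.get("seed", 0)),
            n_boot=int(raw.get("n_boot", 1000)),
            palindrome_policy=raw.get("palindrome_policy", "drop_ambiguous"),
            eaf_ambiguity_window=tuple(raw.get("eaf_ambiguity_window", (0.42, 0.58))),
            out_dir=raw.get("out_dir", "results"),
            base_dir=path.parent,
        )

    def to_yaml(self, path: str | Path) -> None:
        doc = {
            "exposure": self.exposure,
            "outcome": self.outcome,
            "mediators": list(self.mediators),
            "seed": self.seed,
            "n_boot": self.n_boot,
            "palindrome_policy": self.palindrome_policy,
            "eaf_ambiguity_window": list(self.eaf_ambiguity_window),
            "out_dir": str(self.out_dir),
            "traits": [
                {
                    "name": t.name,
                    "type": t.trait_type,
                    "unit": t.unit_label,
                    "instruments": t.instrument_file,
                    "associations": t.association_file,
                }
                for t in self.traits
            ],
        }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


@dataclass
class ScreenResult:
    """Square matrix of IVW estimates: every instrumented trait vs the rest."""

    trait_names: list[str]
    results: dict[tuple[str, str], MRResult]
    unavailable: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "traits": self.trait_names,
            "unavailable_exposures": self.unavailable,
            "cells": {
                f"{e}->{o}": r.to_dict() for (e, o), r in self.results.items()
            },
        }

    def to_tsv(self) -> str:
        header = ["exposure\\outcome"] + self.trait_names
        lines = ["\t".join(header)]
        for e in self.trait_names:
            cells = [e]
            for o in self.trait_names:
                if e == o:
                    cells.append("0")
                elif e in self.unavailable:
                    cells.append("NA")
                else:
                    r = self.results.get((e, o))
                    cells.append(
                        "NA" if r is None else f"{r.beta} ({r.se}){_stars(r.pvalue)}"
                    )
            lines.append("\t".join(cells))
        return "\n".join(lines) + "\n"


def _estimate_pair(
    cfg: StudyConfig,
    exposure_name: str,
    outcome_name: str,
    seed: int,
    methods: tuple[str, ...] = ("ivw", "weighted_median", "egger_slope"),
) -> tuple[HarmonisedSet, dict[str, MRResult], list[str]]:
    """Harmonise one exposure/outcome pair and run the requested estimators."""
    exposure = cfg.load_instruments(exposure_name)
    if exposure is None:
        raise FileNotFoundError(f"no instrument file for exposure {exposure_name!r}")
    outcome = cfg.load_associations(outcome_name)
    h = harmonise(
        exposure,
        outcome,
        palindrome_policy=cfg.palindrome_policy,
        eaf_ambiguity_window=cfg.eaf_ambiguity_window,
    )
    binary = cfg.trait(outcome_name).trait_type == "binary"
    results: dict[str, MRResult] = {}
    notes: list[str] = []
    for method in methods:
        try:
            if method == "ivw":
                r = ivw(h)
            elif method == "weighted_median":
                r = weighted_median(h, n_boot=cfg.n_boot, seed=seed)
            elif method == "egger_slope":
                r = egger(h)
            else:
                raise ValueError(f"unknown method {method!r}")
        except (ValueError, ZeroDivisionError) as exc:
            notes.append(f"{method} failed for {exposure_name}->{outcome_name}: {exc}")
            continue
        if binary:
            r.with_or_scale()
        results[method] = r
    return h, results, notes


def bidirectional_screen(cfg: StudyConfig) -> tuple[ScreenResult, list[str]]:
    """IVW estimate of every instrumented trait on every other trait.

    Traits without an instrument file cannot act as exposure; their row is
    marked unavailable and the run continues.
    """
    names = [t.name for t in cfg.traits]
    results: dict[tuple[str, str], MRResult] = {}
    unavailable: list[str] = []
    log: list[str] = []
    seed_idx = 0
    for e in names:
        if cfg.trait(e).instrument_file is None:
            unavailable.append(e)
            log.append(f"screen: no instruments for {e}; row unavailable")
            continue
        for o in names:
            if o == e:
                continue
            seed_idx += 1
            try:
                _, res, notes = _estimate_pair(
                    cfg, e, o, seed=cfg.seed + seed_idx, methods=("ivw",)
                )
            except Exception as exc:  # noqa: BLE001 - screen is best-effort
                log.append(f"screen {e}->{o} failed: {exc}")
                continue
            log.extend(notes)
            if "ivw" in res:
                results[(e, o)] = res["ivw"]
    return ScreenResult(trait_names=names, results=results, unavailable=unavailable), log


@dataclass
class MediationModel:
    label: str
    mediators: list[str]
    mvmr: MVMRResult
    mediation: MediationResult | None
    note: str = ""

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "mediators": list(self.mediators),
            "mvmr": self.mvmr.to_dict(),
            "mediation": None if self.mediation is None else self.mediation.to_dict(),
            "note": self.note,
        }


@dataclass
class ReportBundle:
    """Everything one pipeline run produced, serialisable as TSV + JSON."""

    config: StudyConfig
    strength: dict[str, dict]
    screen: ScreenResult | None
    total: dict[str, MRResult]
    step_one: dict[str, dict[str, MRResult]]
    step_two: dict[str, dict[str, MRResult]]
    triage_passed: list[str]
    triage_detail: dict[str, dict]
    mediation_models: list[MediationModel]
    log: list[str]

    def to_dict(self) -> dict:
        return {
            "exposure": self.config.exposure,
            "outcome": self.config.outcome,
            "seed": self.config.seed,
            "instrument_strength": self.strength,
            "screen": None if self.screen is None else self.screen.to_dict(),
            "total_effect": {m: r.to_dict() for m, r in self.total.items()},
            "step_one": {
                med: {m: r.to_dict() for m, r in res.items()}
                for med, res in self.step_one.items()
            },
            "step_two": {
                med: {m: r.to_dict() for m, r in res.items()}
                for med, res in self.step_two.items()
            },
            "triage": {"passed": self.triage_passed, "detail": self.triage_detail},
            "mediation": [m.to_dict() for m in self.mediation_models],
        }

    @staticmethod
    def _method_rows(target: str, results: Mapping[str, MRResult]) -> list[list[str]]:
        rows = []
        for method, r in results.items():
            d = r.to_dict()
            rows.append(
                [
                    target,
                    method,
                    str(d["n_snps"]),
                    str(d["beta"]),
                    str(d["se"]),
                    str(d["ci_low"]),
                    str(d["ci_high"]),
                    str(d["pvalue"]),
                    str(d.get("intercept", "")),
                    str(d.get("intercept_se", "")),
                    str(d.get("intercept_p", "")),
                    str(d.get("odds_ratio", "")),
                    str(d.get("or_ci_low", "")),
                    str(d.get("or_ci_high", "")),
                ]
            )
        return rows

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        header = (
            "target\tmethod\tn_snps\tbeta\tse\tci_low\tci_high\tpvalue\t"
            "intercept\tintercept_se\tintercept_p\tor\tor_ci_low\tor_ci_high\n"
        )

        step1 = [header] + [
            "\t".join(row) + "\n"
            for target, res in [(self.config.outcome, self.total)] + list(self.step_one.items())
            for row in self._method_rows(target, res)
        ]
        (out / "step_one.tsv").write_text("".join(step1))

        step2 = [header] + [
            "\t".join(row) + "\n"
            for target, res in self.step_two.items()
            for row in self._method_rows(target, res)
        ]
        (out / "step_two.tsv").write_text("".join(step2))

        if self.screen is not None:
            (out / "screen.tsv").write_text(self.screen.to_tsv())

        med_lines = ["model\tmediators\tn_snps\tbeta\tse\tor\tor_ci_low\tor_ci_high\tpvalue\tmediation_pct\tnote\n"]
        for model in self.mediation_models:
            d = model.mvmr.to_dict()
            binary = self.config.trait(self.config.outcome).trait_type == "binary"
            import math as _math

            or_cells = (
                [
                    str(_math.exp(d["direct_beta"])),
                    str(_math.exp(d["direct_ci_low"])),
                    str(_math.exp(d["direct_ci_high"])),
                ]
                if binary
                else ["", "", ""]
            )
            med_lines.append(
                "\t".join(
                    [
                        model.label,
                        "+".join(model.mediators),
                        str(d["n_snps"]),
                        str(d["direct_beta"]),
                        str(d["direct_se"]),
                        *or_cells,
                        str(d["direct_p"]),
                        ""
                        if model.mediation is None
                        else str(model.mediation.proportion_mediated),
                        model.note,
                    ]
                )
                + "\n"
            )
        (out / "mediation.tsv").write_text("".join(med_lines))

        (out / "results.json").write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))
        (out / "run_log.txt").write_text("".join(line + "\n" for line in self.log))


def _pooled_instruments(
    cfg: StudyConfig,
    exposure_inst: InstrumentSet,
    mediator_group: list[str],
    log: list[str],
) -> InstrumentSet:
    """Union of exposure + mediator instruments with exposure-trait betas.

    Mediator-specific SNPs get their gene-exposure association from the
    exposure's full association table; SNPs absent from it are logged and
    dropped.  Overlapping instruments between traits are kept once.
    """
    records = {r.variant_id: r for r in exposure_inst.records}
    extra_ids: list[str] = []
    for med in mediator_group:
        med_inst = cfg.load_instruments(med)
        if med_inst is None:
            log.append(f"mvmr: no instrument file for mediator {med}; using exposure SNPs only")
            continue
        extra_ids.extend(r.variant_id for r in med_inst.records if r.variant_id not in records)
    if extra_ids:
        exposure_assoc = cfg.load_associations(cfg.exposure).by_id()
        found = 0
        for vid in extra_ids:
            rec = exposure_assoc.get(vid)
            if rec is None:
                log.append(f"mvmr: {vid} missing from {cfg.exposure} associations; dropped")
            elif vid not in records:
                records[vid] = rec
                found += 1
        log.append(
            f"mvmr: pooled {len(exposure_inst.records)} exposure + {found} mediator instruments"
        )
    return InstrumentSet(
        trait_name=exposure_inst.trait_name,
        records=list(records.values()),
        trait_type=exposure_inst.trait_type,
        unit_label=exposure_inst.unit_label,
    )


def run_two_step(cfg: StudyConfig, include_screen: bool = True) -> ReportBundle:
    """Run the complete two-step mediation analysis described by ``cfg``.

    Fatal errors in any single estimator are recorded in the run log and the
    remaining analyses continue.  Re-running with the same config and seed
    reproduces every emitted number bit-identically.
    """
    log = [
        f"exposure={cfg.exposure} outcome={cfg.outcome} mediators={cfg.mediators}",
        f"seed={cfg.seed} n_boot={cfg.n_boot} palindrome_policy={cfg.palindrome_policy} "
        f"window={cfg.eaf_ambiguity_window}",
    ]

    strength: dict[str, dict] = {}
    for t in cfg.traits:
        inst = cfg.load_instruments(t.name)
        if inst is None or not inst.records:
            continue
        ns = [r.n for r in inst.records if r.n is not None]
        if not ns:
            log.append(f"strength: no sample sizes for {t.name}; skipped")
            continue
        try:
            s = instrument_strength(inst, n_sample=int(max(ns)))
        except ValueError as exc:
            log.append(f"strength: {t.name}: {exc}")
            continue
        strength[t.name] = {
            "r_squared": s.r_squared,
            "f_statistic": s.f_statistic,
            "n_snps": s.n_snps,
            "n_sample": s.n_sample,
            "coverage": s.coverage,
        }

    screen = None
    if include_screen:
        screen, screen_log = bidirectional_screen(cfg)
        log.extend(screen_log)

    seed_idx = 10_000  # disjoint from the screen's seed offsets

    def next_seed() -> int:
        nonlocal seed_idx
        seed_idx += 1
        return cfg.seed + seed_idx

    # total (crude) effect of exposure on outcome
    h_total, total, notes = _estimate_pair(cfg, cfg.exposure, cfg.outcome, next_seed())
    log.extend(notes)
    log.append(
        f"total: {len(h_total)} SNPs retained, {len(h_total.exclusion_log)} excluded "
        f"({[f'{v}:{r}' for v, r in h_total.exclusion_log[:10]]}...)"
    )

    step_one: dict[str, dict[str, MRResult]] = {}
    step_two: dict[str, dict[str, MRResult]] = {}
    for med in cfg.mediators:
        try:
            _, res1, notes1 = _estimate_pair(cfg, cfg.exposure, med, next_seed())
            step_one[med] = res1
            log.extend(notes1)
        except Exception as exc:  # noqa: BLE001
            step_one[med] = {}
            log.append(f"step one {cfg.exposure}->{med} failed: {exc}")
        try:
            _, res2, notes2 = _estimate_pair(cfg, med, cfg.outcome, next_seed())
            step_two[med] = res2
            log.extend(notes2)
        except Exception as exc:  # noqa: BLE001
            step_two[med] = {}
            log.append(f"step two {med}->{cfg.outcome} failed: {exc}")

    passed, decisions = mediator_triage(step_one, step_two)
    triage_detail = {n: dataclasses.asdict(d) for n, d in decisions.items()}
    log.append(f"triage passed: {passed}")

    binary_meds = {m for m in cfg.mediators if cfg.trait(m).trait_type == "binary"}
    models: list[MediationModel] = []
    if "ivw" in total and passed:
        groups = [[m] for m in passed]
        if len(passed) > 1:
            groups.append(list(passed))
        exposure_inst = cfg.load_instruments(cfg.exposure)
        outcome_assoc = cfg.load_associations(cfg.outcome)
        for group in groups:
            label = "adjusted_for_" + "+".join(group)
            try:
                # multivariable design: pool the exposure's and each mediator's
                # instruments, with exposure betas looked up in the exposure's
                # full association table so mediator-specific SNPs identify the
                # conditional mediator effect
                pooled = _pooled_instruments(cfg, exposure_inst, group, log)
                h = harmonise(
                    pooled,
                    outcome_assoc,
                    palindrome_policy=cfg.palindrome_policy,
                    eaf_ambiguity_window=cfg.eaf_ambiguity_window,
                    mediators={m: cfg.load_associations(m) for m in group},
                )
                mv = mvmr_ivw(h)
            except Exception as exc:  # noqa: BLE001
                log.append(f"mediation model {label} failed: {exc}")
                continue
            note = ""
            try:
                medres = proportion_mediated(total["ivw"], mv, binary_mediators=binary_meds)
            except BinaryMediatorError as exc:
                medres, note = None, str(exc)
            except ZeroDivisionError as exc:
                medres, note = None, str(exc)
            models.append(
                MediationModel(label=label, mediators=group, mvmr=mv, mediation=medres, note=note)
            )

    return ReportBundle(
        config=cfg,
        strength=strength,
        screen=screen,
        total=total,
        step_one=step_one,
        step_two=step_two,
        triage_passed=passed,
        triage_detail=triage_detail,
        mediation_models=models,
        log=log,
    )
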