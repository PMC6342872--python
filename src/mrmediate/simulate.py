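"""Synthetic two-sample GWAS summary statistics with known causal structure.

Generates independent SNPs with per-allele effects on an exposure, optional
mediators and an outcome, then adds independent sampling noise per dataset
(the two-sample design).  Horizontal pleiotropy and mediation structure are
configurable, so every estimator can be validated against the generating
truth without any external download.

Per SNP k the generative model is::

    maf      p_k ~ Uniform(maf_range)
    exposure gamma_k  (half-normal, scaled so the set explains r2_exposure)
    mediator delta_mk = theta_xm_m * gamma_k   (+ mediator-specific instruments)
    outcome  Gamma_k  = beta_direct * gamma_k + sum_m beta_my_m * delta_mk + alpha_k

with ``alpha_k`` drawn per ``pleiotropy_mode`` ("none", "balanced",
"directional" or "inside_violating"; the last draws alpha correlated with
gamma, breaking the InSIDE condition).  Sampling SEs follow
``1 / sqrt(2 p (1-p) n)`` and observed betas are true betas plus independent
normal noise per dataset.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

from .pipeline import StudyConfig, TraitSpec
from .summary_io import InstrumentSet, VariantAssociation, write_association_table

__all__ = [
    "MediatorSpec",
    "SimulationTruth",
    "SimulatedStudy",
    "simulate_summary_stats",
    "make_fixture_study",
]

_NONPALINDROMIC_PAIRS = [("A", "C"), ("A", "G"), ("T", "C"), ("T", "G")]
_PALINDROMIC_PAIRS = [("A", "T"), ("C", "G")]
_MODES = ("none", "balanced", "directional", "inside_violating")


@dataclass(frozen=True)
class MediatorSpec:
    """Generating parameters for one mediator trait."""

    name: str
    theta_xm: float  # exposure -> mediator
    beta_my: float  # mediator -> outcome
    n_instruments: int = 30  # mediator-specific SNPs (no exposure effect)
    r2: float = 0.02  # variance of mediator explained by its own instruments
    trait_type: str = "continuous"


@dataclass(frozen=True)
class SimulationTruth:
    """Generating parameters paired with every simulated dataset."""

    seed: int
    n_snps: int = 77
    beta_causal: float = 0.4  # exposure -> outcome direct coefficient
    beta_direct: float | None = None  # overrides beta_causal when mediators present
    pleiotropy_mode: str = "none"
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    inside_corr: float = 0.7  # corr(alpha, gamma) under inside_violating
    mediators: tuple[MediatorSpec, ...] = ()
    n_exposure: int = 322_154
    n_outcome: int = 184_305
    n_mediator: int = 100_000
    r2_exposure: float = 0.024
    maf_range: tuple[float, float] = (0.05, 0.45)
    palindromic_fraction: float = 0.1
    scramble_orientation: bool = True  # random per-dataset allele designation flips
    exposure_name: str = "X"
    outcome_name: str = "Y"
    outcome_type: str = "binary"

    def __post_init__(self) -> None:
        if self.pleiotropy_mode not in _MODES:
            raise ValueError(f"pleiotropy_mode must be one of {_MODES}")
        if self.pleiotropy_mode == "none" and (self.pleiotropy_mean or self.pleiotropy_sd):
            raise ValueError("pleiotropy_mode 'none' requires zero pleiotropy mean and sd")
        if self.pleiotropy_sd < 0:
            raise ValueError("pleiotropy_sd must be non-negative")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie in (0, 0.5]")
        if self.n_snps < 1 or min(self.n_exposure, self.n_outcome, self.n_mediator) < 2:
            raise ValueError("counts must be positive")
        if not 0.0 < self.r2_exposure < 1.0:
            raise ValueError("r2_exposure must be in (0, 1)")

    @property
    def direct_effect(self) -> float:
        return self.beta_causal if self.beta_direct is None else self.beta_direct

    @property
    def total_effect(self) -> float:
        """Direct plus all mediated paths."""
        return self.direct_effect + sum(m.theta_xm * m.beta_my for m in self.mediators)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["mediators"] = [dataclasses.asdict(m) for m in self.mediators]
        d["total_effect"] = self.total_effect
        return d


@dataclass
class SimulatedStudy:
    """Simulated association tables plus an echo of the generating truth."""

    truth: SimulationTruth
    exposure_instruments: InstrumentSet
    mediator_instruments: dict[str, InstrumentSet]
    tables: dict[str, InstrumentSet]  # full association table per trait
    true_betas: dict[str, np.ndarray] = field(default_factory=dict)  # generating effects, table order


def _scaled_effects(rng: np.random.Generator, mafs: np.ndarray, r2: float) -> np.ndarray:
    """Half-normal per-allele effects rescaled so 2p(1-p)beta^2 sums to r2."""
    raw = np.abs(rng.standard_normal(mafs.size))
    var = 2.0 * mafs * (1.0 - mafs) * raw**2
    return raw * np.sqrt(r2 / var.sum())


def _draw_alleles(rng: np.random.Generator, n: int, palindromic_fraction: float):
    ea, oa = [], []
    for _ in range(n):
        if rng.random() < palindromic_fraction:
            pair = _PALINDROMIC_PAIRS[rng.integers(len(_PALINDROMIC_PAIRS))]
        else:
            pair = _NONPALINDROMIC_PAIRS[rng.integers(len(_NONPALINDROMIC_PAIRS))]
        if rng.random() < 0.5:
            pair = pair[::-1]
        ea.append(pair[0])
        oa.append(pair[1])
    return np.array(ea), np.array(oa)


def _pleiotropy(rng: np.random.Generator, truth: SimulationTruth, gamma: np.ndarray) -> np.ndarray:
    mode = truth.pleiotropy_mode
    k = gamma.size
    if mode == "none":
        return np.zeros(k)
    if mode == "balanced":
        return rng.normal(0.0, truth.pleiotropy_sd, k)
    if mode == "directional":
        return truth.pleiotropy_mean + rng.normal(0.0, truth.pleiotropy_sd, k)
    # inside_violating: alpha correlated with instrument strength gamma
    z = rng.standard_normal(k)
    g_std = (gamma - gamma.mean()) / gamma.std() if gamma.std() > 0 else np.zeros(k)
    rho = truth.inside_corr
    return truth.pleiotropy_mean + truth.pleiotropy_sd * (
        rho * g_std + np.sqrt(1.0 - rho**2) * z
    )


def _make_table(
    rng: np.random.Generator,
    truth: SimulationTruth,
    ids: np.ndarray,
    ea: np.ndarray,
    oa: np.ndarray,
    mafs: np.ndarray,
    true_betas: np.ndarray,
    n_sample: int,
    trait_name: str,
    trait_type: str,
) -> InstrumentSet:
    se = 1.0 / np.sqrt(2.0 * mafs * (1.0 - mafs) * n_sample)
    beta = true_betas + rng.normal(0.0, se)
    pvals = np.clip(2.0 * stats.norm.sf(np.abs(beta / se)), 1e-300, 1.0)
    flip = (
        rng.random(ids.size) < 0.5
        if truth.scramble_orientation
        else np.zeros(ids.size, dtype=bool)
    )
    records = [
        VariantAssociation(
            variant_id=str(ids[k]),
            effect_allele=str(oa[k] if flip[k] else ea[k]),
            other_allele=str(ea[k] if flip[k] else oa[k]),
            beta=float(-beta[k] if flip[k] else beta[k]),
            se=float(se[k]),
            eaf=float(1.0 - mafs[k] if flip[k] else mafs[k]),
            pvalue=float(pvals[k]),
            n=float(n_sample),
        )
        for k in range(ids.size)
    ]
    return InstrumentSet(trait_name=trait_name, records=records, trait_type=trait_type)


def simulate_summary_stats(truth: SimulationTruth) -> SimulatedStudy:
    """Draw one full two-sample study from the generating model.

    Returns the exposure instrument set, per-mediator instrument sets, and a
    complete association table for every trait covering all simulated SNPs.
    Noise is drawn independently per dataset; fixing ``truth.seed`` reproduces
    the study exactly.
    """
    rng = np.random.default_rng(truth.seed)
    k_exp = truth.n_snps
    n_extra = [m.n_instruments for m in truth.mediators]
    k_all = k_exp + sum(n_extra)

    ids = np.array([f"rs{1000 + i}" for i in range(k_all)])
    mafs = rng.uniform(*truth.maf_range, k_all)
    ea, oa = _draw_alleles(rng, k_all, truth.palindromic_fraction)

    gamma = np.zeros(k_all)
    gamma[:k_exp] = _scaled_effects(rng, mafs[:k_exp], truth.r2_exposure)

    # mediator-specific instrument blocks sit after the exposure block
    offsets = np.cumsum([k_exp] + n_extra)
    delta = {}
    for m, start, stop in zip(truth.mediators, offsets[:-1], offsets[1:]):
        d = m.theta_xm * gamma
        if stop > start:
            d[start:stop] = _scaled_effects(rng, mafs[start:stop], m.r2)
        delta[m.name] = d

    alpha = np.zeros(k_all)
    alpha[:k_exp] = _pleiotropy(rng, truth, gamma[:k_exp])
    big_gamma = truth.direct_effect * gamma + alpha
    for m in truth.mediators:
        big_gamma = big_gamma + m.beta_my * delta[m.name]

    tables: dict[str, InstrumentSet] = {}
    tables[truth.exposure_name] = _make_table(
        rng, truth, ids, ea, oa, mafs, gamma, truth.n_exposure, truth.exposure_name, "continuous"
    )
    for m in truth.mediators:
        tables[m.name] = _make_table(
            rng, truth, ids, ea, oa, mafs, delta[m.name], truth.n_mediator, m.name, m.trait_type
        )
    tables[truth.outcome_name] = _make_table(
        rng,
        truth,
        ids,
        ea,
        oa,
        mafs,
        big_gamma,
        truth.n_outcome,
        truth.outcome_name,
        truth.outcome_type,
    )

    def _subset(table: InstrumentSet, index: np.ndarray) -> InstrumentSet:
        wanted = set(ids[index])
        return InstrumentSet(
            trait_name=table.trait_name,
            records=[r for r in table.records if r.variant_id in wanted],
            trait_type=table.trait_type,
            unit_label=table.unit_label,
        )

    exposure_instruments = _subset(tables[truth.exposure_name], np.arange(k_exp))
    mediator_instruments = {
        m.name: _subset(tables[m.name], np.arange(start, stop))
        for m, start, stop in zip(truth.mediators, offsets[:-1], offsets[1:])
    }
    true_betas = {truth.exposure_name: gamma, truth.outcome_name: big_gamma}
    true_betas.update({m.name: delta[m.name] for m in truth.mediators})
    return SimulatedStudy(
        truth=truth,
        exposure_instruments=exposure_instruments,
        mediator_instruments=mediator_instruments,
        tables=tables,
        true_betas=true_betas,  # generating frame, before any orientation scramble
    )


_PROFILES = {
    "null_mediator": dict(
        beta_causal=0.4,
        mediators=(MediatorSpec("M1", theta_xm=0.0, beta_my=0.0),),
    ),
    "single_mediator": dict(
        beta_causal=0.2,
        mediators=(MediatorSpec("M1", theta_xm=0.3, beta_my=0.5),),
    ),
    "dual_mediator": dict(
        beta_causal=0.15,
        mediators=(
            MediatorSpec("M1", theta_xm=0.3, beta_my=0.5),
            MediatorSpec("M2", theta_xm=0.25, beta_my=0.4),
        ),
    ),
}


def make_fixture_study(
    profile: str,
    out_dir: str | Path,
    seed: int,
    *,
    n_snps: int = 77,
    n_boot: int = 500,
    **truth_overrides,
) -> tuple[StudyConfig, SimulationTruth]:
    """Write a consortium-style study (TSV tables + config + truth echo) to disk.

    ``profile`` is one of ``null_mediator``, ``single_mediator`` or
    ``dual_mediator``.  Emits one association table per trait, instrument
    tables for the exposure and each mediator, a ``config.yaml`` runnable by
    the pipeline, and ``truth.json``/``README.txt`` documenting the embedded
    generating parameters.
    """
    if profile not in _PROFILES:
        raise ValueError(f"unknown profile {profile!r}; choose from {sorted(_PROFILES)}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    params = dict(_PROFILES[profile])
    params.update(truth_overrides)
    truth = SimulationTruth(seed=seed, n_snps=n_snps, **params)
    study = simulate_summary_stats(truth)

    traits: list[TraitSpec] = []
    for name, table in study.tables.items():
        assoc_path = out_dir / f"{name}_associations.tsv"
        write_association_table(table, assoc_path)
        inst_path = None
        inst = (
            study.exposure_instruments
            if name == truth.exposure_name
            else study.mediator_instruments.get(name)
        )
        if inst is not None:
            inst_path = out_dir / f"{name}_instruments.tsv"
            write_association_table(inst, inst_path)
        traits.append(
            TraitSpec(
                name=name,
                trait_type=table.trait_type,
                unit_label=table.unit_label or ("log-odds" if table.trait_type == "binary" else "SD"),
                instrument_file=str(inst_path.name) if inst_path else None,
                association_file=str(assoc_path.name),
            )
        )

    cfg = StudyConfig(
        exposure=truth.exposure_name,
        outcome=truth.outcome_name,
        mediators=[m.name for m in truth.mediators],
        traits=traits,
        seed=seed,
        n_boot=n_boot,
        base_dir=out_dir,
        out_dir=str(out_dir / "results"),
    )
    cfg.to_yaml(out_dir / "config.yaml")
    (out_dir / "truth.json").write_text(json.dumps(truth.to_dict(), indent=2) + "\n")
    (out_dir / "README.txt").write_text(
        f"Synthetic two-sample MR study, profile '{profile}'.\n"
        f"Generating direct effect {truth.direct_effect}, total effect {truth.total_effect}.\n"
        f"Mediators: {[m.name for m in truth.mediators]}.\n"
        f"See truth.json for all generating parameters; run with config.yaml.\n"
    )
    return cfg, truth
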