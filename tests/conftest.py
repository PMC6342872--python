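from __future__ import annotations

import numpy as np
import pytest

from mrmediate.summary_io import HarmonisedRow, HarmonisedSet, InstrumentSet, VariantAssociation

_ALLELES = [("A", "C"), ("A", "G"), ("T", "C"), ("T", "G")]


def build_harmonised(e, se_e, d, se_d, mediators=None, exposure="X", outcome="Y"):
    """Assemble a HarmonisedSet straight from beta/SE arrays."""
    mediators = mediators or {}
    rows = []
    for k in range(len(e)):
        ea, oa = _ALLELES[k % len(_ALLELES)]
        rows.append(
            HarmonisedRow(
                variant_id=f"rs{k}",
                effect_allele=ea,
                other_allele=oa,
                beta_exp=float(e[k]),
                se_exp=float(se_e[k]),
                beta_out=float(d[k]),
                se_out=float(se_d[k]),
                eaf_exp=0.3,
                mediators={name: (float(vals[0][k]), float(vals[1][k])) for name, vals in mediators.items()},
            )
        )
    return HarmonisedSet(
        exposure_name=exposure,
        outcome_name=outcome,
        rows=rows,
        mediator_names=list(mediators),
    )


def build_instruments(ids, ea, oa, beta, se, eaf=None, trait="X", **kw):
    records = [
        VariantAssociation(
            variant_id=ids[k],
            effect_allele=ea[k],
            other_allele=oa[k],
            beta=float(beta[k]),
            se=float(se[k]),
            eaf=None if eaf is None else float(eaf[k]),
        )
        for k in range(len(ids))
    ]
    return InstrumentSet(trait_name=trait, records=records, **kw)


@pytest.fixture
def rng():
    return np.random.default_rng(20260906)


@pytest.fixture
def random_harmonised(rng):
    """Factory for random k-SNP harmonised sets with positive SEs."""

    def make(k=10, seed=None):
        r = np.random.default_rng(seed) if seed is not None else rng
        e = r.normal(0.1, 0.05, k)
        e[np.abs(e) < 1e-3] = 0.05
        return build_harmonised(
            e=e,
            se_e=r.uniform(0.005, 0.02, k),
            d=r.normal(0.05, 0.05, k),
            se_d=r.uniform(0.01, 0.05, k),
        )

    return make
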