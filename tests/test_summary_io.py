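from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mrmediate.simulate import SimulationTruth, simulate_summary_stats
from mrmediate.summary_io import (
    COMPLEMENT,
    HarmonisationError,
    InstrumentSet,
    VariantAssociation,
    harmonise,
    read_association_table,
    rescale_estimate,
    write_association_table,
)

from .conftest import build_instruments


def _write(tmp_path, text, name="table.tsv"):
    p = tmp_path / name
    p.write_text(text)
    return p


HEADER = "variant_id\teffect_allele\tother_allele\teaf\tbeta\tse\n"


class TestReadAssociationTable:
    def test_three_row_identity_read_back(self, tmp_path):
        path = _write(
            tmp_path,
            HEADER
            + "rs1\tA\tG\t0.2\t0.05\t0.01\n"
            + "rs2\tt\tc\t0.4\t-0.02\t0.02\n"
            + "rs3\tC\tA\t0.6\t0.10\t0.03\n",
        )
        s = read_association_table(path, trait_name="BMI")
        assert len(s) == 3 and not s.exclusions
        assert s.records[0] == VariantAssociation("rs1", "A", "G", 0.05, 0.01, eaf=0.2)
        # alleles upper-cased
        assert (s.records[1].effect_allele, s.records[1].other_allele) == ("T", "C")

    def test_nonpositive_se_routed_to_exclusions(self, tmp_path):
        path = _write(tmp_path, HEADER + "rs1\tA\tG\t0.2\t0.05\t0.0\nrs2\tA\tG\t0.2\t0.05\t0.01\n")
        s = read_association_table(path)
        assert [r.variant_id for r in s.records] == ["rs2"]
        assert s.exclusions == [("rs1", "nonpositive_se")]

    @pytest.mark.parametrize(
        "row,reason",
        [
            ("rs1\tA\tA\t0.2\t0.05\t0.01\n", "identical_alleles"),
            ("rs1\tN\tG\t0.2\t0.05\t0.01\n", "malformed_allele"),
            ("rs1\tA\tG\t1.5\t0.05\t0.01\n", "eaf_out_of_range"),
            ("rs1\tA\tG\t0.2\t\t0.01\n", "missing_beta"),
        ],
    )
    def test_invalid_rows_logged_with_reason(self, tmp_path, row, reason):
        s = read_association_table(_write(tmp_path, HEADER + row))
        assert s.exclusions == [("rs1", reason)]

    def test_column_map_and_csv(self, tmp_path):
        path = _write(tmp_path, "snp,ea,oa,b,stderr\nrs1,A,G,0.05,0.01\n", "t.csv")
        s = read_association_table(
            path,
            column_map={"variant_id": "snp", "effect_allele": "ea", "other_allele": "oa", "beta": "b", "se": "stderr"},
        )
        assert len(s) == 1 and s.records[0].eaf is None

    def test_missing_required_column_fatal(self, tmp_path):
        path = _write(tmp_path, "variant_id\teffect_allele\n" + "rs1\tA\n")
        with pytest.raises(ValueError, match="required column"):
            read_association_table(path)

    def test_unreadable_file_fatal(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_association_table(tmp_path / "nope.tsv")

    def test_simulator_table_round_trip(self, tmp_path):
        truth = SimulationTruth(seed=5, n_snps=77)
        study = simulate_summary_stats(truth)
        path = tmp_path / "x.tsv"
        write_association_table(study.exposure_instruments, path)
        back = read_association_table(path, trait_name="X")
        assert len(back) == 77 and not back.exclusions
        for a, b in zip(study.exposure_instruments.records, back.records):
            assert a.variant_id == b.variant_id
            assert (a.effect_allele, a.other_allele) == (b.effect_allele, b.other_allele)
            for f in ("beta", "se", "eaf", "pvalue", "n"):
                assert getattr(b, f) == pytest.approx(getattr(a, f), rel=1e-9)


def _one(vid="rs1", ea="A", oa="G", beta=0.1, se=0.01, eaf=0.3, trait="X", **kw):
    return InstrumentSet(
        trait_name=trait,
        records=[VariantAssociation(vid, ea, oa, beta, se, eaf=eaf)],
        **kw,
    )


class TestHarmonise:
    def test_aligned_case_retained(self):
        h = harmonise(_one(), _one(beta=0.2, trait="Y"))
        assert len(h) == 1 and h.rows[0].beta_out == 0.2

    def test_swapped_alleles_flip_sign_and_eaf(self):
        out = _one(ea="G", oa="A", beta=0.2, eaf=0.3, trait="Y")
        h = harmonise(_one(), out)
        assert h.rows[0].beta_out == -0.2
        # harmonised orientation is the exposure's effect allele
        assert (h.rows[0].effect_allele, h.rows[0].other_allele) == ("A", "G")

    def test_strand_flip_resolved_for_nonpalindromic(self):
        # exposure A/G; outcome reported on the other strand as T/C
        out = _one(ea="T", oa="C", beta=0.2, trait="Y")
        h = harmonise(_one(), out)
        assert h.rows[0].beta_out == 0.2

    def test_palindromic_ambiguous_dropped(self):
        exp = _one(ea="A", oa="T", eaf=0.50)
        out = _one(ea="A", oa="T", beta=0.2, eaf=0.50, trait="Y")
        exp2 = _one(vid="rs2", ea="C", oa="A", eaf=0.2)
        out2 = _one(vid="rs2", ea="C", oa="A", beta=0.1, eaf=0.2, trait="Y")
        merged_exp = InstrumentSet("X", exp.records + exp2.records)
        merged_out = InstrumentSet("Y", out.records + out2.records)
        h = harmonise(merged_exp, merged_out, eaf_ambiguity_window=(0.42, 0.58))
        assert ("rs1", "palindromic_ambiguous") in h.exclusion_log
        assert [r.variant_id for r in h.rows] == ["rs2"]

    def test_palindromic_policy_oracle_enumeration(self):
        """Exhaustive check of the palindromic-SNP policy over allele/eaf configs."""
        window = (0.42, 0.58)
        eafs = [None, 0.30, 0.50, 0.70]
        configs = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]
        for ea_x, oa_x in configs:
            for ea_y, oa_y in configs:
                if {ea_y, oa_y} != {ea_x, oa_x}:
                    continue
                for eaf_x in eafs:
                    for eaf_y in eafs:
                        for policy in ("drop_all", "drop_ambiguous", "keep"):
                            exp = _one(ea=ea_x, oa=oa_x, eaf=eaf_x)
                            out = _one(ea=ea_y, oa=oa_y, beta=0.2, eaf=eaf_y, trait="Y")
                            # independent statement of the spec rule
                            ambiguous = (
                                eaf_x is None
                                or eaf_y is None
                                or window[0] < eaf_x < window[1]
                                or window[0] < eaf_y < window[1]
                            )
                            expect_drop = policy == "drop_all" or (
                                policy == "drop_ambiguous" and ambiguous
                            )
                            if expect_drop:
                                with pytest.raises(HarmonisationError):
                                    harmonise(exp, out, palindrome_policy=policy, eaf_ambiguity_window=window)
                            else:
                                h = harmonise(exp, out, palindrome_policy=policy, eaf_ambiguity_window=window)
                                assert len(h) == 1

    def test_palindromic_informative_eaf_strand_corrected(self):
        # same labels but eaf on opposite sides of 0.5: outcome allele is on
        # the other strand, so the aligned beta must flip
        exp = _one(ea="A", oa="T", eaf=0.2)
        out = _one(ea="A", oa="T", beta=0.2, eaf=0.8, trait="Y")
        h = harmonise(exp, out)
        assert h.rows[0].beta_out == pytest.approx(-0.2)

    def test_allele_mismatch_logged(self):
        out = _one(ea="A", oa="C", beta=0.2, trait="Y")
        exp2 = _one(vid="rs2")
        merged = InstrumentSet("X", _one().records[:1] + exp2.records)
        out2 = _one(vid="rs2", beta=0.1, trait="Y")
        h = harmonise(merged, InstrumentSet("Y", out.records + out2.records))
        assert ("rs1", "allele_mismatch") in h.exclusion_log

    def test_unmatched_snp_logged(self):
        exp = InstrumentSet("X", _one().records + _one(vid="rs9").records)
        h = harmonise(exp, _one(beta=0.2, trait="Y"))
        assert ("rs9", "missing_in_Y") in h.exclusion_log

    def test_zero_survivors_fatal_with_log(self):
        with pytest.raises(HarmonisationError) as exc:
            harmonise(_one(), _one(vid="rsX", trait="Y"))
        assert exc.value.exclusion_log == [("rs1", "missing_in_Y")]

    def test_empty_input_fatal(self):
        with pytest.raises(ValueError):
            harmonise(InstrumentSet("X", []), _one(trait="Y"))

    def test_self_harmonisation_is_identity(self):
        study = simulate_summary_stats(SimulationTruth(seed=9, n_snps=40, palindromic_fraction=0.0))
        s = study.exposure_instruments
        h = harmonise(s, s)
        np.testing.assert_allclose(h.beta_out, h.beta_exp)
        np.testing.assert_allclose(h.se_out, h.se_exp)

    def test_partition_retained_plus_excluded(self):
        truth = SimulationTruth(seed=3, n_snps=60, palindromic_fraction=0.3, scramble_orientation=True)
        study = simulate_summary_stats(truth)
        outcome = study.tables["Y"]
        # drop a few outcome rows to force missing_in_Y entries
        outcome = InstrumentSet("Y", outcome.records[:-5], trait_type="binary")
        h = harmonise(study.exposure_instruments, outcome)
        retained = {r.variant_id for r in h.rows}
        excluded = [v for v, _ in h.exclusion_log]
        assert retained.isdisjoint(excluded)
        assert retained | set(excluded) == {r.variant_id for r in study.exposure_instruments.records}
        assert len(excluded) == len(set(excluded))

    def test_duplicate_variant_ids_rejected(self):
        recs = _one().records + _one().records
        with pytest.raises(ValueError, match="duplicate"):
            InstrumentSet("X", recs)


@given(
    beta=st.floats(-5, 5, allow_nan=False),
    eaf=st.floats(0.01, 0.99),
    ea=st.sampled_from("ACGT"),
    oa=st.sampled_from("ACGT"),
)
def test_double_flip_is_identity(beta, eaf, ea, oa):
    if ea == oa:
        return
    rec = VariantAssociation("rs1", ea, oa, beta, 0.1, eaf=eaf)
    back = rec.flipped().flipped()
    assert back.effect_allele == ea and back.other_allele == oa
    assert back.beta == pytest.approx(beta)
    assert back.eaf == pytest.approx(eaf)


@settings(max_examples=50)
@given(
    betas=st.lists(st.floats(-1, 1, allow_nan=False), min_size=3, max_size=10),
    flip_mask=st.lists(st.booleans(), min_size=3, max_size=10),
)
def test_harmonise_recovers_swapped_outcome(betas, flip_mask):
    """Swapping alleles + negating beta in the outcome table must be undone."""
    k = min(len(betas), len(flip_mask))
    ids = [f"rs{i}" for i in range(k)]
    ea, oa = ["A"] * k, ["G"] * k
    exp = build_instruments(ids, ea, oa, [0.1] * k, [0.01] * k, eaf=[0.3] * k)
    out_ea = ["G" if flip_mask[i] else "A" for i in range(k)]
    out_oa = ["A" if flip_mask[i] else "G" for i in range(k)]
    out_beta = [-betas[i] if flip_mask[i] else betas[i] for i in range(k)]
    out_eaf = [0.7 if flip_mask[i] else 0.3 for i in range(k)]
    out = build_instruments(ids, out_ea, out_oa, out_beta, [0.01] * k, eaf=out_eaf, trait="Y")
    h = harmonise(exp, out)
    np.testing.assert_allclose(h.beta_out, betas[:k], atol=1e-12)


class TestRescaleEstimate:
    def test_identity_factor(self):
        assert rescale_estimate(0.123, 0.456, 1.0) == (0.123, 0.456)

    def test_ngsp_to_ifcc_paper_values(self):
        beta, se = rescale_estimate(0.45, 0.04, 10.929)
        assert (round(beta, 2), round(se, 2)) == (4.92, 0.44)
        beta2, _ = rescale_estimate(0.05, 0.33 / 10.929, 10.929)
        assert round(beta2, 2) == 0.55

    @pytest.mark.parametrize("factor", [0.0, -1.0, -10.929])
    def test_nonpositive_factor_fatal(self, factor):
        with pytest.raises(ValueError):
            rescale_estimate(0.1, 0.01, factor)

    @given(b=st.floats(-10, 10), s=st.floats(1e-6, 10), f=st.floats(1e-3, 1e3))
    def test_scales_both_linearly(self, b, s, f):
        rb, rs = rescale_estimate(b, s, f)
        assert rb == pytest.approx(b * f) and rs == pytest.approx(s * f)
        # z-score (hence p) unchanged
        if b != 0:
            assert rb / rs == pytest.approx(b / s)


def test_complement_table_involution():
    for a, b in COMPLEMENT.items():
        assert COMPLEMENT[b] == a
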