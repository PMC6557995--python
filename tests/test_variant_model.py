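"""Variant normalization, VCF/PED reading, and hard filtering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pedvar.errors import ConfigError, DataError, ParseError
from pedvar.variant_model import (
    FilterThresholds,
    GenotypeCall,
    Variant,
    hard_filter,
    normalize,
    read_pedigree,
    read_variants,
    write_vcf,
)

alleles = st.text(alphabet="ACGT", min_size=1, max_size=6)


@pytest.mark.parametrize(
    "pos,ref,alt,exp_pos,exp_ref,exp_alt",
    [
        (100, "CT", "CA", 101, "T", "A"),  # shared prefix, SNV core
        (100, "A", "G", 100, "A", "G"),  # already minimal
        (100, "GCC", "GC", 100, "GC", "G"),  # suffix then anchor kept
        (100, "ATG", "A", 100, "ATG", "A"),  # deletion already anchored
        (100, "TACA", "TA", 100, "TAC", "T"),  # suffix trimmed, anchor kept
    ],
)
def test_normalize_minimal_representation(pos, ref, alt, exp_pos, exp_ref, exp_alt):
    v = normalize(Variant("1", pos, ref, alt))
    assert (v.pos, v.ref, v.alt) == (exp_pos, exp_ref, exp_alt)


@given(ref=alleles, alt=alleles)
@settings(max_examples=200, derandomize=True)
def test_normalize_idempotent(ref, alt):
    if ref == alt:
        return
    once = normalize(Variant("7", 500, ref, alt))
    assert normalize(once) == once


def test_ref_equals_alt_rejected():
    with pytest.raises(DataError):
        Variant("1", 1, "A", "A")


def test_symbolic_alleles_flagged_not_dropped():
    v = Variant("1", 100, "A", "<DEL>")
    assert v.symbolic
    assert normalize(v) == v


def _write_text_vcf(path, body, samples=("S1",)):
    header = (
        "##fileformat=VCFv4.2\n"
        "##contig=<ID=1>\n"
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="GT">\n'
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="DP">\n'
        '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="GQ">\n'
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(samples)
        + "\n"
    )
    path.write_text(header + body)
    return path


class TestReadVariants:
    def test_multiallelic_decomposition(self, tmp_path):
        path = _write_text_vcf(
            tmp_path / "m.vcf",
            "1\t100\t.\tA\tG,T\t99\t.\t.\tGT:DP:GQ\t1/2:40:80\n",
        )
        records = read_variants(path)
        assert [r.variant.variant_id for r in records] == ["1:100:A:G", "1:100:A:T"]
        assert all(r.calls["S1"].gt == "het" for r in records)

    def test_empty_body(self, tmp_path):
        assert read_variants(_write_text_vcf(tmp_path / "e.vcf", "")) == []

    def test_malformed_row_reports_line(self, tmp_path):
        path = _write_text_vcf(tmp_path / "bad.vcf", "1\t100\t.\tA\n")
        with pytest.raises(ParseError, match=":7:"):
            read_variants(path)

    def test_round_trip_canonical_ids(self, tmp_path):
        rng = np.random.default_rng(3)
        rows = []
        for i in range(50):
            ref, alt = ("A", "G") if i % 2 else ("AT", "A")
            rows.append(("1", 1000 + 10 * i, ref, alt, "het", 30, 60, 500.0))
        df = pd.DataFrame(
            rows, columns=["chrom", "pos", "ref", "alt", "gt", "depth", "gq", "qual"]
        )
        df["variant_id"] = [
            f"{c}:{p}:{r}:{a}" for c, p, r, a in zip(df.chrom, df.pos, df.ref, df.alt)
        ]
        path = tmp_path / "rt.vcf"
        write_vcf(path, "S1", df)
        back = [r.variant.variant_id for r in read_variants(path)]
        assert back == list(df["variant_id"])
        del rng


class TestHardFilter:
    thresholds = FilterThresholds(min_depth=8, min_gq=20, min_qual=30.0)

    def test_low_depth_fails_with_reason(self):
        call = GenotypeCall("S1", "het", depth=3, genotype_quality=99)
        decision = hard_filter(Variant("1", 1, "A", "G"), [call], self.thresholds, qual=100)
        assert not decision.passed and "min_depth" in decision.reasons

    def test_zero_thresholds_pass_everything(self):
        zero = FilterThresholds(0, 0, 0.0)
        call = GenotypeCall("S1", "het", depth=0, genotype_quality=0)
        assert hard_filter(Variant("1", 1, "A", "G"), [call], zero, qual=0.0).passed

    def test_boundary_is_ge_to_pass(self):
        call = GenotypeCall("S1", "het", depth=8, genotype_quality=20)
        v = Variant("1", 1, "A", "G")
        assert hard_filter(v, [call], self.thresholds, qual=30.0).passed
        assert not hard_filter(v, [call], self.thresholds, qual=29.9).passed

    def test_missing_genotype_exempt_from_depth(self):
        call = GenotypeCall("S1", "missing", depth=0, genotype_quality=0)
        assert hard_filter(Variant("1", 1, "A", "G"), [call], self.thresholds, qual=99).passed

    def test_unknown_site_field_is_config_error(self):
        t = FilterThresholds(site_level_expressions=(("QD", ">=", 2.0),))
        with pytest.raises(ConfigError, match="QD"):
            hard_filter(Variant("1", 1, "A", "G"), [], t, qual=99, info={})

    def test_site_expression_applied(self):
        t = FilterThresholds(0, 0, 0.0, site_level_expressions=(("FS", "<=", 60.0),))
        v = Variant("1", 1, "A", "G")
        assert hard_filter(v, [], t, qual=99, info={"FS": 10.0}).passed
        assert not hard_filter(v, [], t, qual=99, info={"FS": 80.0}).passed

    @given(
        depth=st.integers(0, 50),
        gq=st.integers(0, 120),
        qual=st.floats(0, 200, allow_nan=False),
        bump=st.integers(0, 30),
    )
    @settings(max_examples=150, derandomize=True)
    def test_monotone_in_thresholds(self, depth, gq, qual, bump):
        """Raising any threshold never converts a fail into a pass."""
        call = GenotypeCall("S1", "het", depth=depth, genotype_quality=gq)
        v = Variant("1", 1, "A", "G")
        lo = FilterThresholds(10, 30, 50.0)
        for raised in (
            FilterThresholds(10 + bump, 30, 50.0),
            FilterThresholds(10, 30 + bump, 50.0),
            FilterThresholds(10, 30, 50.0 + bump),
        ):
            if not hard_filter(v, [call], lo, qual=qual).passed:
                assert not hard_filter(v, [call], raised, qual=qual).passed


class TestReadPedigree:
    def test_two_affected_one_pedigree(self, tmp_path):
        ped = tmp_path / "p.ped"
        ped.write_text("F2887\tA1\t0\t0\t2\t2\nF2887\tA2\t0\t0\t2\t2\n")
        kin = tmp_path / "k.tsv"
        kin.write_text("pedigree_id\tkinship\nF2887\t0.03\n")
        out = read_pedigree(ped, kinship_path=kin)
        assert len(out) == 1
        assert out[0].sequenced_affected == ("A1", "A2")
        assert out[0].kinship == pytest.approx(0.03)

    def test_only_unaffected_gives_empty_list(self, tmp_path):
        ped = tmp_path / "p.ped"
        ped.write_text("F1\tA1\t0\t0\t2\t1\nF1\tA2\t0\t0\t2\t1\n")
        assert read_pedigree(ped) == []

    def test_duplicate_sample_id_rejected(self, tmp_path):
        ped = tmp_path / "p.ped"
        ped.write_text("F1\tA1\t0\t0\t2\t2\nF2\tA1\t0\t0\t2\t2\n")
        with pytest.raises(DataError, match="duplicate"):
            read_pedigree(ped)

    def test_vcf_sample_missing_from_ped_rejected(self, tmp_path):
        ped = tmp_path / "p.ped"
        ped.write_text("F1\tA1\t0\t0\t2\t2\n")
        with pytest.raises(DataError, match="ZZ"):
            read_pedigree(ped, sequenced_samples=["A1", "ZZ"])
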