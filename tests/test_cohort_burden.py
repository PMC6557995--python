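"""Cohort-count algebra and the exact Fisher burden test."""

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from pedvar.cohort_burden import (
    CohortCounts,
    derive_germline_subset,
    fisher_exact_2x2,
    gene_burden,
    quality_filter,
    subtract_counts,
    subtract_tables,
)
from pedvar.errors import DataError


def fisher_enumeration_oracle(a, b, c, d):
    """Independent exact oracle: enumerate all same-margin tables and sum the
    factorial-form hypergeometric probabilities of those no more probable
    than the observed table, in rational arithmetic."""
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    n = r1 + r2
    if min(r1, r2, c1, c2) == 0:
        return 1.0

    def prob(aa):
        bb, cc = r1 - aa, c1 - aa
        dd = r2 - cc
        if min(bb, cc, dd) < 0:
            return None
        num = (
            math.factorial(r1) * math.factorial(r2)
            * math.factorial(c1) * math.factorial(c2)
        )
        den = (
            math.factorial(n) * math.factorial(aa) * math.factorial(bb)
            * math.factorial(cc) * math.factorial(dd)
        )
        return Fraction(num, den)

    p_obs = prob(a)
    total = Fraction(0)
    for aa in range(0, min(r1, c1) + 1):
        p = prob(aa)
        if p is not None and p <= p_obs:
            total += p
    return float(total)


class TestFisher:
    def test_no_signal_table(self):
        assert fisher_exact_2x2(0, 10, 0, 10)[1] == 1.0

    def test_all_zero_margin(self):
        odds, p = fisher_exact_2x2(0, 0, 0, 0)
        assert p == 1.0 and math.isnan(odds)

    def test_rare_carrier_vs_large_control(self):
        # 1 carrier among ~7000 cancer alleles, none among 60000 controls
        odds, p = fisher_exact_2x2(1, 6999, 0, 60000)
        assert odds == math.inf
        assert p == pytest.approx(fisher_enumeration_oracle(1, 6999, 0, 60000), abs=1e-12)
        assert p == pytest.approx(7000 / 67000, abs=1e-12)

    def test_small_table_matches_enumeration(self):
        _, p = fisher_exact_2x2(5, 5, 1, 9)
        assert p == pytest.approx(fisher_enumeration_oracle(5, 5, 1, 9), abs=1e-12)

    @given(st.integers(0, 12), st.integers(0, 12), st.integers(0, 12), st.integers(0, 12))
    @settings(max_examples=150, derandomize=True)
    def test_matches_scipy_two_sided(self, a, b, c, d):
        _, p = fisher_exact_2x2(a, b, c, d)
        p_scipy = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1]
        assert p == pytest.approx(p_scipy, rel=1e-7, abs=1e-12)

    @given(st.integers(0, 15), st.integers(0, 15), st.integers(0, 15), st.integers(0, 15))
    @settings(max_examples=100, derandomize=True)
    def test_symmetric_under_row_and_column_swap(self, a, b, c, d):
        p = fisher_exact_2x2(a, b, c, d)[1]
        assert fisher_exact_2x2(d, c, b, a)[1] == pytest.approx(p, abs=1e-12)

    def test_large_table_path_is_stable(self):
        # wide-support path (log-space) against scipy
        _, p = fisher_exact_2x2(400, 5600, 300, 5700)
        p_scipy = stats.fisher_exact([[400, 5600], [300, 5700]])[1]
        assert p == pytest.approx(p_scipy, rel=1e-6)

    def test_negative_cell_rejected(self):
        with pytest.raises(DataError):
            fisher_exact_2x2(-1, 2, 3, 4)


class TestSubtraction:
    def test_elementwise(self):
        m = CohortCounts("v", "general", 5, 100)
        s = CohortCounts("v", "non-cancer", 3, 60)
        out = subtract_counts(m, s)
        assert (out.ac, out.an) == (2, 40)
        assert out.cohort == "general-minus-non-cancer"

    def test_rare_allele_retained(self):
        out = subtract_counts(
            CohortCounts("v", "full", 1, 14000), CohortCounts("v", "complement", 0, 12000)
        )
        assert out.ac == 1

    def test_negative_difference_is_error_unless_clamped(self):
        m = CohortCounts("v1", "a", 3, 100)
        s = CohortCounts("v1", "b", 4, 60)
        with pytest.raises(DataError, match="v1"):
            subtract_counts(m, s)
        assert subtract_counts(m, s, clamp=True).ac == 0

    def test_mismatched_variants_rejected(self):
        with pytest.raises(DataError):
            subtract_counts(CohortCounts("v1", "a", 1, 10), CohortCounts("v2", "b", 0, 5))

    @given(
        ac_s=st.integers(0, 50),
        ac_extra=st.integers(0, 50),
        an_s=st.integers(50, 200),
        an_extra=st.integers(0, 100),
    )
    @settings(max_examples=100, derandomize=True)
    def test_subtract_then_add_back_restores_minuend(self, ac_s, ac_extra, an_s, an_extra):
        ac_extra = min(ac_extra, an_extra)  # subset-private AC bounded by its AN
        m = CohortCounts("v", "gen", ac_s + ac_extra, an_s + an_extra)
        s = CohortCounts("v", "nc", ac_s, an_s)
        diff = subtract_counts(m, s)
        assert (diff.ac + s.ac, diff.an + s.an) == (m.ac, m.an)


class TestGermlineSubset:
    def _tables(self, rows_full, rows_comp):
        cols = ["variant_id", "cohort", "AC", "AN", "filter_status"]
        full = pd.DataFrame(
            [(v, "full", ac, an, "pass") for v, ac, an in rows_full], columns=cols
        )
        comp = pd.DataFrame(
            [(v, "comp", ac, an, "pass") for v, ac, an in rows_comp], columns=cols
        )
        return full, comp

    def test_fully_cancelled_variant_excluded(self):
        full, comp = self._tables([("v1", 2, 100)], [("v1", 2, 80)])
        assert derive_germline_subset(full, comp) == set()

    def test_absent_from_complement_included(self):
        full, comp = self._tables([("v1", 1, 100)], [])
        assert derive_germline_subset(full, comp) == {"v1"}

    def test_random_tables_match_rowwise_oracle(self):
        rng = np.random.default_rng(5)
        names = [f"v{i}" for i in range(100)]
        full_ac = rng.integers(0, 6, 100)
        comp_ac = np.minimum(rng.integers(0, 6, 100), full_ac)
        full, comp = self._tables(
            [(v, int(a), 200) for v, a in zip(names, full_ac)],
            [(v, int(a), 150) for v, a in zip(names, comp_ac)],
        )
        expected = {v for v, fa, ca in zip(names, full_ac, comp_ac) if fa - ca > 0}
        assert derive_germline_subset(full, comp) == expected

    def test_subtract_tables_roundtrip(self):
        full, comp = self._tables(
            [("v1", 5, 100), ("v2", 1, 100)], [("v1", 3, 60), ("v2", 0, 60)]
        )
        diff = subtract_tables(full, comp, "derived")
        back = diff.merge(comp, on="variant_id", suffixes=("_d", "_c"))
        assert ((back["AC_d"] + back["AC_c"]).to_numpy() == full["AC"].to_numpy()).all()


class TestQualityFilter:
    cols = ["variant_id", "cohort", "AC", "AN", "filter_status"]

    def test_pass_in_all_sources_kept(self):
        df = pd.DataFrame(
            [("v1", "exome", 1, 10, "pass"), ("v1", "genome", 1, 10, "pass")],
            columns=self.cols,
        )
        assert set(quality_filter(df)["variant_id"]) == {"v1"}

    def test_any_non_pass_drops_variant(self):
        df = pd.DataFrame(
            [("v1", "exome", 1, 10, "pass"), ("v1", "genome", 1, 10, "non-pass")],
            columns=self.cols,
        )
        assert quality_filter(df).empty

    def test_single_source_pass_kept(self):
        df = pd.DataFrame([("v1", "exome", 1, 10, "pass")], columns=self.cols)
        assert len(quality_filter(df)) == 1


class TestGeneBurden:
    cols = ["variant_id", "cohort", "AC", "AN", "filter_status"]

    def _cohort(self, rows, name):
        return pd.DataFrame(
            [(v, name, ac, an, "pass") for v, ac, an in rows], columns=self.cols
        )

    def test_single_variant_reduces_to_fisher(self):
        a = self._cohort([("v1", 2, 100)], "a")
        b = self._cohort([("v1", 1, 200)], "b")
        res = gene_burden("G", ["v1"], a, b)
        assert res.table == (2, 98, 1, 199)
        assert res.p_two_sided == pytest.approx(
            fisher_exact_2x2(2, 98, 1, 199)[1], abs=1e-15
        )

    def test_an_aggregated_as_maximum(self):
        a = self._cohort([("v1", 1, 100), ("v2", 2, 90)], "a")
        b = self._cohort([("v1", 0, 150), ("v2", 0, 140)], "b")
        res = gene_burden("G", ["v1", "v2"], a, b)
        assert res.table[0] == 3 and res.table[0] + res.table[1] == 100

    def test_empty_gene_is_null(self):
        a = self._cohort([], "a")
        b = self._cohort([], "b")
        res = gene_burden("G", [], a, b)
        assert res.p_two_sided == 1.0 and res.table == (0, 0, 0, 0)
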