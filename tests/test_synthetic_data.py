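"""Generator determinism, conservation identities, and planted structure."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pedvar.errors import ConfigError
from pedvar.synthetic_data import (
    SimConfig,
    simulate_cohort_counts,
    simulate_pedigree_dataset,
    simulate_pssm,
    simulate_somatic_spectrum,
)
from pedvar.tolerance import ALPHABET


@pytest.mark.parametrize(
    "field,value,match",
    [
        ("planted_af_max", 1.5, "planted_af_max"),
        ("enrichment_odds", 0.0, "enrichment_odds"),
        ("n_planted_shared", 999, "n_planted_shared"),
        ("hotspot_mass", -0.1, "hotspot_mass"),
        ("cohort_sizes", {"general": 0, "non-cancer": 1, "control": 1, "full": 1, "complement": 1}, "general"),
    ],
)
def test_invalid_config_names_offending_field(small_config, field, value, match):
    cfg = dataclasses.replace(small_config, **{field: value})
    with pytest.raises(ConfigError, match=match):
        cfg.validate()


def test_general_smaller_than_noncancer_rejected(small_config):
    sizes = dict(small_config.cohort_sizes)
    sizes["general"] = sizes["non-cancer"] - 1
    with pytest.raises(ConfigError, match="non-cancer"):
        dataclasses.replace(small_config, cohort_sizes=sizes).validate()


class TestPedigreeDataset:
    def test_deterministic_under_seed(self, small_config):
        a = simulate_pedigree_dataset(small_config)
        b = simulate_pedigree_dataset(small_config)
        for sample in a[0]:
            pd.testing.assert_frame_equal(a[0][sample], b[0][sample])
        pd.testing.assert_frame_equal(a[1], b[1])
        assert a[2].planted_by_pedigree == b[2].planted_by_pedigree

    def test_nothing_planted_when_zero(self, small_config):
        cfg = dataclasses.replace(small_config, n_planted_shared=0)
        _, _, truth = simulate_pedigree_dataset(cfg)
        assert truth.planted_shared_variant_ids == []

    def test_planted_present_het_in_every_affected(self, small_config):
        per_sample, _, truth = simulate_pedigree_dataset(small_config)
        for pid, n_seq, _ in small_config.pedigree_layout:
            for s in range(n_seq):
                calls = per_sample[f"{pid}_S{s + 1}"]
                sub = calls[calls["variant_id"].isin(truth.planted_by_pedigree[pid])]
                assert len(sub) == small_config.n_planted_shared
                assert (sub["gt"] == "het").all()

    def test_single_sample_pedigree_gets_all_planted(self):
        cfg = SimConfig(
            seed=3, n_background_variants=100, n_planted_shared=3,
            pedigree_layout=(("F9", 1, 0.25),), pssm_length=50,
        )
        per_sample, _, truth = simulate_pedigree_dataset(cfg)
        calls = per_sample["F9_S1"]
        assert set(truth.planted_by_pedigree["F9"]) <= set(calls["variant_id"])

    def test_planted_are_rare_nonsilent_in_annotation(self, small_config):
        _, annotation, truth = simulate_pedigree_dataset(small_config)
        ann = annotation.set_index("variant_id")
        for vid in truth.planted_shared_variant_ids:
            assert ann.loc[vid, "consequence"] == "missense"
            assert float(ann.loc[vid, "af_control"]) <= small_config.planted_af_max


class TestCohortCounts:
    def test_general_is_sum_of_latent_subsets(self, small_config):
        table = simulate_cohort_counts(small_config)
        wide = table.pivot(index="variant_id", columns="cohort", values="AC")
        assert (wide["general"] == wide["cancer_latent"] + wide["non-cancer"]).all()

    def test_allele_numbers_echo_config(self, small_config):
        table = simulate_cohort_counts(small_config)
        gen = table[table["cohort"] == "general"]
        assert (gen["AN"] == small_config.cohort_sizes["general"]).all()
        assert (table["AC"] <= table["AN"]).all()
        assert (table["AC"] >= 0).all()

    def test_full_dominates_complement(self, small_config):
        table = simulate_cohort_counts(small_config)
        wide = table.pivot(index="variant_id", columns="cohort", values="AC")
        assert (wide["full"] >= wide["complement"]).all()

    def test_deterministic(self, small_config):
        pd.testing.assert_frame_equal(
            simulate_cohort_counts(small_config), simulate_cohort_counts(small_config)
        )

    def test_no_enrichment_balances_cancer_and_noncancer(self, small_config):
        """With enrichment_odds = 1 the planted gene's cancer-subset carrier
        frequency matches the non-cancer frequency in expectation (pooled
        binomial check over 200 seeds, 3 standard errors)."""
        ac_c = ac_n = an_c = an_n = 0
        for seed in range(200):
            cfg = dataclasses.replace(small_config, seed=seed, enrichment_odds=1.0)
            table = simulate_cohort_counts(cfg)
            planted = table["variant_id"].str.startswith("CP")
            cancer = table[planted & (table["cohort"] == "cancer_latent")]
            nonc = table[planted & (table["cohort"] == "non-cancer")]
            ac_c += cancer["AC"].sum()
            an_c += cancer["AN"].sum()
            ac_n += nonc["AC"].sum()
            an_n += nonc["AN"].sum()
        f = (ac_c + ac_n) / (an_c + an_n)
        se = np.sqrt(f * (1 - f) * (1 / an_c + 1 / an_n))
        assert abs(ac_c / an_c - ac_n / an_n) < 3 * se


class TestPssm:
    def test_fully_conserved_wild_type_is_row_max(self):
        pssm = simulate_pssm(80, conserved_fraction=1.0, seed=5)
        wt_idx = np.array([ALPHABET.index(a) for a in pssm.wild_type])
        wt_scores = pssm.scores[np.arange(80), wt_idx]
        assert (wt_scores == pssm.scores.max(axis=1)).all()
        # strict maximum: no other residue ties
        tied = (pssm.scores == wt_scores[:, None]).sum(axis=1)
        assert (tied == 1).all()

    def test_length_validation(self):
        with pytest.raises(ConfigError):
            simulate_pssm(0, 0.5, seed=1)

    def test_deterministic(self):
        a = simulate_pssm(30, 0.4, seed=12)
        b = simulate_pssm(30, 0.4, seed=12)
        assert a.wild_type == b.wild_type and (a.scores == b.scores).all()


class TestSomaticSpectrum:
    def test_counts_conserved(self):
        sp = simulate_somatic_spectrum(100, 57, [10], 0.3, seed=2)
        assert sp.missense_counts.sum() == 57

    def test_zero_mutations(self):
        sp = simulate_somatic_spectrum(50, 0, [], 0.0, seed=2)
        assert (sp.missense_counts == 0).all()

    def test_mass_above_one_rejected(self):
        with pytest.raises(ConfigError):
            simulate_somatic_spectrum(50, 10, [1], 1.5, seed=2)

    def test_hotspot_position_out_of_range_rejected(self):
        with pytest.raises(ConfigError):
            simulate_somatic_spectrum(50, 10, [51], 0.2, seed=2)

    def test_no_hotspot_mass_is_uniform_multinomial(self):
        """Chi-square goodness of fit at alpha 0.01 over 100 seeds rejects
        roughly as often as chance allows."""
        L, n = 20, 500
        failures = 0
        for seed in range(100):
            sp = simulate_somatic_spectrum(L, n, [], 0.0, seed=seed)
            stat, p = stats.chisquare(sp.missense_counts)
            failures += p < 0.01
        assert failures <= 5

    def test_hotspot_mass_lands_on_hotspots(self):
        totals = 0
        for seed in range(50):
            sp = simulate_somatic_spectrum(200, 100, [42], 0.3, seed=seed)
            totals += sp.missense_counts[41]
        # expectation per draw: 0.3 + 0.7/200
        expected = 50 * 100 * (0.3 + 0.7 / 200)
        assert abs(totals - expected) < 4 * np.sqrt(expected)
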