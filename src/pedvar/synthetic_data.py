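"""Synthetic input generation with planted ground truth.

Every input the pipeline consumes — per-sample variant calls, pedigree
metadata, annotation, population cohort allele-count tables, PSSMs and
somatic mutation lists — can be generated here with a known planted
structure, so each downstream stage is testable without any external
download:

* each pedigree's sequenced affected relatives share a small number of
  planted rare non-silent heterozygous variants against a large background
  of independently assigned, mostly common or silent variants;
* one designated gene's carrier odds are multiplied in the latent cancer
  subset of the population tables (detectable by cohort subtraction plus a
  Fisher burden test);
* the PSSM has conserved positions where the wild-type residue is the strict
  row maximum;
* the somatic spectrum places a configurable mass of missense mutations on
  planted hotspot residues.

All generators are pure functions of (config, seed).  Sub-generators derive
child seeds from the one global seed by fixed stream offsets, so adding a
generator never perturbs earlier streams.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError
from .recurrence import SOMATIC_COLUMNS, MutationSpectrum
from .tolerance import ALPHABET, PSSM

_BASES = "ACGT"

# fixed stream offsets for child seeds (order is frozen; append only)
_STREAMS = {"pedigree": 1, "cohort": 2, "pssm": 3, "somatic": 4, "types": 5, "null": 6}
_SEED_MOD = 2**31 - 1


def child_seed(seed: int, stream: str) -> int:
    return (seed * 9973 + _STREAMS[stream]) % _SEED_MOD


_DEFAULT_LAYOUT = tuple(
    (f"F{i + 1:03d}", 2, k)
    for i, k in enumerate(
        [0.0625, 0.25, 0.125, 0.125, 0.016, 0.0625, 0.25, 0.03, 0.125, 0.25]
    )
)

_DEFAULT_COHORT_SIZES = {
    "general": 24000,
    "non-cancer": 18000,
    "control": 30000,
    "full": 14000,
    "complement": 12000,
}

_DEFAULT_TYPE_TOTALS = {"CT1": 400, "CT2": 600, "CT3": 800, "CT4": 1000, "CT5": 1200}


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic datasets.

    ``n_planted_shared`` is per pedigree.  ``background_af_distribution``
    are Beta shape parameters for background allele frequencies — (0.2, 20)
    gives a rare-variant-heavy site-frequency spectrum.  Cohort sizes are
    allele numbers (2x samples); the latent cancer subset has allele number
    general minus non-cancer.
    """

    seed: int = 42
    n_background_variants: int = 2000
    n_planted_shared: int = 5
    planted_af_max: float = 0.001
    background_af_distribution: tuple[float, float] = (0.2, 20.0)
    fraction_silent: float = 0.5
    pedigree_layout: tuple[tuple[str, int, float], ...] = _DEFAULT_LAYOUT
    cohort_sizes: Mapping[str, int] = field(
        default_factory=lambda: dict(_DEFAULT_COHORT_SIZES)
    )
    enrichment_odds: float = 5.0
    pssm_length: int = 377
    conserved_fraction: float = 0.7
    n_somatic: int = 102
    hotspot_positions: tuple[int, ...] = (42,)
    hotspot_mass: float = 0.3
    # plumbing beyond the headline knobs
    planted_gene: str = "GENE_CAND"
    planted_population_af: float = 5e-4
    n_background_genes: int = 200
    n_somatic_truncating: int = 6
    cancer_type_totals: Mapping[str, int] = field(
        default_factory=lambda: dict(_DEFAULT_TYPE_TOTALS)
    )

    def validate(self) -> None:
        for name in (
            "planted_af_max",
            "fraction_silent",
            "conserved_fraction",
            "hotspot_mass",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        if self.n_background_variants < 0:
            raise ConfigError("n_background_variants must be >= 0")
        if self.n_planted_shared > self.n_background_variants:
            raise ConfigError(
                "n_planted_shared exceeds n_background_variants "
                f"({self.n_planted_shared} > {self.n_background_variants})"
            )
        if self.enrichment_odds <= 0:
            raise ConfigError("enrichment_odds must be positive")
        for cohort, an in self.cohort_sizes.items():
            if an <= 0:
                raise ConfigError(f"cohort_sizes[{cohort!r}] must be positive")
        for key in ("general", "non-cancer", "control", "full", "complement"):
            if key not in self.cohort_sizes:
                raise ConfigError(f"cohort_sizes missing required cohort {key!r}")
        if self.cohort_sizes["general"] < self.cohort_sizes["non-cancer"]:
            raise ConfigError(
                "cohort_sizes: 'general' allele number must be >= 'non-cancer'"
            )
        if self.cohort_sizes["full"] < self.cohort_sizes["complement"]:
            raise ConfigError(
                "cohort_sizes: 'full' allele number must be >= 'complement'"
            )
        if self.pssm_length < 1:
            raise ConfigError("pssm_length must be >= 1")
        for pos in self.hotspot_positions:
            if not (1 <= pos <= self.pssm_length):
                raise ConfigError(
                    f"hotspot_positions entry {pos} outside [1, {self.pssm_length}]"
                )
        for pid, n_seq, kin in self.pedigree_layout:
            if n_seq < 1:
                raise ConfigError(f"pedigree_layout[{pid}]: need >= 1 sequenced sample")
            if not (0.0 <= kin <= 0.5):
                raise ConfigError(f"pedigree_layout[{pid}]: kinship outside [0, 0.5]")


@dataclass
class TruthTable:
    """Planted ground truth recorded alongside each synthetic bundle."""

    planted_by_pedigree: dict[str, list[str]] = field(default_factory=dict)
    planted_enriched_gene: str = ""
    planted_hotspots: list[int] = field(default_factory=list)
    # rare non-silent background variants that happen to be shared by all
    # affected members of a pedigree (chance collisions, recorded so exact
    # candidate-set comparisons stay honest)
    background_collisions: dict[str, list[str]] = field(default_factory=dict)

    @property
    def planted_shared_variant_ids(self) -> list[str]:
        return [vid for ids in self.planted_by_pedigree.values() for vid in ids]

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "TruthTable":
        return cls(**json.loads(text))


# ---------------------------------------------------------------------------
# variant universe helpers


def _draw_alleles(rng: np.random.Generator, indel: bool) -> tuple[str, str]:
    ref = _BASES[rng.integers(4)]
    if not indel:
        alt = _BASES[(int(_BASES.index(ref)) + 1 + rng.integers(3)) % 4]
        return ref, alt
    extra = _BASES[rng.integers(4)]
    if rng.random() < 0.5:
        return ref + extra, ref  # deletion, left-anchored minimal form
    return ref, ref + extra  # insertion


def _consequences(rng: np.random.Generator, n: int, fraction_silent: float) -> np.ndarray:
    silent = rng.random(n) < fraction_silent
    cons = np.empty(n, dtype=object)
    cons[silent] = rng.choice(["synonymous", "intronic"], size=int(silent.sum()))
    cons[~silent] = rng.choice(
        ["missense", "frameshift", "stopgain", "splicing"],
        size=int((~silent).sum()),
        p=[0.8, 0.1, 0.05, 0.05],
    )
    return cons


def _hgvs_p_for(rng: np.random.Generator, pssm: PSSM, used: set[int]) -> str:
    """A missense HGVS.p consistent with the fixture PSSM's wild type."""
    while True:
        pos = int(rng.integers(1, pssm.length + 1))
        if pos not in used:
            used.add(pos)
            break
    wt = pssm.wild_type[pos - 1]
    alternatives = [aa for aa in ALPHABET if aa != wt]
    mut = alternatives[rng.integers(19)]
    return f"p.{wt}{pos}{mut}"


# ---------------------------------------------------------------------------
# pedigree dataset


def simulate_pedigree_dataset(
    config: SimConfig,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame, TruthTable]:
    """Generate per-sample variant call tables, an annotation table and the
    planted truth.

    Planted shared variants are heterozygous in every sequenced affected
    sample of their pedigree, rare (control AF 0, i.e. unseen) and
    non-silent; each pedigree's first planted variant lands in the designated
    enriched gene with a PSSM-consistent missense HGVS.p.  Background
    variants are assigned independently per sample from their Beta-drawn
    allele frequency.  Identical config (including seed) reproduces identical
    output.
    """
    config.validate()
    rng = np.random.default_rng(child_seed(config.seed, "pedigree"))
    pssm = simulate_pssm(
        config.pssm_length, config.conserved_fraction, child_seed(config.seed, "pssm")
    )

    a, b = config.background_af_distribution
    n_bg = config.n_background_variants
    afs = np.clip(rng.beta(a, b, size=n_bg), 1e-6, 0.5)
    consequences = _consequences(rng, n_bg, config.fraction_silent)
    genes = [f"G{int(g):04d}" for g in rng.integers(1, config.n_background_genes + 1, n_bg)]

    rows = []
    for i in range(n_bg):
        chrom = str(1 + i % 22)
        pos = 1_000_000 + 41 * (i // 22)
        ref, alt = _draw_alleles(rng, indel=bool(rng.random() < 0.05))
        rows.append(
            (
                f"{chrom}:{pos}:{ref}:{alt}", chrom, pos, ref, alt, genes[i],
                consequences[i], float(afs[i]),
            )
        )
    background = pd.DataFrame(
        rows,
        columns=["variant_id", "chrom", "pos", "ref", "alt", "gene", "consequence", "af"],
    )

    truth = TruthTable(planted_enriched_gene=config.planted_gene,
                       planted_hotspots=list(config.hotspot_positions))
    planted_rows = []
    used_positions: set[int] = set()
    for p_index, (pid, n_seq, _kin) in enumerate(config.pedigree_layout):
        ids = []
        for j in range(config.n_planted_shared):
            chrom = str(1 + (p_index * 7 + j) % 22)
            pos = 5_000_000 + 1000 * p_index + 13 * j
            ref, alt = _draw_alleles(rng, indel=False)
            vid = f"{chrom}:{pos}:{ref}:{alt}"
            gene = config.planted_gene if j == 0 else f"PG{p_index:02d}_{j}"
            hgvs_p = _hgvs_p_for(rng, pssm, used_positions) if j == 0 else "."
            planted_rows.append(
                (vid, chrom, pos, ref, alt, gene, "missense", 0.0, pid, hgvs_p)
            )
            ids.append(vid)
        truth.planted_by_pedigree[pid] = ids
    planted = pd.DataFrame(
        planted_rows,
        columns=[
            "variant_id", "chrom", "pos", "ref", "alt", "gene", "consequence",
            "af", "pedigree", "hgvs_p",
        ],
    )

    # per-sample genotype assignment
    per_sample: dict[str, pd.DataFrame] = {}
    bg_af = background["af"].to_numpy()
    p_het = 2 * bg_af * (1 - bg_af)
    p_hom = bg_af**2
    sample_carrier_masks: dict[str, np.ndarray] = {}
    for pid, n_seq, _kin in config.pedigree_layout:
        for s in range(n_seq):
            sample_id = f"{pid}_S{s + 1}"
            u = rng.random(n_bg)
            gt = np.where(u < p_hom, "hom_alt", np.where(u < p_hom + p_het, "het", "hom_ref"))
            carrier = gt != "hom_ref"
            sample_carrier_masks[sample_id] = carrier
            bg_part = background.loc[carrier, ["chrom", "pos", "ref", "alt", "variant_id"]].copy()
            bg_part["gt"] = gt[carrier]
            pl_part = planted.loc[
                planted["pedigree"] == pid,
                ["chrom", "pos", "ref", "alt", "variant_id"],
            ].copy()
            pl_part["gt"] = "het"
            calls = pd.concat([bg_part, pl_part], ignore_index=True)
            n = len(calls)
            calls["depth"] = np.maximum(rng.poisson(60, n), 10)
            calls["gq"] = rng.integers(50, 100, n)
            calls["qual"] = rng.uniform(100, 2000, n).round(1)
            per_sample[sample_id] = calls.reset_index(drop=True)

    # record chance background collisions: rare non-silent background shared
    # by every affected member of a pedigree
    rare_nonsilent = (
        background["consequence"].isin(["missense", "frameshift", "stopgain", "splicing"])
        & (background["af"] <= config.planted_af_max)
    ).to_numpy()
    for pid, n_seq, _kin in config.pedigree_layout:
        samples = [f"{pid}_S{s + 1}" for s in range(n_seq)]
        shared = rare_nonsilent.copy()
        for sample_id in samples:
            shared &= sample_carrier_masks[sample_id]
        collisions = background.loc[shared, "variant_id"].tolist()
        if collisions:
            truth.background_collisions[pid] = collisions

    annotation_rows = []
    for row in background.itertuples(index=False):
        annotation_rows.append(
            (row.variant_id, row.gene, "NM_000001.1", "exon1", "c.?", ".",
             row.consequence, row.af, "unknown")
        )
    for row in planted.itertuples(index=False):
        annotation_rows.append(
            (row.variant_id, row.gene, "NM_900001.1", "exon2", "c.?", row.hgvs_p,
             row.consequence, row.af, "damaging")
        )
    annotation = pd.DataFrame(
        annotation_rows,
        columns=[
            "variant_id", "gene", "transcript", "exon", "hgvs_c", "hgvs_p",
            "consequence", "af_control", "insilico",
        ],
    )
    return per_sample, annotation, truth


# ---------------------------------------------------------------------------
# cohort counts


def simulate_cohort_counts(
    config: SimConfig,
    annotation: pd.DataFrame | None = None,
    planted_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Generate a population cohort allele-count table.

    For each variant with latent population allele frequency f, non-cancer
    counts are Binomial(AN_non-cancer, f) and latent cancer-subset counts are
    Binomial(AN_cancer, f') where AN_cancer = AN_general - AN_non-cancer and
    f' has the carrier odds multiplied by ``enrichment_odds`` for the planted
    gene's variants; the general cohort is their elementwise sum (rows for
    the latent cancer subset are emitted under cohort ``cancer_latent`` so
    the construction identity is checkable).  A full/complement release pair
    is generated for germline-set subtraction; planted ids get at least one
    subset-private allele.  Control counts follow the annotated control AF,
    so unseen-in-controls variants stay at AC 0 there.

    With no ``annotation`` supplied a self-contained variant universe is
    drawn from the config alone.
    """
    config.validate()
    rng = np.random.default_rng(child_seed(config.seed, "cohort"))
    if annotation is None:
        n = max(config.n_background_variants // 10, 20)
        a, b = config.background_af_distribution
        afs = np.clip(rng.beta(a, b, size=n), 1e-6, 0.5)
        genes = [f"G{int(g):04d}" for g in rng.integers(1, config.n_background_genes + 1, n)]
        ids = [f"C{i}:{1_000 + i}:A:G" for i in range(n)]
        n_planted = len(config.pedigree_layout)
        for j in range(n_planted):
            ids.append(f"CP{j}:{9_000 + j}:A:G")
            genes.append(config.planted_gene)
        afs = np.concatenate([afs, np.zeros(n_planted)])
        df = pd.DataFrame({"variant_id": ids, "gene": genes, "af_control": afs})
        planted_set = set(ids[-n_planted:]) if n_planted else set()
    else:
        df = annotation[["variant_id", "gene", "af_control"]].copy()
        df["af_control"] = df["af_control"].fillna(0.0)
        planted_set = set(planted_ids or [])
        if not planted_set:
            planted_set = set(df.loc[df["gene"] == config.planted_gene, "variant_id"])

    an_general = int(config.cohort_sizes["general"])
    an_nc = int(config.cohort_sizes["non-cancer"])
    an_cancer = an_general - an_nc
    an_control = int(config.cohort_sizes["control"])
    an_full = int(config.cohort_sizes["full"])
    an_comp = int(config.cohort_sizes["complement"])
    an_tcga = an_full - an_comp

    control_af = df["af_control"].to_numpy(dtype=float)
    latent_f = np.where(control_af > 0, control_af, config.planted_population_af)
    is_planted_gene = df["gene"].eq(config.planted_gene).to_numpy()
    odds = latent_f / (1 - latent_f) * config.enrichment_odds
    f_enriched = odds / (1 + odds)
    f_cancer = np.where(is_planted_gene, f_enriched, latent_f)

    ac_nc = rng.binomial(an_nc, latent_f)
    ac_cancer = rng.binomial(an_cancer, f_cancer)
    ac_general = ac_nc + ac_cancer
    ac_control = rng.binomial(an_control, control_af)
    ac_comp = rng.binomial(an_comp, latent_f)
    ac_tcga = rng.binomial(an_tcga, f_cancer)
    in_planted = df["variant_id"].isin(planted_set).to_numpy()
    # planted variants are guaranteed at least one subset-private allele
    ac_tcga = np.where(in_planted, np.maximum(ac_tcga, 1), ac_tcga)
    ac_full = ac_comp + ac_tcga

    # a small fraction of background rows fails release-level QC
    non_pass = (rng.random(len(df)) < 0.02) & ~in_planted

    blocks = []
    for cohort, ac, an in (
        ("general", ac_general, an_general),
        ("non-cancer", ac_nc, an_nc),
        ("cancer_latent", ac_cancer, an_cancer),
        ("control", ac_control, an_control),
        ("full", ac_full, an_full),
        ("complement", ac_comp, an_comp),
    ):
        blocks.append(
            pd.DataFrame(
                {
                    "variant_id": df["variant_id"],
                    "cohort": cohort,
                    "AC": np.minimum(ac, an).astype(int),
                    "AN": an,
                    "filter_status": np.where(non_pass, "non-pass", "pass"),
                }
            )
        )
    return pd.concat(blocks, ignore_index=True)


# ---------------------------------------------------------------------------
# PSSM


def simulate_pssm(length: int, conserved_fraction: float, seed: int) -> PSSM:
    """A synthetic PSI-BLAST-style PSSM with planted conservation.

    At conserved positions the wild-type residue scores 6..11 while every
    other residue scores <= 0, making the wild type the strict row maximum;
    unconserved positions draw all 20 scores from a flat -4..6 range.
    """
    if length < 1:
        raise ConfigError(f"pssm length must be >= 1, got {length}")
    if not (0.0 <= conserved_fraction <= 1.0):
        raise ConfigError("conserved_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    wt_idx = rng.integers(0, 20, size=length)
    conserved = rng.random(length) < conserved_fraction
    scores = rng.integers(-4, 7, size=(length, 20))
    neg = rng.integers(-6, 1, size=(length, 20))
    scores[conserved] = neg[conserved]
    high = rng.integers(6, 12, size=length)
    scores[conserved, wt_idx[conserved]] = high[conserved]
    wild_type = "".join(ALPHABET[i] for i in wt_idx)
    return PSSM(wild_type, scores.astype(np.int64))


# ---------------------------------------------------------------------------
# somatic spectrum


def simulate_somatic_spectrum(
    length: int,
    n_mutations: int,
    hotspots: Sequence[int],
    hotspot_mass: float,
    seed: int,
    gene: str = "GENE_CAND",
    truncating: int = 0,
) -> MutationSpectrum:
    """Multinomial somatic missense spectrum with planted hotspots.

    Residue probabilities put ``hotspot_mass`` (split evenly) on the hotspot
    residues and spread the remaining mass uniformly over all residues, so
    the expected hotspot count is hotspot_mass * n_mutations (plus the
    uniform share) and the total count is conserved exactly.
    """
    if length < 1:
        raise ConfigError("length must be >= 1")
    if not (0.0 <= hotspot_mass <= 1.0):
        raise ConfigError(f"hotspot_mass must lie in [0, 1], got {hotspot_mass}")
    if hotspot_mass > 0 and not hotspots:
        raise ConfigError("hotspot_mass > 0 requires at least one hotspot position")
    for pos in hotspots:
        if not (1 <= pos <= length):
            raise ConfigError(f"hotspot position {pos} outside [1, {length}]")
    rng = np.random.default_rng(seed)
    probs = np.full(length, (1 - hotspot_mass) / length)
    for pos in hotspots:
        probs[pos - 1] += hotspot_mass / len(hotspots)
    counts = rng.multinomial(n_mutations, probs) if n_mutations else np.zeros(length, int)
    return MutationSpectrum(gene, length, counts, truncating_count=truncating)


def simulate_somatic_table(
    config: SimConfig, pssm: PSSM | None = None
) -> tuple[pd.DataFrame, Mapping[str, int]]:
    """MAF-like somatic mutation rows for the planted gene, with cancer types.

    Mutations are assigned to cancer types with probabilities proportional to
    each type's sample total except the first type, whose weight is tripled
    (the planted per-type enrichment).  Returns (table, per-type sample
    totals).
    """
    config.validate()
    seed = child_seed(config.seed, "somatic")
    if pssm is None:
        pssm = simulate_pssm(
            config.pssm_length, config.conserved_fraction, child_seed(config.seed, "pssm")
        )
    spectrum = simulate_somatic_spectrum(
        config.pssm_length,
        config.n_somatic - config.n_somatic_truncating,
        config.hotspot_positions,
        config.hotspot_mass,
        seed,
        gene=config.planted_gene,
        truncating=config.n_somatic_truncating,
    )
    rng = np.random.default_rng(child_seed(config.seed, "types"))
    types = list(config.cancer_type_totals)
    weights = np.array([config.cancer_type_totals[t] for t in types], dtype=float)
    if weights.size:
        weights[0] *= 3.0
    weights /= weights.sum()
    rows = []
    counter = 0
    for pos in range(1, spectrum.protein_length + 1):
        for _ in range(int(spectrum.missense_counts[pos - 1])):
            wt = pssm.wild_type[pos - 1]
            mut = [aa for aa in ALPHABET if aa != wt][rng.integers(19)]
            ctype = types[rng.choice(len(types), p=weights)]
            counter += 1
            rows.append(
                (config.planted_gene, pos, wt, mut, "missense", ctype, f"TS{counter:04d}")
            )
    for _ in range(spectrum.truncating_count):
        pos = int(rng.integers(1, spectrum.protein_length + 1))
        ctype = types[rng.choice(len(types), p=weights)]
        counter += 1
        rows.append(
            (config.planted_gene, pos, pssm.wild_type[pos - 1], "*",
             "stopgain", ctype, f"TS{counter:04d}")
        )
    table = pd.DataFrame(rows, columns=SOMATIC_COLUMNS)
    return table, dict(config.cancer_type_totals)
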