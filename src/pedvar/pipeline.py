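"""End-to-end orchestration: demo bundle generation, staged execution, and
the consolidated report.

Stage order: read -> normalize -> hard-filter -> per-pedigree sharing ->
rare/non-silent filtering -> germline-subset co-occurrence -> evidence and
verdict -> cohort burden -> substitution tolerance -> somatic recurrence.
Every stage logs counts in/out and writes its rejects to sidecar TSVs, so
input variants are always accounted for (kept + rejected), never silently
dropped.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import cohort_burden, cosegregation, recurrence, tolerance
from .errors import ConfigError
from .synthetic_data import (
    SimConfig,
    child_seed,
    simulate_cohort_counts,
    simulate_pedigree_dataset,
    simulate_pssm,
    simulate_somatic_table,
)
from .tolerance import parse_hgvs_p, read_pssm, write_pssm
from .variant_model import (
    FilterThresholds,
    annotation_row_to_variant,
    hard_filter,
    read_annotation,
    read_pedigree,
    read_variants,
    write_annotation,
    write_kinship,
    write_ped,
    write_vcf,
)

logger = logging.getLogger(__name__)

CANDIDATE_COLUMNS = [
    "pedigree",
    "evaluation",
    "genotype",
    "gene",
    "type",
    "transcript",
    "exon",
    "hgvs_c",
    "hgvs_p",
    "variant_id",
    "shared",
    "rare",
    "non_silent",
    "cohort_cooccurring",
    "triggered_rule",
]


@dataclass
class RunConfig:
    """One-file description of a full run; CLI flags override YAML keys."""

    vcf_dir: Path
    ped: Path
    annotation: Path
    cohort: Path
    kinship: Path | None = None
    pssm: Path | None = None
    somatic: Path | None = None
    outdir: Path = Path("out")
    seed: int = 42
    stages: dict[str, bool] = field(
        default_factory=lambda: {
            "cosegregation": True,
            "burden": True,
            "tolerance": True,
            "recurrence": True,
        }
    )
    af_max: float = 0.001
    benign_af: float = 0.05
    missing_as_carrier: bool = False
    require_cooccurrence: bool = False
    lof_genes: tuple[str, ...] = ()
    min_depth: int = 8
    min_gq: int = 20
    min_qual: float = 30.0
    burden_cohort_a: str = "general-minus-non-cancer"
    burden_cohort_b: str = "control"
    tolerance_gene: str | None = None
    tolerance_set_size: int = 3
    tolerance_n_sets: int = 10000
    recurrence_gene: str | None = None
    protein_length: int = 377
    window_halfwidth: int = 2
    hotspot_alpha: float = 0.001
    cancer_type_totals: dict[str, int] = field(default_factory=dict)

    def validate(self) -> None:
        for name in ("vcf_dir", "ped", "annotation", "cohort"):
            path = getattr(self, name)
            if not Path(path).exists():
                raise ConfigError(f"inputs.{name}: no such path {path}")
        if not (0 <= self.af_max <= 1):
            raise ConfigError("rarity.af_max must lie in [0, 1]")
        if self.tolerance_set_size < 1 or self.tolerance_n_sets < 1:
            raise ConfigError("tolerance set_size and n_sets must be >= 1")
        if self.window_halfwidth < 0:
            raise ConfigError("recurrence.window must be >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides: Any) -> "RunConfig":
        path = Path(path)
        raw = yaml.safe_load(path.read_text())
        base = path.parent
        inputs = raw.get("inputs", {})

        def _p(key: str) -> Path | None:
            return base / inputs[key] if key in inputs and inputs[key] else None

        cfg = cls(
            vcf_dir=_p("vcf_dir"),
            ped=_p("ped"),
            annotation=_p("annotation"),
            cohort=_p("cohort"),
            kinship=_p("kinship"),
            pssm=_p("pssm"),
            somatic=_p("somatic"),
            outdir=base / raw.get("outdir", "out"),
            seed=int(raw.get("seed", 42)),
        )
        cfg.stages.update(raw.get("stages", {}))
        cfg.af_max = float(raw.get("rarity", {}).get("af_max", cfg.af_max))
        sharing = raw.get("sharing", {})
        cfg.missing_as_carrier = bool(
            sharing.get("missing_as_carrier", cfg.missing_as_carrier)
        )
        acmg_cfg = raw.get("acmg", {})
        cfg.benign_af = float(acmg_cfg.get("benign_af", cfg.benign_af))
        cfg.lof_genes = tuple(acmg_cfg.get("lof_genes", []))
        filt = raw.get("filters", {})
        cfg.min_depth = int(filt.get("min_depth", cfg.min_depth))
        cfg.min_gq = int(filt.get("min_gq", cfg.min_gq))
        cfg.min_qual = float(filt.get("min_qual", cfg.min_qual))
        cfg.require_cooccurrence = bool(
            raw.get("cooccurrence", {}).get("require", cfg.require_cooccurrence)
        )
        burden = raw.get("burden", {})
        cfg.burden_cohort_a = burden.get("cohort_a", cfg.burden_cohort_a)
        cfg.burden_cohort_b = burden.get("cohort_b", cfg.burden_cohort_b)
        tol = raw.get("tolerance", {})
        cfg.tolerance_gene = tol.get("gene", cfg.tolerance_gene)
        cfg.tolerance_set_size = int(tol.get("set_size", cfg.tolerance_set_size))
        cfg.tolerance_n_sets = int(tol.get("n_sets", cfg.tolerance_n_sets))
        rec = raw.get("recurrence", {})
        cfg.recurrence_gene = rec.get("gene", cfg.recurrence_gene)
        cfg.protein_length = int(rec.get("protein_length", cfg.protein_length))
        cfg.window_halfwidth = int(rec.get("window", cfg.window_halfwidth))
        cfg.hotspot_alpha = float(rec.get("alpha", cfg.hotspot_alpha))
        cfg.cancer_type_totals = {
            str(k): int(v) for k, v in rec.get("cancer_type_totals", {}).items()
        }
        for key, value in overrides.items():
            if value is not None:
                setattr(cfg, key, value)
        return cfg

    def digest(self) -> str:
        payload = {
            k: str(v) for k, v in dataclasses.asdict(self).items()
        }
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class Report:
    candidates: pd.DataFrame
    burden: pd.DataFrame | None
    tolerance_scores: pd.DataFrame | None
    hotspots: pd.DataFrame | None
    gene_class: dict | None
    enrichment: pd.DataFrame | None
    stage_log: list[dict]
    provenance: dict

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.candidates.to_csv(outdir / "candidates.tsv", sep="\t", index=False)
        if self.burden is not None:
            self.burden.to_csv(outdir / "burden.tsv", sep="\t", index=False)
        if self.tolerance_scores is not None:
            self.tolerance_scores.to_csv(
                outdir / "tolerance.tsv", sep="\t", index=False
            )
        if self.hotspots is not None:
            self.hotspots.to_csv(outdir / "hotspots.tsv", sep="\t", index=False)
        if self.enrichment is not None:
            self.enrichment.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
        summary = {
            "provenance": self.provenance,
            "stages": self.stage_log,
            "n_candidates": int(len(self.candidates)),
            "gene_class": self.gene_class,
            "top_burden_gene": (
                str(self.burden.iloc[0]["gene"])
                if self.burden is not None and len(self.burden)
                else None
            ),
        }
        (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))


def _load_calls(config: RunConfig, stage_log: list[dict], outdir: Path):
    """Read, normalize and hard-filter every per-sample VCF."""
    thresholds = FilterThresholds(config.min_depth, config.min_gq, config.min_qual)
    vcf_paths = sorted(Path(config.vcf_dir).glob("*.vcf"))
    calls_by_sample: dict[str, dict] = {}
    reject_rows = []
    n_in = n_kept = 0
    for path in vcf_paths:
        sample = path.stem
        records = read_variants(path)
        kept: dict[str, object] = {}
        for rec in records:
            n_in += 1
            decision = hard_filter(
                rec.variant, rec.calls.values(), thresholds, qual=rec.qual, info=rec.info
            )
            if decision.passed:
                call = rec.calls.get(sample) or next(iter(rec.calls.values()))
                kept[rec.variant.variant_id] = call
                n_kept += 1
            else:
                reject_rows.append(
                    (sample, rec.variant.variant_id, ";".join(decision.reasons))
                )
        calls_by_sample[sample] = kept
    assert n_in == n_kept + len(reject_rows), "hard-filter stage lost variants"
    pd.DataFrame(
        reject_rows, columns=["sample", "variant_id", "reasons"]
    ).to_csv(outdir / "rejects_hard_filter.tsv", sep="\t", index=False)
    stage_log.append(
        {"stage": "hard_filter", "in": n_in, "kept": n_kept, "rejected": len(reject_rows)}
    )
    return calls_by_sample


def run_all(config: RunConfig) -> Report:
    """Execute the configured stages and assemble the consolidated report."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage_log: list[dict] = []

    annotation = read_annotation(config.annotation)
    ann_by_id = {row["variant_id"]: row for _, row in annotation.iterrows()}
    cohort = cohort_burden.read_cohort_table(config.cohort)
    cohort_pass = cohort_burden.quality_filter(cohort)
    stage_log.append(
        {
            "stage": "cohort_quality_filter",
            "in": int(cohort["variant_id"].nunique()),
            "kept": int(cohort_pass["variant_id"].nunique()),
        }
    )

    calls_by_sample = _load_calls(config, stage_log, outdir)
    pedigrees = read_pedigree(
        config.ped, kinship_path=config.kinship,
        sequenced_samples=sorted(calls_by_sample),
    )

    germline_set = _germline_subset(cohort_pass)
    control = cohort_pass[cohort_pass["cohort"] == "control"]
    control_ac = dict(zip(control["variant_id"], control["AC"]))

    candidate_rows = []
    reject_rows = []
    if config.stages.get("cosegregation", True):
        for ped in pedigrees:
            shared = cosegregation.shared_candidates(
                ped, calls_by_sample, config.missing_as_carrier
            )
            annotated, unannotated = [], []
            for vid in sorted(shared):
                if vid in ann_by_id:
                    annotated.append(annotation_row_to_variant(ann_by_id[vid]))
                else:
                    unannotated.append(vid)
            kept, rejected = cosegregation.filter_rare_nonsilent(
                annotated, config.af_max
            )
            for av, reason in rejected:
                reject_rows.append((ped.pedigree_id, av.variant.variant_id, reason))
            for vid in unannotated:
                reject_rows.append((ped.pedigree_id, vid, "unannotated"))
            assert len(shared) == len(kept) + len(rejected) + len(unannotated)
            for av in kept:
                vid = av.variant.variant_id
                cooc = cosegregation.cohort_cooccurrence(vid, germline_set)
                if config.require_cooccurrence and not cooc:
                    reject_rows.append((ped.pedigree_id, vid, "no_cohort_cooccurrence"))
                    continue
                context = cosegregation.EvidenceContext(
                    shared_in_pedigree=len(ped.sequenced_affected) > 1,
                    absent_in_controls=(
                        (av.control_af in (None, 0.0)) and control_ac.get(vid, 0) == 0
                    ),
                    insilico_damaging=av.insilico_damaging,
                    known_lof_gene=av.gene in config.lof_genes,
                )
                verdict = cosegregation.classify(av, context, config.benign_af)
                genotypes = {
                    calls_by_sample[s][vid].gt
                    for s in ped.sequenced_affected
                    if vid in calls_by_sample[s]
                }
                genotype = "Hom" if genotypes == {"hom_alt"} else "Het"
                candidate_rows.append(
                    (
                        ped.pedigree_id, verdict.tier, genotype, av.gene,
                        av.consequence, av.transcript, av.exon, av.hgvs_c,
                        av.hgvs_p, vid, True, True, True, cooc,
                        verdict.triggered_rule,
                    )
                )
        stage_log.append(
            {
                "stage": "cosegregation",
                "pedigrees": len(pedigrees),
                "candidates": len(candidate_rows),
                "rejected": len(reject_rows),
            }
        )
    candidates = pd.DataFrame(candidate_rows, columns=CANDIDATE_COLUMNS)
    pd.DataFrame(
        reject_rows, columns=["pedigree", "variant_id", "reason"]
    ).to_csv(outdir / "rejects_cosegregation.tsv", sep="\t", index=False)

    burden_df = None
    if config.stages.get("burden", True):
        burden_df = _run_burden(config, annotation, cohort_pass)
        stage_log.append({"stage": "burden", "genes": int(len(burden_df))})

    tolerance_df = None
    if config.stages.get("tolerance", True) and config.pssm:
        gene = config.tolerance_gene
        if gene is None and burden_df is not None and len(burden_df):
            gene = str(burden_df.iloc[0]["gene"])
        tolerance_df = _run_tolerance(config, candidates, gene)
        stage_log.append(
            {
                "stage": "tolerance",
                "gene": gene,
                "mutations": int(len(tolerance_df)) if tolerance_df is not None else 0,
            }
        )

    hotspots_df = gene_class = enrichment_df = None
    if config.stages.get("recurrence", True) and config.somatic:
        hotspots_df, gene_class, enrichment_df = _run_recurrence(config)
        stage_log.append(
            {
                "stage": "recurrence",
                "hotspots": int(hotspots_df["is_hotspot"].sum()),
            }
        )

    report = Report(
        candidates=candidates,
        burden=burden_df,
        tolerance_scores=tolerance_df,
        hotspots=hotspots_df,
        gene_class=gene_class,
        enrichment=enrichment_df,
        stage_log=stage_log,
        provenance={"config_sha256": config.digest(), "seed": config.seed},
    )
    report.write(outdir)
    return report


def _germline_subset(cohort_pass: pd.DataFrame) -> set[str]:
    full = cohort_pass[cohort_pass["cohort"] == "full"]
    comp = cohort_pass[cohort_pass["cohort"] == "complement"]
    if full.empty:
        return set()
    return cohort_burden.derive_germline_subset(full, comp)


def _run_burden(
    config: RunConfig, annotation: pd.DataFrame, cohort_pass: pd.DataFrame
) -> pd.DataFrame:
    nonsilent = annotation[
        annotation["consequence"].isin(["missense", "frameshift", "stopgain", "splicing"])
    ]
    gene_to_ids = {
        gene: list(sub["variant_id"]) for gene, sub in nonsilent.groupby("gene")
    }
    cohorts = {name: cohort_pass[cohort_pass["cohort"] == name] for name in
               set(cohort_pass["cohort"])}

    def resolve(label: str) -> pd.DataFrame:
        if cohort_pass.empty:
            return cohort_pass
        if label in cohorts:
            return cohorts[label]
        if "-minus-" in label:
            left, right = label.split("-minus-", 1)
            if left in cohorts and right in cohorts:
                return cohort_burden.subtract_tables(
                    cohorts[left], cohorts[right], label
                )
        raise ConfigError(f"burden cohort {label!r} not derivable from table")

    return cohort_burden.burden_scan(
        gene_to_ids, resolve(config.burden_cohort_a), resolve(config.burden_cohort_b)
    )


def _run_tolerance(
    config: RunConfig, candidates: pd.DataFrame, gene: str | None
) -> pd.DataFrame | None:
    if gene is None:
        return None
    pssm = read_pssm(config.pssm)
    rows = candidates[
        (candidates["gene"] == gene) & (candidates["type"] == "missense")
    ]
    mutations = []
    for hgvs_p in rows["hgvs_p"]:
        try:
            mutations.append(parse_hgvs_p(str(hgvs_p)))
        except Exception:
            continue
    if not mutations:
        return pd.DataFrame(
            columns=["mutation", "delta_s", "set_mean", "empirical_p"]
        )
    scores = [tolerance.delta_s(pssm, *m) for m in mutations]
    observed = float(pd.Series([s.delta_s for s in scores]).mean())
    null = tolerance.sample_null(
        pssm,
        set_size=config.tolerance_set_size,
        n_sets=config.tolerance_n_sets,
        seed=child_seed(config.seed, "null"),
    )
    p = tolerance.empirical_p(observed, null)
    return pd.DataFrame(
        {
            "mutation": [f"p.{s.wt}{s.position}{s.mut}" for s in scores],
            "delta_s": [s.delta_s for s in scores],
            "set_mean": observed,
            "empirical_p": p,
        }
    )


def _run_recurrence(config: RunConfig):
    somatic = recurrence.read_somatic_table(config.somatic)
    gene = config.recurrence_gene
    if gene is None:
        gene = somatic["gene"].mode().iat[0]
    spectrum = recurrence.spectrum_from_table(
        somatic, gene, config.protein_length,
        cancer_type_totals=config.cancer_type_totals or None,
    )
    hits = recurrence.hotspot_scan(
        spectrum, config.window_halfwidth, config.hotspot_alpha
    )
    hotspots_df = pd.DataFrame(
        {
            "residue": [h.residue for h in hits],
            "window_lo": [h.window[0] for h in hits],
            "window_hi": [h.window[1] for h in hits],
            "count": [h.count_in_window for h in hits],
            "p_raw": [h.p_raw for h in hits],
            "p_adjusted": [h.p_adjusted for h in hits],
            "is_hotspot": [h.is_hotspot for h in hits],
        }
    )
    label, fractions = recurrence.classify_20_20(spectrum)
    gene_class = {"gene": gene, "label": label, **fractions}
    enrichment_df = recurrence.cancer_type_enrichment(spectrum)
    return hotspots_df, gene_class, enrichment_df


# ---------------------------------------------------------------------------
# demo bundle


def make_demo(outdir: str | Path, seed: int, **sim_overrides: Any) -> dict[str, Path]:
    """Write a complete synthetic input bundle, truth JSON and run config.

    The bundle validates against every format reader and is byte-identical
    across runs with the same seed.
    """
    outdir = Path(outdir)
    (outdir / "vcfs").mkdir(parents=True, exist_ok=True)
    config = SimConfig(seed=seed, **sim_overrides)
    config.validate()

    per_sample, annotation, truth = simulate_pedigree_dataset(config)
    cohort = simulate_cohort_counts(
        config, annotation, planted_ids=truth.planted_shared_variant_ids
    )
    pssm = simulate_pssm(
        config.pssm_length, config.conserved_fraction, child_seed(config.seed, "pssm")
    )
    somatic, type_totals = simulate_somatic_table(config, pssm)

    paths: dict[str, Path] = {}
    for sample, calls in sorted(per_sample.items()):
        path = outdir / "vcfs" / f"{sample}.vcf"
        write_vcf(path, sample, calls)
    paths["vcf_dir"] = outdir / "vcfs"

    pedigrees = []
    from .variant_model import Pedigree

    for pid, n_seq, kin in config.pedigree_layout:
        pedigrees.append(
            Pedigree(pid, tuple(f"{pid}_S{s + 1}" for s in range(n_seq)), kin)
        )
    write_ped(outdir / "pedigree.ped", pedigrees)
    write_kinship(outdir / "kinship.tsv", pedigrees)
    write_annotation(outdir / "annotation.tsv", annotation)
    cohort_burden.write_cohort_table(outdir / "cohort.tsv", cohort)
    write_pssm(outdir / "gene.pssm", pssm)
    somatic.to_csv(outdir / "somatic.tsv", sep="\t", index=False)
    (outdir / "truth.json").write_text(truth.to_json())

    run_yaml: dict[str, Any] = {
        "inputs": {
            "vcf_dir": "vcfs",
            "ped": "pedigree.ped",
            "kinship": "kinship.tsv",
            "annotation": "annotation.tsv",
            "cohort": "cohort.tsv",
            "pssm": "gene.pssm",
            "somatic": "somatic.tsv",
        },
        "outdir": "out",
        "seed": seed,
        "rarity": {"af_max": config.planted_af_max},
        "burden": {"cohort_a": "general-minus-non-cancer", "cohort_b": "control"},
        "tolerance": {"gene": None, "set_size": 3, "n_sets": 2000},
        "recurrence": {
            "gene": config.planted_gene,
            "protein_length": config.pssm_length,
            "window": 2,
            "alpha": 0.001,
            "cancer_type_totals": {k: int(v) for k, v in type_totals.items()},
        },
    }
    (outdir / "run.yaml").write_text(yaml.safe_dump(run_yaml, sort_keys=True))
    for name in (
        "pedigree.ped", "kinship.tsv", "annotation.tsv", "cohort.tsv",
        "gene.pssm", "somatic.tsv", "truth.json", "run.yaml",
    ):
        paths[name.split(".")[0]] = outdir / name
    return paths
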