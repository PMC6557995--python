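"""Variant/pedigree data model, standard-format readers, normalization and
site-level hard filtering.

Conventions
-----------
* Coordinates are VCF-style 1-based inclusive throughout.
* The canonical variant id is ``chrom:pos:ref:alt`` on the *normalized*
  representation (shared suffix trimmed, then shared prefix trimmed keeping a
  single anchor base for indels).
* A value passes a numeric threshold when ``value >= threshold``; it fails
  strictly below.  This boundary convention is deliberate and tested.
"""

from __future__ import annotations

import operator
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import ConfigError, DataError, ParseError

# Genotype states on the decomposed, normalized representation.
GT_HOM_REF = "hom_ref"
GT_HET = "het"
GT_HOM_ALT = "hom_alt"
GT_MISSING = "missing"

# Closed consequence vocabulary; "non-silent" = protein-altering classes.
CONSEQUENCES = (
    "missense",
    "frameshift",
    "stopgain",
    "splicing",
    "synonymous",
    "intronic",
    "other",
)
NON_SILENT = frozenset({"missense", "frameshift", "stopgain", "splicing"})
TRUNCATING = frozenset({"frameshift", "stopgain", "splicing"})

_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class Variant:
    """A single substitution or indel, 1-based, one alt allele."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if not self.ref or not self.alt:
            raise DataError(f"empty allele at {self.chrom}:{self.pos}")
        if self.ref == self.alt:
            raise DataError(f"ref == alt at {self.chrom}:{self.pos} ({self.ref})")

    @property
    def symbolic(self) -> bool:
        """True for alleles outside plain ACGT strings (e.g. <DEL>, breakends)."""
        return not (set(self.ref) <= _BASES and set(self.alt) <= _BASES)

    @property
    def variant_id(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1 and not self.symbolic


def normalize(variant: Variant) -> Variant:
    """Return the minimal representation of ``variant``.

    Trims the shared suffix, then the shared prefix, keeping one anchor base
    so indels stay left-anchored.  Idempotent; symbolic alleles are returned
    unchanged (they carry no base-level redundancy to trim).
    """
    if variant.symbolic:
        return variant
    ref, alt, pos = variant.ref, variant.alt, variant.pos
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    if (ref, alt, pos) == (variant.ref, variant.alt, variant.pos):
        return variant
    return Variant(variant.chrom, pos, ref, alt)


@dataclass(frozen=True)
class GenotypeCall:
    sample_id: str
    gt: str
    depth: int = 0
    genotype_quality: int = 0

    def __post_init__(self) -> None:
        if self.gt not in (GT_HOM_REF, GT_HET, GT_HOM_ALT, GT_MISSING):
            raise DataError(f"unknown genotype state {self.gt!r}")
        if self.gt != GT_MISSING and self.depth < 0:
            raise DataError(f"negative depth for sample {self.sample_id}")

    @property
    def carries_alt(self) -> bool:
        return self.gt in (GT_HET, GT_HOM_ALT)


@dataclass(frozen=True)
class AnnotatedVariant:
    """A variant joined with its functional annotation row."""

    variant: Variant
    gene: str
    transcript: str = "."
    exon: str = "."
    hgvs_c: str = "."
    hgvs_p: str = "."
    consequence: str = "other"
    control_af: float | None = None
    insilico_damaging: str = "unknown"  # damaging | tolerated | unknown

    def __post_init__(self) -> None:
        if self.consequence not in CONSEQUENCES:
            raise DataError(f"unknown consequence {self.consequence!r}")
        if self.control_af is not None and not (0.0 <= self.control_af <= 1.0):
            raise DataError(f"control_af out of [0,1]: {self.control_af}")
        if self.insilico_damaging not in ("damaging", "tolerated", "unknown"):
            raise DataError(f"bad insilico value {self.insilico_damaging!r}")

    @property
    def non_silent(self) -> bool:
        return self.consequence in NON_SILENT


@dataclass(frozen=True)
class Pedigree:
    pedigree_id: str
    sequenced_affected: tuple[str, ...]
    kinship: float

    def __post_init__(self) -> None:
        if len(self.sequenced_affected) < 1:
            raise DataError(f"pedigree {self.pedigree_id} has no sequenced affected")
        if not (0.0 <= self.kinship <= 0.5):
            raise DataError(f"kinship out of [0, 0.5] for {self.pedigree_id}")


@dataclass(frozen=True)
class SiteRecord:
    """One decomposed VCF site: variant + QUAL/INFO + per-sample calls."""

    variant: Variant
    qual: float
    info: Mapping[str, float] = field(default_factory=dict)
    calls: Mapping[str, GenotypeCall] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# hard filtering


_COMPARATORS = {
    ">=": operator.ge,
    "<=": operator.le,
    ">": operator.gt,
    "<": operator.lt,
    "==": operator.eq,
}


@dataclass(frozen=True)
class FilterThresholds:
    """Site/call hard-filter thresholds.

    ``site_level_expressions`` are (field, comparator, value) triples checked
    against the INFO dict; a record must satisfy every expression to pass.
    The defaults follow widely used site-level heuristics and are fully
    overridable.
    """

    min_depth: int = 8
    min_gq: int = 20
    min_qual: float = 30.0
    site_level_expressions: tuple[tuple[str, str, float], ...] = ()

    def __post_init__(self) -> None:
        for name in ("min_depth", "min_gq", "min_qual"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        for fld, cmp, _ in self.site_level_expressions:
            if cmp not in _COMPARATORS:
                raise ConfigError(f"unknown comparator {cmp!r} in expression on {fld!r}")


@dataclass(frozen=True)
class FilterDecision:
    passed: bool
    reasons: tuple[str, ...] = ()


def hard_filter(
    variant: Variant,
    calls: Iterable[GenotypeCall],
    thresholds: FilterThresholds,
    qual: float | None = None,
    info: Mapping[str, float] | None = None,
) -> FilterDecision:
    """Apply hard thresholds to one site; all violated reasons are listed.

    A call with a missing genotype carries no depth/GQ requirement.  A field
    named in a site-level expression but absent from INFO is a configuration
    error (silently passing a typo'd filter is worse than failing loudly).
    """
    reasons: list[str] = []
    if qual is not None and qual < thresholds.min_qual:
        reasons.append("min_qual")
    for call in calls:
        if call.gt == GT_MISSING:
            continue
        if call.depth < thresholds.min_depth and "min_depth" not in reasons:
            reasons.append("min_depth")
        if call.genotype_quality < thresholds.min_gq and "min_gq" not in reasons:
            reasons.append("min_gq")
    info = info or {}
    for fld, cmp, value in thresholds.site_level_expressions:
        if fld not in info:
            raise ConfigError(f"site expression references unknown field {fld!r}")
        if not _COMPARATORS[cmp](info[fld], value):
            reasons.append(f"{fld}{cmp}{value}")
    return FilterDecision(passed=not reasons, reasons=tuple(reasons))


# ---------------------------------------------------------------------------
# VCF reading


def _prescan_vcf(path: Path) -> None:
    # cyvcf2/htslib does not report line numbers; a cheap structural scan of
    # uncompressed files lets parse errors point at the offending line.
    saw_header = False
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                saw_header = True
                continue
            if not line.strip():
                continue
            if not saw_header:
                raise ParseError(f"{path}:{lineno}: data before #CHROM header")
            if len(line.rstrip("\n").split("\t")) < 8:
                raise ParseError(f"{path}:{lineno}: fewer than 8 VCF columns")
    if not saw_header:
        raise ParseError(f"{path}: missing #CHROM header line")


def read_variants(vcf_path: str | Path) -> list[SiteRecord]:
    """Read a VCF 4.x file into decomposed, order-preserving site records.

    Multi-allelic records are split into one record per alt allele; genotype
    phase is ignored.  Genotypes are re-expressed against each alt: a sample
    is het for every alt allele it carries once.
    """
    from cyvcf2 import VCF

    path = Path(vcf_path)
    if not path.exists():
        raise ParseError(f"no such VCF: {path}")
    if path.suffix not in (".gz", ".bcf"):
        _prescan_vcf(path)
    try:
        vcf = VCF(str(path))
    except Exception as exc:  # htslib raises bare Exceptions
        raise ParseError(f"{path}: {exc}") from exc
    samples = list(vcf.samples)
    records: list[SiteRecord] = []
    for rec in vcf:
        depths = rec.format("DP")
        gqs = rec.format("GQ")
        info = {k: v for k, v in rec.INFO if isinstance(v, (int, float))}
        for alt_index, alt in enumerate(rec.ALT, start=1):
            variant = normalize(Variant(rec.CHROM, rec.POS, rec.REF, alt))
            calls = {}
            for si, sample in enumerate(samples):
                alleles = rec.genotypes[si][:-1] if rec.genotypes else []
                if not alleles or any(a < 0 for a in alleles):
                    gt = GT_MISSING
                else:
                    n_alt = sum(1 for a in alleles if a == alt_index)
                    gt = (GT_HOM_REF, GT_HET, GT_HOM_ALT)[min(n_alt, 2)]
                depth = int(depths[si][0]) if depths is not None else 0
                gq = int(gqs[si][0]) if gqs is not None else 0
                calls[sample] = GenotypeCall(sample, gt, max(depth, 0), max(gq, 0))
            records.append(
                SiteRecord(
                    variant=variant,
                    qual=float(rec.QUAL) if rec.QUAL is not None else 0.0,
                    info=info,
                    calls=calls,
                )
            )
    return records


def write_vcf(
    path: str | Path,
    sample_id: str,
    rows: pd.DataFrame,
) -> None:
    """Write a single-sample VCF 4.2 with GT:DP:GQ from a calls table.

    ``rows`` needs columns chrom, pos, ref, alt, gt, depth, gq, qual; rows are
    sorted by (chrom, pos) on output.
    """
    gt_field = {GT_HOM_REF: "0/0", GT_HET: "0/1", GT_HOM_ALT: "1/1", GT_MISSING: "./."}
    ordered = rows.sort_values(["chrom", "pos"], kind="stable")
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in sorted(ordered["chrom"].unique()):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample_id}\n")
        for row in ordered.itertuples(index=False):
            fh.write(
                f"{row.chrom}\t{row.pos}\t.\t{row.ref}\t{row.alt}\t"
                f"{row.qual:.1f}\t.\t.\tGT:DP:GQ\t"
                f"{gt_field[row.gt]}:{row.depth}:{row.gq}\n"
            )


# ---------------------------------------------------------------------------
# pedigree reading


def read_pedigree(
    ped_path: str | Path,
    kinship_path: str | Path | None = None,
    kinship: Mapping[str, float] | None = None,
    sequenced_samples: Sequence[str] | None = None,
) -> list[Pedigree]:
    """Read a 6-column PED file plus a kinship sidecar into Pedigree objects.

    Affection status 2 marks affected.  When ``sequenced_samples`` is given
    (the sample ids present in the VCF set) only those individuals enter
    ``sequenced_affected``, and a sequenced sample absent from the PED file is
    a data error.  Pedigrees without a known kinship default to 0.
    """
    ped = pd.read_csv(
        ped_path,
        sep=r"\s+",
        header=None,
        comment="#",
        dtype=str,
        names=["fid", "iid", "father", "mother", "sex", "phenotype"],
    )
    if ped["iid"].duplicated().any():
        dup = ped.loc[ped["iid"].duplicated(), "iid"].iloc[0]
        raise DataError(f"duplicate sample id in PED: {dup}")
    kin: dict[str, float] = dict(kinship or {})
    if kinship_path is not None:
        side = pd.read_csv(kinship_path, sep="\t", dtype={"pedigree_id": str})
        kin.update(zip(side["pedigree_id"], side["kinship"].astype(float)))
    if sequenced_samples is not None:
        unknown = set(sequenced_samples) - set(ped["iid"])
        if unknown:
            raise DataError(f"VCF samples absent from PED: {sorted(unknown)}")
    pedigrees = []
    for fid, group in ped.groupby("fid", sort=True):
        affected = group.loc[group["phenotype"] == "2", "iid"].tolist()
        if sequenced_samples is not None:
            affected = [s for s in affected if s in set(sequenced_samples)]
        if not affected:
            continue
        pedigrees.append(Pedigree(str(fid), tuple(affected), kin.get(str(fid), 0.0)))
    return pedigrees


def write_ped(path: str | Path, pedigrees: Iterable[Pedigree]) -> None:
    """Write pedigrees as a 6-column pre-MAKEPED PED file (all affected)."""
    with open(path, "wt", encoding="utf-8") as fh:
        for ped in pedigrees:
            for sample in ped.sequenced_affected:
                fh.write(f"{ped.pedigree_id}\t{sample}\t0\t0\t0\t2\n")


def write_kinship(path: str | Path, pedigrees: Iterable[Pedigree]) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("pedigree_id\tkinship\n")
        for ped in pedigrees:
            fh.write(f"{ped.pedigree_id}\t{ped.kinship}\n")


# ---------------------------------------------------------------------------
# annotation table I/O

ANNOTATION_COLUMNS = [
    "variant_id",
    "gene",
    "transcript",
    "exon",
    "hgvs_c",
    "hgvs_p",
    "consequence",
    "af_control",
    "insilico",
]


def read_annotation(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(ANNOTATION_COLUMNS[:8]) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: annotation table lacks columns {sorted(missing)}")
    # '.' is the missing marker, but only af_control becomes numeric NaN;
    # string columns keep the literal dot
    df["af_control"] = pd.to_numeric(df["af_control"].replace(".", ""), errors="coerce")
    if "insilico" not in df.columns:
        df["insilico"] = "unknown"
    df["insilico"] = df["insilico"].fillna("unknown")
    return df


def write_annotation(path: str | Path, df: pd.DataFrame) -> None:
    out = df.copy()
    if "insilico" not in out.columns:
        out["insilico"] = "unknown"
    out.to_csv(path, sep="\t", index=False, na_rep=".", columns=ANNOTATION_COLUMNS)


def annotation_row_to_variant(row: Mapping[str, object]) -> AnnotatedVariant:
    """Build an AnnotatedVariant from one annotation-table row."""
    chrom, pos, ref, alt = str(row["variant_id"]).split(":")
    af = row.get("af_control")
    af = None if af is None or pd.isna(af) else float(af)
    return AnnotatedVariant(
        variant=Variant(chrom, int(pos), ref, alt),
        gene=str(row["gene"]),
        transcript=str(row.get("transcript", ".")),
        exon=str(row.get("exon", ".")),
        hgvs_c=str(row.get("hgvs_c", ".")),
        hgvs_p=str(row.get("hgvs_p", ".")),
        consequence=str(row["consequence"]),
        control_af=af,
        insilico_damaging=str(row.get("insilico", "unknown") or "unknown"),
    )
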