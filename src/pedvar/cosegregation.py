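"""Pedigree co-segregation filtering, cohort co-occurrence, and ACMG-style
classification of candidate variants.

A candidate co-segregating variant is one carried (at least one alternate
allele) by every sequenced affected member of a pedigree, rare in population
controls, and protein-altering.  Candidates can additionally be flagged for
co-occurrence with a cancer-germline variant set derived by population-table
subtraction, and are classified through the evidence-combination engine in
:mod:`pedvar.acmg`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from . import acmg
from .acmg import EvidenceCode, Verdict, combine
from .errors import DataError
from .variant_model import (
    AnnotatedVariant,
    GenotypeCall,
    Pedigree,
)

# re-exported: the spec surface of this module includes the combiner
combine_acmg = combine

DEFAULT_AF_MAX = 0.001
DEFAULT_BENIGN_AF = 0.05


@dataclass(frozen=True)
class CandidateFlags:
    shared: bool = False
    rare: bool = False
    non_silent: bool = False
    cohort_cooccurring: bool = False


@dataclass
class CandidateSet:
    pedigree_id: str
    variants: list[AnnotatedVariant] = field(default_factory=list)
    flags: dict[str, CandidateFlags] = field(default_factory=dict)
    verdicts: dict[str, Verdict] = field(default_factory=dict)


def shared_candidates(
    pedigree: Pedigree,
    calls_by_sample: Mapping[str, Mapping[str, GenotypeCall]],
    missing_as_carrier: bool = False,
) -> set[str]:
    """Variant ids carried by every sequenced affected sample of a pedigree.

    Carrier status means >=1 alternate allele (het or hom-alt) on the
    decomposed, normalized representation; a missing genotype excludes the
    variant unless ``missing_as_carrier`` relaxes that (precision-favoring
    default).  A variant id absent from a sample's call map counts as not
    carried.
    """
    for sample in pedigree.sequenced_affected:
        if sample not in calls_by_sample:
            raise DataError(
                f"pedigree {pedigree.pedigree_id}: sample {sample} has no call set"
            )

    def carries(call: GenotypeCall | None) -> bool:
        if call is None:
            return False
        if call.gt == "missing":
            return missing_as_carrier
        return call.carries_alt

    first = pedigree.sequenced_affected[0]
    shared = {
        vid for vid, call in calls_by_sample[first].items() if carries(call)
    }
    for sample in pedigree.sequenced_affected[1:]:
        calls = calls_by_sample[sample]
        shared = {vid for vid in shared if carries(calls.get(vid))}
    return shared


def filter_rare_nonsilent(
    variants: Iterable[AnnotatedVariant],
    af_max: float = DEFAULT_AF_MAX,
) -> tuple[list[AnnotatedVariant], list[tuple[AnnotatedVariant, str]]]:
    """Keep protein-altering variants that are rare (or unseen) in controls.

    An absent control frequency counts as rare — unobserved variants are the
    interesting ones.  Returns (kept, rejected-with-reason); silent and
    common variants are routed to the reject list, never silently dropped.
    """
    kept: list[AnnotatedVariant] = []
    rejected: list[tuple[AnnotatedVariant, str]] = []
    for av in variants:
        if not av.non_silent:
            rejected.append((av, f"silent:{av.consequence}"))
        elif av.control_af is not None and av.control_af > af_max:
            rejected.append((av, f"common:af={av.control_af}>{af_max}"))
        else:
            kept.append(av)
    return kept, rejected


def cohort_cooccurrence(variant_id: str, germline_variant_set: set[str]) -> bool:
    """True iff the canonical id occurs in the derived cancer-germline set."""
    return variant_id in germline_variant_set


@dataclass(frozen=True)
class EvidenceContext:
    """Pipeline facts feeding the (simplified, documented) evidence mapping."""

    shared_in_pedigree: bool = False
    absent_in_controls: bool = False
    insilico_damaging: str = "unknown"
    known_lof_gene: bool = False


def assign_evidence(
    variant: AnnotatedVariant,
    context: EvidenceContext,
    benign_af: float = DEFAULT_BENIGN_AF,
) -> list[EvidenceCode]:
    """Deterministic mapping from pipeline context to generic evidence codes.

    truncating change in a known loss-of-function gene -> very strong
    pathogenic; absent in controls -> moderate pathogenic; co-segregation
    across affected relatives -> supporting pathogenic; in-silico damaging ->
    supporting pathogenic; common in controls (af > ``benign_af``) ->
    stand-alone benign.  This is a declared simplification of per-criterion
    ACMG usage, which is not recoverable from annotation tables alone.
    """
    evidence: list[EvidenceCode] = []
    if context.known_lof_gene and variant.consequence in ("frameshift", "stopgain", "splicing"):
        evidence.append(acmg.pvs("PVS_lof_in_lof_gene"))
    if context.absent_in_controls:
        evidence.append(acmg.pm("PM_absent_in_controls"))
    if context.shared_in_pedigree:
        evidence.append(acmg.pp("PP_cosegregation"))
    if context.insilico_damaging == "damaging":
        evidence.append(acmg.pp("PP_insilico"))
    if variant.control_af is not None and variant.control_af > benign_af:
        evidence.append(acmg.ba("BA_common_in_controls"))
    return evidence


def classify(
    variant: AnnotatedVariant,
    context: EvidenceContext,
    benign_af: float = DEFAULT_BENIGN_AF,
) -> Verdict:
    """Assign evidence then combine into a five-tier verdict."""
    return combine_acmg(assign_evidence(variant, context, benign_af))


def build_candidate_set(
    pedigree: Pedigree,
    shared_ids: set[str],
    annotated: Sequence[AnnotatedVariant],
    af_max: float = DEFAULT_AF_MAX,
    germline_set: set[str] | None = None,
) -> CandidateSet:
    """Assemble the per-pedigree candidate table with provenance flags."""
    shared_annotated = [
        av for av in annotated if av.variant.variant_id in shared_ids
    ]
    kept, _ = filter_rare_nonsilent(shared_annotated, af_max)
    cand = CandidateSet(pedigree.pedigree_id)
    for av in kept:
        vid = av.variant.variant_id
        cand.variants.append(av)
        cand.flags[vid] = CandidateFlags(
            shared=True,
            rare=True,
            non_silent=True,
            cohort_cooccurring=(
                cohort_cooccurrence(vid, germline_set)
                if germline_set is not None
                else False
            ),
        )
    return cand
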