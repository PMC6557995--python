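"""Allele-count algebra over population cohorts.

Covers the three cohort-level steps of the analysis: deriving a
cancer-germline variant set by subtracting a complement release from its
superset (ExAC minus ExAC-non-TCGA in the original study), deriving
cancer-cohort counts by cohort subtraction (general minus non-cancer), and
Fisher exact burden testing of a gene's aggregate allele counts between two
cohorts.

The Fisher test is computed with exact integer hypergeometric weights: for a
2x2 table with row sums r1, r2 and first-column sum c1, the table with
``a = k`` has probability proportional to ``C(r1, k) * C(r2, c1 - k)``.  The
standard two-sided p-value is the total weight of tables no more probable
than the observed one, divided by ``C(r1 + r2, c1)`` — an exact rational,
converted to float only at the end, so ties are resolved exactly.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

import pandas as pd
from statsmodels.stats.multitest import multipletests

from .errors import DataError

logger = logging.getLogger(__name__)

COHORT_COLUMNS = ["variant_id", "cohort", "AC", "AN", "filter_status"]


@dataclass(frozen=True)
class CohortCounts:
    """AC/AN for one variant in one named cohort."""

    variant_id: str
    cohort: str
    ac: int
    an: int
    filter_status: str = "pass"

    def __post_init__(self) -> None:
        if not (0 <= self.ac <= self.an):
            raise DataError(
                f"{self.variant_id}/{self.cohort}: need 0 <= AC <= AN, "
                f"got AC={self.ac}, AN={self.an}"
            )


@dataclass(frozen=True)
class BurdenResult:
    gene: str
    table: tuple[int, int, int, int]  # (carriers_a, rest_a, carriers_b, rest_b)
    odds_ratio: float
    p_two_sided: float
    n_variants: int = 0


def subtract_counts(
    minuend: CohortCounts,
    subtrahend: CohortCounts,
    derived_name: str | None = None,
    clamp: bool = False,
) -> CohortCounts:
    """Elementwise AC/AN subtraction deriving a subset cohort.

    A negative difference is a data inconsistency naming the variant;
    ``clamp=True`` converts it to 0 with a logged warning instead (real
    releases do contain subset inconsistencies).
    """
    if minuend.variant_id != subtrahend.variant_id:
        raise DataError(
            f"subtracting counts of different variants: "
            f"{minuend.variant_id} vs {subtrahend.variant_id}"
        )
    ac = minuend.ac - subtrahend.ac
    an = minuend.an - subtrahend.an
    if ac < 0 or an < 0:
        if not clamp:
            raise DataError(
                f"negative cohort subtraction for {minuend.variant_id}: "
                f"AC {minuend.ac}-{subtrahend.ac}, AN {minuend.an}-{subtrahend.an}"
            )
        logger.warning("clamping negative subtraction for %s", minuend.variant_id)
        ac, an = max(ac, 0), max(an, 0)
    ac = min(ac, an) if clamp else ac
    name = derived_name or f"{minuend.cohort}-minus-{subtrahend.cohort}"
    return CohortCounts(minuend.variant_id, name, ac, an, minuend.filter_status)


def subtract_tables(
    minuend: pd.DataFrame,
    subtrahend: pd.DataFrame,
    derived_name: str,
    clamp: bool = False,
) -> pd.DataFrame:
    """Row-wise :func:`subtract_counts` over cohort tables keyed by variant id.

    Variants absent from the subtrahend are treated as AC = AN = 0 there.
    """
    sub = subtrahend.set_index("variant_id")
    rows = []
    for row in minuend.itertuples(index=False):
        if row.variant_id in sub.index:
            s = sub.loc[row.variant_id]
            s_counts = CohortCounts(
                row.variant_id, str(s["cohort"]), int(s["AC"]), int(s["AN"]),
                str(s.get("filter_status", "pass")),
            )
        else:
            s_counts = CohortCounts(row.variant_id, "absent", 0, 0)
        m_counts = CohortCounts(
            row.variant_id, str(row.cohort), int(row.AC), int(row.AN),
            str(getattr(row, "filter_status", "pass")),
        )
        d = subtract_counts(m_counts, s_counts, derived_name, clamp=clamp)
        rows.append((d.variant_id, d.cohort, d.ac, d.an, d.filter_status))
    return pd.DataFrame(rows, columns=COHORT_COLUMNS)


def derive_germline_subset(
    full_table: pd.DataFrame, complement_table: pd.DataFrame, clamp: bool = False
) -> set[str]:
    """Variant ids private to the subset cohort: derived AC > 0 after
    subtracting the complement release from the full release."""
    derived = subtract_tables(full_table, complement_table, "derived_subset", clamp)
    return set(derived.loc[derived["AC"] > 0, "variant_id"])


def quality_filter(rows: pd.DataFrame) -> pd.DataFrame:
    """Keep variants whose filter status is 'pass' in every source present.

    Tables may carry one row per (variant, cohort, source); a variant with a
    non-pass status in any of its sources is dropped entirely.  A variant seen
    in a single source only needs that one pass.
    """
    bad = set(rows.loc[rows["filter_status"] != "pass", "variant_id"])
    return rows[~rows["variant_id"].isin(bad)].reset_index(drop=True)


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Two-sided Fisher exact test on the table [[a, b], [c, d]].

    Returns ``(odds_ratio, p)``.  The p-value sums the hypergeometric
    probabilities of all same-margin tables with probability <= observed,
    computed in exact integer/rational arithmetic.  OR = ad/bc, +inf when
    bc = 0 with ad > 0, NaN when both products vanish.  A table with an empty
    margin carries no information: p = 1.
    """
    for name, v in zip("abcd", (a, b, c, d)):
        if v < 0 or int(v) != v:
            raise DataError(f"fisher cell {name} must be a non-negative integer")
    a, b, c, d = int(a), int(b), int(c), int(d)
    if a * d > 0 and b * c == 0:
        odds = math.inf
    elif a * d == 0 and b * c == 0:
        odds = math.nan
    else:
        odds = (a * d) / (b * c)
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    if min(r1, r2, c1, c2) == 0:
        return odds, 1.0
    kmin, kmax = max(0, c1 - r2), min(r1, c1)
    if kmax - kmin < 256:
        weights = [
            math.comb(r1, k) * math.comb(r2, c1 - k) for k in range(kmin, kmax + 1)
        ]
        w_obs = weights[a - kmin]
        num = sum(w for w in weights if w <= w_obs)
        return odds, float(Fraction(num, sum(weights)))
    # very wide support: exact big-integer enumeration is needlessly slow, so
    # sum hypergeometric log-probabilities instead (stable to ~1e-13)
    import numpy as np
    from scipy.special import gammaln
    from scipy.special import logsumexp

    k = np.arange(kmin, kmax + 1)
    logw = (
        gammaln(r1 + 1) - gammaln(k + 1) - gammaln(r1 - k + 1)
        + gammaln(r2 + 1) - gammaln(c1 - k + 1) - gammaln(r2 - c1 + k + 1)
    )
    log_obs = logw[a - kmin]
    mask = logw <= log_obs + 1e-12
    p = float(np.exp(logsumexp(logw[mask]) - logsumexp(logw)))
    return odds, min(p, 1.0)


def gene_burden(
    gene: str,
    variant_ids: Iterable[str],
    cohort_a: pd.DataFrame,
    cohort_b: pd.DataFrame,
) -> BurdenResult:
    """Fisher burden test of one gene's aggregate allele counts.

    Carriers per cohort = sum of AC over the gene's variants; trials = the
    cohort's maximum AN over those variants (call-rate conservative: using
    the max avoids double-counting chromosomes across sites).  An empty gene
    yields the null result p = 1.
    """
    ids = set(variant_ids)
    sub_a = cohort_a[cohort_a["variant_id"].isin(ids)]
    sub_b = cohort_b[cohort_b["variant_id"].isin(ids)]
    if sub_a.empty and sub_b.empty:
        return BurdenResult(gene, (0, 0, 0, 0), math.nan, 1.0, 0)
    ca = int(sub_a["AC"].sum())
    cb = int(sub_b["AC"].sum())
    na = int(sub_a["AN"].max()) if not sub_a.empty else 0
    nb = int(sub_b["AN"].max()) if not sub_b.empty else 0
    if ca > na or cb > nb:
        raise DataError(f"gene {gene}: carriers exceed trials ({ca}/{na}, {cb}/{nb})")
    odds, p = fisher_exact_2x2(ca, na - ca, cb, nb - cb)
    return BurdenResult(gene, (ca, na - ca, cb, nb - cb), odds, p, len(ids))


def burden_scan(
    gene_to_ids: Mapping[str, Sequence[str]],
    cohort_a: pd.DataFrame,
    cohort_b: pd.DataFrame,
) -> pd.DataFrame:
    """Per-gene burden tests with Benjamini-Hochberg FDR across genes.

    Returns a frame sorted by raw p with columns gene, a, b, c, d, OR, p, q.
    """
    results = [
        gene_burden(gene, ids, cohort_a, cohort_b)
        for gene, ids in sorted(gene_to_ids.items())
    ]
    df = pd.DataFrame(
        {
            "gene": [r.gene for r in results],
            "a": [r.table[0] for r in results],
            "b": [r.table[1] for r in results],
            "c": [r.table[2] for r in results],
            "d": [r.table[3] for r in results],
            "OR": [r.odds_ratio for r in results],
            "p": [r.p_two_sided for r in results],
        }
    )
    if len(df):
        df["q"] = multipletests(df["p"], method="fdr_bh")[1]
    else:
        df["q"] = []
    return df.sort_values("p", kind="stable").reset_index(drop=True)


def read_cohort_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"variant_id": str, "cohort": str})
    missing = set(COHORT_COLUMNS) - set(df.columns)
    if missing:
        raise DataError(f"{path}: cohort table lacks columns {sorted(missing)}")
    df["AC"] = df["AC"].astype(int)
    df["AN"] = df["AN"].astype(int)
    return df


def write_cohort_table(path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False, columns=COHORT_COLUMNS)
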