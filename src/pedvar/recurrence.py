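"""Somatic recurrence statistics on a protein mutation spectrum.

Three analyses over per-residue somatic missense counts:

* a windowed binomial hotspot scan — for each residue, the missense count in
  a fixed-halfwidth window is tested against Binomial(N_missense, |window|/L)
  with Bonferroni control over the L tests;
* the 20/20 oncogene / tumor-suppressor heuristic — a gene looks
  oncogene-like when more than 20% of its missense mutations sit at recurrent
  residues, and TSG-like when more than 20% of its non-silent mutations are
  truncating (strictly "more than": 0.20 exactly is neither);
* per-cancer-type binomial enrichment against a pooled (or supplied)
  background mutation rate, BH-adjusted across types.

Fusion events are parsed and counted but excluded from all three statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import DataError
from .variant_model import TRUNCATING

SOMATIC_COLUMNS = [
    "gene",
    "protein_pos",
    "aa_ref",
    "aa_alt",
    "consequence",
    "cancer_type",
    "sample_id",
]


@dataclass(frozen=True)
class MutationSpectrum:
    """Per-residue somatic missense counts plus truncating totals for one
    gene/protein."""

    gene: str
    protein_length: int
    missense_counts: np.ndarray  # length L, index 0 = residue 1
    truncating_count: int = 0
    per_cancer_type: Mapping[str, tuple[int, int]] = field(default_factory=dict)
    fusion_count: int = 0

    def __post_init__(self) -> None:
        counts = np.asarray(self.missense_counts, dtype=np.int64)
        object.__setattr__(self, "missense_counts", counts)
        if self.protein_length < 1:
            raise DataError("protein_length must be >= 1")
        if counts.shape != (self.protein_length,):
            raise DataError("missense_counts must have one entry per residue")
        if (counts < 0).any() or self.truncating_count < 0:
            raise DataError("mutation counts must be non-negative")
        for ctype, (mutated, total) in self.per_cancer_type.items():
            if not (0 <= mutated <= total):
                raise DataError(f"cancer type {ctype}: mutated > total samples")

    @property
    def n_missense(self) -> int:
        return int(self.missense_counts.sum())

    @property
    def total_nonsilent(self) -> int:
        return self.n_missense + self.truncating_count


def binom_upper_tail(x: int, n: int, p: float) -> float:
    """P(X >= x) for X ~ Binomial(n, p) — the tail used by both the hotspot
    scan and the cancer-type enrichment test."""
    if x <= 0:
        return 1.0
    if x > n:
        return 0.0
    return float(stats.binom.sf(x - 1, n, p))


@dataclass(frozen=True)
class HotspotResult:
    residue: int
    window: tuple[int, int]
    count_in_window: int
    p_raw: float
    p_adjusted: float
    is_hotspot: bool


def spectrum_from_table(
    table: pd.DataFrame,
    gene: str,
    protein_length: int,
    cancer_type_totals: Mapping[str, int] | None = None,
) -> MutationSpectrum:
    """Build a spectrum from a minimal MAF-like somatic table.

    Missense rows contribute per-residue counts; frameshift/stopgain/splicing
    rows the truncating total; rows with consequence ``fusion`` are tallied
    separately and excluded from the statistics.  Per-type sample totals, when
    supplied, yield the (mutated samples, total samples) map used by the
    enrichment test.
    """
    sub = table[table["gene"] == gene]
    counts = np.zeros(protein_length, dtype=np.int64)
    truncating = 0
    fusions = 0
    for row in sub.itertuples(index=False):
        cons = str(row.consequence)
        if cons == "fusion":
            fusions += 1
            continue
        if cons == "missense":
            pos = int(row.protein_pos)
            if not (1 <= pos <= protein_length):
                raise DataError(
                    f"{gene}: protein_pos {pos} outside [1, {protein_length}]"
                )
            counts[pos - 1] += 1
        elif cons in TRUNCATING:
            truncating += 1
    per_type: dict[str, tuple[int, int]] = {}
    if cancer_type_totals is not None:
        nonfusion = sub[sub["consequence"] != "fusion"]
        for ctype, total in cancer_type_totals.items():
            mutated = nonfusion.loc[
                nonfusion["cancer_type"] == ctype, "sample_id"
            ].nunique()
            per_type[ctype] = (int(mutated), int(total))
    return MutationSpectrum(
        gene, protein_length, counts, truncating, per_type, fusions
    )


def hotspot_scan(
    spectrum: MutationSpectrum, window_halfwidth: int = 2, alpha: float = 0.05
) -> list[HotspotResult]:
    """Fixed-halfwidth windowed binomial scan for mutation hotspots.

    For residue i the window is [i-w, i+w] clipped to [1, L]; its missense
    count X is tested upper-tail against Binomial(N, |window|/L) where N is
    the gene's total missense count.  Bonferroni adjustment multiplies by L.
    """
    if window_halfwidth < 0:
        raise DataError("window_halfwidth must be >= 0")
    L = spectrum.protein_length
    n = spectrum.n_missense
    cum = np.concatenate([[0], np.cumsum(spectrum.missense_counts)])
    results = []
    for residue in range(1, L + 1):
        lo = max(1, residue - window_halfwidth)
        hi = min(L, residue + window_halfwidth)
        count = int(cum[hi] - cum[lo - 1])
        width = hi - lo + 1
        p_raw = 1.0 if n == 0 else binom_upper_tail(count, n, width / L)
        p_adj = min(1.0, L * p_raw)
        results.append(
            HotspotResult(residue, (lo, hi), count, p_raw, p_adj, p_adj < alpha)
        )
    return results


def classify_20_20(
    spectrum: MutationSpectrum,
    recurrence_min: int = 2,
    threshold: float = 0.20,
) -> tuple[str, dict[str, float]]:
    """20/20-rule gene classification.

    Oncogene fraction: missense mutations at recurrent residues (count >=
    ``recurrence_min``) over all missense mutations.  TSG fraction:
    truncating mutations over all non-silent mutations.  Labels require the
    fraction to strictly exceed ``threshold``.
    """
    if spectrum.total_nonsilent == 0:
        raise DataError("cannot classify a spectrum with zero non-silent mutations")
    counts = spectrum.missense_counts
    recurrent_mass = int(counts[counts >= recurrence_min].sum())
    onc_frac = recurrent_mass / spectrum.n_missense if spectrum.n_missense else 0.0
    tsg_frac = spectrum.truncating_count / spectrum.total_nonsilent
    onc = onc_frac > threshold
    tsg = tsg_frac > threshold
    label = {
        (True, True): "both",
        (True, False): "oncogene-like",
        (False, True): "tsg-like",
        (False, False): "neither",
    }[(onc, tsg)]
    return label, {"oncogene_fraction": onc_frac, "tsg_fraction": tsg_frac}


def cancer_type_enrichment(
    spectrum: MutationSpectrum, background_rate: float | None = None
) -> pd.DataFrame:
    """Upper-tail binomial enrichment of mutated-sample counts per cancer
    type, BH-adjusted across types.

    The background rate defaults to the pooled mutated fraction across all
    types (each type is then asked whether it exceeds the gene's overall
    mutation rate).
    """
    items = sorted(spectrum.per_cancer_type.items())
    if not items:
        return pd.DataFrame(
            columns=["cancer_type", "mutated", "total", "rate", "p_raw", "p_adjusted"]
        )
    mutated = np.array([m for _, (m, t) in items])
    totals = np.array([t for _, (m, t) in items])
    if (totals <= 0).any():
        raise DataError("every cancer type needs a positive sample total")
    if background_rate is None:
        background_rate = float(mutated.sum() / totals.sum())
    p_raw = np.array(
        [
            binom_upper_tail(int(m), int(t), background_rate)
            for m, t in zip(mutated, totals)
        ]
    )
    p_adj = multipletests(p_raw, method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "cancer_type": [c for c, _ in items],
            "mutated": mutated,
            "total": totals,
            "rate": mutated / totals,
            "p_raw": p_raw,
            "p_adjusted": p_adj,
        }
    )


def read_somatic_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, na_values=["."], keep_default_na=False)
    missing = set(SOMATIC_COLUMNS) - set(df.columns)
    if missing:
        raise DataError(f"{path}: somatic table lacks columns {sorted(missing)}")
    return df


def write_somatic_table(path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep=".", columns=SOMATIC_COLUMNS)
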