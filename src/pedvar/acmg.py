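"""ACMG-AMP style evidence combination.

The engine has two deliberately separate halves:

* :func:`combine` — the published five-tier combining table, encoded
  faithfully and exhaustively tested.  Evidence strengths are counted per
  direction and matched against the pathogenic / likely-pathogenic / benign /
  likely-benign combinations; anything unmatched, and any conflict (at least
  one fired rule in each direction), is uncertain significance.
* evidence *assignment* (in :mod:`pedvar.cosegregation`) — a documented,
  config-driven simplification mapping pipeline context onto generic codes.

Strength labels: ``stand_alone`` (benign only, BA-class), ``very_strong``
(pathogenic only, PVS-class), ``strong`` (PS/BS), ``moderate`` (PM),
``supporting`` (PP/BP).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable

from .errors import DataError

PATHOGENIC = "pathogenic"
BENIGN = "benign"

STRENGTHS = ("stand_alone", "very_strong", "strong", "moderate", "supporting")

TIERS = (
    "benign",
    "likely_benign",
    "uncertain_significance",
    "likely_pathogenic",
    "pathogenic",
)


@dataclass(frozen=True)
class EvidenceCode:
    code: str
    direction: str
    strength: str

    def __post_init__(self) -> None:
        if self.direction not in (PATHOGENIC, BENIGN):
            raise DataError(f"unknown direction {self.direction!r}")
        if self.strength not in STRENGTHS:
            raise DataError(f"unknown strength {self.strength!r}")
        if self.strength == "stand_alone" and self.direction != BENIGN:
            raise DataError("stand-alone strength is benign-only (BA-class)")
        if self.strength == "very_strong" and self.direction != PATHOGENIC:
            raise DataError("very-strong strength is pathogenic-only (PVS-class)")


# Convenience constructors for the generic code classes.
def pvs(code: str = "PVS") -> EvidenceCode:
    return EvidenceCode(code, PATHOGENIC, "very_strong")


def ps(code: str = "PS") -> EvidenceCode:
    return EvidenceCode(code, PATHOGENIC, "strong")


def pm(code: str = "PM") -> EvidenceCode:
    return EvidenceCode(code, PATHOGENIC, "moderate")


def pp(code: str = "PP") -> EvidenceCode:
    return EvidenceCode(code, PATHOGENIC, "supporting")


def ba(code: str = "BA") -> EvidenceCode:
    return EvidenceCode(code, BENIGN, "stand_alone")


def bs(code: str = "BS") -> EvidenceCode:
    return EvidenceCode(code, BENIGN, "strong")


def bp(code: str = "BP") -> EvidenceCode:
    return EvidenceCode(code, BENIGN, "supporting")


@dataclass(frozen=True)
class Verdict:
    tier: str
    triggered_rule: str

    def __post_init__(self) -> None:
        if self.tier not in TIERS:
            raise DataError(f"unknown tier {self.tier!r}")


def _counts(evidence: Iterable[EvidenceCode]) -> tuple[Counter, Counter]:
    path: Counter = Counter()
    ben: Counter = Counter()
    for ev in evidence:
        (path if ev.direction == PATHOGENIC else ben)[ev.strength] += 1
    return path, ben


def combine(evidence: Iterable[EvidenceCode]) -> Verdict:
    """Combine evidence codes into a five-tier verdict.

    Pathogenic:
      Ia  1 very-strong AND (>=1 strong OR >=2 moderate OR 1 moderate +
          1 supporting OR >=2 supporting)
      II  >=2 strong
      III 1 strong AND (>=3 moderate OR 2 moderate + >=2 supporting OR
          1 moderate + >=4 supporting)
    Likely pathogenic:
      I   1 very-strong + 1 moderate
      II  1 strong + 1-2 moderate
      III 1 strong + >=2 supporting
      IV  >=3 moderate
      V   2 moderate + >=2 supporting
      VI  1 moderate + >=4 supporting
    Benign: 1 stand-alone, or >=2 strong benign.
    Likely benign: 1 strong benign + 1 supporting benign, or >=2 supporting.

    Conflicts (>=1 fired rule in each direction) and unmatched combinations
    return uncertain significance.  The triggered rule name is reported.
    """
    evidence = list(evidence)
    path, ben = _counts(evidence)
    if path and ben:
        return Verdict("uncertain_significance", "conflicting_evidence")
    if ben:
        if ben["stand_alone"] >= 1:
            return Verdict("benign", "BA_stand_alone")
        if ben["strong"] >= 2:
            return Verdict("benign", "BS>=2")
        if ben["strong"] >= 1 and ben["supporting"] >= 1:
            return Verdict("likely_benign", "BS+BP")
        if ben["supporting"] >= 2:
            return Verdict("likely_benign", "BP>=2")
        return Verdict("uncertain_significance", "insufficient_benign")
    if path:
        vs, st, mo, su = (
            path["very_strong"],
            path["strong"],
            path["moderate"],
            path["supporting"],
        )
        if vs >= 1 and (st >= 1 or mo >= 2 or (mo >= 1 and su >= 1) or su >= 2):
            return Verdict("pathogenic", "PVS+support")
        if st >= 2:
            return Verdict("pathogenic", "PS>=2")
        if st >= 1 and (mo >= 3 or (mo >= 2 and su >= 2) or (mo >= 1 and su >= 4)):
            return Verdict("pathogenic", "PS+moderates")
        if vs >= 1 and mo >= 1:
            return Verdict("likely_pathogenic", "PVS+PM")
        if st >= 1 and mo >= 1:
            return Verdict("likely_pathogenic", "PS+PM")
        if st >= 1 and su >= 2:
            return Verdict("likely_pathogenic", "PS+PP>=2")
        if mo >= 3:
            return Verdict("likely_pathogenic", "PM>=3")
        if mo >= 2 and su >= 2:
            return Verdict("likely_pathogenic", "PM2+PP>=2")
        if mo >= 1 and su >= 4:
            return Verdict("likely_pathogenic", "PM+PP>=4")
        return Verdict("uncertain_significance", "insufficient_pathogenic")
    return Verdict("uncertain_significance", "no_evidence")


def tier_rank(tier: str) -> int:
    """Ordinal position of a tier on the benign→pathogenic axis."""
    return TIERS.index(tier)
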