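"""PSSM substitution-tolerance scoring.

A PSI-BLAST position-specific scoring matrix assigns each protein position a
20-vector of integer log-odds scores.  The tolerance statistic for a missense
change is the score difference

    dS = S(mutant residue) - S(wild-type residue)

at that position; negative dS means the profile tolerates the mutant less
than the wild type.  Observed mutation sets are compared against a Monte
Carlo null of random mutation sets (uniform position, uniform mutant residue
over the 19 non-wild-type letters) via a lower-tail add-one empirical
p-value.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import DataError, ParseError

#: PSI-BLAST column order for the 20 canonical amino acids.
ALPHABET = "ARNDCQEGHILKMFPSTWYV"
_AA_INDEX = {aa: i for i, aa in enumerate(ALPHABET)}

_HEADER = (
    "Last position-specific scoring matrix computed, weighted observed "
    "percentages rounded down, information per position, and relative "
    "weight of gapless real matches to pseudocounts"
)


@dataclass(frozen=True)
class PSSM:
    """Wild-type sequence plus an L x 20 integer log-odds matrix (1-based
    positions in the public API)."""

    wild_type: str
    scores: np.ndarray

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=np.int64)
        object.__setattr__(self, "scores", scores)
        if scores.ndim != 2 or scores.shape[1] != 20:
            raise DataError("PSSM scores must be an L x 20 matrix")
        if len(self.wild_type) != scores.shape[0]:
            raise DataError("wild-type length does not match matrix length")
        bad = set(self.wild_type) - set(ALPHABET)
        if bad:
            raise DataError(f"wild-type residues outside the 20-letter alphabet: {bad}")

    @property
    def length(self) -> int:
        return self.scores.shape[0]

    def score(self, position: int, residue: str) -> int:
        """Log-odds score of ``residue`` at 1-based ``position``."""
        self._check_position(position)
        if residue not in _AA_INDEX:
            raise DataError(f"residue {residue!r} not in the amino-acid alphabet")
        return int(self.scores[position - 1, _AA_INDEX[residue]])

    def _check_position(self, position: int) -> None:
        if not (1 <= position <= self.length):
            raise DataError(
                f"position {position} outside [1, {self.length}] (1-based)"
            )


@dataclass(frozen=True)
class SubstitutionScore:
    position: int
    wt: str
    mut: str
    delta_s: int


@dataclass(frozen=True)
class NullDistribution:
    set_size: int
    n_sets: int
    samples: np.ndarray
    seed: int


def delta_s(pssm: PSSM, position: int, wt: str, mut: str) -> SubstitutionScore:
    """Score difference of a substitution relative to the wild type.

    ``wt`` must match the PSSM wild-type residue at that position — a
    mismatch means the mutation list and the matrix describe different
    proteins, which is reported rather than silently scored.
    """
    pssm._check_position(position)
    if pssm.wild_type[position - 1] != wt:
        raise DataError(
            f"wild-type mismatch at position {position}: PSSM has "
            f"{pssm.wild_type[position - 1]!r}, mutation claims {wt!r}"
        )
    return SubstitutionScore(
        position, wt, mut, pssm.score(position, mut) - pssm.score(position, wt)
    )


def mean_delta_s(pssm: PSSM, mutations: Sequence[tuple[int, str, str]]) -> float:
    """Arithmetic mean dS over a set of (position, wt, mut) substitutions."""
    if not mutations:
        raise DataError("mean over an empty mutation set is undefined")
    return float(
        np.mean([delta_s(pssm, pos, wt, mut).delta_s for pos, wt, mut in mutations])
    )


def expected_mean_delta_s(pssm: PSSM) -> float:
    """Exact expectation of dS for one random mutation under the null
    (uniform position, uniform over the 19 non-wild-type residues):
    sum over positions and non-wild-type residues of dS / (19 L)."""
    wt_idx = np.array([_AA_INDEX[aa] for aa in pssm.wild_type])
    wt_scores = pssm.scores[np.arange(pssm.length), wt_idx]
    row_sums = pssm.scores.sum(axis=1)
    # per position: sum over a != wt of (S_a - S_wt) = rowsum - 20 * S_wt
    return float(np.sum(row_sums - 20 * wt_scores) / (19 * pssm.length))


def sample_null(pssm: PSSM, set_size: int, n_sets: int, seed: int) -> NullDistribution:
    """Monte Carlo null of mean dS over random mutation sets.

    Each set draws ``set_size`` mutations independently with replacement:
    position uniform on 1..L, then mutant residue uniform over the 19
    letters differing from the wild type at that position.
    """
    if pssm.length == 0:
        raise DataError("cannot sample from a zero-length PSSM")
    if set_size < 1 or n_sets < 1:
        raise DataError("set_size and n_sets must be >= 1")
    rng = np.random.default_rng(seed)
    wt_idx = np.array([_AA_INDEX[aa] for aa in pssm.wild_type])
    positions = rng.integers(0, pssm.length, size=(n_sets, set_size))
    alt = rng.integers(0, 19, size=(n_sets, set_size))
    mut_idx = alt + (alt >= wt_idx[positions])  # skip the wild-type letter
    ds = pssm.scores[positions, mut_idx] - pssm.scores[positions, wt_idx[positions]]
    return NullDistribution(set_size, n_sets, ds.mean(axis=1), seed)


def empirical_p(observed_mean: float, null: NullDistribution) -> float:
    """Lower-tail add-one empirical p: (1 + #{samples <= observed}) / (n + 1).

    The pseudo-count keeps the estimate away from an impossible zero.
    """
    if null.n_sets < 1:
        raise DataError("empty null distribution")
    return (1 + int(np.sum(null.samples <= observed_mean))) / (null.n_sets + 1)


# ---------------------------------------------------------------------------
# PSI-BLAST ASCII serialization


def parse_pssm_ascii(text: str) -> PSSM:
    """Parse the ``-out_ascii_pssm`` dialect of PSI-BLAST.

    Captures the first (log-odds) 20-column block of each position row;
    the weighted-percentage block and trailing statistics are ignored.
    """
    wild_type: list[str] = []
    rows: list[list[int]] = []
    in_body = False
    for lineno, line in enumerate(text.splitlines(), start=1):
        tokens = line.split()
        if not in_body:
            if tokens[:2] == list(ALPHABET[:2]) and tokens[: 20] == list(ALPHABET):
                in_body = True
            continue
        if not tokens:
            if rows:
                break
            continue
        if not tokens[0].isdigit():
            break  # trailing K/Lambda statistics
        if len(tokens) < 22:
            raise ParseError(f"line {lineno}: truncated PSSM row ({len(tokens)} fields)")
        pos, residue = int(tokens[0]), tokens[1]
        if pos != len(rows) + 1:
            raise ParseError(f"line {lineno}: expected position {len(rows) + 1}, got {pos}")
        if residue not in _AA_INDEX:
            raise ParseError(f"line {lineno}: unknown residue {residue!r}")
        try:
            scores = [int(tok) for tok in tokens[2:22]]
        except ValueError as exc:
            raise ParseError(f"line {lineno}: non-integer score ({exc})") from exc
        wild_type.append(residue)
        rows.append(scores)
    if not rows:
        raise ParseError("no PSSM body found (missing alphabet header line?)")
    return PSSM("".join(wild_type), np.array(rows, dtype=np.int64))


def write_pssm_ascii(pssm: PSSM) -> str:
    """Serialize in the PSI-BLAST ASCII dialect (log-odds block, a dummy
    percentage block, and trailing statistics), round-trippable through
    :func:`parse_pssm_ascii`."""
    lines = ["", _HEADER]
    header = "            " + "  ".join(ALPHABET) + "   " + "  ".join(ALPHABET)
    lines.append(header)
    for i in range(pssm.length):
        cells = "".join(f"{int(v):4d}" for v in pssm.scores[i])
        pct = "".join(f"{0:4d}" for _ in range(20))
        lines.append(f"{i + 1:5d} {pssm.wild_type[i]} {cells} {pct}  0.00 0.00")
    lines.append("")
    lines.append("                      K         Lambda")
    lines.append("Standard Ungapped    0.1337     0.3176")
    lines.append("")
    return "\n".join(lines) + "\n"


def read_pssm(path) -> PSSM:
    with open(path, "rt", encoding="utf-8") as fh:
        return parse_pssm_ascii(fh.read())


def write_pssm(path, pssm: PSSM) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write(write_pssm_ascii(pssm))


def parse_hgvs_p(hgvs_p: str) -> tuple[int, str, str]:
    """Parse a simple one-letter missense HGVS protein string like ``p.D73H``
    into (position, wt, mut)."""
    body = hgvs_p[2:] if hgvs_p.startswith("p.") else hgvs_p
    if len(body) < 3 or body[0] not in _AA_INDEX or body[-1] not in _AA_INDEX:
        raise ParseError(f"cannot parse missense HGVS.p {hgvs_p!r}")
    try:
        pos = int(body[1:-1])
    except ValueError as exc:
        raise ParseError(f"cannot parse missense HGVS.p {hgvs_p!r}") from exc
    return pos, body[0], body[-1]
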