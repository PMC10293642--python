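"""Codon-pair counting, length-adjusted pair scores, and context analysis.

Pairs are overlapping adjacent codons (i, i+1) within each transcript,
with the stop codon participating as the 3′ member of the final pair, so a
transcript of L codons contributes L − 1 pairs. The length-adjusted pair
score expresses a pair count as a percentage of the gene's total codon
count (pairs + transcripts), mirroring how published per-gene pair tables
adjust for transcript length. Context preference is
measured by Pearson adjusted residuals on the 64×64 pair contingency
table: a pair with residual above +5 is in "good" context (the 3′ codon
follows the 5′ codon more often than its marginal frequencies predict),
below −5 "bad"; values in [−5, +5] are not significant.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .genetic_code import CODONS
from .sequence_io import CdsRecord, split_codons

CONTEXT_BAND = 5.0

_IDX = {c: i for i, c in enumerate(CODONS)}


@dataclass(frozen=True)
class PairTable:
    """64×64 observed codon-pair counts (row = 5′ codon, column = 3′ codon).

    ``n_sequences`` records how many transcripts were pooled, so the total
    codon count (pairs + transcripts) is recoverable for length-adjusted
    scoring.
    """

    observed: np.ndarray  # (64, 64) float array of counts
    n_sequences: int = 0

    def __post_init__(self) -> None:
        if self.observed.shape != (64, 64):
            raise ValueError("pair table must be 64×64")

    @property
    def total(self) -> int:
        return int(self.observed.sum())

    @property
    def total_codons(self) -> int:
        """Total codons of the pooled transcripts: N pairs + n transcripts."""
        return self.total + self.n_sequences

    @property
    def score_denominator(self) -> int:
        # codon total when provenance is known, else the raw pair total
        return self.total_codons if self.n_sequences else self.total

    def count(self, c5: str, c3: str) -> int:
        return int(self.observed[_IDX[c5], _IDX[c3]])

    def expected(self) -> np.ndarray:
        """Independence expectation E = rowsum × colsum / N."""
        n = self.observed.sum()
        if n == 0:
            raise ValueError("empty pair table")
        return np.outer(self.observed.sum(axis=1), self.observed.sum(axis=0)) / n

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.observed, index=CODONS, columns=CODONS)


def count_pairs(records: Sequence[CdsRecord]) -> PairTable:
    """Count overlapping codon pairs pooled over a gene's transcripts.

    N = Σ_transcripts (codon count − 1); the stop codon is included as the
    3′ codon of each transcript's last pair.
    """
    obs = np.zeros((64, 64), dtype=float)
    for rec in records:
        codons = split_codons(rec)
        for a, b in zip(codons, codons[1:]):
            obs[_IDX[a], _IDX[b]] += 1
    return PairTable(observed=obs, n_sequences=len(records))


def adjusted_pair_score(count: int, total: int) -> float:
    """Length-adjusted pair score: 100 × count / total, to 2 decimals.

    ``total`` is the pooled codon count of the gene (pairs + transcripts);
    per-gene reporting passes :attr:`PairTable.score_denominator`.
    """
    if total <= 0:
        raise ValueError("total count must be positive")
    if count > total:
        raise ValueError("pair count exceeds total")
    return round(100.0 * count / total, 2)


def top_pairs(table: PairTable, k: int = 15) -> pd.DataFrame:
    """The k most frequent codon pairs with adjusted scores.

    Ordered by count descending; equal counts are broken by the pair
    string in descending lexicographic order (matches how equal-count
    blocks are conventionally listed).
    """
    n = table.score_denominator
    entries = []
    nz_rows, nz_cols = np.nonzero(table.observed)
    for i, j in zip(nz_rows, nz_cols):
        c = int(table.observed[i, j])
        pair = f"{CODONS[i]}-{CODONS[j]}"
        entries.append((c, pair))
    entries.sort(key=lambda e: (-e[0], _descending_key(e[1])))
    entries = entries[:k]
    return pd.DataFrame(
        {
            "pair": [p for _, p in entries],
            "codon5": [p.split("-")[0] for _, p in entries],
            "codon3": [p.split("-")[1] for _, p in entries],
            "count": [c for c, _ in entries],
            "adjusted_score": [adjusted_pair_score(c, n) for c, _ in entries],
        }
    )


def _descending_key(s: str) -> tuple[int, ...]:
    # sort() is ascending; invert character codes to sort strings descending
    return tuple(-ord(ch) for ch in s)


def context_residuals(table: PairTable) -> np.ndarray:
    """Pearson adjusted residuals of the pair contingency table.

    residual = (O − E) / sqrt(E (1 − rowsum/N)(1 − colsum/N)); cells whose
    margins vanish (E = 0) are NaN.
    """
    n = table.total
    if n == 0:
        raise ValueError("empty pair table")
    rows = table.observed.sum(axis=1)
    cols = table.observed.sum(axis=0)
    if (rows > 0).sum() < 2 or (cols > 0).sum() < 2:
        raise ValueError("degenerate pair table: a single populated row/column")
    expected = np.outer(rows, cols) / n
    with np.errstate(divide="ignore", invalid="ignore"):
        denom = np.sqrt(
            expected * np.outer(1.0 - rows / n, 1.0 - cols / n)
        )
        res = (table.observed - expected) / denom
    res[expected == 0] = np.nan
    return res


def classify_context(
    residuals: np.ndarray, band: float = CONTEXT_BAND
) -> np.ndarray:
    """Class map over the residual matrix.

    ``good`` above +band, ``bad`` below −band, ``not_significant`` within
    the band, ``absent`` where no data exist (NaN residual).
    """
    classes = np.full(residuals.shape, "not_significant", dtype=object)
    classes[residuals > band] = "good"
    classes[residuals < -band] = "bad"
    classes[np.isnan(residuals)] = "absent"
    return classes


def context_frame(table: PairTable, band: float = CONTEXT_BAND) -> pd.DataFrame:
    """Sparse long-format pair table: counts, scores, residuals, classes."""
    res = context_residuals(table)
    classes = classify_context(res, band=band)
    expected = table.expected()
    n = table.score_denominator
    rows = []
    for i, j in zip(*np.nonzero(table.observed)):
        rows.append(
            {
                "codon5": CODONS[i],
                "codon3": CODONS[j],
                "count": int(table.observed[i, j]),
                "adjusted_score": adjusted_pair_score(
                    int(table.observed[i, j]), n
                ),
                "expected": float(expected[i, j]),
                "residual": float(res[i, j]),
                "context": classes[i, j],
            }
        )
    return (
        pd.DataFrame(rows)
        .sort_values(["codon5", "codon3"])
        .reset_index(drop=True)
    )


def start_context(records: Sequence[CdsRecord]) -> pd.DataFrame:
    """Ranked frequencies of the codon immediately after the initiator ATG.

    Ties are broken by lexicographic codon order so the ranking is
    deterministic.
    """
    counts: dict[str, int] = {}
    for rec in records:
        codons = split_codons(rec)
        if len(codons) < 2:
            continue
        counts[codons[1]] = counts.get(codons[1], 0) + 1
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no transcript long enough for a second codon")
    items = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return pd.DataFrame(
        {
            "codon": [c for c, _ in items],
            "count": [n for _, n in items],
            "frequency": [n / total for _, n in items],
            "rank": range(1, len(items) + 1),
        }
    )
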