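"""Length-adjusted codon frequencies and rare-codon flagging.

A codon's frequency is adjusted for transcript length by expressing it as
a percentage of all codons in the transcript; the gene-level value is the
unweighted mean over the gene's transcripts. Codons whose gene-average
percentage falls strictly below 0.5% are flagged rare.
"""

from __future__ import annotations

import pandas as pd

from .genetic_code import CodonCountTable, GeneticCode, STANDARD_CODE
from .sequence_io import GeneSet

RARE_THRESHOLD = 0.5  # percent


def codon_percentages(
    counts: CodonCountTable,
    code: GeneticCode = STANDARD_CODE,
    include_stop: bool = True,
) -> pd.Series:
    """Percentage occurrence of every codon: 100 × count / total codons."""
    codons = list(code.sense_codons)
    if include_stop:
        codons += list(code.stop_codons)
    values = pd.Series({c: float(counts.get(c)) for c in codons})
    total = values.sum()
    if total == 0:
        raise ValueError("empty codon count table")
    return 100.0 * values / total


def adjusted_frequency_table(
    gene_set: GeneSet,
    code: GeneticCode = STANDARD_CODE,
    include_stop: bool = True,
    threshold: float = RARE_THRESHOLD,
) -> pd.DataFrame:
    """Per-gene mean codon percentages with rare flags and degeneracy class.

    One row per (gene, codon). The mean is over per-transcript percentages
    (not pooled counts), so duplicating a transcript's sequence does not
    change a gene's values. Degeneracy class is only assigned to the 59
    multi-family sense codons.
    """
    rows = []
    for gene in gene_set:
        per_transcript = pd.DataFrame(
            [
                codon_percentages(
                    CodonCountTable.from_records([rec]),
                    code=code,
                    include_stop=include_stop,
                )
                for rec in gene_set[gene]
            ]
        )
        means = per_transcript.mean(axis=0)
        for codon, mean_pct in means.items():
            if codon in code.codon_to_aa and code.degeneracy(codon) > 1:
                klass = code.degeneracy(codon)
            else:
                klass = 0  # singleton or stop: outside the degeneracy panels
            rows.append(
                {
                    "gene": gene,
                    "codon": codon,
                    "mean_pct": float(mean_pct),
                    "rare": bool(mean_pct < threshold),
                    "degeneracy": klass,
                }
            )
    return pd.DataFrame(rows)


def flag_rare(
    table: pd.DataFrame, threshold: float = RARE_THRESHOLD
) -> tuple[dict[str, set[str]], pd.Series]:
    """Rare codon set per gene plus a cross-gene summary.

    Returns ``(per_gene, summary)`` where ``summary[codon]`` counts the
    genes in which the codon is rare (strict ``< threshold``). Only sense
    codons of multi-codon families are considered.
    """
    sense = table[table["degeneracy"] > 0]
    per_gene: dict[str, set[str]] = {}
    for gene, sub in sense.groupby("gene", sort=True):
        per_gene[gene] = set(sub.loc[sub["mean_pct"] < threshold, "codon"])
    summary = (
        sense.assign(is_rare=sense["mean_pct"] < threshold)
        .groupby("codon", sort=True)["is_rare"]
        .sum()
        .astype(int)
    )
    return per_gene, summary


def group_by_degeneracy(
    table: pd.DataFrame, code: GeneticCode = STANDARD_CODE
) -> dict[int, pd.DataFrame]:
    """Split the frequency table into 2-/3-/4-/6-fold degeneracy panels.

    Codons of six-fold amino acids (Leu, Ser, Arg) all sit in the 6-fold
    panel regardless of their codon block. Panel sizes over the standard
    code: 18 / 3 / 20 / 18 codons.
    """
    panels: dict[int, pd.DataFrame] = {}
    for k in (2, 3, 4, 6):
        sub = table[table["degeneracy"] == k]
        panels[k] = sub.sort_values(["gene", "codon"]).reset_index(drop=True)
    return panels
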