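"""Nucleotide composition: overall, position-wise, and synonymous third position.

Overall and positional percentages are computed over the full deposited CDS
including the stop codon by default (transcript lengths in curated CDS
records include the stop). The synonymous third-position fractions (A3s,
C3s, G3s, T3s, GC3s) always exclude stops, Met and Trp and follow the
codonW convention: for each base, the fraction of eligible third positions
carrying the base among codon occurrences whose family can synonymously
place that base at the third position.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .genetic_code import BASES, GeneticCode, STANDARD_CODE
from .sequence_io import CdsRecord, GeneSet, split_codons


@dataclass(frozen=True)
class CompositionProfile:
    """Per-entity composition bundle (percentages except the s-fractions)."""

    overall: dict[str, float]      # %A, %C, %G, %T, %GC
    positional: dict[str, float]   # %A1..%T3, %GC1..%GC3
    synonymous: dict[str, float]   # A3s..T3s, GC3s as fractions in [0,1]

    def as_series(self) -> pd.Series:
        out: dict[str, float] = {}
        out.update({f"pct_{k}": v for k, v in self.overall.items()})
        out.update({f"pct_{k}": v for k, v in self.positional.items()})
        out.update(self.synonymous)
        return pd.Series(out)


def base_composition(
    record: CdsRecord, include_stop: bool = True
) -> dict[str, float]:
    """Overall %A/%C/%G/%T and %GC of one CDS.

    With ``include_stop=False`` the final codon is dropped from the span.
    """
    seq = record.sequence if include_stop else record.sequence[:-3]
    if not seq:
        raise ValueError("empty sequence span")
    n = len(seq)
    counts = Counter(seq)
    pct = {b: 100.0 * counts.get(b, 0) / n for b in BASES}
    pct["GC"] = pct["G"] + pct["C"]
    return pct


def positional_composition(
    codons: Sequence[str], include_stop: bool = True
) -> dict[str, float]:
    """Per-position base percentages (A1..T3) and GC1/GC2/GC3."""
    if not include_stop:
        codons = codons[:-1]
    if not codons:
        raise ValueError("no codons in span")
    n = len(codons)
    out: dict[str, float] = {}
    for pos in (0, 1, 2):
        counts = Counter(c[pos] for c in codons)
        for b in BASES:
            out[f"{b}{pos + 1}"] = 100.0 * counts.get(b, 0) / n
        out[f"GC{pos + 1}"] = out[f"G{pos + 1}"] + out[f"C{pos + 1}"]
    return out


def synonymous_third_composition(
    codons: Sequence[str], code: GeneticCode = STANDARD_CODE
) -> dict[str, float]:
    """A3s, C3s, G3s, T3s and GC3s over synonymously variable codons.

    Eligible codons are occurrences of multi-codon sense families (Met,
    Trp, stops excluded). For base X, the denominator counts occurrences
    whose family offers X at the third position; GC3s pools G and C.
    """
    eligible = [
        c
        for c in codons
        if c in code.codon_to_aa and code.degeneracy(c) > 1
    ]
    if not eligible:
        raise ValueError("no eligible codons for synonymous composition")
    out: dict[str, float] = {}
    # family → set of bases reachable at the third position
    fam_bases: dict[str, set[str]] = {
        aa: {c[2] for c in fam} for aa, fam in code.families.items()
    }
    for base in BASES:
        denom = sum(
            1 for c in eligible if base in fam_bases[code.codon_to_aa[c]]
        )
        num = sum(1 for c in eligible if c[2] == base)
        key = f"{base}3s"
        out[key] = num / denom if denom else float("nan")
    gc_denom = sum(
        1
        for c in eligible
        if fam_bases[code.codon_to_aa[c]] & {"G", "C"}
    )
    gc_num = sum(1 for c in eligible if c[2] in "GC")
    out["GC3s"] = gc_num / gc_denom if gc_denom else float("nan")
    return out


def composition_profile(
    record: CdsRecord,
    code: GeneticCode = STANDARD_CODE,
    include_stop: bool = True,
) -> CompositionProfile:
    codons = split_codons(record)
    return CompositionProfile(
        overall=base_composition(record, include_stop=include_stop),
        positional=positional_composition(codons, include_stop=include_stop),
        synonymous=synonymous_third_composition(codons, code=code),
    )


def composition_table(
    gene_set: GeneSet,
    code: GeneticCode = STANDARD_CODE,
    include_stop: bool = True,
) -> pd.DataFrame:
    """Per-transcript composition rows plus one unweighted-mean row per gene.

    Gene averages are means of per-transcript values, matching how per-gene
    statistics are reported for multi-isoform genes.
    """
    rows = []
    for gene in gene_set:
        per_gene = []
        for rec in gene_set[gene]:
            s = composition_profile(
                rec, code=code, include_stop=include_stop
            ).as_series()
            s["gene"] = gene
            s["entity"] = rec.transcript_id
            s["level"] = "transcript"
            s["length_nt"] = len(rec)
            rows.append(s)
            per_gene.append(s)
        mean = (
            pd.DataFrame(per_gene)
            .drop(columns=["gene", "entity", "level"])
            .mean(numeric_only=True)
        )
        mean["gene"] = gene
        mean["entity"] = gene
        mean["level"] = "gene_mean"
        rows.append(mean)
    df = pd.DataFrame(rows).reset_index(drop=True)
    lead = ["gene", "entity", "level", "length_nt"]
    return df[lead + [c for c in df.columns if c not in lead]]
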