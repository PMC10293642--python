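"""Standard genetic code, synonymous families, and codon counting.

The analyses in this package all reduce to bookkeeping over the 64 codons of
the standard nuclear code: 61 sense codons in 18 multi-codon synonymous
families (9 two-fold, 1 three-fold, 5 four-fold, 3 six-fold) plus the two
singletons Met (ATG) and Trp (TGG), and 3 stop codons (TAA/TAG/TGA).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
from Bio.Data import CodonTable

BASES = ("A", "C", "G", "T")

#: all 64 codons in lexicographic order — the canonical axis for count tables
CODONS = tuple(a + b + c for a in BASES for b in BASES for c in BASES)


def _standard_table() -> CodonTable.CodonTable:
    # NCBI table 1, DNA alphabet
    return CodonTable.unambiguous_dna_by_id[1]


@dataclass(frozen=True)
class GeneticCode:
    """Codon → amino-acid map plus the synonymous-family structure.

    Attributes
    ----------
    codon_to_aa : mapping of the 61 sense codons to one-letter amino acids.
    stop_codons : the 3 stop triplets.
    families : amino acid → tuple of its codons (sorted), all 20 amino acids.
    """

    codon_to_aa: Mapping[str, str]
    stop_codons: tuple[str, ...]
    families: Mapping[str, tuple[str, ...]] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.families is None:
            fams: dict[str, list[str]] = {}
            for codon, aa in self.codon_to_aa.items():
                fams.setdefault(aa, []).append(codon)
            object.__setattr__(
                self, "families", {aa: tuple(sorted(c)) for aa, c in fams.items()}
            )

    @classmethod
    def standard(cls) -> "GeneticCode":
        tab = _standard_table()
        c2a = {c: a for c, a in tab.forward_table.items() if len(c) == 3}
        return cls(codon_to_aa=c2a, stop_codons=tuple(sorted(tab.stop_codons)))

    # -- family structure -------------------------------------------------

    def degeneracy(self, codon: str) -> int:
        """Number of synonymous codons of ``codon``'s amino acid."""
        return len(self.families[self.codon_to_aa[codon]])

    def family(self, codon: str) -> tuple[str, ...]:
        return self.families[self.codon_to_aa[codon]]

    def is_stop(self, codon: str) -> bool:
        return codon in self.stop_codons

    @property
    def sense_codons(self) -> tuple[str, ...]:
        """All 61 sense codons, lexicographic."""
        return tuple(c for c in CODONS if c in self.codon_to_aa)

    @property
    def synonymous_codons(self) -> tuple[str, ...]:
        """The 59 sense codons of multi-codon families (Met, Trp excluded)."""
        return tuple(c for c in self.sense_codons if self.degeneracy(c) > 1)

    def families_by_degeneracy(self) -> dict[int, list[str]]:
        """Degeneracy class (2/3/4/6) → amino acids in that class."""
        out: dict[int, list[str]] = {}
        for aa, codons in self.families.items():
            if len(codons) > 1:
                out.setdefault(len(codons), []).append(aa)
        return {k: sorted(v) for k, v in sorted(out.items())}


@dataclass(frozen=True)
class CodonCountTable:
    """Counts of the 64 codons for a transcript or a pooled gene."""

    counts: Mapping[str, int]

    @classmethod
    def from_codons(cls, codons: Iterable[str]) -> "CodonCountTable":
        c = Counter(codons)
        bad = set(c) - set(CODONS)
        if bad:
            raise ValueError(f"non-codon keys: {sorted(bad)}")
        return cls(counts=dict(c))

    @classmethod
    def from_records(cls, records: Iterable) -> "CodonCountTable":
        """Pool codon counts over CdsRecord-like objects (have .sequence)."""
        c: Counter[str] = Counter()
        for rec in records:
            seq = rec.sequence
            c.update(seq[i : i + 3] for i in range(0, len(seq), 3))
        return cls(counts=dict(c))

    def get(self, codon: str) -> int:
        return self.counts.get(codon, 0)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def total_sense(self, code: GeneticCode) -> int:
        return sum(n for c, n in self.counts.items() if not code.is_stop(c))

    def __add__(self, other: "CodonCountTable") -> "CodonCountTable":
        merged = Counter(self.counts)
        merged.update(other.counts)
        return CodonCountTable(counts=dict(merged))

    def as_array(self) -> np.ndarray:
        """Counts as a length-64 vector in ``CODONS`` order."""
        return np.array([self.get(c) for c in CODONS], dtype=float)


STANDARD_CODE = GeneticCode.standard()
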