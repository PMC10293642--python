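"""Codon-bias indices: RSCU, CAI, ENc, scaled chi-square, GRAVY, AROMA, PR2.

These are the classical within-gene measures of synonymous codon usage:

* RSCU — observed codon count over the count expected under equal use
  within the synonymous family; values within a family sum to the family's
  degeneracy, 1 means no bias.
* CAI — geometric mean of relative-adaptiveness weights derived from a
  highly expressed reference set; the CAI_59 convention excludes Met, Trp
  and stops.
* ENc — Wright's effective number of codons: 20 means a single codon per
  family, 61 fully even usage. The expected value under composition alone
  is the classical function of GC3s used in ENc–GC3 plots.
* SCS — scaled chi-square: chi-square of observed vs equal synonymous
  usage summed over families, divided by the eligible codon count.
* GRAVY / AROMA — mean Kyte–Doolittle hydropathy and aromatic-residue
  fraction of the encoded protein.
* PR2 — parity-rule-2 coordinates, G3/(G3+C3) vs A3/(A3+T3), at third
  codon positions; (0.5, 0.5) means no within-strand bias.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from Bio.SeqUtils.ProtParamData import kd as KYTE_DOOLITTLE

from .genetic_code import CodonCountTable, GeneticCode, STANDARD_CODE

AROMATIC = frozenset("FYW")

RSCU_OVER = 1.6
RSCU_UNDER = 0.6


# ---------------------------------------------------------------------------
# RSCU


@dataclass(frozen=True)
class RscuVector:
    """RSCU values for the 59 synonymously variable sense codons.

    ``zero_families`` lists amino acids whose family had no usage at all;
    their codons carry RSCU 0 rather than NaN.
    """

    values: Mapping[str, float]
    zero_families: tuple[str, ...] = ()

    def __getitem__(self, codon: str) -> float:
        return self.values[codon]

    def full61(self, code: GeneticCode = STANDARD_CODE) -> dict[str, float]:
        """All 61 sense codons, with the singletons Met/Trp fixed at 1."""
        out = dict(self.values)
        for c in code.sense_codons:
            if c not in out:
                out[c] = 1.0
        return out


def rscu(
    counts: CodonCountTable, code: GeneticCode = STANDARD_CODE
) -> RscuVector:
    """Relative synonymous codon usage: obs / (family_total / degeneracy)."""
    values: dict[str, float] = {}
    zero: list[str] = []
    for aa, fam in code.families.items():
        if len(fam) == 1:
            continue
        total = sum(counts.get(c) for c in fam)
        if total == 0:
            zero.append(aa)
            for c in fam:
                values[c] = 0.0
        else:
            expected = total / len(fam)
            for c in fam:
                values[c] = counts.get(c) / expected
    return RscuVector(values=values, zero_families=tuple(sorted(zero)))


def classify_rscu(
    v: RscuVector, over: float = RSCU_OVER, under: float = RSCU_UNDER
) -> dict[str, str]:
    """Classify each codon as overrepresented (> 1.6), random, or underrepresented (< 0.6)."""
    out = {}
    for codon, val in v.values.items():
        if val > over:
            out[codon] = "overrepresented"
        elif val < under:
            out[codon] = "underrepresented"
        else:
            out[codon] = "random"
    return out


# ---------------------------------------------------------------------------
# CAI


@dataclass(frozen=True)
class ReferenceWeights:
    """Relative adaptiveness w per codon (max-w codon of each family = 1)."""

    weights: Mapping[str, float]
    provenance: str = "unspecified"

    def __post_init__(self) -> None:
        for c, w in self.weights.items():
            if not (0.0 < w <= 1.0):
                raise ValueError(f"weight for {c} outside (0, 1]: {w}")

    @classmethod
    def from_counts(
        cls,
        counts: Mapping[str, float],
        code: GeneticCode = STANDARD_CODE,
        provenance: str = "counts",
    ) -> "ReferenceWeights":
        """Build w = count / max family count; zero counts get 0.5 first.

        The 0.5 pseudo-count keeps the geometric mean finite for codons the
        reference set happens never to use.
        """
        weights: dict[str, float] = {}
        for aa, fam in code.families.items():
            if len(fam) == 1:
                continue
            adj = {c: (counts.get(c, 0) or 0.5) for c in fam}
            mx = max(adj.values())
            for c in fam:
                weights[c] = adj[c] / mx
        return cls(weights=weights, provenance=provenance)

    @classmethod
    def from_tsv(
        cls, path: str | Path, code: GeneticCode = STANDARD_CODE
    ) -> "ReferenceWeights":
        """Load a two-column TSV: ``codon<TAB>weight`` or ``codon<TAB>count``."""
        values: dict[str, float] = {}
        with open(path, newline="") as fh:
            reader = csv.reader(
                (ln for ln in fh if not ln.startswith("#")), delimiter="\t"
            )
            header = next(reader)
            if header[0].lower() != "codon" or header[1].lower() not in (
                "weight",
                "count",
            ):
                raise ValueError(
                    "reference table needs columns codon + weight|count"
                )
            is_weight = header[1].lower() == "weight"
            for row in reader:
                values[row[0].upper()] = float(row[1])
        if is_weight:
            return cls(weights=values, provenance=str(path))
        return cls.from_counts(values, code=code, provenance=str(path))

    @classmethod
    def uniform(cls, code: GeneticCode = STANDARD_CODE) -> "ReferenceWeights":
        return cls(
            weights={c: 1.0 for c in code.synonymous_codons},
            provenance="uniform",
        )


def default_human_reference(
    code: GeneticCode = STANDARD_CODE,
) -> ReferenceWeights:
    """Bundled default reference for CAI.

    A synthetic approximation of genome-wide human codon-usage frequencies
    (per-1000 scale); substitute a curated high-expression reference table
    via :meth:`ReferenceWeights.from_tsv` for serious CAI comparisons.
    """
    path = resources.files("codonusage.data") / "human_usage_synthetic.tsv"
    with resources.as_file(path) as p:
        return ReferenceWeights.from_tsv(p, code=code)


def cai(
    counts: CodonCountTable,
    ref: ReferenceWeights,
    code: GeneticCode = STANDARD_CODE,
) -> float:
    """Codon adaptation index: geometric mean of w over the 59-codon set."""
    log_sum = 0.0
    n = 0
    for c in code.synonymous_codons:
        k = counts.get(c)
        if k:
            w = ref.weights.get(c)
            if w is None or w <= 0:
                raise ValueError(f"reference has no positive weight for {c}")
            log_sum += k * math.log(w)
            n += k
    if n == 0:
        raise ValueError("no eligible codon occurrences for CAI")
    return math.exp(log_sum / n)


# ---------------------------------------------------------------------------
# ENc


def _family_homozygosity(counts: Sequence[int]) -> float | None:
    """Wright's F̂ = (n·Σp² − 1)/(n − 1); None when undefined (n < 2) or ≤ 0."""
    n = sum(counts)
    if n < 2:
        return None
    p2 = sum((k / n) ** 2 for k in counts)
    f = (n * p2 - 1.0) / (n - 1.0)
    if f <= 0.0:
        return None
    return f


def enc(
    counts: CodonCountTable, code: GeneticCode = STANDARD_CODE
) -> float:
    """Wright's effective number of codons, clamped to [20, 61].

    ENc = 2 + 9/F̄2 + 1/F̄3 + 5/F̄4 + 3/F̄6 where F̄k averages the family
    homozygosities of degeneracy class k. A class with no defined family is
    imputed: the three-fold class (Ile) from the mean of the two- and
    four-fold classes, any other from the mean of the defined classes.
    """
    class_f: dict[int, float] = {}
    per_class: dict[int, list[float]] = {}
    for aa, fam in code.families.items():
        k = len(fam)
        if k == 1:
            continue
        f = _family_homozygosity([counts.get(c) for c in fam])
        if f is not None:
            per_class.setdefault(k, []).append(f)
    for k in (2, 3, 4, 6):
        if per_class.get(k):
            class_f[k] = float(np.mean(per_class[k]))
    if not class_f:
        raise ValueError("no synonymous family informative for ENc")
    if 3 not in class_f and 2 in class_f and 4 in class_f:
        class_f[3] = (class_f[2] + class_f[4]) / 2.0
    fallback = float(np.mean(list(class_f.values())))
    n_families = {2: 9, 3: 1, 4: 5, 6: 3}
    value = 2.0
    for k, nfam in n_families.items():
        value += nfam / class_f.get(k, fallback)
    return float(min(61.0, max(20.0, value)))


def enc_expected(s: float) -> float:
    """Expected ENc under composition alone: 2 + s + 29/(s² + (1−s)²)."""
    if not 0.0 <= s <= 1.0:
        raise ValueError(f"GC3s fraction outside [0, 1]: {s}")
    return 2.0 + s + 29.0 / (s * s + (1.0 - s) ** 2)


def enc_gc3_classify(
    enc_obs: float,
    s: float,
    tol_on: float = 1.0,
    tol_near: float = 2.0,
) -> str:
    """Place an observed ENc relative to the expected curve.

    ``on_curve`` within ±tol_on; ``near_curve`` within ±tol_near; otherwise
    ``below_curve`` (selection and other forces) or ``above_curve``.
    """
    delta = enc_obs - enc_expected(s)
    if abs(delta) <= tol_on:
        return "on_curve"
    if abs(delta) <= tol_near:
        return "near_curve"
    return "below_curve" if delta < 0 else "above_curve"


# ---------------------------------------------------------------------------
# Scaled chi-square


def scaled_chi_square(
    counts: CodonCountTable, code: GeneticCode = STANDARD_CODE
) -> float:
    """Chi-square against equal synonymous usage, scaled by codon count.

    Met and Trp are excluded. 0 means exactly equal usage within every
    family; larger values mean stronger bias.
    """
    chi2 = 0.0
    n_total = 0
    for aa, fam in code.families.items():
        if len(fam) == 1:
            continue
        obs = [counts.get(c) for c in fam]
        total = sum(obs)
        if total == 0:
            continue
        expected = total / len(fam)
        chi2 += sum((o - expected) ** 2 / expected for o in obs)
        n_total += total
    if n_total == 0:
        raise ValueError("no eligible codons for scaled chi-square")
    return chi2 / n_total


# ---------------------------------------------------------------------------
# Protein indices


def gravy(protein: str) -> float:
    """Grand average of hydropathy (mean Kyte–Doolittle); positive = hydrophobic."""
    if not protein:
        raise ValueError("empty protein")
    try:
        return sum(KYTE_DOOLITTLE[aa] for aa in protein) / len(protein)
    except KeyError as exc:
        raise ValueError(f"unknown residue: {exc.args[0]}") from exc


def aroma(protein: str) -> float:
    """Fraction of aromatic residues (Phe, Tyr, Trp)."""
    if not protein:
        raise ValueError("empty protein")
    return sum(1 for aa in protein if aa in AROMATIC) / len(protein)


# ---------------------------------------------------------------------------
# PR2


def pr2(
    codons: Sequence[str],
    code: GeneticCode = STANDARD_CODE,
    fourfold_only: bool = False,
) -> tuple[float, float]:
    """Parity-rule-2 coordinates (x = G3/(G3+C3), y = A3/(A3+T3)).

    Third positions of sense codons (stops excluded); with
    ``fourfold_only`` restricted to four-fold degenerate families, the
    classical strictly neutral site set. A zero denominator yields NaN for
    that coordinate.
    """
    eligible = []
    for c in codons:
        if c not in code.codon_to_aa:
            continue
        if fourfold_only and code.degeneracy(c) != 4:
            continue
        eligible.append(c)
    if not eligible:
        raise ValueError("no eligible codons for PR2")
    thirds = [c[2] for c in eligible]
    a3, t3 = thirds.count("A"), thirds.count("T")
    g3, c3 = thirds.count("G"), thirds.count("C")
    x = g3 / (g3 + c3) if (g3 + c3) else float("nan")
    y = a3 / (a3 + t3) if (a3 + t3) else float("nan")
    return (x, y)
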