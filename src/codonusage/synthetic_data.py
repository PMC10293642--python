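"""Synthetic coding-sequence generator with controllable codon-usage structure.

Transcripts are drawn codon by codon: an amino-acid stream is sampled from
per-gene amino-acid weights and each amino acid is realised as a codon
from its synonymous family using per-gene synonymous weights (explicit, or
drawn once per gene from a symmetric Dirichlet). Every transcript starts
with ATG, ends with a single stop, contains no internal stop, and has
length divisible by 3, so all generator output passes CDS validation.

Randomness is organised as one master seed with per-(gene, transcript)
derived substreams, so adding a transcript to a spec never perturbs the
sequences already generated.

The analytic expectations implied by the weights (RSCU per codon, the
preferred codon per family, expected GC3s) are available from
:func:`known_truth` for parameter-recovery testing.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .genetic_code import GeneticCode, STANDARD_CODE
from .sequence_io import CdsRecord, GeneSet

AMINO_ACIDS = tuple(sorted(set(STANDARD_CODE.codon_to_aa.values())))


@dataclass(frozen=True)
class GeneSpec:
    """Generation recipe for one gene.

    Lengths are in nucleotides including the stop codon and are rounded to
    multiples of 3. ``codon_weights`` maps amino acid → {codon: weight};
    families not listed fall back to ``dirichlet_alpha`` (a symmetric
    Dirichlet draw per gene) or to uniform weights when that is None.
    ``pair_motifs`` plants (5′ codon, 3′ codon, per-position probability)
    motifs to create codon-context structure.
    """

    n_transcripts: int = 1
    length_range: tuple[int, int] = (846, 2313)
    lengths: tuple[int, ...] | None = None  # explicit nt lengths, overrides range
    codon_weights: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    dirichlet_alpha: float | None = None
    aa_weights: Mapping[str, float] | None = None
    stop_weights: Mapping[str, float] | None = None
    pair_motifs: tuple[tuple[str, str, float], ...] = ()


@dataclass(frozen=True)
class GeneratorSpec:
    """A full synthetic study: gene label → :class:`GeneSpec`, one master seed."""

    genes: Mapping[str, GeneSpec]
    seed: int = 0


def _substream(seed: int, gene: str, index: int) -> np.random.Generator:
    # crc32 keys the gene label into the seed sequence deterministically
    return np.random.default_rng(
        np.random.SeedSequence([seed, zlib.crc32(gene.encode()), index])
    )


def _gene_rng(seed: int, gene: str) -> np.random.Generator:
    return _substream(seed, gene, 0xFFFF)


def resolve_codon_weights(
    spec: GeneratorSpec, gene: str, code: GeneticCode = STANDARD_CODE
) -> dict[str, dict[str, float]]:
    """The per-family synonymous weights a gene actually uses, normalised.

    Dirichlet-backed families are drawn once per gene from a dedicated
    substream, so the resolved weights are a deterministic function of the
    spec — this is what :func:`known_truth` builds on.
    """
    gspec = spec.genes[gene]
    rng = _gene_rng(spec.seed, gene)
    weights: dict[str, dict[str, float]] = {}
    for aa in AMINO_ACIDS:
        fam = code.families[aa]
        if aa in gspec.codon_weights:
            w = np.array(
                [gspec.codon_weights[aa].get(c, 0.0) for c in fam], dtype=float
            )
            if w.sum() <= 0 or (w < 0).any():
                raise ValueError(f"gene {gene}: invalid weights for {aa}")
        elif gspec.dirichlet_alpha is not None:
            w = rng.dirichlet([gspec.dirichlet_alpha] * len(fam))
        else:
            w = np.ones(len(fam))
        weights[aa] = {c: float(x) for c, x in zip(fam, w / w.sum())}
    return weights


def _aa_probs(gspec: GeneSpec) -> tuple[tuple[str, ...], np.ndarray]:
    if gspec.aa_weights is None:
        aas = AMINO_ACIDS
        p = np.ones(len(aas))
    else:
        aas = tuple(sorted(gspec.aa_weights))
        p = np.array([gspec.aa_weights[a] for a in aas], dtype=float)
        if p.sum() <= 0 or (p < 0).any():
            raise ValueError("invalid amino-acid weights")
    return aas, p / p.sum()


def generate_cds(
    spec: GeneratorSpec,
    gene: str,
    index: int = 0,
    code: GeneticCode = STANDARD_CODE,
) -> CdsRecord:
    """Draw one synthetic coding transcript for ``gene``."""
    gspec = spec.genes[gene]
    rng = _substream(spec.seed, gene, index)
    weights = resolve_codon_weights(spec, gene, code=code)
    aas, aa_p = _aa_probs(gspec)

    if gspec.lengths is not None:
        length_nt = gspec.lengths[index % len(gspec.lengths)]
    else:
        lo, hi = gspec.length_range
        length_nt = int(rng.integers(lo, hi + 1))
    n_codons = max(2, length_nt // 3)

    n_body = n_codons - 2
    aa_idx = rng.choice(len(aas), size=n_body, p=aa_p)
    body = np.empty(n_body, dtype=object)
    for k, aa in enumerate(aas):
        mask = aa_idx == k
        m = int(mask.sum())
        if not m:
            continue
        fam = code.families[aa]
        w = np.array([weights[aa][c] for c in fam])
        body[mask] = np.array(fam, dtype=object)[
            rng.choice(len(fam), size=m, p=w)
        ]
    body = body.tolist()

    for c5, c3, prob in gspec.pair_motifs:
        hits = np.nonzero(rng.random(max(0, n_body - 1)) < prob)[0]
        for i in hits:
            body[i], body[i + 1] = c5, c3

    if gspec.stop_weights is None:
        stops = code.stop_codons
        sp = np.ones(len(stops)) / len(stops)
    else:
        stops = tuple(sorted(gspec.stop_weights))
        sp = np.array([gspec.stop_weights[s] for s in stops], dtype=float)
        sp = sp / sp.sum()
    stop = stops[int(rng.choice(len(stops), p=sp))]

    return CdsRecord(
        transcript_id=f"{gene}_t{index + 1:02d}",
        gene=gene,
        sequence="ATG" + "".join(body) + stop,
    )


def generate_gene_set(
    spec: GeneratorSpec, code: GeneticCode = STANDARD_CODE
) -> GeneSet:
    """Generate all transcripts of all genes in the spec."""
    gs = GeneSet()
    for gene in spec.genes:
        for i in range(spec.genes[gene].n_transcripts):
            gs.add(generate_cds(spec, gene, index=i, code=code))
    return gs


def known_truth(
    spec: GeneratorSpec, code: GeneticCode = STANDARD_CODE
) -> dict[str, dict]:
    """Analytic expectations implied by a spec, per gene.

    ``rscu`` — expected RSCU per synonymous codon (degeneracy × normalised
    weight); ``preferred`` — max-weight codon per family; ``gc3s`` —
    expected GC3s given the amino-acid and codon weights.
    """
    out: dict[str, dict] = {}
    for gene, gspec in spec.genes.items():
        weights = resolve_codon_weights(spec, gene, code=code)
        aas, aa_p = _aa_probs(gspec)
        aa_prob = dict(zip(aas, aa_p))
        exp_rscu: dict[str, float] = {}
        preferred: dict[str, str] = {}
        gc_num = 0.0
        gc_den = 0.0
        for aa, fam_w in weights.items():
            fam = code.families[aa]
            if len(fam) > 1:
                for c in fam:
                    exp_rscu[c] = len(fam) * fam_w[c]
                preferred[aa] = max(fam, key=lambda c: (fam_w[c], c))
                p_aa = aa_prob.get(aa, 0.0)
                gc_den += p_aa
                gc_num += p_aa * sum(
                    w for c, w in fam_w.items() if c[2] in "GC"
                )
        out[gene] = {
            "rscu": exp_rscu,
            "preferred": preferred,
            "gc3s": gc_num / gc_den if gc_den else float("nan"),
        }
    return out


def four_gene_preset(seed: int = 0, dirichlet_alpha: float | None = None) -> GeneratorSpec:
    """Preset mirroring the study's gene-set structure.

    Four genes with 11/1/4/6 transcripts and the exact deposited CDS
    lengths (nt, stop included): APP-like 1,920–2,313; CCND1-like 888;
    CCNE1-like 1,086–1,233; PTPA-like 846–1,077. Codon usage is uniform
    unless a Dirichlet concentration is given.
    """
    lengths = {
        "APP": (2313, 2256, 2088, 2241, 1920, 1983, 2259, 2202, 2145, 2145, 2034),
        "CCND1": (888,),
        "CCNE1": (1188, 1086, 1098, 1233),
        "PTPA": (1077, 867, 885, 972, 846, 972),
    }
    genes = {
        g: GeneSpec(
            n_transcripts=len(ls),
            lengths=ls,
            length_range=(min(ls), max(ls)),
            dirichlet_alpha=dirichlet_alpha,
        )
        for g, ls in lengths.items()
    }
    return GeneratorSpec(genes=genes, seed=seed)
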