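# Methods

## Sequence model and validation

The unit of analysis is a coding transcript: an A/C/G/T string of length
≥ 6 and divisible by 3, beginning with ATG, ending with TAA/TAG/TGA.
Internal stop codons are rejected by default (curated CDS records should
not contain them; their presence indicates a frame error) and can be
demoted to a warning for exploratory work. Transcripts are grouped by gene;
wherever a per-gene value is reported it is the unweighted mean of the
gene's per-transcript values, so a gene with eleven isoforms and a gene
with one are summarised on the same footing and duplicating a transcript's
sequence under a new id changes pooled counts but not per-gene means
derived from per-transcript statistics.

FASTA headers follow a `gene|transcript_id` convention by default; any
regex with `gene`/`transcript_id` named groups can be substituted, and a
TSV manifest (gene, transcript_id, path) reproduces arbitrary groupings.
Ambiguity codes are not translated: composition percentages are defined to
sum to exactly 100, so records containing non-ACGT characters are rejected
(or, optionally, dropped with a warning).

## Composition conventions

Overall and positional composition are computed over the full CDS
including the stop codon by default. Deposited transcript lengths include
the stop, and nothing in the quantities' definitions excludes it; a flag
drops the final codon for tools that do, which can move any percentage by
at most three bases' worth. The synonymous third-position fractions
(A3s … GC3s) always exclude stops and the singleton codons ATG/TGG, and
use the codonW convention: for base X, the numerator counts eligible codon
occurrences with X at position 3 and the denominator counts occurrences
whose synonymous family can place X at position 3. Tools differ on this
definition, which is why it is spelled out here; under it GC3s of a
poly-GGG body is exactly 1 and a forced 50/50 C3/G3 four-fold gene gives
C3s = 0.5, GC3s = 1.

## Bias indices

**RSCU.** `obs / (family_total / degeneracy)` per codon within each of the
18 multi-codon families. Values in a used family sum to the family's
degeneracy; a family with zero usage yields 0 for all members and is
flagged rather than treated as NaN. Classification thresholds are the
conventional 1.6 / 0.6 cut points.

**CAI.** Geometric mean of relative adaptiveness `w` over the 59-codon set
("CAI_59": Met, Trp, and stops excluded, since single-codon families carry
no choice). Reference weights are `count / max family count`, with zero
counts replaced by 0.5 before normalisation so the geometric mean stays
finite. The bundled default table is a synthetic approximation of
genome-wide human codon-usage frequencies (per-1000 scale) — adequate as a
neutral default, but comparisons against published CAI values should load
a curated high-expression reference via the documented TSV format
(`codon<TAB>weight` or `codon<TAB>count`).

**ENc.** Wright's estimator with per-family homozygosity
`F = (nΣp² − 1)/(n − 1)`, averaged within each degeneracy class.
Families with n < 2, or with F ≤ 0 (possible at small n under even usage),
are treated as uninformative. A class with no informative family is
imputed: the three-fold class (Ile only — easily absent in a short
transcript) from the mean of the two- and four-fold classes, any other
from the mean of the defined classes. The result is clamped to [20, 61],
the estimator's interpretable range; sampling noise can otherwise push it
slightly past either end. The expected-ENc curve
`2 + s + 29/(s² + (1−s)²)` classifies observations as on (±1), near (±2),
or below/above the curve; the tolerances are reporting conventions, both
configurable.

**SCS.** Per-family χ² against equal usage, summed and divided by the
eligible codon count (Met/Trp excluded). The statistic is sometimes quoted
as lying in [0, 1]; that holds for two-fold families (a family used
exclusively through one codon contributes exactly its count, giving
SCS = 1) but not in general, so no upper bound is enforced.

**GRAVY / AROMA.** Mean Kyte–Doolittle hydropathy (the standard scale,
spanning −4.5 to +4.5) and the F+Y+W fraction of the translated protein,
terminal stop dropped.

**PR2.** `x = G3/(G3+C3)`, `y = A3/(A3+T3)` over third positions of sense
codons (stops excluded) by default; a four-fold-only mode restricts to the
strictly neutral site set of classical parity analysis. A vanishing
denominator yields NaN for that coordinate rather than an arbitrary value.
The package reports coordinates and leaves purine/pyrimidine-preference
interpretation to the analyst.

## Rare codons

Codon frequencies are length-adjusted by expressing them as percentages of
the transcript's total codons (stop codons in the denominator by default,
consistent with full-CDS bookkeeping; a flag excludes them). Gene values
are means of per-transcript percentages; rarity is strict `< 0.5 %`, so a
codon at exactly 0.5 % is not rare and an entirely absent codon is. The
degeneracy panels assign each codon to its amino acid's fold class — all
six codons of Leu/Ser/Arg sit in the six-fold panel even though their
codon blocks split 4+2 — giving panels of 18/3/20/18 codons.

## Codon pairs and context

Pairs are overlapping adjacent codons pooled across a gene's transcripts,
stop codon included as the 3′ member of each transcript's final pair, so
N_pairs = Σ(codons − 1). The length-adjusted pair score is
`100 × count / total codons` (pairs + transcripts), reported to two
decimals; this denominator, rather than N_pairs, is what reproduces the
published per-gene pair tables under a single rounding rule. Top-k tables
order by count descending with ties broken by the pair string in
descending lexicographic order, matching the ordering of equal-count
blocks in those tables.

Context is classified by Pearson adjusted residuals on the 64×64
contingency table,
`(O − E)/√(E(1 − r/N)(1 − c/N))`, approximately standard normal under
independence; the ±5 band (far beyond the nominal 1.96 — a conservative
convention for these highly structured tables) separates good (> +5) and
bad (< −5) context from noise, with margin-less cells reported as absent.
Under independent codon draws ≥ 99 % of populated cells fall inside the
band, which the tests verify by simulation.

## Multivariate analysis

The PCA operates on the transcripts × 59 RSCU matrix, column-centred and
unscaled by default — RSCU is already family-normalised, so variance
differences between codons are signal, not units; a correlation-mode
switch exists because published analyses often leave this unstated. The
decomposition is a deterministic full SVD with each axis oriented so its
largest-|loading| codon is positive, making scores and loadings
reproducible across linear-algebra backends. Axis inertia percentages are
non-increasing and `scores × loadingsᵀ + column means` reconstructs the
matrix to numerical precision. Correlations default to Pearson (two-tailed)
with Spearman available, labelled NS/*/**/*** at 0.05/0.01/0.001.

## Synthetic data

The generator draws an amino-acid stream from per-gene amino-acid weights
(uniform over the 20 amino acids unless specified) and realises each amino
acid as a codon from explicit synonymous weights, a per-gene symmetric
Dirichlet draw (concentration α — small α means strongly skewed usage), or
uniform weights. Every output passes CDS validation by construction.
Randomness uses one master seed with per-(gene, transcript) substreams, so
extending a spec never perturbs existing sequences. Optional pair motifs
overwrite adjacent codon slots with a given probability to plant
good-context pairs for the residual machinery.

`known_truth` returns the analytic expectations the weights imply
(RSCU = degeneracy × normalised weight, the preferred codon per family,
expected GC3s), which the tests use for parameter recovery: at 110k codons
the observed RSCU tracks the analytic value within 0.1 (the band is ≈ 3.8
sampling SDs for six-fold families at that size), and a planted one-hot
codon is classified overrepresented in ≥ 95 of 100 replicates at 400
codons per replicate.

What the generator does **not** emulate: real exon structure, UTRs,
codon autocorrelation beyond planted motifs, amino-acid composition of
real proteomes, or phylogenetic relatedness between isoforms (each
transcript is an independent draw, unlike real splice variants sharing
exons). Passing tests therefore demonstrate the correctness of the
statistics under the stated sampling model, not biological conclusions
about any real gene set.

## Problem sizes and determinism

The test and acceptance workloads use synthetic genes of 10k–110k codons
for limit and recovery checks, 100 replicates for detection rates, and the
22-transcript preset for end-to-end runs; these sizes put stochastic
checks several SDs inside their bands while keeping a full run in seconds.
All pipeline outputs are byte-deterministic for a fixed gene set and
configuration: TSVs are written with 12-significant-digit formatting
(lossless well past the 1e-9 round-trip requirement), orderings are
explicit everywhere, and the only randomness in the package lives in the
generator's seeded streams.

## Known limitations

- ENc imputation for sparsely covered degeneracy classes is a pragmatic
  convention; very short transcripts (< ~100 codons) yield noisy ENc.
- CAI values depend strongly on the reference table; the bundled default
  is synthetic and intended for relative comparisons only.
- The adjusted-residual normal approximation degrades for cells with
  E ≲ 1; the ±5 band absorbs most of this in practice.
- PCA on fewer transcripts than codons (the usual case) spans at most
  n − 1 axes; inertia percentages are relative to that subspace.
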