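"""PCA of RSCU profiles and correlation reporting.

The RSCU matrix (transcripts × 59 synonymous codons) is decomposed with a
deterministic SVD-based PCA. By default columns are centred but not
scaled — RSCU values are already normalised within each family — and each
axis is oriented so its largest-magnitude loading is positive, which makes
loadings reproducible across linear-algebra backends.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genetic_code import CodonCountTable, GeneticCode, STANDARD_CODE
from .indices import rscu
from .sequence_io import GeneSet


@dataclass(frozen=True)
class PcaResult:
    """Scores, loadings, and explained inertia of an RSCU PCA."""

    scores: pd.DataFrame          # entities × axes
    loadings: pd.DataFrame        # variables × axes
    explained_pct: np.ndarray     # % inertia per axis, non-increasing
    column_means: pd.Series


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    label: str  # NS / * / ** / ***


def rscu_matrix(
    gene_set: GeneSet,
    genes: list[str] | None = None,
    code: GeneticCode = STANDARD_CODE,
) -> pd.DataFrame:
    """One row per transcript, columns = the 59 synonymous codons in fixed order."""
    if genes is None:
        genes = list(gene_set)
    order = list(code.synonymous_codons)
    rows = {}
    for gene in genes:
        for rec in gene_set[gene]:
            counts = CodonCountTable.from_records([rec])
            v = rscu(counts, code=code)
            rows[rec.transcript_id] = [v[c] for c in order]
    if len(rows) < 2:
        raise ValueError("need at least 2 transcripts for an RSCU matrix")
    return pd.DataFrame.from_dict(rows, orient="index", columns=order)


def pca(
    matrix: pd.DataFrame, center: bool = True, scale: bool = False
) -> PcaResult:
    """Deterministic SVD-based principal component analysis.

    ``scale=True`` divides each column by its standard deviation
    (correlation PCA); zero-variance columns stay unscaled. Raises on an
    all-constant matrix.
    """
    x = matrix.to_numpy(dtype=float)
    if x.shape[0] < 2:
        raise ValueError("need at least 2 rows")
    means = x.mean(axis=0)
    centered = x - means if center else x.copy()
    if scale:
        sd = centered.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        centered = centered / sd
    if not np.any(centered - centered[0]):
        raise ValueError("constant matrix has no principal axes")
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    var = s**2
    explained = 100.0 * var / var.sum()
    # orient each axis: largest-|loading| variable gets a positive loading
    for k in range(vt.shape[0]):
        j = int(np.argmax(np.abs(vt[k])))
        if vt[k, j] < 0:
            vt[k] = -vt[k]
            u[:, k] = -u[:, k]
    axes = [f"PC{i + 1}" for i in range(len(s))]
    scores = pd.DataFrame(u * s, index=matrix.index, columns=axes)
    loadings = pd.DataFrame(vt.T, index=matrix.columns, columns=axes)
    return PcaResult(
        scores=scores,
        loadings=loadings,
        explained_pct=explained,
        column_means=pd.Series(means, index=matrix.columns),
    )


def top_loadings(result: PcaResult, axis: int = 1, k: int = 5) -> pd.DataFrame:
    """The k variables with the largest |loading| on a 1-based axis."""
    col = f"PC{axis}"
    if col not in result.loadings.columns:
        raise IndexError(f"axis {axis} out of range")
    lo = result.loadings[col]
    order = lo.abs().sort_values(ascending=False, kind="stable").index[:k]
    return pd.DataFrame(
        {"codon": order, "loading": lo.loc[order].to_numpy()}
    ).reset_index(drop=True)


def significance_label(p: float) -> str:
    """Star notation at the 0.05 / 0.01 / 0.001 cutoffs."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "NS"


def correlate(
    x, y, method: str = "pearson"
) -> CorrelationResult:
    """Two-tailed correlation of two equal-length numeric vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("need two equal-length vectors of length ≥ 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in an input vector")
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    elif method == "spearman":
        r, p = stats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method: {method}")
    return CorrelationResult(r=float(r), p=float(p), label=significance_label(p))
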