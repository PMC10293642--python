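"""Assembly of per-gene reports: composition, indices, RSCU, PR2, ENc–GC3,
rare codons, codon pairs and context, PCA, and length correlations.

``run_all`` writes a deterministic set of machine-readable TSVs plus a
JSON summary; numbers in TSVs keep full precision (12 significant digits)
except the pair adjusted score, which is defined to 2 decimals. On any
stage failure the output directory is left without partial files.
"""

from __future__ import annotations

import json
import logging
import shutil
import tempfile
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import codon_pairs, composition, indices, multivariate, rare_codons
from .genetic_code import CodonCountTable, GeneticCode, STANDARD_CODE
from .sequence_io import GeneSet, translate, split_codons, validate_cds

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.12g"


@dataclass
class RunConfig:
    """All tunables of a full analysis run."""

    output_dir: Path = Path("codonusage_out")
    reference_weights: str | Path | None = None  # TSV; None = bundled default
    rscu_over: float = indices.RSCU_OVER
    rscu_under: float = indices.RSCU_UNDER
    rare_threshold: float = rare_codons.RARE_THRESHOLD
    context_band: float = codon_pairs.CONTEXT_BAND
    enc_tol_on: float = 1.0
    enc_tol_near: float = 2.0
    include_stop: bool = True
    correlation_method: str = "pearson"
    pca_scale: bool = False
    top_k_pairs: int = 15
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("rscu_over", "rscu_under", "rare_threshold",
                     "context_band", "enc_tol_on", "enc_tol_near"):
            if getattr(self, name) <= 0:
                raise ValueError(f"threshold {name} must be positive")


def _reference(config: RunConfig, code: GeneticCode) -> indices.ReferenceWeights:
    if config.reference_weights is None:
        return indices.default_human_reference(code=code)
    return indices.ReferenceWeights.from_tsv(config.reference_weights, code=code)


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def index_table(
    gene_set: GeneSet,
    config: RunConfig | None = None,
    code: GeneticCode = STANDARD_CODE,
) -> pd.DataFrame:
    """Per-transcript bias indices plus one unweighted-mean row per gene."""
    config = config or RunConfig()
    ref = _reference(config, code)
    rows = []
    for gene in gene_set:
        per_gene = []
        for rec in gene_set[gene]:
            counts = CodonCountTable.from_records([rec])
            codons = split_codons(rec)
            protein = translate(rec, code=code)
            syn = composition.synonymous_third_composition(codons, code=code)
            x, y = indices.pr2(codons, code=code)
            row = {
                "gene": gene,
                "entity": rec.transcript_id,
                "level": "transcript",
                "length_nt": len(rec),
                "CAI": indices.cai(counts, ref, code=code),
                "ENc": indices.enc(counts, code=code),
                "SCS": indices.scaled_chi_square(counts, code=code),
                "GRAVY": indices.gravy(protein),
                "AROMA": indices.aroma(protein),
                "PR2x": x,
                "PR2y": y,
                "GC3s": syn["GC3s"],
            }
            rows.append(row)
            per_gene.append(row)
        mean = pd.DataFrame(per_gene).mean(numeric_only=True).to_dict()
        mean.update({"gene": gene, "entity": gene, "level": "gene_mean"})
        rows.append(mean)
    return pd.DataFrame(rows)


def rscu_table(
    gene_set: GeneSet,
    config: RunConfig | None = None,
    code: GeneticCode = STANDARD_CODE,
) -> pd.DataFrame:
    """Pooled per-gene RSCU with over/random/under classification."""
    config = config or RunConfig()
    rows = []
    for gene in gene_set:
        counts = CodonCountTable.from_records(gene_set[gene])
        v = indices.rscu(counts, code=code)
        classes = indices.classify_rscu(
            v, over=config.rscu_over, under=config.rscu_under
        )
        for codon in code.synonymous_codons:
            rows.append(
                {
                    "gene": gene,
                    "codon": codon,
                    "amino_acid": code.codon_to_aa[codon],
                    "rscu": v[codon],
                    "class": classes[codon],
                }
            )
    return pd.DataFrame(rows)


def enc_gc3_table(
    index_df: pd.DataFrame, config: RunConfig | None = None
) -> pd.DataFrame:
    """ENc–GC3 plot data with the curve classification per transcript."""
    config = config or RunConfig()
    sub = index_df[index_df["level"] == "transcript"]
    rows = []
    for _, r in sub.iterrows():
        expected = indices.enc_expected(r["GC3s"])
        rows.append(
            {
                "gene": r["gene"],
                "entity": r["entity"],
                "GC3s": r["GC3s"],
                "ENc": r["ENc"],
                "ENc_expected": expected,
                "class": indices.enc_gc3_classify(
                    r["ENc"], r["GC3s"],
                    tol_on=config.enc_tol_on, tol_near=config.enc_tol_near,
                ),
            }
        )
    return pd.DataFrame(rows)


def correlation_table(
    index_df: pd.DataFrame,
    comp_df: pd.DataFrame,
    method: str = "pearson",
) -> pd.DataFrame:
    """Transcript length vs composition and bias indices, one row per variable."""
    idx = index_df[index_df["level"] == "transcript"].set_index("entity")
    comp = comp_df[comp_df["level"] == "transcript"].set_index("entity")
    merged = idx.join(comp, rsuffix="_comp")
    length = merged["length_nt"].to_numpy(dtype=float)
    variables = [
        "pct_A", "pct_C", "pct_G", "pct_T",
        "pct_A3", "pct_C3", "pct_G3", "pct_T3",
        "pct_GC", "pct_GC1", "pct_GC2", "pct_GC3",
        "CAI", "ENc", "SCS", "GRAVY", "AROMA", "PR2x", "PR2y",
    ]
    rows = []
    for var in variables:
        if var not in merged.columns:
            continue
        y = merged[var].to_numpy(dtype=float)
        try:
            res = multivariate.correlate(length, y, method=method)
            rows.append(
                {"variable": var, "r": res.r, "p": res.p, "label": res.label}
            )
        except ValueError:
            rows.append(
                {"variable": var, "r": np.nan, "p": np.nan, "label": "NA"}
            )
    return pd.DataFrame(rows)


def run_all(
    gene_set: GeneSet,
    config: RunConfig | None = None,
    code: GeneticCode = STANDARD_CODE,
) -> dict[str, Path]:
    """Run every analysis stage and write the full report to disk.

    Returns the mapping of report name → written path. Outputs are
    deterministic for a fixed gene set and config.
    """
    config = config or RunConfig()
    outdir = Path(config.output_dir)
    for gene in gene_set:
        for rec in gene_set[gene]:
            verdict = validate_cds(rec, code=code)
            if not verdict:
                raise ValueError(
                    f"[validate] {rec.transcript_id}: {', '.join(verdict.reasons)}"
                )
    staging = Path(tempfile.mkdtemp(prefix="codonusage_"))
    written: dict[str, Path] = {}
    try:
        stage = "composition"
        comp_df = composition.composition_table(
            gene_set, code=code, include_stop=config.include_stop
        )
        _write_tsv(comp_df, staging / "composition.tsv")

        stage = "indices"
        idx_df = index_table(gene_set, config=config, code=code)
        _write_tsv(idx_df, staging / "indices.tsv")

        stage = "rscu"
        _write_tsv(rscu_table(gene_set, config=config, code=code),
                   staging / "rscu.tsv")

        stage = "pr2"
        pr2_df = idx_df[idx_df["level"] == "transcript"][
            ["gene", "entity", "PR2x", "PR2y"]
        ]
        _write_tsv(pr2_df, staging / "pr2.tsv")

        stage = "enc_gc3"
        _write_tsv(enc_gc3_table(idx_df, config=config),
                   staging / "enc_gc3.tsv")

        stage = "rare_codons"
        rare_df = rare_codons.adjusted_frequency_table(
            gene_set, code=code,
            include_stop=config.include_stop,
            threshold=config.rare_threshold,
        )
        _write_tsv(rare_df, staging / "rare_codons.tsv")
        _, summary = rare_codons.flag_rare(rare_df, threshold=config.rare_threshold)
        _write_tsv(
            summary.rename("n_genes_rare").reset_index(),
            staging / "rare_summary.tsv",
        )

        stage = "codon_pairs"
        pair_frames, top_frames = [], []
        for gene in gene_set:
            table = codon_pairs.count_pairs(gene_set[gene])
            pf = codon_pairs.context_frame(table, band=config.context_band)
            pf.insert(0, "gene", gene)
            pair_frames.append(pf)
            tf = codon_pairs.top_pairs(table, k=config.top_k_pairs)
            tf.insert(0, "gene", gene)
            top_frames.append(tf)
        _write_tsv(pd.concat(pair_frames, ignore_index=True),
                   staging / "pair_context.tsv")
        _write_tsv(pd.concat(top_frames, ignore_index=True),
                   staging / "top_pairs.tsv")

        stage = "start_context"
        sc_frames = []
        for gene in gene_set:
            sc = codon_pairs.start_context(gene_set[gene])
            sc.insert(0, "gene", gene)
            sc_frames.append(sc)
        _write_tsv(pd.concat(sc_frames, ignore_index=True),
                   staging / "start_context.tsv")

        stage = "pca"
        matrix = multivariate.rscu_matrix(gene_set, code=code)
        result = multivariate.pca(matrix, scale=config.pca_scale)
        scores = result.scores.iloc[:, :2].reset_index(names="entity")
        scores["kind"] = "score"
        loadings = result.loadings.iloc[:, :2].reset_index(names="entity")
        loadings["kind"] = "loading"
        pca_df = pd.concat([scores, loadings], ignore_index=True)
        _write_tsv(pca_df, staging / "pca.tsv")

        stage = "correlations"
        corr_df = correlation_table(
            idx_df, comp_df, method=config.correlation_method
        )
        _write_tsv(corr_df, staging / "correlations.tsv")

        stage = "summary"
        gene_means = idx_df[idx_df["level"] == "gene_mean"].set_index("gene")
        summary_json = {
            "n_genes": len(gene_set),
            "n_transcripts": gene_set.n_transcripts,
            "thresholds": {
                "rscu_over": config.rscu_over,
                "rscu_under": config.rscu_under,
                "rare_pct": config.rare_threshold,
                "context_band": config.context_band,
            },
            "pca_explained_pct": [float(v) for v in result.explained_pct[:2]],
            "gene_means": {
                g: {
                    k: float(gene_means.loc[g, k])
                    for k in ("CAI", "ENc", "SCS", "GRAVY", "AROMA",
                              "PR2x", "PR2y", "GC3s")
                }
                for g in gene_means.index
            },
        }
        with open(staging / "summary.json", "w") as fh:
            json.dump(summary_json, fh, indent=2, sort_keys=True)
            fh.write("\n")

        outdir.mkdir(parents=True, exist_ok=True)
        for f in sorted(staging.iterdir()):
            target = outdir / f.name
            shutil.move(str(f), target)
            written[f.stem] = target
            logger.info("wrote %s", target)
    except Exception as exc:
        raise RuntimeError(f"[{stage}] {exc}") from exc
    finally:
        shutil.rmtree(staging, ignore_errors=True)
    return written


def compare_groups(
    gene_set: GeneSet,
    groups: dict[str, str],
    config: RunConfig | None = None,
    code: GeneticCode = STANDARD_CODE,
) -> dict[str, dict]:
    """Group-level summaries (e.g. up- vs down-regulated gene sets).

    ``groups`` maps every gene label to a group name. Returns, per group:
    transcript count, PR2 mean ± SD, PCA explained inertia of the group's
    RSCU matrix (when ≥ 2 transcripts), and length-vs-index correlations.
    """
    config = config or RunConfig()
    missing = [g for g in gene_set if g not in groups]
    if missing:
        raise ValueError(f"genes not assigned to a group: {missing}")
    by_group: dict[str, list[str]] = {}
    for gene, grp in groups.items():
        by_group.setdefault(grp, []).append(gene)
    if any(not genes for genes in by_group.values()):
        raise ValueError("empty group")

    idx_df = index_table(gene_set, config=config, code=code)
    comp_df = composition.composition_table(
        gene_set, code=code, include_stop=config.include_stop
    )
    out: dict[str, dict] = {}
    for grp, genes in sorted(by_group.items()):
        sub = idx_df[
            (idx_df["level"] == "transcript") & idx_df["gene"].isin(genes)
        ]
        summary: dict = {"genes": sorted(genes), "n_transcripts": len(sub)}
        for coord in ("PR2x", "PR2y"):
            vals = sub[coord].to_numpy(dtype=float)
            summary[f"{coord}_mean"] = float(np.mean(vals))
            summary[f"{coord}_sd"] = (
                float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
            )
        if len(sub) >= 2:
            matrix = multivariate.rscu_matrix(gene_set, genes=sorted(genes), code=code)
            res = multivariate.pca(matrix, scale=config.pca_scale)
            summary["pca_explained_pct"] = [
                float(v) for v in res.explained_pct[:2]
            ]
        if len(sub) >= 3:
            sub_comp = comp_df[
                (comp_df["level"] == "transcript")
                & comp_df["gene"].isin(genes)
            ]
            summary["correlations"] = correlation_table(
                pd.concat([sub]), sub_comp, method=config.correlation_method
            ).to_dict(orient="records")
        out[grp] = summary
    return out
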