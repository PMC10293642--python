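import numpy as np
import pytest

import codonusage as cu
from codonusage.codon_pairs import PairTable
from codonusage.genetic_code import CODONS


class TestCountPairs:
    def test_minimal_cds(self, tiny_record):
        table = cu.count_pairs([tiny_record])
        assert table.total == 2
        assert table.count("ATG", "AAA") == 1
        assert table.count("AAA", "TAA") == 1

    def test_pooled_n_equals_codons_minus_transcripts(self, four_gene_set):
        """N = Σ(codons − 1): 7,851 / 295 / 1,531 / 1,867 for the four
        deposited gene structures."""
        expected = {"APP": 7851, "CCND1": 295, "CCNE1": 1531, "PTPA": 1867}
        for gene, n in expected.items():
            table = cu.count_pairs(four_gene_set[gene])
            assert table.total == n
            n_codons = sum(len(r) // 3 for r in four_gene_set[gene])
            assert table.total + len(four_gene_set[gene]) == n_codons

    def test_stop_is_a_pair_member(self, four_gene_set):
        table = cu.count_pairs(four_gene_set["CCND1"])
        stops = [c for c in ("TAA", "TAG", "TGA")]
        col_total = sum(
            table.count(c5, s) for c5 in CODONS for s in stops
        )
        assert col_total == 1  # one transcript → one terminal pair


class TestAdjustedPairScore:
    @pytest.mark.parametrize(
        "count, total, score",
        [(11, 296, 3.72), (77, 7862, 0.98), (18, 1873, 0.96), (13, 1535, 0.85),
         (0, 100, 0.0)],
    )
    def test_printed_scores(self, count, total, score):
        # denominators are the genes' pooled codon totals (pairs + transcripts)
        assert cu.adjusted_pair_score(count, total) == score

    def test_rejects_bad_totals(self):
        with pytest.raises(ValueError):
            cu.adjusted_pair_score(1, 0)
        with pytest.raises(ValueError):
            cu.adjusted_pair_score(5, 4)


class TestTopPairs:
    def test_dominant_pair_first(self):
        rec = cu.CdsRecord("t", "g", "ATG" + "GAAGAA" * 30 + "GCC" + "TAA")
        table = cu.count_pairs([rec])
        top = cu.top_pairs(table, k=3)
        assert top.iloc[0]["pair"] == "GAA-GAA"

    def test_tie_break_descending_pair_string(self):
        obs = np.zeros((64, 64))
        idx = {c: i for i, c in enumerate(CODONS)}
        obs[idx["GTG"], idx["GAA"]] = 44
        obs[idx["GAA"], idx["GCC"]] = 44
        obs[idx["AAA"], idx["AAA"]] = 90
        top = cu.top_pairs(PairTable(observed=obs), k=3)
        assert list(top["pair"]) == ["AAA-AAA", "GTG-GAA", "GAA-GCC"]

    def test_k_larger_than_nonzero_returns_all(self, tiny_record):
        table = cu.count_pairs([tiny_record])
        assert len(cu.top_pairs(table, k=100)) == 2

    def test_scores_in_output(self, four_gene_set):
        table = cu.count_pairs(four_gene_set["CCND1"])
        top = cu.top_pairs(table, k=15)
        first = top.iloc[0]
        assert first["adjusted_score"] == cu.adjusted_pair_score(
            int(first["count"]), table.score_denominator
        )


class TestContextResiduals:
    def test_row_margins_sum_to_zero(self, four_gene_set):
        table = cu.count_pairs(four_gene_set["APP"])
        diff = table.observed - table.expected()
        assert np.allclose(diff.sum(axis=1), 0.0, atol=1e-8)
        assert np.allclose(diff.sum(axis=0), 0.0, atol=1e-8)

    def test_independence_keeps_residuals_in_band(self, code):
        """Codons drawn independently: ≥99% of populated cells within ±5."""
        spec = cu.GeneratorSpec(
            genes={"I": cu.GeneSpec(n_transcripts=6, lengths=(9000,))},
            seed=42,
        )
        gs = cu.generate_gene_set(spec)
        table = cu.count_pairs(gs["I"])
        res = cu.context_residuals(table)
        populated = res[~np.isnan(res)]
        frac = np.mean(np.abs(populated) <= 5.0)
        assert frac >= 0.99

    def test_forced_cooccurrence_exceeds_plus_5(self):
        spec = cu.GeneratorSpec(
            genes={
                "M": cu.GeneSpec(
                    n_transcripts=4,
                    lengths=(6000,),
                    pair_motifs=(("CAA", "GAA", 0.08),),
                )
            },
            seed=7,
        )
        gs = cu.generate_gene_set(spec)
        table = cu.count_pairs(gs["M"])
        res = cu.context_residuals(table)
        idx = {c: i for i, c in enumerate(CODONS)}
        assert res[idx["CAA"], idx["GAA"]] > 5.0

    def test_transpose_consistency(self, four_gene_set):
        table = cu.count_pairs(four_gene_set["PTPA"])
        classes = cu.classify_context(cu.context_residuals(table))
        transposed = cu.classify_context(
            cu.context_residuals(PairTable(observed=table.observed.T))
        )
        assert (classes.T == transposed).all()

    def test_degenerate_table_raises(self):
        obs = np.zeros((64, 64))
        obs[0, 1] = 5
        with pytest.raises(ValueError, match="degenerate"):
            cu.context_residuals(PairTable(observed=obs))


class TestClassifyContext:
    @pytest.mark.parametrize(
        "value, klass",
        [(6.2, "good"), (-7.0, "bad"), (4.9, "not_significant"),
         (-5.0, "not_significant"), (np.nan, "absent")],
    )
    def test_band(self, value, klass):
        res = np.array([[value, 0.0], [0.0, 0.0]])
        assert cu.classify_context(res)[0, 0] == klass


class TestStartContext:
    def test_constant_second_codon(self):
        recs = [
            cu.CdsRecord(f"t{i}", "g", "ATGAAG" + "GCA" * 5 + "TAA")
            for i in range(4)
        ]
        sc = cu.start_context(recs)
        assert sc.iloc[0]["codon"] == "AAG"
        assert sc.iloc[0]["frequency"] == 1.0

    def test_tie_broken_lexicographically(self):
        recs = [
            cu.CdsRecord("t1", "g", "ATGTTTTAA"),
            cu.CdsRecord("t2", "g", "ATGAAATAA"),
        ]
        sc = cu.start_context(recs)
        assert list(sc["codon"]) == ["AAA", "TTT"]
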