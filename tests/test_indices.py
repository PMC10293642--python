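import math

import numpy as np
import pytest

import codonusage as cu
from codonusage.genetic_code import CodonCountTable


def counts_of(d):
    return CodonCountTable(counts=d)


class TestRscu:
    def test_uniform_two_fold(self, code):
        v = cu.rscu(counts_of({"TTT": 10, "TTC": 10}), code)
        assert v["TTT"] == v["TTC"] == 1.0

    def test_leucine_hand_computation(self, code):
        # family total 3, degeneracy 6 → expected 0.5 per codon
        v = cu.rscu(counts_of({"CTG": 2, "CTT": 1}), code)
        assert v["CTG"] == 4.0
        assert v["CTT"] == 2.0
        assert v["CTA"] == 0.0

    def test_zero_family_flagged(self, code):
        v = cu.rscu(counts_of({"TTT": 5}), code)
        assert "L" in v.zero_families
        assert v["CTG"] == 0.0

    def test_family_sums_equal_degeneracy_random_tables(self, code):
        """Within every used family, RSCU sums to the family degeneracy
        (checked over 1,000 random count tables)."""
        rng = np.random.default_rng(2024)
        codons = list(code.synonymous_codons)
        for _ in range(1000):
            raw = rng.integers(0, 30, size=len(codons))
            v = cu.rscu(counts_of(dict(zip(codons, map(int, raw)))), code)
            for aa, fam in code.families.items():
                if len(fam) == 1:
                    continue
                total = sum(v[c] for c in fam)
                if aa in v.zero_families:
                    assert total == 0.0
                else:
                    assert math.isclose(total, len(fam), rel_tol=1e-12)

    @pytest.mark.parametrize(
        "value, klass",
        [(1.7, "overrepresented"), (1.0, "random"), (1.6, "random"),
         (0.6, "random"), (0.5, "underrepresented")],
    )
    def test_classification_thresholds(self, value, klass):
        v = cu.RscuVector(values={"TTT": value})
        assert cu.classify_rscu(v)["TTT"] == klass


class TestCai:
    def test_all_preferred_codons(self, code):
        ref = cu.default_human_reference(code)
        preferred = {}
        for aa, fam in code.families.items():
            if len(fam) > 1:
                best = max(fam, key=lambda c: ref.weights[c])
                preferred[best] = 10
        assert cu.cai(counts_of(preferred), ref, code) == pytest.approx(1.0)

    def test_uniform_reference_gives_one(self, code):
        ref = cu.ReferenceWeights.uniform(code)
        assert cu.cai(counts_of({"CTA": 7, "GGG": 3}), ref, code) == 1.0

    def test_constant_weight_is_geometric_mean(self, code):
        ref = cu.ReferenceWeights(
            weights={"TTT": 0.5, "TTC": 1.0}, provenance="test"
        )
        assert cu.cai(counts_of({"TTT": 42}), ref, code) == pytest.approx(0.5)

    def test_scale_invariance(self, four_gene_set, code):
        """Duplicating a transcript leaves CAI unchanged."""
        ref = cu.default_human_reference(code)
        rec = four_gene_set["CCND1"][0]
        once = CodonCountTable.from_records([rec])
        twice = CodonCountTable.from_records([rec, rec])
        assert cu.cai(once, ref, code) == pytest.approx(
            cu.cai(twice, ref, code), rel=1e-12
        )

    def test_zero_count_reference_codons_get_pseudocount(self, code):
        ref = cu.ReferenceWeights.from_counts({"TTT": 10}, code)
        assert 0 < ref.weights["TTC"] < 1
        assert ref.weights["TTT"] == 1.0


class TestEnc:
    def test_one_codon_per_family_is_20(self, code):
        counts = {}
        for aa, fam in code.families.items():
            if len(fam) > 1:
                counts[fam[0]] = 500
        assert cu.enc(counts_of(counts), code) == pytest.approx(20.0)

    def test_uniform_usage_approaches_61(self, code):
        spec = cu.GeneratorSpec(
            genes={"U": cu.GeneSpec(n_transcripts=1, lengths=(90000,))},
            seed=5,
        )
        rec = cu.generate_cds(spec, "U")
        counts = CodonCountTable.from_records([rec])
        assert cu.enc(counts, code) == pytest.approx(61.0, abs=1.0)

    def test_one_hot_generator_approaches_20(self, code):
        weights = {
            aa: {max(fam): 1.0}
            for aa, fam in code.families.items()
            if len(fam) > 1
        }
        spec = cu.GeneratorSpec(
            genes={"H": cu.GeneSpec(lengths=(30000,), codon_weights=weights)},
            seed=5,
        )
        rec = cu.generate_cds(spec, "H")
        counts = CodonCountTable.from_records([rec])
        assert cu.enc(counts, code) == pytest.approx(20.0, abs=0.5)

    def test_range_clamped_on_random_tables(self, code):
        rng = np.random.default_rng(7)
        codons = list(code.synonymous_codons)
        for _ in range(200):
            raw = rng.integers(0, 8, size=len(codons))
            table = counts_of(dict(zip(codons, map(int, raw))))
            if table.total == 0:
                continue
            try:
                value = cu.enc(table, code)
            except ValueError:
                continue
            assert 20.0 <= value <= 61.0

    def test_missing_ile_family_imputed(self, code):
        # all families present except the single three-fold one
        counts = {}
        rng = np.random.default_rng(3)
        for aa, fam in code.families.items():
            if len(fam) > 1 and aa != "I":
                for c in fam:
                    counts[c] = int(rng.integers(5, 20))
        value = cu.enc(counts_of(counts), code)
        assert 20.0 <= value <= 61.0


class TestEncExpected:
    @pytest.mark.parametrize("s, expected", [(0.5, 60.5), (0.0, 31.0), (1.0, 32.0)])
    def test_closed_form(self, s, expected):
        assert cu.enc_expected(s) == pytest.approx(expected)

    def test_symmetry_and_maximum(self):
        grid = np.linspace(0, 1, 101)
        vals = [cu.enc_expected(s) - s for s in grid]  # symmetric part
        for s in grid:
            assert cu.enc_expected(s) - s == pytest.approx(
                cu.enc_expected(1 - s) - (1 - s)
            )
        assert max(range(101), key=lambda i: vals[i]) == 50

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            cu.enc_expected(1.2)

    @pytest.mark.parametrize(
        "delta, klass",
        [(0.0, "on_curve"), (-1.5, "near_curve"), (-10.0, "below_curve"),
         (10.0, "above_curve")],
    )
    def test_curve_classification(self, delta, klass):
        s = 0.4
        assert cu.enc_gc3_classify(cu.enc_expected(s) + delta, s) == klass


def scs_oracle(counts, code):
    """Independent per-family chi-square / n, coded from the definition."""
    chi = 0.0
    n = 0
    for aa, fam in code.families.items():
        if len(fam) == 1:
            continue
        obs = [counts.get(c) for c in fam]
        tot = sum(obs)
        if tot == 0:
            continue
        n += tot
        e = tot / len(fam)
        chi += sum((o - e) ** 2 / e for o in obs)
    return chi / n


class TestScaledChiSquare:
    def test_equal_usage_is_zero(self, code):
        counts = {c: 4 for c in code.synonymous_codons}
        assert cu.scaled_chi_square(counts_of(counts), code) == pytest.approx(0.0)

    def test_exclusive_two_fold_usage_is_one(self, code):
        assert cu.scaled_chi_square(counts_of({"TTT": 50}), code) == pytest.approx(1.0)

    def test_matches_brute_force_oracle(self, code):
        rng = np.random.default_rng(99)
        codons = list(code.synonymous_codons)
        for _ in range(1000):
            raw = rng.integers(0, 12, size=len(codons))
            table = counts_of(dict(zip(codons, map(int, raw))))
            if table.total == 0:
                continue
            assert cu.scaled_chi_square(table, code) == pytest.approx(
                scs_oracle(table, code), rel=1e-12
            )

    def test_met_trp_do_not_contribute(self, code):
        a = cu.scaled_chi_square(counts_of({"TTT": 9, "TTC": 3}), code)
        b = cu.scaled_chi_square(
            counts_of({"TTT": 9, "TTC": 3, "ATG": 50, "TGG": 50}), code
        )
        assert a == pytest.approx(b)


class TestProteinIndices:
    def test_gravy_hand_values(self):
        assert cu.gravy("AG") == pytest.approx(0.7)  # (1.8 − 0.4)/2
        assert cu.gravy("III") == pytest.approx(4.5)
        assert cu.gravy("KKK") < 0

    def test_gravy_unknown_residue(self):
        with pytest.raises(ValueError, match="unknown residue"):
            cu.gravy("AXA")

    @pytest.mark.parametrize(
        "protein, frac", [("FYW", 1.0), ("AAAA", 0.0), ("AAAF", 0.25)]
    )
    def test_aroma(self, protein, frac):
        assert cu.aroma(protein) == frac


class TestPr2:
    def test_balanced_thirds(self, code):
        codons = ["GCA", "GCT", "GCG", "GCC"] * 5  # Ala: thirds A/T/G/C equal
        assert cu.pr2(codons, code) == (0.5, 0.5)

    def test_all_g_thirds(self, code):
        x, y = cu.pr2(["GCG", "CTG"] * 3, code)
        assert x == 1.0
        assert math.isnan(y)

    def test_all_a_thirds_undefined_x(self, code):
        x, y = cu.pr2(["GCA"] * 4, code)
        assert y == 1.0
        assert math.isnan(x)

    def test_stops_excluded(self, code):
        with_stop = cu.pr2(["GCA", "GCT", "TAA"], code)
        without = cu.pr2(["GCA", "GCT"], code)
        assert with_stop[1] == without[1] == 0.5
        assert math.isnan(with_stop[0]) and math.isnan(without[0])

    def test_fourfold_only_mode(self, code):
        # AAA (Lys, two-fold) ignored in the four-fold-only span
        x, y = cu.pr2(["GCA", "GCT", "AAA", "AAA"], code, fourfold_only=True)
        assert y == 0.5
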