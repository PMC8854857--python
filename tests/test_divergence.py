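import itertools
import math

import numpy as np
import pytest

from conftest import random_seq
from plastidcomp.divergence import (
    UndefinedStatisticError,
    alignment_from_strings,
    classify_sites,
    divergence_matrix,
    hypervariable_regions,
    nucleotide_diversity,
    pairwise_divergence,
    read_alignment,
    region_variability,
    sliding_windows,
)
from plastidcomp.io import Feature, FeatureTable, FormatError, ValidationError


class TestReadAlignment:
    def test_identity_maps_on_gapless_rows(self):
        aln = alignment_from_strings(["a", "b"], ["ACGTACGTAC", "ACGTACGTAC"])
        assert aln.length == 10
        assert [aln.pos_of_col("a", c) for c in (1, 5, 10)] == [1, 5, 10]

    def test_column_map_skips_gaps(self):
        aln = alignment_from_strings(["a"], ["AC-GT"])
        assert [aln.pos_of_col("a", c) for c in range(1, 6)] == [1, 2, 0, 3, 4]
        assert [aln.col_of_pos("a", p) for p in range(1, 5)] == [1, 2, 4, 5]

    def test_ragged_rows_rejected(self, tmp_path):
        p = tmp_path / "bad.fasta"
        p.write_text(">a\nACGT\n>b\nAC\n")
        with pytest.raises(FormatError):
            read_alignment(p)

    def test_ungapping_reproduces_input(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">a\nAC--GTA\n>b\nACGTGT-\n")
        aln = read_alignment(p)
        assert aln.ungapped("a") == "ACGTA"
        assert aln.ungapped("b") == "ACGTGT"


class TestSiteClasses:
    def test_identical_rows_have_no_variation(self):
        aln = alignment_from_strings(list("abcd"), ["ACGT"] * 4)
        s = classify_sites(aln)
        assert (s.variable_sites, s.parsimony_informative_sites) == (0, 0)

    def test_definitions_on_constructed_columns(self):
        # col1 A/A/C/C: variable + informative; col2 A/A/A/G: variable singleton
        rows = ["AA", "AA", "CA", "CG"]
        s = classify_sites(alignment_from_strings(list("abcd"), rows))
        assert s.variable_sites == 2
        assert s.parsimony_informative_sites == 1
        assert s.singleton_sites == 1

    def test_gapped_and_n_columns_excluded(self):
        rows = ["A-GN", "ACGA", "ACGA", "ACGA"]
        s = classify_sites(alignment_from_strings(list("abcd"), rows))
        assert s.gap_free_columns == 2

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_per_column_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        rows = [
            "".join(rng.choice(list("ACGT-N"), size=500, p=[0.23, 0.23, 0.23, 0.23, 0.05, 0.03]))
            for _ in range(4)
        ]
        s = classify_sites(alignment_from_strings(list("abcd"), rows))
        var = inf = gapfree = 0
        for col in zip(*rows):
            if any(c in "-N" for c in col):
                continue
            gapfree += 1
            counts = {b: col.count(b) for b in set(col)}
            if len(counts) >= 2:
                var += 1
                if sum(1 for v in counts.values() if v >= 2) >= 2:
                    inf += 1
        assert (s.gap_free_columns, s.variable_sites, s.parsimony_informative_sites) == (
            gapfree, var, inf,
        )

    def test_invariant_ordering(self):
        rng = np.random.default_rng(9)
        rows = ["".join(rng.choice(list("ACGT-"), size=300)) for _ in range(5)]
        s = classify_sites(alignment_from_strings(list("abcde"), rows))
        assert s.parsimony_informative_sites <= s.variable_sites <= s.gap_free_columns
        assert s.singleton_sites + s.parsimony_informative_sites <= s.variable_sites


class TestDiversity:
    def test_identical_pair_zero(self):
        aln = alignment_from_strings(["a", "b"], ["ACGTACGTAC"] * 2)
        d = nucleotide_diversity(aln)
        assert d.pi == 0 and d.theta == 0

    def test_two_rows_closed_form(self):
        aln = alignment_from_strings(["a", "b"], ["ACGTACGTAC", "ACGTACGTAT"])
        d = nucleotide_diversity(aln)
        assert d.pi == pytest.approx(0.1)
        assert d.theta == pytest.approx(0.1)  # a_1 = 1

    def test_three_rows_closed_form(self):
        # pairwise diffs: ab=1, ac=2, bc=1 over 4 sites -> pi = (4/3)/4
        aln = alignment_from_strings(["a", "b", "c"], ["AAAA", "AAAC", "AAGC"])
        d = nucleotide_diversity(aln)
        assert d.pi == pytest.approx((1 + 2 + 1) / 3 / 4)
        assert d.S == 2
        assert d.theta == pytest.approx(2 / ((1 + 0.5) * 4))

    def test_pairwise_mean_matches_brute_force(self):
        rng = np.random.default_rng(11)
        rows = ["".join(rng.choice(list("ACGT"), size=200)) for _ in range(5)]
        aln = alignment_from_strings(list("abcde"), rows)
        d = nucleotide_diversity(aln)
        pairs = list(itertools.combinations(range(5), 2))
        manual = np.mean(
            [sum(x != y for x, y in zip(rows[i], rows[j])) / 200 for i, j in pairs]
        )
        assert d.pi == pytest.approx(manual)

    def test_theta_definition_consistent_with_site_classes(self):
        rng = np.random.default_rng(12)
        rows = ["".join(rng.choice(list("ACGT-"), size=400)) for _ in range(4)]
        aln = alignment_from_strings(list("abcd"), rows)
        d = nucleotide_diversity(aln)
        s = classify_sites(aln)
        assert d.S == s.variable_sites
        a_n = 1 + 1 / 2 + 1 / 3
        assert d.theta == pytest.approx(d.S / (a_n * d.L))

    def test_all_gap_columns_undefined(self):
        aln = alignment_from_strings(["a", "b"], ["---", "AC-"])
        with pytest.raises(UndefinedStatisticError):
            nucleotide_diversity(aln)


class TestWindows:
    def test_window_starts_600_200(self):
        aln = alignment_from_strings(["a", "b"], ["A" * 1000] * 2)
        ws = sliding_windows(aln, 600, 200)
        assert [(w.start, w.end) for w in ws] == [(1, 600), (201, 800), (401, 1000)]
        assert not any(w.partial for w in ws)

    def test_final_partial_window_flagged(self):
        aln = alignment_from_strings(["a", "b"], ["A" * 700] * 2)
        ws = sliding_windows(aln, 600, 200)
        assert ws[-1].partial and ws[-1].end == 700

    def test_window_larger_than_alignment_single_window(self):
        aln = alignment_from_strings(["a", "b"], ["ACGTACGT"] * 2)
        ws = sliding_windows(aln, 600, 200)
        assert len(ws) == 1 and (ws[0].start, ws[0].end) == (1, 8)

    def test_peak_localizes_planted_variation(self):
        rng = np.random.default_rng(13)
        base = random_seq(rng, 2000)
        other = list(base)
        for i in range(100):  # heavy variation in the first 100 columns
            other[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[other[i]]
        aln = alignment_from_strings(["a", "b"], [base, "".join(other)])
        ws = sliding_windows(aln, 600, 200)
        best = max(ws, key=lambda w: w.pi)
        assert best.start == 1

    def test_pi_conservation_over_partitioning_windows(self):
        """Whole-alignment pi is the gap-free-weighted mean of window pi when
        the windows tile the columns without overlap."""
        rng = np.random.default_rng(14)
        rows = ["".join(rng.choice(list("ACGT-"), size=1200, p=[0.24] * 4 + [0.04]))
                for _ in range(4)]
        aln = alignment_from_strings(list("abcd"), rows)
        ws = sliding_windows(aln, 300, 300)
        whole = nucleotide_diversity(aln)
        num = sum(w.pi * w.gap_free for w in ws if w.gap_free)
        den = sum(w.gap_free for w in ws)
        assert whole.pi == pytest.approx(num / den)
        assert den == whole.L


class TestHypervariable:
    def _mk(self, rng, hotspots, L=4000, n=4, p0=0.002, p1=0.08):
        base = random_seq(rng, L)
        rows = [base]
        for _ in range(n - 1):
            row = list(base)
            for i in range(L):
                rate = p1 if any(s <= i < e for s, e in hotspots) else p0
                if rng.random() < rate:
                    row[i] = rng.choice([b for b in "ACGT" if b != row[i]])
            rows.append("".join(row))
        return alignment_from_strings([f"s{i}" for i in range(n)], rows)

    def test_single_peak_annotated_with_feature(self):
        rng = np.random.default_rng(15)
        aln = self._mk(rng, [(1000, 1400)])
        ws = sliding_windows(aln, 300, 100)
        table = FeatureTable("s0", [Feature("clpPx", "gene", "+", [(900, 1500)])], 4000)
        regions = hypervariable_regions(ws, aln, table, k=1)
        assert len(regions) == 1
        assert "clpPx" in regions[0].features

    def test_planted_hotspots_recovered(self):
        rng = np.random.default_rng(16)
        hot = [(500, 800), (1900, 2200), (3300, 3600)]
        aln = self._mk(rng, hot)
        ws = sliding_windows(aln, 300, 100)
        regions = hypervariable_regions(ws, aln, None, k=3)
        for s, e in hot:
            assert any(r.start <= e and r.end >= s for r in regions)

    def test_tie_broken_by_coordinate(self):
        aln = alignment_from_strings(["a", "b"], ["AAAA" * 200, "AAAA" * 200])
        ws = sliding_windows(aln, 100, 100)
        regions = hypervariable_regions(ws, aln, None, k=2)
        assert regions[0].start < regions[1].start


class TestPairwise:
    def test_single_gap_run_is_one_indel(self):
        aln = alignment_from_strings(["x", "y"], ["AC---GT", "ACAAAGT"])
        d = pairwise_divergence(aln, "x", "y")
        assert (d.indel_events, d.substitutions) == (1, 0)

    def test_substitutions_counted_per_column(self):
        aln = alignment_from_strings(["x", "y"], ["ACGT", "TCGA"])
        d = pairwise_divergence(aln, "x", "y")
        assert (d.indel_events, d.substitutions) == (0, 2)

    def test_shared_gap_columns_fuse_interrupted_runs(self):
        # x's run is interrupted only by a both-gap column: one event
        aln = alignment_from_strings(["x", "y"], ["A---C", "A-GTC"])
        d = pairwise_divergence(aln, "x", "y")
        assert d.indel_events == 1

    def test_symmetry_and_diagonal(self):
        rng = np.random.default_rng(17)
        rows = ["".join(rng.choice(list("ACGT-"), size=300)) for _ in range(3)]
        aln = alignment_from_strings(list("abc"), rows)
        for i, j in itertools.combinations(range(3), 2):
            d1, d2 = pairwise_divergence(aln, i, j), pairwise_divergence(aln, j, i)
            assert (d1.indel_events, d1.substitutions) == (d2.indel_events, d2.substitutions)
        d = pairwise_divergence(aln, 1, 1)
        assert (d.indel_events, d.substitutions) == (0, 0)

    def test_matrix_triangles(self):
        aln = alignment_from_strings(["x", "y"], ["AC---GT", "TCAAAGT"])
        df = divergence_matrix(aln)
        assert df.loc["x", "y"] == 1  # indels upper
        assert df.loc["y", "x"] == 1  # substitutions lower


class TestRegionVariability:
    def test_identical_region_zero_percent(self):
        aln = alignment_from_strings(["r", "s"], ["ACGTACGTAC"] * 2)
        table = FeatureTable("r", [Feature("g1", "gene", "+", [(1, 10)])], 10)
        df = region_variability(aln, table)
        assert df.loc[df.region == "g1", "percent_variable"].item() == 0.0

    def test_region_deleted_in_other_taxa_reaches_100(self):
        aln = alignment_from_strings(["r", "s"], ["ACGTACGTAC", "AC------AC"])
        table = FeatureTable("r", [Feature("mid", "gene", "+", [(3, 8)])], 10)
        df = region_variability(aln, table)
        assert df.loc[df.region == "mid", "percent_variable"].item() == 100.0

    def test_planted_rate_ordering(self):
        rng = np.random.default_rng(18)
        base = random_seq(rng, 3000)
        row = list(base)
        for i in range(3000):
            rate = 0.01 if i < 1500 else 0.08
            if rng.random() < rate:
                row[i] = rng.choice([b for b in "ACGT" if b != row[i]])
        aln = alignment_from_strings(["r", "s"], [base, "".join(row)])
        table = FeatureTable(
            "r",
            [Feature("low", "gene", "+", [(1, 1500)]), Feature("high", "gene", "+", [(1501, 3000)])],
            3000,
        )
        df = region_variability(aln, table).set_index("region")
        assert df.loc["low", "percent_variable"] < df.loc["high", "percent_variable"]

    def test_pooled_coding_vs_noncoding(self):
        aln = alignment_from_strings(["r", "s"], ["ACGTACGTAC", "ACGAACGTTC"])
        table = FeatureTable(
            "r",
            [Feature("g", "gene", "+", [(1, 4)]), Feature("g-h", "intergenic", "+", [(5, 10)])],
            10,
        )
        df = region_variability(aln, table)
        assert df.attrs["percent_coding"] == 25.0
        assert df.attrs["percent_noncoding"] == pytest.approx(round(100 / 6, 2))
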