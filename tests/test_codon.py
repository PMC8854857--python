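import itertools
import math

import numpy as np
import pytest

from oracles import codon_translate, oracle_pathway_counts, oracle_syn_sites
from plastidcomp.codon import (
    CodonAlignment,
    ValidationError,
    build_codon_alignment,
    dnds_matrix,
    dnds_table,
    jukes_cantor,
    ng86_pair,
    pathway_differences,
    syn_site_fraction,
)
from plastidcomp.io import CircularGenome, Feature, FeatureTable

SENSE_CODONS = [
    "".join(c)
    for c in itertools.product("TCAG", repeat=3)
    if codon_translate("".join(c)) != "*"
]


class TestSitesAndPathways:
    def test_site_fractions_match_translation_oracle(self):
        for codon in SENSE_CODONS:
            assert syn_site_fraction(codon) == pytest.approx(oracle_syn_sites(codon))

    def test_pathway_counts_match_enumeration_oracle(self):
        """Every sense-codon pair (0-3 differences) agrees with exhaustive
        minimal-pathway enumeration."""
        for c1, c2 in itertools.combinations(SENSE_CODONS, 2):
            got = pathway_differences(c1, c2)
            want = oracle_pathway_counts(c1, c2)
            assert got == pytest.approx(want), (c1, c2)

    def test_pathway_symmetry(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            c1, c2 = rng.choice(SENSE_CODONS, size=2)
            assert pathway_differences(c1, c2) == pytest.approx(
                pathway_differences(c2, c1)
            )


class TestNG86Pair:
    def test_identical_sequences_zero(self):
        r = ng86_pair("ATGAAACCC", "ATGAAACCC")
        assert (r.Sd, r.Nd, r.dS, r.dN) == (0, 0, 0, 0)

    def test_phe_ten_codon_worked_example(self):
        """10 Phe codons with one synonymous third-position change:
        S = 10/3, pS = 0.3, dS = -(3/4) ln(0.6) ~ 0.3831, dN = 0."""
        r = ng86_pair("TTT" * 10, "TTT" * 9 + "TTC")
        assert r.S == pytest.approx(10 / 3)
        assert r.Sd == 1 and r.Nd == 0
        assert r.pS == pytest.approx(0.3)
        assert r.dS == pytest.approx(0.3831, abs=1e-4)
        assert r.dN == 0

    def test_symmetry(self):
        a, b = "ATGAAACCCGGG", "ATGAAGCCAGGA"
        r1, r2 = ng86_pair(a, b), ng86_pair(b, a)
        assert (r1.S, r1.N, r1.Sd, r1.Nd) == pytest.approx((r2.S, r2.N, r2.Sd, r2.Nd))

    def test_site_conservation(self):
        rng = np.random.default_rng(1)
        codons = rng.choice(SENSE_CODONS, size=40)
        seq_a = "".join(codons)
        seq_b = "".join(rng.choice(SENSE_CODONS, size=40))
        r = ng86_pair(seq_a, seq_b)
        assert r.S + r.N == pytest.approx(3 * r.codons_used, abs=1e-9)

    def test_gapped_codons_dropped_pairwise(self):
        r = ng86_pair("ATG---CCC", "ATGAAACCC")
        assert r.codons_used == 2

    def test_purely_synonymous_changes_give_zero_dn(self):
        """Third-position synonymous swaps within 4-fold codon families."""
        fourfold = ["CT", "GT", "TC", "CC", "AC", "GC", "CG", "GG"]
        rng = np.random.default_rng(2)
        pre, post = [], []
        for stem in fourfold * 3:
            b1, b2 = rng.choice(list("ACGT"), size=2, replace=False)
            pre.append(stem + b1)
            post.append(stem + b2)
        r = ng86_pair("".join(pre), "".join(post))
        assert r.Nd == 0 and r.dN == 0
        assert r.Sd == len(pre)

    def test_saturation_flagged_as_infinite(self):
        assert math.isinf(jukes_cantor(0.8))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            ng86_pair("ATGAAA", "ATG")


def _orf(codons):
    return "ATG" + "".join(codons) + "TAA"


def _genome_with_genes(gid, genes):
    """genes: dict name -> (cds_with_stop, pseudo)."""
    seq_parts, feats, pos = [], [], 1
    spacer = "CCAATTGGCCAATTGGCCAATTGG"
    for name, (cds, pseudo) in genes.items():
        seq_parts.append(spacer)
        pos += len(spacer)
        feats.append(Feature(name, "gene", "+", [(pos, pos + len(cds) - 1)], pseudo=pseudo))
        seq_parts.append(cds)
        pos += len(cds)
    seq_parts.append(spacer)
    g = CircularGenome(gid, "".join(seq_parts))
    return g, FeatureTable(gid, feats, genome_length=g.length)


class TestBuildCodonAlignment:
    def test_terminal_stop_stripped(self):
        g1, t1 = _genome_with_genes("a", {"g1": ("ATGAAATAA", False)})
        g2, t2 = _genome_with_genes("b", {"g1": ("ATGAAATAA", False)})
        ca = build_codon_alignment({"a": g1, "b": g2}, {"a": t1, "b": t2})
        assert ca.sequences == {"a": "ATGAAA", "b": "ATGAAA"}

    def test_gene_missing_in_one_taxon_excluded(self):
        g1, t1 = _genome_with_genes("a", {"g1": ("ATGAAATAA", False), "g2": ("ATGCCCTAA", False)})
        g2, t2 = _genome_with_genes("b", {"g1": ("ATGAAATAA", False)})
        ca = build_codon_alignment({"a": g1, "b": g2}, {"a": t1, "b": t2})
        assert ca.genes_used == ["g1"]
        assert "absent" in ca.genes_excluded["g2"]

    def test_pseudogene_in_any_taxon_excluded_for_all(self):
        g1, t1 = _genome_with_genes("a", {"g1": ("ATGAAATAA", True)})
        g2, t2 = _genome_with_genes("b", {"g1": ("ATGAAATAA", False)})
        ca = build_codon_alignment({"a": g1, "b": g2}, {"a": t1, "b": t2})
        assert ca.genes_used == []
        assert "pseudo" in ca.genes_excluded["g1"]

    def test_internal_stop_excluded_not_fatal(self):
        g1, t1 = _genome_with_genes("a", {"g1": ("ATGTAAAAATAA", False), "g2": ("ATGCCCTAA", False)})
        g2, t2 = _genome_with_genes("b", {"g1": ("ATGTAAAAATAA", False), "g2": ("ATGCCCTAA", False)})
        ca = build_codon_alignment({"a": g1, "b": g2}, {"a": t1, "b": t2})
        assert ca.genes_used == ["g2"]
        assert "internal stop" in ca.genes_excluded["g1"]

    def test_minus_strand_gene_extracted_in_frame(self):
        cds = "ATGAAACCCTAA"
        from plastidcomp.io import revcomp

        flank = "CCAATTGG"
        seq = flank + revcomp(cds) + flank
        g = CircularGenome("a", seq)
        t = FeatureTable(
            "a", [Feature("g1", "gene", "-", [(len(flank) + 1, len(flank) + len(cds))])],
            genome_length=g.length,
        )
        ca = build_codon_alignment({"a": g}, {"a": t})
        assert ca.sequences["a"] == "ATGAAACCC"

    def test_concatenation_order_alphabetical(self):
        genes = {"zzz": ("ATGGGGTAA", False), "aaa": ("ATGAAATAA", False)}
        g1, t1 = _genome_with_genes("a", genes)
        g2, t2 = _genome_with_genes("b", genes)
        ca = build_codon_alignment({"a": g1, "b": g2}, {"a": t1, "b": t2})
        assert ca.genes_used == ["aaa", "zzz"]
        assert ca.sequences["a"] == "ATGAAA" + "ATGGGG"


class TestDndsMatrix:
    def _aln(self, seqs):
        return CodonAlignment(ids=list(seqs), sequences=seqs, genes_used=["g"])

    def test_extreme_ds_filtered_with_reason(self):
        rng = np.random.default_rng(3)
        fourfold = ["CT", "GT", "TC", "CC", "AC", "GC", "CG", "GG"]
        a = "".join(s + "A" for s in fourfold)
        b = "".join(s + "G" for s in fourfold)  # all synonymous -> huge dS
        rates = dnds_matrix(self._aln({"x": a, "y": b}), {"dn_max": 0.5, "ds_max": 0.5, "ds_min": 0.0005})
        assert rates[0].filtered and "dS >" in rates[0].filter_reason

    def test_tiny_ds_filtered(self):
        a = "GGA" * 4000
        b = "GGG" + "GGA" * 3999
        rates = dnds_matrix(self._aln({"x": a, "y": b}))
        assert rates[0].filtered and "dS <" in rates[0].filter_reason

    def test_zero_zero_pair_is_na_not_filtered(self):
        rates = dnds_matrix(self._aln({"x": "ATGAAA", "y": "ATGAAA"}))
        assert not rates[0].filtered
        assert math.isnan(rates[0].omega)
        assert "NA" in dnds_table(rates).values

    def test_synonymous_biased_evolution_recovers_purifying_signal(self):
        """Descendants evolved with a 3:1 synonymous:nonsynonymous change
        bias should all show omega < 1."""
        rng = np.random.default_rng(4)
        anc = list(rng.choice(SENSE_CODONS, size=400))
        taxa = {}
        for t in range(4):
            codons = list(anc)
            for _ in range(60):
                i = int(rng.integers(len(codons)))
                c = codons[i]
                syn = [
                    alt for alt in SENSE_CODONS
                    if sum(x != y for x, y in zip(alt, c)) == 1
                    and codon_translate(alt) == codon_translate(c)
                ]
                non = [
                    alt for alt in SENSE_CODONS
                    if sum(x != y for x, y in zip(alt, c)) == 1
                    and codon_translate(alt) != codon_translate(c)
                ]
                pool = syn if (rng.random() < 0.75 and syn) else non
                if pool:
                    codons[i] = pool[int(rng.integers(len(pool)))]
            taxa[f"t{t}"] = "".join(codons)
        rates = dnds_matrix(self._aln(taxa))
        omegas = [r.omega for r in rates if not math.isnan(r.omega)]
        assert omegas and all(w < 1 for w in omegas)
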