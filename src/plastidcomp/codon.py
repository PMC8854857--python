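"""Concatenated codon alignments and Nei–Gojobori (1986) pairwise dN/dS.

The NG86 estimator counts, for each codon, the fraction of one-step changes
that are synonymous (the codon's synonymous "sites"), and resolves codons
differing at several positions by averaging the synonymous/nonsynonymous
split over all minimal mutational pathways, excluding pathways passing
through stop codons.  Proportions are corrected for multiple hits with the
Jukes–Cantor formula d = -(3/4) ln(1 - (4/3) p).

Changes that create a stop codon are counted as nonsynonymous in the site
fractions (the denominator stays 3 per position); when every pathway between
two codons passes through a stop, the average is taken over all pathways.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from functools import lru_cache

from Bio.Data import CodonTable

from .io import CircularGenome, FeatureTable, ValidationError, revcomp

#: dN/dS extreme-value filters: saturated or misassigned pairs are excluded.
DEFAULT_FILTERS = {"dn_max": 0.5, "ds_max": 5.0, "ds_min": 0.0005}

_NUCS = "TCAG"


@lru_cache(maxsize=None)
def _code(table_id: int = 1):
    """(codon -> amino acid, set of stop codons) for an NCBI table id."""
    tab = CodonTable.unambiguous_dna_by_id[table_id]
    return dict(tab.forward_table), frozenset(tab.stop_codons)


@lru_cache(maxsize=None)
def syn_site_fraction(codon: str, table_id: int = 1) -> float:
    """Number of synonymous sites of a codon (0..3).

    Each position contributes (# synonymous one-step changes) / 3; mutations
    to stop codons count as nonsynonymous.
    """
    fwd, stops = _code(table_id)
    if codon in stops:
        raise ValidationError(f"stop codon {codon} has no site decomposition")
    aa = fwd[codon]
    s = 0.0
    for pos in range(3):
        for nuc in _NUCS:
            if nuc == codon[pos]:
                continue
            alt = codon[:pos] + nuc + codon[pos + 1 :]
            if alt not in stops and fwd[alt] == aa:
                s += 1.0
    return s / 3.0


@lru_cache(maxsize=None)
def pathway_differences(c1: str, c2: str, table_id: int = 1) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences between two codons.

    Averaged over all minimal mutational pathways; pathways through stop
    codons are excluded unless every pathway is blocked.
    """
    fwd, stops = _code(table_id)
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(diff):
        cur = c1
        steps = []
        blocked = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in stops:
                blocked = True
            steps.append((cur, nxt))
            cur = nxt
        # intermediate stops block a path; endpoints are assumed coding
        inter_stops = any(b in stops for _, b in steps[:-1])
        syn = sum(
            1.0 for a, b in steps if a not in stops and b not in stops and fwd[a] == fwd[b]
        )
        nonsyn = len(steps) - syn
        paths.append((inter_stops or blocked, syn, nonsyn))
    valid = [p for p in paths if not p[0]]
    use = valid if valid else paths
    sd = sum(p[1] for p in use) / len(use)
    nd = sum(p[2] for p in use) / len(use)
    return sd, nd


def jukes_cantor(p: float) -> float:
    """JC69 distance from a difference proportion; inf when saturated."""
    if p < 0:
        raise ValidationError("negative proportion")
    if p == 0:
        return 0.0
    if p >= 0.75:
        return math.inf
    return -0.75 * math.log(1.0 - p * 4.0 / 3.0)


@dataclass
class CodonPairRates:
    """NG86 counts and corrected rates for one sequence pair."""

    id_i: str
    id_j: str
    codons_used: int
    S: float
    N: float
    Sd: float
    Nd: float
    pS: float
    pN: float
    dS: float
    dN: float
    omega: float  # nan when dS == 0 or either rate saturated
    filtered: bool = False
    filter_reason: str = ""


def ng86_pair(
    seq_i: str, seq_j: str, id_i: str = "i", id_j: str = "j", table_id: int = 1
) -> CodonPairRates:
    """NG86 dN/dS for an in-frame, equal-length, stop-free sequence pair.

    Codons containing gaps or ambiguity in either sequence are dropped
    pairwise.
    """
    if len(seq_i) != len(seq_j):
        raise ValidationError("sequences differ in length")
    if len(seq_i) % 3:
        raise ValidationError("sequence length not divisible by 3")
    seq_i, seq_j = seq_i.upper(), seq_j.upper()
    fwd, stops = _code(table_id)
    S = N = Sd = Nd = 0.0
    used = 0
    for k in range(0, len(seq_i), 3):
        c1, c2 = seq_i[k : k + 3], seq_j[k : k + 3]
        if any(ch not in "ACGT" for ch in c1 + c2) or c1 in stops or c2 in stops:
            continue
        used += 1
        s1, s2 = syn_site_fraction(c1, table_id), syn_site_fraction(c2, table_id)
        S += (s1 + s2) / 2.0
        N += 3.0 - (s1 + s2) / 2.0
        sd, nd = pathway_differences(c1, c2, table_id)
        Sd += sd
        Nd += nd
    if used == 0:
        raise ValidationError(f"pair ({id_i},{id_j}): no comparable codons")
    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    dS, dN = jukes_cantor(pS), jukes_cantor(pN)
    if dS == 0 or math.isinf(dS) or math.isinf(dN):
        omega = math.nan
    else:
        omega = dN / dS
    return CodonPairRates(id_i, id_j, used, S, N, Sd, Nd, pS, pN, dS, dN, omega)


@dataclass
class CodonAlignment:
    """Concatenated shared-gene codon sequences, one per taxon."""

    ids: list[str]
    sequences: dict[str, str]
    genes_used: list[str] = field(default_factory=list)
    genes_excluded: dict[str, str] = field(default_factory=dict)  # name -> reason

    @property
    def length(self) -> int:
        return len(next(iter(self.sequences.values()))) if self.sequences else 0


def extract_cds(
    genome: CircularGenome, table: FeatureTable, gene_name: str
) -> str:
    """Spliced, strand-oriented CDS of one gene (exons in genomic order;
    reversed and complemented for minus-strand genes)."""
    gene = table.get(gene_name, "gene") or table.get(gene_name)
    if gene is None:
        raise LookupError(f"{genome.id}: gene {gene_name!r} not annotated")
    parts = [genome.fetch(s, e) for s, e in table.exon_intervals(gene)]
    seq = "".join(parts)
    return revcomp(seq) if gene.strand == "-" else seq


def build_codon_alignment(
    genomes: dict[str, CircularGenome],
    tables: dict[str, FeatureTable],
    table_id: int = 1,
) -> CodonAlignment:
    """Concatenate the protein-coding genes shared by every taxon.

    A gene is excluded (with a logged reason) when it is absent or
    pseudogenized in any taxon, when its CDS length is not a multiple of
    three or differs between taxa, or when it contains an internal stop.
    The terminal stop codon is removed before concatenation; gene order is
    alphabetical so output is reproducible.
    """
    ids = list(genomes)
    _, stops = _code(table_id)
    all_names = sorted(
        {g.name for t in tables.values() for g in t.of_kind("gene")}
    )
    used: list[str] = []
    excluded: dict[str, str] = {}
    pieces: dict[str, list[str]] = {gid: [] for gid in ids}
    for name in all_names:
        genes = {gid: tables[gid].get(name, "gene") for gid in ids}
        if any(g is None for g in genes.values()):
            excluded[name] = "absent in some taxa"
            continue
        if any(g.pseudo for g in genes.values()):
            excluded[name] = "pseudogene in some taxa"
            continue
        cds = {gid: extract_cds(genomes[gid], tables[gid], name) for gid in ids}
        if any(len(s) % 3 for s in cds.values()):
            excluded[name] = "length not divisible by 3"
            continue
        if len({len(s) for s in cds.values()}) != 1:
            excluded[name] = "CDS length differs between taxa"
            continue
        # strip the terminal stop, then reject internal stops
        stripped = {}
        ok = True
        for gid, s in cds.items():
            if s[-3:] in stops:
                s = s[:-3]
            codons = [s[k : k + 3] for k in range(0, len(s), 3)]
            if any(c in stops for c in codons):
                excluded[name] = "internal stop codon"
                ok = False
                break
            stripped[gid] = s
        if not ok:
            continue
        if len({len(s) for s in stripped.values()}) != 1:
            excluded[name] = "terminal stop present in only some taxa"
            continue
        used.append(name)
        for gid in ids:
            pieces[gid].append(stripped[gid])
    return CodonAlignment(
        ids=ids,
        sequences={gid: "".join(pieces[gid]) for gid in ids},
        genes_used=used,
        genes_excluded=excluded,
    )


def dnds_matrix(
    codon_aln: CodonAlignment,
    filters: dict[str, float] | None = None,
    table_id: int = 1,
) -> list[CodonPairRates]:
    """All pairwise NG86 rates with extreme-value filtering.

    Pairs with dN above ``dn_max``, dS above ``ds_max`` (synonymous
    saturation) or dS below ``ds_min`` (likely misassigned orthologs) are
    flagged ``filtered`` with the triggered rule; dS == dN == 0 pairs are
    reported with omega = nan but are not filtered.
    """
    if len(codon_aln.ids) < 2:
        raise ValidationError("need >= 2 taxa")
    f = dict(DEFAULT_FILTERS if filters is None else filters)
    out = []
    for i, j in itertools.combinations(codon_aln.ids, 2):
        r = ng86_pair(codon_aln.sequences[i], codon_aln.sequences[j], i, j, table_id)
        reasons = []
        if r.dN > f["dn_max"]:
            reasons.append(f"dN > {f['dn_max']}")
        if r.dS > f["ds_max"]:
            reasons.append(f"dS > {f['ds_max']}")
        if 0 < r.dS < f["ds_min"]:
            reasons.append(f"dS < {f['ds_min']}")
        if reasons:
            r.filtered = True
            r.filter_reason = "; ".join(reasons)
        out.append(r)
    return out


def dnds_table(rates: list[CodonPairRates]) -> "object":
    """Lower-triangle DataFrame with 'omega (dN/dS)' cells."""
    import pandas as pd

    ids = []
    for r in rates:
        for x in (r.id_i, r.id_j):
            if x not in ids:
                ids.append(x)
    df = pd.DataFrame("—", index=ids, columns=ids, dtype=object)
    for r in rates:
        cell = (
            "filtered"
            if r.filtered
            else ("NA" if math.isnan(r.omega) else f"{r.omega:.4f} ({r.dN:.4f}/{r.dS:.4f})")
        )
        df.loc[max(r.id_i, r.id_j, key=ids.index), min(r.id_i, r.id_j, key=ids.index)] = cell
    return df
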