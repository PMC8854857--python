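"""Independent brute-force oracles used to verify the fast implementations.

These deliberately share no code with the package: the IR oracle scans every
diagonal, the SSR oracle tests every (start, unit, copies) triple, and the
codon oracle enumerates mutational pathways with Biopython translation.
"""

from __future__ import annotations

import itertools

import numpy as np
from Bio.Seq import Seq

_COMP = str.maketrans("ACGTN", "TGCAN")


def rc(s: str) -> str:
    return s.translate(_COMP)[::-1]


def brute_force_ir_lengths(seq: str, min_len: int):
    """(lsc, ir, ssc) from an exhaustive O(L^2) scan of every diagonal
    between the doubled sequence and its reverse complement; None when no
    disjoint inverted-repeat pair of length >= min_len exists."""
    L = len(seq)
    s2 = seq + seq
    u = rc(s2)
    a_arr = np.frombuffer(s2.encode(), dtype=np.uint8)
    u_arr = np.frombuffer(u.encode(), dtype=np.uint8)
    n = 2 * L
    pairs = set()
    for d in range(-(n - 1), n):
        lo, hi = max(0, d), min(n, n + d)
        if hi - lo < min_len:
            continue
        eq = a_arr[lo:hi] == u_arr[lo - d : hi - d]
        padded = np.concatenate(([0], eq.view(np.int8), [0]))
        edges = np.flatnonzero(np.diff(padded))
        for rs, re in zip(edges[::2], edges[1::2]):
            m = int(re - rs)
            if m < min_len:
                continue
            a = int(lo + rs)
            b = n - (a - d) - m
            m = min(m, L)
            pairs.add((min(a % L, b % L), max(a % L, b % L), m))
    best = None
    for a, b, m in pairs:
        gap_ab = (b - (a + m)) % L
        gap_ba = (a - (b + m)) % L
        if a == b or gap_ab < 0 or gap_ba < 0:
            continue
        if (b - a) % L < m or (a - b) % L < m:
            continue  # overlapping copies
        if best is None or m > best[0]:
            best = (m, gap_ab, gap_ba)
    if best is None:
        return None
    m, g1, g2 = best
    return (max(g1, g2), m, min(g1, g2))


def brute_force_ssrs(seq: str, thresholds: dict[int, int]):
    """Every maximal perfect tandem repeat meeting its threshold, as a set of
    (start_1based, unit_len, copies). Linear sequences only."""
    L = len(seq)
    out = set()
    for u, min_copies in thresholds.items():
        for start in range(0, L - u * min_copies + 1):
            unit = seq[start : start + u]
            if any(c not in "ACGT" for c in unit):
                continue
            if any(u % p == 0 and unit == unit[:p] * (u // p) for p in range(1, u)):
                continue  # non-primitive
            if start >= 1 and seq[start - 1] == seq[start - 1 + u]:
                continue  # not the leftmost start of this tract
            copies = 1
            while seq[start + copies * u : start + (copies + 1) * u] == unit:
                copies += 1
            if copies >= min_copies:
                out.add((start + 1, u, copies))
    return out


def codon_translate(codon: str) -> str:
    return str(Seq(codon).translate())


def oracle_pathway_counts(c1: str, c2: str):
    """(syn, nonsyn) differences averaged over minimal pathways, excluding
    pathways through stop codons (all pathways if every one is blocked)."""
    diffs = [i for i in range(3) if c1[i] != c2[i]]
    if not diffs:
        return 0.0, 0.0
    all_paths = []
    for order in itertools.permutations(diffs):
        cur = c1
        syn = nonsyn = 0
        through_stop = False
        chain = [cur]
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            chain.append(nxt)
            cur = nxt
        for a, b in zip(chain, chain[1:]):
            ta, tb = codon_translate(a), codon_translate(b)
            if ta == "*" or tb == "*":
                nonsyn += 1
            elif ta == tb:
                syn += 1
            else:
                nonsyn += 1
        if any(codon_translate(c) == "*" for c in chain[1:-1]):
            through_stop = True
        all_paths.append((through_stop, syn, nonsyn))
    valid = [p for p in all_paths if not p[0]]
    use = valid or all_paths
    return (
        sum(p[1] for p in use) / len(use),
        sum(p[2] for p in use) / len(use),
    )


def oracle_syn_sites(codon: str) -> float:
    """Synonymous sites of one codon; mutations to stops are nonsynonymous."""
    aa = codon_translate(codon)
    s = 0
    for pos in range(3):
        for nuc in "ACGT":
            if nuc == codon[pos]:
                continue
            alt = codon[:pos] + nuc + codon[pos + 1 :]
            t = codon_translate(alt)
            if t != "*" and t == aa:
                s += 1
    return s / 3.0
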