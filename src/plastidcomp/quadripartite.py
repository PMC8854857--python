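"""Quadripartite structure detection and IR-junction analysis.

A typical plastome is a circle partitioned into a large single-copy region
(LSC), a small single-copy region (SSC) and two inverted repeats (IRb, IRa)
that are exact reverse complements of each other.  Detection finds the
maximal-length pair of disjoint reverse-complement repeats on the circle and
labels the shorter single-copy gap SSC.  The canonical rotation places LSC at
base 1 with region order LSC, IRb, SSC, IRa along ascending coordinates, so
the four junctions are

    JLB = lsc_len + 1            (first base of IRb)
    JSB = lsc_len + irb_len + 1  (first base of SSC)
    JSA = jsb + ssc_len          (first base of IRa)
    JLA = genome length          (last base of IRa)
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .io import CircularGenome, Feature, FeatureTable, ValidationError, revcomp

SEED_K = 31  # k-mer seed length; collision-free at plastome scale


class NoQuadripartiteError(ValueError):
    """No inverted-repeat pair of the required length exists."""


class StructuralError(ValueError):
    """Best repeat pair overlaps itself on the circle."""


@dataclass(frozen=True)
class QuadripartitePartition:
    """Region lengths and junction coordinates in canonical rotation."""

    lsc_len: int
    irb_len: int
    ssc_len: int
    ira_len: int
    rotation_offset: int = 0
    strand_flipped: bool = False

    def __post_init__(self) -> None:
        if self.irb_len != self.ira_len:
            raise ValidationError("IR copies must have equal length")
        if self.lsc_len <= self.ssc_len:
            raise ValidationError("LSC must be longer than SSC")

    @property
    def genome_length(self) -> int:
        return self.lsc_len + self.irb_len + self.ssc_len + self.ira_len

    @property
    def jlb(self) -> int:
        return self.lsc_len + 1

    @property
    def jsb(self) -> int:
        return self.lsc_len + self.irb_len + 1

    @property
    def jsa(self) -> int:
        return self.lsc_len + self.irb_len + self.ssc_len + 1

    @property
    def jla(self) -> int:
        return self.genome_length

    @property
    def spans(self) -> dict[str, tuple[int, int]]:
        return {
            "LSC": (1, self.lsc_len),
            "IRb": (self.jlb, self.jsb - 1),
            "SSC": (self.jsb, self.jsa - 1),
            "IRa": (self.jsa, self.jla),
        }

    def region_of(self, pos: int) -> str:
        for name, (s, e) in self.spans.items():
            if s <= pos <= e:
                return name
        raise ValidationError(f"position {pos} outside genome of length {self.genome_length}")


@dataclass(frozen=True)
class JunctionContext:
    """Nearest annotated features on both sides of one junction.

    The junction sits between bases ``boundary - 1`` and ``boundary``.  A
    feature spanning the boundary is reported with distance 0 and the number
    of its bases on each side; otherwise distance is the gap in bp.
    """

    junction: str
    boundary: int
    upstream_name: str
    upstream_distance: int
    upstream_overlap: int
    downstream_name: str
    downstream_distance: int
    downstream_overlap: int


def _maximal_rc_matches(seq: str, min_len: int, k: int = SEED_K):
    """All maximal reverse-complement self-matches of length >= min_len.

    Works on the doubled sequence so repeats may span the origin.  Yields
    (a, b, m): circular substring at 0-based ``a`` (length ``m``) equals the
    reverse complement of the circular substring at ``b``.
    """
    L = len(seq)
    k = min(k, min_len)
    s2 = seq + seq
    u = revcomp(s2)
    s_arr = np.frombuffer(s2.encode(), dtype=np.uint8)
    u_arr = np.frombuffer(u.encode(), dtype=np.uint8)
    n = 2 * L

    kmers: dict[str, list[int]] = {}
    for i in range(n - k + 1):
        kmers.setdefault(s2[i : i + k], []).append(i)
    diags = set()
    for j in range(0, n - k + 1):
        hits = kmers.get(u[j : j + k])
        if hits:
            for i in hits:
                diags.add(i - j)

    seen = set()
    for d in diags:
        # positions i in s2 aligned with i-d in u
        lo = max(0, d)
        hi = min(n, n + d)
        if hi - lo < min_len:
            continue
        eq = s_arr[lo:hi] == u_arr[lo - d : hi - d]
        # maximal runs of equality
        idx = np.flatnonzero(np.diff(np.concatenate(([0], eq.view(np.int8), [0]))))
        for rs, re in zip(idx[::2], idx[1::2]):
            m = int(re - rs)
            if m < min_len:
                continue
            a = int(lo + rs)
            j0 = a - d  # start in u
            b = n - j0 - m  # start of the partner copy in s2 coordinates
            m = min(m, L)
            key = (a % L, b % L, m)
            # each pair appears from both copies and both roles; canonicalise
            norm = (min(key[0], key[1]), max(key[0], key[1]), m)
            if norm in seen:
                continue
            seen.add(norm)
            yield a % L, b % L, m


def _circ_disjoint(a: int, b: int, m: int, L: int) -> bool:
    """Whether circular intervals [a, a+m) and [b, b+m) are disjoint."""
    if a == b:
        return False
    gap_ab = (b - a) % L
    gap_ba = (a - b) % L
    return gap_ab >= m and gap_ba >= m


def _partition_from_pair(seq: str, a: int, b: int, m: int):
    """Candidate canonical forms for a disjoint repeat pair; returns
    (canonical_seq, partition, offset, flipped)."""
    L = len(seq)
    gap_ab = ((b - (a + m)) % L, (a + m) % L)  # (length, start) of gap after copy A
    gap_ba = ((a - (b + m)) % L, (b + m) % L)
    candidates = []
    for (lsc_len, lsc_start), (ssc_len, _) in ((gap_ab, gap_ba), (gap_ba, gap_ab)):
        if lsc_len <= ssc_len:
            continue
        offset = lsc_start  # rotate so LSC starts at base 1
        rot = seq[offset:] + seq[:offset]
        part = QuadripartitePartition(lsc_len, m, ssc_len, m, rotation_offset=offset)
        candidates.append((rot, part, offset, False))
    if not candidates:  # equal single-copy gaps: no LSC/SSC distinction exists
        raise StructuralError("single-copy regions of equal length; cannot label LSC/SSC")
    return min(candidates, key=lambda c: c[0])


def detect_quadripartite(
    genome: CircularGenome, min_ir_len: int = 1000, max_mismatch: int = 0
) -> QuadripartitePartition:
    """Detect the LSC/IRb/SSC/IRa partition of a circular plastome.

    Returns the partition in canonical rotation; ``rotation_offset`` and
    ``strand_flipped`` record how the input maps onto it (see
    :func:`canonical_rotation`).  Raises :class:`NoQuadripartiteError` when no
    disjoint inverted-repeat pair of length >= ``min_ir_len`` exists, and
    :class:`StructuralError` when the only maximal candidates self-overlap on
    the circle.
    """
    if min_ir_len < 100:
        raise ValidationError("min_ir_len must be >= 100")
    if max_mismatch != 0:
        return _detect_with_mismatches(genome, min_ir_len, max_mismatch)
    L = genome.length
    matches = list(_maximal_rc_matches(genome.seq, min_ir_len))
    if not matches:
        raise NoQuadripartiteError(
            f"{genome.id}: no inverted repeat of length >= {min_ir_len}"
        )
    disjoint = [t for t in matches if _circ_disjoint(t[0], t[1], t[2], L)]
    if not disjoint:
        raise StructuralError(f"{genome.id}: best inverted-repeat pair overlaps itself")
    best_m = max(t[2] for t in disjoint)
    best = [t for t in disjoint if t[2] == best_m]

    # Strand-flipped representation: detect on the reverse complement too and
    # keep the lexicographically smaller canonical sequence.
    forward = min(_partition_from_pair(genome.seq, a, b, m) for a, b, m in best)
    rc_seq = revcomp(genome.seq)
    rc_best = []
    for a, b, m in best:
        # repeat pair maps to the rc strand at mirrored positions
        a2 = (L - (a + m)) % L
        b2 = (L - (b + m)) % L
        rc_best.append((a2, b2, m))
    flipped = min(_partition_from_pair(rc_seq, a, b, m) for a, b, m in rc_best)
    if flipped[0] < forward[0]:
        rot, part, offset, _ = flipped
        return replace(part, strand_flipped=True)
    rot, part, offset, _ = forward
    return part


def _detect_with_mismatches(genome, min_ir_len, max_mismatch):
    """Seed-and-extend variant tolerating a small mismatch budget.

    Extends each exact match outward, spending at most ``max_mismatch``
    mismatching positions in total, and reports the partition from the best
    extended pair.  Region lengths then reflect the extended repeat.
    """
    L = genome.length
    seq = genome.seq
    best = None
    for a, b, m in _maximal_rc_matches(seq, min(min_ir_len, 200)):
        # extend the exact core outward on the circle, spending the budget;
        # copy A grows left as copy B grows right (they mirror each other)
        budget = max_mismatch
        la, rb = a, (b + m) % L  # one past the aligned ends
        ext = m
        while budget >= 0 and ext < L:
            la2 = (la - 1) % L
            nxt = seq[la2]
            partner = revcomp(seq[rb])
            if nxt != partner:
                budget -= 1
                if budget < 0:
                    break
            la, rb = la2, (rb + 1) % L
            ext += 1
        if ext >= min_ir_len and _circ_disjoint(la, b, min(ext, L), L):
            if best is None or ext > best[2]:
                best = (la, b, min(ext, L))
    if best is None:
        raise NoQuadripartiteError(
            f"{genome.id}: no inverted repeat of length >= {min_ir_len}"
        )
    _, part, _, _ = _partition_from_pair(genome.seq, *best)
    return part


def canonical_rotation(
    genome: CircularGenome, partition: QuadripartitePartition
) -> tuple[CircularGenome, QuadripartitePartition]:
    """Apply the partition's recorded transform: rotate (and strand-flip if
    needed) so the sequence reads LSC, IRb, SSC, IRa from base 1.

    Idempotent: a canonical genome maps to itself with offset 0.
    """
    seq = revcomp(genome.seq) if partition.strand_flipped else genome.seq
    off = partition.rotation_offset
    canon = seq[off:] + seq[:off]
    return (
        CircularGenome(genome.id, canon, circular=genome.circular),
        replace(partition, rotation_offset=0, strand_flipped=False),
    )


def _nearest_context(boundary: int, features: list[Feature], L: int):
    """Nearest feature strictly upstream and downstream of a boundary, plus
    any feature overlapping it.  Distances measured on the circle."""
    overlapping = None
    up_best = None  # (distance, feature)
    down_best = None
    for f in features:
        if f.contains(boundary - 1 if boundary > 1 else L) and f.contains(boundary):
            overlapping = f
        d_up = (boundary - f.end) % L
        d_down = (f.start - boundary) % L
        if up_best is None or d_up < up_best[0]:
            up_best = (d_up, f)
        if down_best is None or d_down < down_best[0]:
            down_best = (d_down, f)
    return overlapping, up_best, down_best


def junction_context(
    partition: QuadripartitePartition, table: FeatureTable
) -> list[JunctionContext]:
    """Flanking-gene context for the four junctions of a canonical partition.

    For each junction the nearest gene on each side is reported; when a gene
    straddles the junction its distance is 0 and the overlap fields give how
    many of its bases fall on that side of the boundary.
    """
    L = partition.genome_length
    genes = table.genes
    out = []
    for label, boundary in (
        ("JLB", partition.jlb),
        ("JSB", partition.jsb),
        ("JSA", partition.jsa),
        ("JLA", partition.jla + 1),  # boundary after the last base of IRa
    ):
        boundary = ((boundary - 1) % L) + 1
        if not genes:
            out.append(JunctionContext(label, boundary, "none", -1, 0, "none", -1, 0))
            continue
        overlapping, up, down = _nearest_context(boundary, genes, L)
        if overlapping is not None:
            up_bases = sum(
                max(0, min(e, boundary - 1) - s + 1) for s, e in overlapping.intervals
            )
            down_bases = overlapping.length - up_bases
            out.append(
                JunctionContext(
                    label, boundary, overlapping.name, 0, up_bases,
                    overlapping.name, 0, down_bases,
                )
            )
        else:
            out.append(
                JunctionContext(
                    label, boundary, up[1].name, up[0], 0, down[1].name, down[0], 0
                )
            )
    return out
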