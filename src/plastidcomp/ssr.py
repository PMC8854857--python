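"""Perfect microsatellite (SSR) detection, canonicalization and summaries.

An SSR locus is a maximal perfect tandem array of a primitive 1-6 bp unit
meeting a per-unit-length copy threshold.  Motifs that are cyclic rotations
or reverse complements of one another are the same type; each locus is
reported once under its smallest primitive unit (a run of 12 A's is one
mononucleotide SSR, never also an AA dinucleotide SSR).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CircularGenome, FeatureTable, ValidationError, revcomp
from .quadripartite import QuadripartitePartition

#: Minimum copy number per unit length (mono..hexa).
DEFAULT_THRESHOLDS: dict[int, int] = {1: 8, 2: 4, 3: 4, 4: 3, 5: 3, 6: 3}

UNIT_CLASS = {1: "mono", 2: "di", 3: "tri", 4: "tetra", 5: "penta", 6: "hexa"}


def _is_primitive(motif: str) -> bool:
    n = len(motif)
    return not any(
        n % p == 0 and motif == motif[:p] * (n // p) for p in range(1, n)
    )


def canonical_motif(motif: str) -> str:
    """Representative of the rotation + reverse-complement equivalence class.

    The representative is the lexicographically smallest string among all
    cyclic rotations of the motif and of its reverse complement.  Rejects
    non-primitive motifs (e.g. "ATAT"), which are not valid repeat units.
    """
    if not motif:
        raise ValidationError("empty motif")
    if not (1 <= len(motif) <= 6) or any(c not in "ACGT" for c in motif):
        raise ValidationError(f"motif {motif!r} must be 1-6 bp over ACGT")
    if not _is_primitive(motif):
        raise ValidationError(f"motif {motif!r} is not primitive")
    rc = revcomp(motif)
    n = len(motif)
    return min(
        min(motif[i:] + motif[:i] for i in range(n)),
        min(rc[i:] + rc[:i] for i in range(n)),
    )


@dataclass
class SSRLocus:
    """One detected microsatellite.

    ``start`` is 1-based on the genome; ``end = start + length - 1`` and may
    exceed the genome length, in which case the locus wraps the circular
    origin (``wraps`` is then True).
    """

    genome_id: str
    motif: str
    canonical: str
    unit_len: int
    copies: int
    start: int
    genome_length: int
    structural_region: str | None = None
    functional_region: str | None = None

    @property
    def length(self) -> int:
        return self.unit_len * self.copies

    @property
    def end(self) -> int:
        return self.start + self.length - 1

    @property
    def wraps(self) -> bool:
        return self.end > self.genome_length

    @property
    def midpoint(self) -> int:
        """Circular midpoint, 1-based."""
        return (self.start - 1 + (self.length - 1) // 2) % self.genome_length + 1

    def span_key(self) -> tuple[int, int]:
        return (self.start, self.length)


def find_ssrs(
    genome: CircularGenome, thresholds: dict[int, int] | None = None
) -> list[SSRLocus]:
    """All maximal perfect SSRs meeting the copy thresholds, sorted by start.

    On circular genomes, loci crossing the origin are detected and reported
    once with their start in [1, genome length].
    """
    thr = dict(DEFAULT_THRESHOLDS if thresholds is None else thresholds)
    L = genome.length
    if L < min(u * c for u, c in thr.items()):
        return []
    scan = genome.seq + genome.seq if genome.circular else genome.seq
    arr = np.frombuffer(scan.encode(), dtype=np.uint8)
    acgt = np.isin(arr, np.frombuffer(b"ACGT", dtype=np.uint8))
    loci: list[SSRLocus] = []
    for u, min_copies in sorted(thr.items()):
        if len(arr) <= u:
            continue
        eq = (arr[:-u] == arr[u:]) & acgt[:-u] & acgt[u:]
        idx = np.flatnonzero(np.diff(np.concatenate(([0], eq.view(np.int8), [0]))))
        for rs, re in zip(idx[::2], idx[1::2]):
            tract = int(re - rs) + u  # matched region spans rs .. re-1+u
            copies = tract // u
            if copies < min_copies:
                continue
            start0 = int(rs)
            if genome.circular and start0 >= L:
                continue  # duplicate of a run already seen in the first copy
            motif = scan[start0 : start0 + u]
            if not _is_primitive(motif):
                continue
            copies = min(copies, L // u)  # a locus cannot exceed the circle
            loci.append(
                SSRLocus(
                    genome.id, motif, canonical_motif(motif), u, copies, start0 + 1, L
                )
            )
    if genome.circular:
        loci = _dedupe_circular(loci, L)
    loci.sort(key=lambda x: (x.start, x.unit_len))
    return loci


def _dedupe_circular(loci: list[SSRLocus], L: int) -> list[SSRLocus]:
    """Drop seam artifacts: a locus whose circular span is contained in
    another locus with the same canonical motif."""
    out = []
    spans = [(x, set((x.start - 1 + i) % L for i in range(x.length))) for x in loci]
    for i, (x, cov) in enumerate(spans):
        contained = any(
            j != i
            and y.canonical == x.canonical
            and y.length >= x.length
            and cov <= cov2
            and (y.length > x.length or y.start < x.start)
            for j, (y, cov2) in enumerate(spans)
        )
        if not contained:
            out.append(x)
    return out


def classify_ssrs(
    loci: list[SSRLocus],
    partition: QuadripartitePartition,
    table: FeatureTable,
) -> list[SSRLocus]:
    """Fill structural (LSC/SSC/IRa/IRb) and functional (gene/intron/
    intergenic) region labels from the locus midpoint.

    Precedence when annotations overlap: gene > intron > intergenic.
    """
    exonic = [
        iv
        for g in table.genes
        for iv in table.exon_intervals(g)
    ]
    introns = [iv for f in table.of_kind("intron") for iv in f.intervals]
    for locus in loci:
        mid = locus.midpoint
        locus.structural_region = partition.region_of(mid)
        if any(s <= mid <= e for s, e in exonic):
            locus.functional_region = "gene"
        elif any(s <= mid <= e for s, e in introns):
            locus.functional_region = "intron"
        else:
            locus.functional_region = "intergenic"
    return loci


STRUCTURAL = ("LSC", "SSC", "IRa", "IRb")
FUNCTIONAL = ("intergenic", "gene", "intron")


@dataclass
class SSRSummary:
    """Counts by unit class and region, plus per-kb densities."""

    per_genome: pd.DataFrame  # rows: genome; cols: counts and percentages
    unit_counts: pd.DataFrame  # rows: genome; cols: mono..hexa
    density_per_kb: dict[str, float] = field(default_factory=dict)  # LSC/SSC/IR


def ssr_summary(
    loci_by_genome: dict[str, list[SSRLocus]],
    partitions: dict[str, QuadripartitePartition],
) -> SSRSummary:
    """Tabulate classified loci per genome and pool densities by region.

    Density per kb pools loci and region lengths across genomes:
    count / length * 1000, reported to 2 decimals.  IRa and IRb are pooled
    into a single IR class for density, matching how plastome IR statistics
    are conventionally reported.
    """
    rows = []
    unit_rows = []
    for gid, loci in loci_by_genome.items():
        total = len(loci)
        row: dict[str, object] = {"genome": gid, "total": total}
        for reg in FUNCTIONAL + STRUCTURAL:
            key = "structural_region" if reg in STRUCTURAL else "functional_region"
            n = sum(1 for x in loci if getattr(x, key) == reg)
            row[reg] = n
            row[f"{reg}_pct"] = round(100.0 * n / total, 2) if total else 0.0
        rows.append(row)
        unit_rows.append(
            {"genome": gid}
            | {
                UNIT_CLASS[u]: sum(1 for x in loci if x.unit_len == u)
                for u in range(1, 7)
            }
        )
    density: dict[str, float] = {}
    for reg_class, members in (("LSC", ("LSC",)), ("SSC", ("SSC",)), ("IR", ("IRa", "IRb"))):
        count = sum(
            1
            for loci in loci_by_genome.values()
            for x in loci
            if x.structural_region in members
        )
        length = sum(
            sum(p.spans[m][1] - p.spans[m][0] + 1 for m in members)
            for p in partitions.values()
        )
        density[reg_class] = round(count / length * 1000, 2) if length else 0.0
    return SSRSummary(
        per_genome=pd.DataFrame(rows).set_index("genome"),
        unit_counts=pd.DataFrame(unit_rows).set_index("genome"),
        density_per_kb=density,
    )
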