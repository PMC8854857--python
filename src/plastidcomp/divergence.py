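"""Alignment-based divergence statistics.

Implements the DnaSP-style statistics used in comparative plastome studies:
site classification (variable / singleton / parsimony-informative),
nucleotide diversity (pi) and Watterson's theta, sliding-window diversity
profiles, hypervariable-region ranking, pairwise indel/substitution counts,
and per-region percent variability.

Gap policy: for pi, theta and site classes the default is complete deletion
— only columns with an unambiguous base (A/C/G/T) in every row are used;
'N' is treated as missing, like a gap, to avoid inflating diversity.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO

from .io import CircularGenome, Feature, FeatureTable, FormatError, ValidationError
from .quadripartite import QuadripartitePartition

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_GAP = ord("-")
_N = ord("N")


class UndefinedStatisticError(ValueError):
    """Statistic has no defined value on this input (e.g. no gap-free columns)."""


@dataclass
class AlignedMatrix:
    """N aligned sequences as an (N, L) byte matrix with column maps."""

    ids: list[str]
    matrix: np.ndarray  # uint8, values in {A,C,G,T,N,-}
    reference_id: str | None = None

    def __post_init__(self) -> None:
        if self.matrix.ndim != 2:
            raise FormatError("alignment matrix must be 2-D")
        if self.reference_id is None:
            self.reference_id = self.ids[0]
        self._pos_of_col: dict[str, np.ndarray] = {}
        self._col_of_pos: dict[str, np.ndarray] = {}

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    def row(self, id_or_index: str | int) -> np.ndarray:
        return self.matrix[self.index(id_or_index)]

    def index(self, id_or_index: str | int) -> int:
        if isinstance(id_or_index, int):
            return id_or_index
        return self.ids.index(id_or_index)

    def ungapped(self, id_or_index: str | int) -> str:
        row = self.row(id_or_index)
        return row[row != _GAP].tobytes().decode()

    def _build_maps(self, gid: str) -> None:
        row = self.row(gid)
        nongap = row != _GAP
        pos_of_col = np.where(nongap, np.cumsum(nongap), 0)  # 1-based; 0 at gaps
        col_of_pos = np.flatnonzero(nongap) + 1  # 1-based columns per position
        self._pos_of_col[gid] = pos_of_col
        self._col_of_pos[gid] = col_of_pos

    def pos_of_col(self, gid: str, col: int) -> int:
        """Ungapped 1-based position of alignment column ``col`` in genome
        ``gid`` (0 if the genome is gapped there)."""
        if gid not in self._pos_of_col:
            self._build_maps(gid)
        return int(self._pos_of_col[gid][col - 1])

    def col_of_pos(self, gid: str, pos: int) -> int:
        """Alignment column (1-based) holding ungapped position ``pos``."""
        if gid not in self._col_of_pos:
            self._build_maps(gid)
        return int(self._col_of_pos[gid][pos - 1])

    def region_columns(self, gid: str) -> np.ndarray:
        """For every column, the last preceding non-gap position of ``gid``
        (insertion columns inherit the position to their left)."""
        row = self.row(gid)
        nongap = row != _GAP
        return np.maximum.accumulate(np.where(nongap, np.cumsum(nongap), 0))


def read_alignment(path, reference_id: str | None = None) -> AlignedMatrix:
    """Read an aligned FASTA into an :class:`AlignedMatrix`."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: no records")
    lengths = {len(r.seq) for r in records}
    if len(lengths) != 1:
        raise FormatError(f"{path}: ragged alignment, row lengths {sorted(lengths)}")
    ids = [r.id for r in records]
    mat = np.frombuffer(
        "".join(str(r.seq).upper() for r in records).encode(), dtype=np.uint8
    ).reshape(len(records), lengths.pop()).copy()
    return AlignedMatrix(ids, mat, reference_id=reference_id)


def alignment_from_strings(
    ids: list[str], rows: list[str], reference_id: str | None = None
) -> AlignedMatrix:
    if len({len(r) for r in rows}) != 1:
        raise FormatError("ragged alignment")
    mat = np.frombuffer("".join(r.upper() for r in rows).encode(), dtype=np.uint8)
    return AlignedMatrix(ids, mat.reshape(len(rows), -1).copy(), reference_id)


def _gap_free_mask(mat: np.ndarray) -> np.ndarray:
    return np.isin(mat, _BASES).all(axis=0)


def _distinct_base_stats(mat: np.ndarray):
    """Per column: number of distinct bases, and number of bases present in
    >= 2 rows (over gap-free columns the two together classify sites)."""
    counts = np.stack([(mat == b).sum(axis=0) for b in _BASES])  # (4, L)
    n_distinct = (counts > 0).sum(axis=0)
    n_shared = (counts >= 2).sum(axis=0)
    max_count = counts.max(axis=0)
    return n_distinct, n_shared, max_count


@dataclass
class SiteClassCounts:
    total_columns: int
    gap_free_columns: int
    variable_sites: int
    singleton_sites: int
    parsimony_informative_sites: int
    per_region: dict[str, "SiteClassCounts"] = field(default_factory=dict)


def classify_sites(
    aln: AlignedMatrix,
    partition: QuadripartitePartition | None = None,
) -> SiteClassCounts:
    """Classify alignment columns (complete deletion).

    variable: gap-free with >= 2 distinct bases; singleton: variable with
    exactly one deviating sequence; parsimony-informative: >= 2 distinct
    bases each in >= 2 sequences.  With a partition for the reference genome,
    per-region (LSC/SSC/IR) breakdowns are included, assigning each column to
    the region of the nearest preceding reference base.
    """
    if aln.n < 2:
        raise ValidationError("site classification needs >= 2 sequences")
    mat = aln.matrix
    gap_free = _gap_free_mask(mat)
    n_distinct, n_shared, max_count = _distinct_base_stats(mat)
    variable = gap_free & (n_distinct >= 2)
    informative = variable & (n_shared >= 2)
    singleton = variable & (max_count == aln.n - 1)

    def _counts(mask: np.ndarray) -> SiteClassCounts:
        return SiteClassCounts(
            total_columns=int(mask.sum()),
            gap_free_columns=int((gap_free & mask).sum()),
            variable_sites=int((variable & mask).sum()),
            singleton_sites=int((singleton & mask).sum()),
            parsimony_informative_sites=int((informative & mask).sum()),
        )

    out = _counts(np.ones(aln.length, dtype=bool))
    if partition is not None:
        region_pos = aln.region_columns(aln.reference_id)
        bounds = [
            ("LSC", 1, partition.lsc_len),
            ("IRb", partition.jlb, partition.jsb - 1),
            ("SSC", partition.jsb, partition.jsa - 1),
            ("IRa", partition.jsa, partition.jla),
        ]
        for name, s, e in bounds:
            mask = (region_pos >= s) & (region_pos <= e)
            out.per_region[name] = _counts(mask)
        out.per_region["IR"] = SiteClassCounts(
            *[
                getattr(out.per_region["IRa"], f) + getattr(out.per_region["IRb"], f)
                for f in (
                    "total_columns",
                    "gap_free_columns",
                    "variable_sites",
                    "singleton_sites",
                    "parsimony_informative_sites",
                )
            ]
        )
    return out


@dataclass
class DiversityStats:
    pi: float
    theta: float
    n: int
    L: int  # gap-free columns used
    S: int  # segregating sites


def harmonic_a(n: int) -> float:
    return sum(1.0 / i for i in range(1, n))


def nucleotide_diversity(
    aln: AlignedMatrix, columns: slice | None = None
) -> DiversityStats:
    """Pi and Watterson's theta with complete deletion.

    pi is the mean over all sequence pairs of (mismatches / gap-free
    columns); theta = S / (a_n * L) with a_n = sum_{i<n} 1/i.
    """
    if aln.n < 2:
        raise ValidationError("diversity needs >= 2 sequences")
    mat = aln.matrix[:, columns] if columns is not None else aln.matrix
    gap_free = _gap_free_mask(mat)
    L = int(gap_free.sum())
    if L == 0:
        raise UndefinedStatisticError("no gap-free columns")
    sub = mat[:, gap_free]
    n = aln.n
    total = 0
    for i, j in itertools.combinations(range(n), 2):
        total += int((sub[i] != sub[j]).sum())
    pi = total / (n * (n - 1) / 2) / L
    S = int((_distinct_base_stats(sub)[0] >= 2).sum())
    theta = S / (harmonic_a(n) * L)
    return DiversityStats(pi=pi, theta=theta, n=n, L=L, S=S)


@dataclass
class WindowStat:
    start: int  # 1-based alignment column
    end: int
    pi: float
    gap_free: int
    partial: bool = False

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2


def sliding_windows(
    aln: AlignedMatrix, window: int = 600, step: int = 200
) -> list[WindowStat]:
    """Per-window pi over alignment columns: [1,600], [201,800], ...

    The final partial window is retained and flagged.  A window with no
    gap-free column gets pi = nan.
    """
    if not (window >= step >= 1):
        raise ValidationError("require window >= step >= 1")
    L = aln.length
    out = []
    start = 1
    while True:
        end = min(start + window - 1, L)
        try:
            stats = nucleotide_diversity(aln, columns=slice(start - 1, end))
            pi, gf = stats.pi, stats.L
        except UndefinedStatisticError:
            pi, gf = math.nan, 0
        out.append(WindowStat(start, end, pi, gf, partial=(end - start + 1) < window))
        if end >= L:
            break
        start += step
    return out


@dataclass
class HypervariableRegion:
    start: int  # alignment columns
    end: int
    peak_pi: float
    features: list[str] = field(default_factory=list)


def hypervariable_regions(
    windows: list[WindowStat],
    aln: AlignedMatrix,
    table: FeatureTable | None = None,
    k: int = 10,
) -> list[HypervariableRegion]:
    """Top-k divergence hotspots: overlapping top-pi windows merged into
    peaks, annotated with the reference features they overlap, ranked by
    peak pi (ties broken by alignment coordinate)."""
    ranked = sorted(
        (w for w in windows if not math.isnan(w.pi)),
        key=lambda w: (-w.pi, w.start),
    )
    peaks: list[HypervariableRegion] = []
    for w in ranked:
        merged = False
        for p in peaks:
            if w.start <= p.end and w.end >= p.start:
                p.start = min(p.start, w.start)
                p.end = max(p.end, w.end)
                merged = True
                break
        if not merged:
            if len(peaks) >= k:
                break
            peaks.append(HypervariableRegion(w.start, w.end, w.pi))
    if table is not None:
        ref = aln.reference_id
        for p in peaks:
            pos_lo = aln.pos_of_col(ref, p.start) or 1
            pos_hi = aln.pos_of_col(ref, p.end) or pos_lo
            names = []
            for f in table.features:
                if f.kind == "exon":
                    continue
                if any(s <= pos_hi and e >= pos_lo for s, e in f.intervals):
                    if f.name not in names:
                        names.append(f.name)
            p.features = names
    peaks.sort(key=lambda p: (-p.peak_pi, p.start))
    return peaks


@dataclass(frozen=True)
class PairwiseDivergence:
    id_i: str
    id_j: str
    indel_events: int
    substitutions: int


def pairwise_divergence(
    aln: AlignedMatrix, i: str | int, j: str | int
) -> PairwiseDivergence:
    """Indel events and substitutions between two rows.

    Columns gapped in both rows are dropped first; each maximal run of gaps
    remaining in either row counts as one indel event.  Substitutions are
    columns where both rows carry unambiguous bases that differ ('N' columns
    are excluded from the substitution count).
    """
    ii, jj = aln.index(i), aln.index(j)
    a, b = aln.matrix[ii], aln.matrix[jj]
    if ii == jj:
        return PairwiseDivergence(aln.ids[ii], aln.ids[jj], 0, 0)
    keep = ~((a == _GAP) & (b == _GAP))
    a, b = a[keep], b[keep]
    subs = int(
        ((a != b) & np.isin(a, _BASES) & np.isin(b, _BASES)).sum()
    )
    indels = 0
    for row in (a, b):
        gaps = (row == _GAP).view(np.int8)
        indels += int((np.diff(np.concatenate(([0], gaps))) == 1).sum())
    return PairwiseDivergence(aln.ids[ii], aln.ids[jj], indels, subs)


def divergence_matrix(aln: AlignedMatrix) -> "np.ndarray | object":
    """Table 4-shaped DataFrame: indel events in the upper triangle,
    substitutions in the lower triangle."""
    import pandas as pd

    n = aln.n
    df = pd.DataFrame("—", index=aln.ids, columns=aln.ids, dtype=object)
    for i, j in itertools.combinations(range(n), 2):
        d = pairwise_divergence(aln, i, j)
        df.iloc[i, j] = d.indel_events
        df.iloc[j, i] = d.substitutions
    return df


def region_variability(
    aln: AlignedMatrix, table: FeatureTable
) -> "object":
    """Percent variable columns per reference-anchored region (Fig-6 style).

    A column is variable when it shows >= 2 distinct states among
    {A, C, G, T, -} ('N' ignored), so a region deleted in some taxa counts as
    fully variable.  Returns a DataFrame with one row per CDS/intron/
    intergenic region plus pooled coding and non-coding percentages stored in
    ``df.attrs``.
    """
    import pandas as pd

    ref = aln.reference_id
    mat = aln.matrix
    state_counts = np.stack(
        [(mat == b).sum(axis=0) for b in _BASES] + [(mat == _GAP).sum(axis=0)]
    )
    col_variable = (state_counts > 0).sum(axis=0) >= 2
    region_pos = aln.region_columns(ref)

    rows = []
    pooled = {"coding": [0, 0], "noncoding": [0, 0]}  # [variable, total]
    for f in table.features:
        if f.kind == "exon":
            continue
        kind = "coding" if f.kind in ("gene", "tRNA", "rRNA") else "noncoding"
        mask = np.zeros(aln.length, dtype=bool)
        for s, e in f.intervals:
            mask |= (region_pos >= s) & (region_pos <= e)
        ncols = int(mask.sum())
        if ncols == 0:
            continue
        nvar = int((col_variable & mask).sum())
        pooled[kind][0] += nvar
        pooled[kind][1] += ncols
        rows.append(
            {
                "region": f.name,
                "kind": f.kind,
                "aligned_columns": ncols,
                "variable_columns": nvar,
                "percent_variable": round(100.0 * nvar / ncols, 2),
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["percent_coding"] = (
        round(100.0 * pooled["coding"][0] / pooled["coding"][1], 2)
        if pooled["coding"][1]
        else math.nan
    )
    df.attrs["percent_noncoding"] = (
        round(100.0 * pooled["noncoding"][0] / pooled["noncoding"][1], 2)
        if pooled["noncoding"][1]
        else math.nan
    )
    return df
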