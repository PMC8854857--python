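"""Sequence and annotation I/O with a circular 1-based coordinate contract.

All genomic coordinates in this package are 1-based inclusive, matching the
convention of published plastome junction tables.  Intervals never use
negative or beyond-length coordinates: a feature that wraps the circular
origin is represented as two non-wrapping intervals belonging to one feature.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

IUPAC_CHARS = set("ACGTNRYSWKMBDHV")
COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHV", "TGCANYRSWMKVHDB")


class FormatError(ValueError):
    """Malformed input file."""


class ValidationError(ValueError):
    """Input violates a domain invariant."""


def revcomp(seq: str) -> str:
    """Reverse complement over the IUPAC alphabet."""
    return seq.translate(COMPLEMENT)[::-1]


@dataclass
class CircularGenome:
    """A plastome sequence with circular topology.

    Attributes
    ----------
    id : str
        Sequence identifier (FASTA header word).
    seq : str
        Uppercase nucleotide string over the IUPAC alphabet.
    circular : bool
        Whether coordinate arithmetic may wrap the origin.
    """

    id: str
    seq: str
    circular: bool = True

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValidationError(f"genome {self.id!r}: empty sequence")
        self.seq = self.seq.upper()
        bad = next((i for i, c in enumerate(self.seq) if c not in IUPAC_CHARS), None)
        if bad is not None:
            raise ValidationError(
                f"genome {self.id!r}: non-IUPAC character {self.seq[bad]!r} at position {bad + 1}"
            )

    @property
    def length(self) -> int:
        return len(self.seq)

    def fetch(self, start: int, end: int) -> str:
        """Subsequence for the 1-based inclusive interval [start, end].

        On a circular genome ``end`` may be smaller than ``start``, meaning
        the interval wraps the origin.
        """
        L = self.length
        if not (1 <= start <= L and 1 <= end <= L):
            raise ValidationError(f"interval [{start},{end}] outside genome of length {L}")
        if start <= end:
            return self.seq[start - 1 : end]
        if not self.circular:
            raise ValidationError("wrapping interval on a linear genome")
        return self.seq[start - 1 :] + self.seq[:end]


@dataclass
class Feature:
    """One annotated element; wrapping elements carry two intervals."""

    name: str
    kind: str  # gene | tRNA | rRNA | exon | intron | intergenic
    strand: str = "+"
    intervals: list[tuple[int, int]] = field(default_factory=list)
    pseudo: bool = False

    KINDS = frozenset({"gene", "tRNA", "rRNA", "exon", "intron", "intergenic"})

    def __post_init__(self) -> None:
        if self.kind not in self.KINDS:
            raise ValidationError(f"feature {self.name!r}: unknown kind {self.kind!r}")
        for s, e in self.intervals:
            if e < s:
                raise ValidationError(f"feature {self.name!r}: end {e} < start {s}")

    @property
    def start(self) -> int:
        return min(s for s, _ in self.intervals)

    @property
    def end(self) -> int:
        return max(e for _, e in self.intervals)

    @property
    def length(self) -> int:
        return sum(e - s + 1 for s, e in self.intervals)

    def contains(self, pos: int) -> bool:
        return any(s <= pos <= e for s, e in self.intervals)


GENE_KINDS = frozenset({"gene", "tRNA", "rRNA"})


@dataclass
class FeatureTable:
    """Features of one genome plus derived introns and intergenic spacers."""

    genome_id: str
    features: list[Feature] = field(default_factory=list)
    genome_length: int | None = None

    def of_kind(self, *kinds: str) -> list[Feature]:
        return [f for f in self.features if f.kind in kinds]

    @property
    def genes(self) -> list[Feature]:
        return self.of_kind(*GENE_KINDS)

    def get(self, name: str, kind: str | None = None) -> Feature | None:
        for f in self.features:
            if f.name == name and (kind is None or f.kind == kind):
                return f
        return None

    def exon_intervals(self, gene: Feature) -> list[tuple[int, int]]:
        """Coding intervals of a gene: its exon children, else its own span."""
        exons = [f for f in self.features if f.kind == "exon" and f.name == gene.name]
        if exons:
            ivs = [iv for f in exons for iv in f.intervals]
            return sorted(ivs)
        return sorted(gene.intervals)

    def derive_introns(self) -> None:
        """Add intron features in the gaps between exons of each gene."""
        self.features = [f for f in self.features if f.kind != "intron"]
        for gene in self.genes:
            exons = self.exon_intervals(gene)
            if len(exons) < 2:
                continue
            for (s1, e1), (s2, _) in itertools.pairwise(exons):
                if s2 > e1 + 1:
                    self.features.append(
                        Feature(gene.name, "intron", gene.strand, [(e1 + 1, s2 - 1)])
                    )

    def derive_spacers(self) -> None:
        """Add intergenic spacers tiling the complement of gene extents."""
        if self.genome_length is None:
            raise ValidationError("genome_length required to derive spacers")
        L = self.genome_length
        self.features = [f for f in self.features if f.kind != "intergenic"]
        covered = sorted(
            (iv, g.name) for g in self.genes for iv in g.intervals
        )
        if not covered:
            self.features.append(Feature("genome", "intergenic", "+", [(1, L)]))
            return
        # Merge gene extents in genome order; name gaps "upstream-downstream".
        merged: list[list] = []  # [start, end, first_name, last_name]
        for (s, e), name in covered:
            if merged and s <= merged[-1][1] + 1:
                if e > merged[-1][1]:
                    merged[-1][1] = e
                    merged[-1][3] = name
            else:
                merged.append([s, e, name, name])
        for (_, e1, _, n1), (s2, _, n2, _) in itertools.pairwise(merged):
            if s2 > e1 + 1:
                self.features.append(Feature(f"{n1}-{n2}", "intergenic", "+", [(e1 + 1, s2 - 1)]))
        # Wrap gap from last gene back to the first.
        first_s, _, first_n, _ = merged[0]
        _, last_e, _, last_n = merged[-1]
        name = f"{last_n}-{first_n}"
        if last_e < L and first_s > 1:
            self.features.append(
                Feature(name, "intergenic", "+", [(last_e + 1, L), (1, first_s - 1)])
            )
        elif last_e < L:
            self.features.append(Feature(name, "intergenic", "+", [(last_e + 1, L)]))
        elif first_s > 1:
            self.features.append(Feature(name, "intergenic", "+", [(1, first_s - 1)]))

    def derive_all(self) -> "FeatureTable":
        self.derive_introns()
        self.derive_spacers()
        return self


def read_fasta(path: str | Path, circular: bool = True) -> list[CircularGenome]:
    """Read all records of a FASTA file as (by default circular) genomes."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: no FASTA records")
    return [CircularGenome(r.id, str(r.seq), circular=circular) for r in records]


def write_fasta(genomes: list[CircularGenome] | CircularGenome, path: str | Path) -> None:
    if isinstance(genomes, CircularGenome):
        genomes = [genomes]
    recs = [SeqRecord(Seq(g.seq), id=g.id, description="") for g in genomes]
    SeqIO.write(recs, str(path), "fasta")


_GFF_TYPE_MAP = {"gene": "gene", "tRNA": "tRNA", "rRNA": "rRNA", "exon": "exon"}


def _parse_attrs(text: str) -> dict[str, str]:
    out = {}
    for part in text.strip().split(";"):
        if "=" in part:
            k, v = part.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_features(path: str | Path, genome: CircularGenome) -> FeatureTable:
    """Read the GFF3 subset for one genome and derive introns and spacers.

    Recognised types: gene, tRNA, rRNA, exon.  A wrapping element appears as
    two records sharing one ID.  The attribute ``pseudo=true`` marks
    pseudogenes, which are retained but excluded from codon analysis.
    """
    by_id: dict[tuple[str, str], Feature] = {}
    seen_seqids = set()
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise FormatError(f"{path}:{ln}: expected 9 GFF3 columns")
            seqid, _src, ftype, start, end, _score, strand, _frame, attrs = cols
            seen_seqids.add(seqid)
            if seqid != genome.id or ftype not in _GFF_TYPE_MAP:
                continue
            start, end = int(start), int(end)
            if end < start:
                raise ValidationError(f"{path}:{ln}: end {end} < start {start}")
            if not (1 <= start and end <= genome.length):
                raise ValidationError(f"{path}:{ln}: interval outside genome")
            a = _parse_attrs(attrs)
            name = a.get("Name", a.get("ID", f"feat{ln}"))
            fid = a.get("ID", f"{name}:{ln}")
            key = (fid, ftype)
            if key in by_id:
                by_id[key].intervals.append((start, end))
            else:
                by_id[key] = Feature(
                    name,
                    _GFF_TYPE_MAP[ftype],
                    strand if strand in "+-" else "+",
                    [(start, end)],
                    pseudo=a.get("pseudo", "").lower() == "true",
                )
    if genome.id not in seen_seqids:
        raise LookupError(f"{path}: no records for seqid {genome.id!r}")
    table = FeatureTable(genome.id, list(by_id.values()), genome_length=genome.length)
    table.derive_all()
    return table


def write_features(table: FeatureTable, path: str | Path) -> None:
    """Write genes/tRNA/rRNA/exons as a GFF3 subset (derived features omitted)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        counters: dict[str, int] = {}
        for f in table.features:
            if f.kind in ("intron", "intergenic"):
                continue
            n = counters.get(f.name, 0)
            counters[f.name] = n + 1
            fid = f.name if n == 0 else f"{f.name}.{n}"
            attrs = f"ID={fid};Name={f.name}"
            if f.pseudo:
                attrs += ";pseudo=true"
            for s, e in f.intervals:
                fh.write(
                    f"{table.genome_id}\tplastidcomp\t{f.kind if f.kind != 'exon' else 'exon'}"
                    f"\t{s}\t{e}\t.\t{f.strand}\t.\t{attrs}\n"
                )


def gc_content(genome: CircularGenome, interval: tuple[int, int] | None = None) -> float:
    """GC fraction over an interval (whole genome if None).

    Ambiguity codes are excluded from the denominator; only unambiguous
    A/C/G/T are counted.
    """
    seq = genome.seq if interval is None else genome.fetch(*interval)
    if not seq:
        raise ValidationError("zero-length interval")
    gc = seq.count("G") + seq.count("C")
    at = seq.count("A") + seq.count("T")
    if gc + at == 0:
        raise ValidationError("interval contains no unambiguous bases")
    return gc / (gc + at)
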