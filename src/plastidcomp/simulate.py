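"""Synthetic plastome generator with ground-truth annotations and evolution.

Generates circular quadripartite genomes (LSC + IRb + SSC + IRa, with
IRa the exact reverse complement of IRb), plants genes (optionally with
introns), and plants SSR motifs whose recovery is exact by construction:
after assembly the background is scrubbed until the only detectable SSRs are
the planted ones.

`evolve` derives descendant genomes from an ancestor on a star phylogeny
under a per-site substitution probability and an indel event process with
geometric lengths, writes an exact event log, and builds the true multiple
alignment by bookkeeping (never by re-alignment).  With IR homogenization on
(the default, mimicking the concerted evolution of real plastome IRs) every
substitution in one IR copy is mirrored in the other, and indels are kept
out of the IRs entirely so the truth alignment stays exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .io import CircularGenome, Feature, FeatureTable, ValidationError, revcomp
from .quadripartite import QuadripartitePartition
from .ssr import DEFAULT_THRESHOLDS, find_ssrs

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_STOPS = ("TAA", "TAG", "TGA")


@dataclass(frozen=True)
class GeneModel:
    """A gene to plant: CDS length (divisible by 3, incl. stop), position
    offset within its region, optional intron lengths after given codon
    offsets."""

    name: str
    region: str  # LSC | SSC | IRb
    offset: int  # 1-based start within the region
    cds_len: int  # includes start and stop codon
    strand: str = "+"
    introns: tuple[tuple[int, int], ...] = ()  # (cds position after which, length)

    @property
    def genomic_len(self) -> int:
        return self.cds_len + sum(l for _, l in self.introns)


@dataclass(frozen=True)
class PlantedSSR:
    motif: str
    copies: int
    region: str  # LSC | SSC | IRb
    offset: int  # 1-based start within the region


@dataclass(frozen=True)
class PlastomeSpec:
    """Ground-truth description of one synthetic plastome.

    Defaults emulate the quadripartite proportions and per-region GC typical
    of slipper-orchid plastomes (LSC ~86 kb at ~33% GC, tiny SSC ~1.8 kb at
    ~23% GC, IRs ~34.5 kb at ~39% GC).
    """

    lsc_len: int = 86_000
    ir_len: int = 34_500
    ssc_len: int = 1_800
    gc: dict[str, float] = field(
        default_factory=lambda: {"LSC": 0.335, "SSC": 0.23, "IR": 0.394}
    )
    genes: tuple[GeneModel, ...] = ()
    ssrs: tuple[PlantedSSR, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lsc_len <= self.ssc_len:
            raise ValidationError("LSC must be longer than SSC")
        region_len = {"LSC": self.lsc_len, "SSC": self.ssc_len, "IRb": self.ir_len}
        spans: dict[str, list[tuple[int, int]]] = {r: [] for r in region_len}
        for g in self.genes:
            if g.region not in region_len:
                raise ValidationError(f"gene {g.name}: unknown region {g.region}")
            if g.cds_len % 3:
                raise ValidationError(f"gene {g.name}: CDS length not divisible by 3")
            end = g.offset + g.genomic_len - 1
            if not (1 <= g.offset and end <= region_len[g.region]):
                raise ValidationError(f"gene {g.name} does not fit in {g.region}")
            spans[g.region].append((g.offset, end))
        for s in self.ssrs:
            if s.region not in region_len:
                raise ValidationError(f"SSR {s.motif}: unknown region {s.region}")
            end = s.offset + len(s.motif) * s.copies - 1
            if not (2 <= s.offset and end <= region_len[s.region] - 1):
                raise ValidationError(
                    f"SSR {s.motif}x{s.copies} at {s.region}:{s.offset} does not fit"
                )
            spans[s.region].append((s.offset - 1, end + 1))
        for r, ivs in spans.items():
            ivs.sort()
            for (s1, e1), (s2, _) in zip(ivs, ivs[1:]):
                if s2 <= e1:
                    raise ValidationError(f"planted elements overlap in {r}")

    @property
    def genome_length(self) -> int:
        return self.lsc_len + 2 * self.ir_len + self.ssc_len

    @property
    def partition(self) -> QuadripartitePartition:
        return QuadripartitePartition(self.lsc_len, self.ir_len, self.ssc_len, self.ir_len)


def default_gene_models(spec_lsc: int, spec_ssc: int, spec_ir: int) -> tuple[GeneModel, ...]:
    """A compact paper-like gene complement scaled to the region sizes."""
    genes = []
    # LSC genes every ~1.2 kb until the region is reasonably occupied
    n_lsc = max(2, min(20, spec_lsc // 1200))
    pitch = spec_lsc // (n_lsc + 1)
    for i in range(n_lsc):
        introns = ((90, 120),) if i % 5 == 2 else ()
        genes.append(
            GeneModel(
                f"lscg{i+1:02d}",
                "LSC",
                offset=pitch * i + 50,
                cds_len=300 + 30 * (i % 4),
                strand="+" if i % 2 == 0 else "-",
                introns=introns,
            )
        )
    if spec_ssc >= 600:
        genes.append(GeneModel("sscg1", "SSC", offset=80, cds_len=300))
    if spec_ir >= 1500:
        genes.append(GeneModel("irg1", "IRb", offset=200, cds_len=330))
        genes.append(GeneModel("irg2", "IRb", offset=800, cds_len=300, strand="-"))
    return tuple(genes)


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return _BASES[rng.choice(4, size=n, p=p)]


def _random_orf(rng: np.random.Generator, cds_len: int, gc: float) -> str:
    """ATG + random non-stop codons + stop, of total length cds_len."""
    n_mid = cds_len // 3 - 2
    codons = ["ATG"]
    while len(codons) < n_mid + 1:
        c = bytes(_random_bases(rng, 3, gc)).decode()
        if c not in _STOPS:
            codons.append(c)
    codons.append("TAA")
    return "".join(codons)


def generate_plastome(
    spec: PlastomeSpec, seed: int | None = None
) -> tuple[CircularGenome, FeatureTable, list[PlantedSSR]]:
    """Build the genome, its feature table, and the planted SSR list.

    Deterministic under (spec, seed).  The background is re-sampled locally
    until `find_ssrs` detects exactly the planted loci, so SSR recovery on
    generator output is exact by construction.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    region_len = {"LSC": spec.lsc_len, "IRb": spec.ir_len, "SSC": spec.ssc_len}
    region_gc = {"LSC": spec.gc["LSC"], "IRb": spec.gc["IR"], "SSC": spec.gc["SSC"]}
    arrays = {
        r: _random_bases(rng, n, region_gc[r]) for r, n in region_len.items()
    }

    gene_seqs: dict[str, str] = {}

    def regen_gene(g: GeneModel) -> None:
        cds = _random_orf(rng, g.cds_len, region_gc[g.region])
        genomic = cds
        for after, ilen in sorted(g.introns, reverse=True):
            intron = bytes(_random_bases(rng, ilen, region_gc[g.region])).decode()
            genomic = genomic[:after] + intron + genomic[after:]
        if g.strand == "-":
            genomic = revcomp(genomic)
        gene_seqs[g.name] = genomic

    def write_genes() -> None:
        for g in spec.genes:
            arr = np.frombuffer(gene_seqs[g.name].encode(), dtype=np.uint8)
            arrays[g.region][g.offset - 1 : g.offset - 1 + len(arr)] = arr

    def write_ssrs() -> None:
        for s in spec.ssrs:
            tract = (s.motif * s.copies).encode()
            a = arrays[s.region]
            start = s.offset - 1
            a[start : start + len(tract)] = np.frombuffer(tract, dtype=np.uint8)
            # break extendability at both flanks
            unit = s.motif
            left, right = start - 1, start + len(tract)
            if left >= 0 and chr(a[left]) == unit[-1]:
                a[left] = ord(_different_base(unit[-1]))
            if right < len(a) and chr(a[right]) == unit[0]:
                a[right] = ord(_different_base(unit[0]))

    def guard_ir_boundaries() -> None:
        """Keep the IR pair exactly the planted length: the bases flanking the
        repeats must not extend the reverse-complement match by chance.

        Extension across JLB/JLA needs last(LSC) == complement(first(LSC));
        extension across JSB/JSA needs last(SSC) == complement(first(SSC))."""
        comp = dict(zip(b"ACGT", b"TGCA"))
        planted = {
            (r, pos)
            for g in spec.genes
            for r in [g.region]
            for pos in range(g.offset - 1, g.offset - 1 + g.genomic_len)
        }
        for region in ("LSC", "SSC"):
            a = arrays[region]
            if len(a) and a[-1] == comp[a[0]]:
                for idx in (len(a) - 1, 0):
                    if (region, idx) not in planted:
                        a[idx] = ord(_different_base(chr(a[idx])))
                        break
                else:
                    raise ValidationError(
                        f"cannot guard {region} boundary: edges are planted"
                    )

    def assemble() -> CircularGenome:
        ira = np.frombuffer(
            revcomp(bytes(arrays["IRb"]).decode()).encode(), dtype=np.uint8
        )
        seq = bytes(np.concatenate([arrays["LSC"], arrays["IRb"], arrays["SSC"], ira]))
        return CircularGenome("synthetic", seq.decode())

    for g in spec.genes:
        regen_gene(g)
    write_genes()
    write_ssrs()
    guard_ir_boundaries()

    planted_spans = _expected_ssr_spans(spec)
    for _ in range(120):
        genome = assemble()
        found = find_ssrs(genome)
        extra = [x for x in found if (x.start, x.length) not in planted_spans]
        if not extra:
            break
        # resample only what the accidental loci touch: the background bases
        # under each locus, and any gene whose planted sequence the locus
        # overlaps (checking the IRb footprint for loci in the IRa mirror)
        touched: set[tuple[str, int]] = set()
        for x in extra:
            touched |= _scrub_locus(x, spec, arrays, rng, region_gc)
        for g in spec.genes:
            footprint = {
                (g.region, i)
                for i in range(g.offset - 1, g.offset - 1 + g.genomic_len)
            }
            if footprint & touched:
                regen_gene(g)
        write_genes()
        write_ssrs()
        guard_ir_boundaries()
    else:
        raise ValidationError("could not scrub accidental SSRs from the background")

    table = FeatureTable("synthetic", [], genome_length=spec.genome_length)
    offsets = {"LSC": 0, "IRb": spec.lsc_len, "SSC": spec.lsc_len + spec.ir_len}
    ira_start = spec.lsc_len + spec.ir_len + spec.ssc_len
    for g in spec.genes:
        gstart = offsets[g.region] + g.offset
        gend = gstart + g.genomic_len - 1
        table.features.append(Feature(g.name, "gene", g.strand, [(gstart, gend)]))
        exons = _exon_intervals(g, gstart)
        if len(exons) > 1:
            table.features.append(Feature(g.name, "exon", g.strand, exons))
        if g.region == "IRb":
            # mirrored copy in IRa, on the opposite strand
            def mirror(iv):
                s, e = iv
                rel_s, rel_e = s - offsets["IRb"] - 1, e - offsets["IRb"] - 1
                return (
                    ira_start + (spec.ir_len - 1 - rel_e) + 1,
                    ira_start + (spec.ir_len - 1 - rel_s) + 1,
                )
            mstrand = "-" if g.strand == "+" else "+"
            ms, me = mirror((gstart, gend))
            table.features.append(Feature(g.name + "_ira", "gene", mstrand, [(ms, me)]))
            if len(exons) > 1:
                table.features.append(
                    Feature(
                        g.name + "_ira", "exon", mstrand,
                        sorted(mirror(iv) for iv in exons),
                    )
                )
    table.derive_all()
    return assemble(), table, list(spec.ssrs)


def _exon_intervals(g: GeneModel, gstart: int) -> list[tuple[int, int]]:
    """Genomic exon intervals of a planted gene."""
    exons = []
    cursor = gstart
    prev_cds = 0
    for after, ilen in sorted(g.introns):
        exons.append((cursor, cursor + (after - prev_cds) - 1))
        cursor += (after - prev_cds) + ilen
        prev_cds = after
    exons.append((cursor, cursor + (g.cds_len - prev_cds) - 1))
    return exons


def _different_base(b: str) -> str:
    return {"A": "C", "C": "A", "G": "T", "T": "G"}[b]


def _expected_ssr_spans(spec: PlastomeSpec) -> set[tuple[int, int]]:
    """Genome-coordinate (start, length) spans of planted loci, including the
    IRa mirrors of loci planted in IRb."""
    offsets = {"LSC": 0, "IRb": spec.lsc_len, "SSC": spec.lsc_len + spec.ir_len}
    ira_start = spec.lsc_len + spec.ir_len + spec.ssc_len
    spans = set()
    for s in spec.ssrs:
        length = len(s.motif) * s.copies
        spans.add((offsets[s.region] + s.offset, length))
        if s.region == "IRb":
            rel = s.offset - 1
            mirror_start = ira_start + (spec.ir_len - (rel + length)) + 1
            spans.add((mirror_start, length))
    return spans


def _scrub_locus(locus, spec, arrays, rng, region_gc) -> set[tuple[str, int]]:
    """Replace the bases under an accidental SSR with fresh random sequence,
    mapping genome coordinates back onto the region arrays (IRa maps onto the
    mirrored IRb positions).  Returns the touched (region, index) pairs."""
    L = spec.genome_length
    touched: set[tuple[str, int]] = set()
    bounds = [
        ("LSC", 0, spec.lsc_len),
        ("IRb", spec.lsc_len, spec.lsc_len + spec.ir_len),
        ("SSC", spec.lsc_len + spec.ir_len, spec.lsc_len + spec.ir_len + spec.ssc_len),
        ("IRa", spec.lsc_len + spec.ir_len + spec.ssc_len, L),
    ]
    for p in range(locus.start - 1, locus.start - 1 + locus.length):
        p %= L
        for name, s, e in bounds:
            if s <= p < e:
                if name == "IRa":
                    rel = spec.ir_len - 1 - (p - s)
                    arrays["IRb"][rel] = _random_bases(rng, 1, region_gc["IRb"])[0]
                    touched.add(("IRb", rel))
                else:
                    arrays[name][p - s] = _random_bases(rng, 1, region_gc[name])[0]
                    touched.add((name, p - s))
                break
    return touched


@dataclass(frozen=True)
class EvolutionSpec:
    """Star-phylogeny divergence process applied to an ancestor."""

    sub_prob: float = 0.005  # per-site substitution probability per lineage
    indel_rate: float = 0.0  # expected indel events per site per lineage
    indel_mean_len: float = 4.0
    region_multipliers: tuple[tuple[int, int, float], ...] = ()  # (start, end, x)
    ir_homogenize: bool = True

    def __post_init__(self) -> None:
        if not (0 <= self.sub_prob <= 1 and self.indel_rate >= 0):
            raise ValidationError("rates out of range")


@dataclass
class SubEvent:
    position: int  # 1-based ancestor coordinate
    from_base: str
    to_base: str
    mirrored: bool = False


@dataclass
class IndelEvent:
    position: int  # 1-based ancestor coordinate (insertion: after this base)
    length: int
    kind: str  # "ins" | "del"
    inserted: str = ""


@dataclass
class EventLog:
    """Per-descendant mutation events, replayable against the ancestor."""

    events: dict[str, tuple[list[SubEvent], list[IndelEvent]]] = field(
        default_factory=dict
    )

    def replay(self, ancestor: CircularGenome, descendant_id: str) -> str:
        subs, indels = self.events[descendant_id]
        arr = bytearray(ancestor.seq.encode())
        for ev in subs:
            assert chr(arr[ev.position - 1]) == ev.from_base
            arr[ev.position - 1] = ord(ev.to_base)
        for ev in sorted(indels, key=lambda e: -e.position):
            if ev.kind == "del":
                del arr[ev.position - 1 : ev.position - 1 + ev.length]
            else:
                arr[ev.position : ev.position] = ev.inserted.encode()
        return arr.decode()


def _mirror_pos(pos: int, irb: tuple[int, int], ira: tuple[int, int]) -> int:
    """Map a 1-based position in IRb to its reverse-complement partner in IRa."""
    return ira[1] - (pos - irb[0])


def evolve(
    ancestor: CircularGenome,
    spec: EvolutionSpec,
    n_descendants: int,
    seed: int = 0,
    partition: QuadripartitePartition | None = None,
):
    """Evolve independent descendants and return
    (descendants, EventLog, truth AlignedMatrix incl. the ancestor row).

    With ``ir_homogenize`` (requires ``partition``) substitutions drawn in
    IRb are mirrored into IRa and indels avoid both IR copies, so descendant
    IRs remain exact reverse complements.
    """
    from .divergence import AlignedMatrix

    rng = np.random.default_rng(seed)
    L = ancestor.length
    anc = np.frombuffer(ancestor.seq.encode(), dtype=np.uint8)
    homog = spec.ir_homogenize and partition is not None
    if homog:
        irb = partition.spans["IRb"]
        ira = partition.spans["IRa"]
        in_ira = np.zeros(L, dtype=bool)
        in_ira[ira[0] - 1 : ira[1]] = True
        in_ir = in_ira.copy()
        in_ir[irb[0] - 1 : irb[1]] = True
    else:
        in_ira = np.zeros(L, dtype=bool)
        in_ir = in_ira

    prob = np.full(L, spec.sub_prob)
    for s, e, mult in spec.region_multipliers:
        prob[s - 1 : e] *= mult
    prob = np.clip(prob, 0.0, 1.0)

    log = EventLog()
    desc_subs: dict[str, dict[int, int]] = {}  # 0-based pos -> new byte
    desc_dels: dict[str, set[int]] = {}
    desc_ins: dict[str, dict[int, str]] = {}  # after 0-based pos -> seq
    names = [f"d{i+1}" for i in range(n_descendants)]
    for name in names:
        subs: list[SubEvent] = []
        smap: dict[int, int] = {}
        hit = np.flatnonzero((rng.random(L) < prob) & ~in_ira)
        for p in hit:
            old = chr(anc[p])
            if old not in "ACGT":
                continue
            choices = [b for b in "ACGT" if b != old]
            new = choices[rng.integers(0, 3)]
            smap[int(p)] = ord(new)
            subs.append(SubEvent(int(p) + 1, old, new))
            if homog and irb[0] - 1 <= p < irb[1]:
                mp = _mirror_pos(int(p) + 1, irb, ira) - 1
                m_old = chr(anc[mp])
                m_new = revcomp(new)
                smap[mp] = ord(m_new)
                subs.append(SubEvent(mp + 1, m_old, m_new, mirrored=True))

        indels: list[IndelEvent] = []
        dels: set[int] = set()
        ins: dict[int, str] = {}
        eligible = np.flatnonzero(~in_ir) if homog else np.arange(L)
        n_events = rng.poisson(spec.indel_rate * len(eligible))
        for _ in range(n_events):
            p = int(eligible[rng.integers(0, len(eligible))])
            length = int(rng.geometric(1.0 / spec.indel_mean_len))
            if rng.random() < 0.5:
                # deletion starting at p, clipped to stay in eligible territory
                span = []
                q = p
                while len(span) < length and q < L and not in_ir[q]:
                    span.append(q)
                    q += 1
                if not span or any(q in dels for q in span):
                    continue  # colliding deletions are redrawn as nothing
                dels.update(span)
                indels.append(IndelEvent(p + 1, len(span), "del"))
            else:
                if p in ins:
                    continue
                seq = bytes(_random_bases(rng, length, 0.35)).decode()
                ins[p] = seq
                indels.append(IndelEvent(p + 1, length, "ins", inserted=seq))
        # an insertion anchored on a deleted base cannot be replayed exactly
        for q in [q for q in ins if q in dels]:
            del ins[q]
        indels = [
            e for e in indels if e.kind == "del" or (e.position - 1) not in dels
        ]
        log.events[name] = (subs, indels)
        desc_subs[name], desc_dels[name], desc_ins[name] = smap, dels, ins

    # Build descendant sequences and the truth alignment by bookkeeping.
    aln_rows: dict[str, list[str]] = {ancestor.id: []}
    for name in names:
        aln_rows[name] = []
    descendants = []
    for name in names:
        arr = anc.copy()
        for p, b in desc_subs[name].items():
            arr[p] = b
        out = []
        for p in range(L):
            if p in desc_dels[name]:
                continue
            out.append(chr(arr[p]))
            if p in desc_ins[name]:
                out.append(desc_ins[name][p])
        descendants.append(CircularGenome(name, "".join(out)))

    for p in range(L):
        aln_rows[ancestor.id].append(chr(anc[p]))
        for name in names:
            if p in desc_dels[name]:
                aln_rows[name].append("-")
            else:
                b = desc_subs[name].get(p)
                aln_rows[name].append(chr(b) if b is not None else chr(anc[p]))
        for name in names:
            seq = desc_ins[name].get(p)
            if seq is None:
                continue
            aln_rows[ancestor.id].append("-" * len(seq))
            for other in names:
                aln_rows[other].append(seq if other == name else "-" * len(seq))

    ids = [ancestor.id] + names
    mat = np.frombuffer(
        "".join("".join(aln_rows[i]) for i in ids).encode(), dtype=np.uint8
    ).reshape(len(ids), -1).copy()
    truth = AlignedMatrix(ids, mat, reference_id=ancestor.id)
    return descendants, log, truth
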