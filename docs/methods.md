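# Methods

This note records the models, conventions and numerical choices behind
plastidcomp, in the order the pipeline runs them.

## Coordinates and formats

All genomic coordinates are 1-based inclusive. Circular topology is handled
by interval splitting: an element spanning the origin is stored as two
non-wrapping intervals of one feature, never as coordinates below 1 or above
the genome length. Sequences travel as FASTA (via Biopython), annotations as
a GFF3 subset (gene/tRNA/rRNA/exon records; attribute `pseudo=true` marks
pseudogenes, which are kept in the table but barred from codon analysis).
Introns are derived as gaps between the exons of a gene, intergenic spacers
as the complement of gene extents on the circle, named
`upstream-downstream` in genome order. GC content counts G+C over
unambiguous bases only; other IUPAC codes are accepted on input but excluded
from both numerator and denominator.

## Quadripartite detection

The partition is defined as the maximal-length pair of disjoint
reverse-complement repeats on the circle, with the shorter single-copy gap
labelled SSC. Search is exact (mismatch budget 0 by default): 31-mer seeds
shared between the doubled sequence and its reverse complement select
diagonals, each diagonal's maximal runs are verified base by base, and the
longest disjoint pair wins; ties are broken by the smallest JLB after
canonical rotation, then lexicographically. Real plastome IR copies are
near-identical, so exactness costs nothing on clean assemblies and buys
determinism and oracle comparability; a seed-and-extend mode with a small
mismatch budget exists for degraded inputs but is not used by any shipped
analysis.

Canonical orientation: of the two strand representations, each rotated so
LSC starts at base 1 with region order LSC–IRb–SSC–IRa, the
lexicographically smaller sequence is canonical. Forward and
reverse-complement inputs therefore canonicalize to the identical string,
with `strand_flipped` recording which happened. Junction coordinates follow
the convention of published plastome tables: JLB/JSB/JSA are the first base
of the downstream region and JLA is the last base of IRa (the genome length
in canonical rotation). Junction context reports, per side, the nearest gene
and its distance measured from the junction coordinate to the gene end
(or start), with distance 0 and the per-side base split when a gene
straddles the boundary. SSC flip isomers are not standardized: the reported
SSC strand follows the input.

## SSR scan

A locus is a maximal perfect tandem array of a primitive unit (1–6 bp)
meeting its copy threshold; the defaults are mono 8, di 4, tri 4, tetra 3,
penta 3, hexa 3. Only perfect repeats are reported — no compound or
interrupted joining. Detection compares the sequence with itself shifted by
each unit length; a maximal run of agreement of length m yields
⌊(m+u)/u⌋ copies at the leftmost in-phase start. Non-primitive units are
discarded, which is exactly what enforces the smallest-primitive-unit rule
(a run of 12 A's would otherwise resurface as AA×6, AAA×4, ...). On
circular genomes the scan runs on the doubled sequence; seam artifacts are
removed by dropping any locus whose circular span is contained in a longer
locus of the same canonical type. Motif types are equivalence classes under
cyclic rotation and reverse complement; the class representative is the
lexicographic minimum over all rotations of the motif and of its reverse
complement.

Region assignment uses the locus midpoint (deterministic and symmetric for
junction-straddling loci), with precedence gene > intron > intergenic when
annotations overlap. IR loci are counted once per copy — a locus in IRb and
its mirror in IRa are two loci — so per-genome IRa and IRb counts are always
equal. Densities pool loci and region lengths across genomes:
count/length×1000, to 2 decimals, with the two IR copies pooled as one
class.

## Divergence statistics

Site classification and diversity use complete deletion: only columns where
every row carries an unambiguous base participate, and `N` counts as
missing, like a gap, to avoid inflating diversity. A gap-free column is
variable with ≥2 distinct bases, a singleton when exactly one sequence
deviates, parsimony-informative with ≥2 bases each in ≥2 sequences.
π is the mean over all N(N−1)/2 pairs of per-pair mismatch proportion;
θ = S/(a_n·L) over the same gap-free column set, so S is by construction
the variable-site count of the classifier.

Sliding windows are defined on alignment columns, not reference
coordinates, at 600/200 by default; complete deletion is applied per
window, the final short window is kept and flagged, and an all-gap window
gets π = NaN. Hypervariable regions are built by scanning windows in
descending π, merging any window that overlaps an existing peak and opening
new peaks until k exist; peaks are then annotated with the reference
features their columns overlap. Ties rank by coordinate.

Pairwise indel/substitution counts first drop columns gapped in both rows;
each remaining maximal gap run in either row is one indel event regardless
of length (a run interrupted only by shared-gap columns still counts once),
and substitutions are columns with two differing unambiguous bases.

Per-region percent variability is anchored on the reference genome's
annotation: a region's columns are those whose nearest preceding reference
base falls in the region (insertion columns inherit leftward), and a column
is variable when it shows ≥2 distinct states over {A,C,G,T,−} with N
ignored — so a region deleted in some taxa is 100% variable, matching how
such regions behave in identity plots. Pooled coding (gene/tRNA/rRNA) and
non-coding (intron + spacer) percentages accompany the per-region table.

## Codon rates

Shared protein-coding genes are spliced strand-aware, stop-stripped,
checked for frame and internal stops, and concatenated alphabetically by
gene name; a gene absent or pseudogenized in any taxon, or failing a frame
or equal-length check, is excluded with a recorded reason. Codon-aware
alignment of unequal-length orthologs is out of scope, so equal length
across taxa is a requirement, not an alignment step.

The estimator is Nei–Gojobori (1986). Synonymous sites per codon are the
per-position fractions of the three possible changes that preserve the
amino acid, averaged over the two sequences; mutations creating a stop are
counted as nonsynonymous with the denominator kept at 3. Codons differing
at 2–3 positions are resolved by averaging the synonymous/nonsynonymous
split over all minimal mutational pathways; pathways through stop codons
are excluded, with a fallback to all pathways when every one is blocked
(possible only for rare codon pairs). pS = Sd/S and pN = Nd/N are corrected
with Jukes–Cantor, d = −(3/4)·ln(1−(4/3)p), reported saturated (infinite)
at p ≥ 3/4. ω is undefined (NA) when dS = 0. Codons containing gaps or
ambiguity in either sequence of a pair are dropped pairwise. The genetic
code table is selectable (NCBI table ids via Biopython; default 1); plastid
protein genes translate identically under tables 1 and 11. Extreme-value
filters (dN > 0.5, dS > 5, dS < 0.0005) flag likely saturation or ortholog
misassignment; filtered pairs are reported but excluded from summaries.

NG86 deliberately does not model transition/transversion bias or codon
usage (that is YN00's territory), so its dN/dS values are comparable in
direction and magnitude, not digit-for-digit, with yn00 output.

## Synthetic plastomes

The generator emulates the layout the analyses target: LSC ≫ IR > SSC with
two exact reverse-complement IR copies, per-region GC (defaults 33.5 / 23 /
39.4% for LSC/SSC/IR, genome ~157 kb — the slipper-orchid configuration
with its unusually tiny SSC), planted ORF genes (ATG + non-stop codons +
TAA, optionally split by introns; IRb genes mirrored into IRa), and planted
SSR tracts whose flanks are set so they cannot extend. Two constructive
guarantees make recovery exact rather than probable: the bases flanking the
IR copies are adjusted so the reverse-complement match cannot extend past
the planted boundary by chance, and the background is iteratively scrubbed
— any accidental SSR is resampled locally (regenerating a planted gene only
if the locus touches it) until a scan finds exactly the planted set. All
randomness flows from one seeded generator, so (spec, seed) determines every
output byte.

Evolution is a star phylogeny: each descendant independently receives
Bernoulli(p) substitutions per site (default p = 0.005, the low-percent
interspecific divergence typical of congeneric plastomes), with optional
interval multipliers to plant hotspots, and Poisson indel events with
geometric lengths (mean 4 by default). With IR homogenization on (default),
substitutions drawn in IRb are mirrored into IRa — mimicking concerted IR
evolution — and indels avoid the IRs entirely, keeping the event
bookkeeping exact. The true multiple alignment is constructed from the
event log (deletions become gaps at ancestor columns, insertions become
descendant-specific column blocks), never by re-alignment, and the log
replays to the exact descendant sequence. Insertions whose anchor base is
deleted in the same lineage are discarded rather than logged ambiguously.

What the generator does not emulate: phylogenetic covariance (no tree
shape), codon-aware selection, rate heterogeneity beyond the planted
multipliers, SSC flip-flop isomers, and sequencing/assembly error. Tests
passing on generator output therefore validate the algorithms and their
bookkeeping, not robustness to misassembly or alignment error in real data.

## Problem sizes

The shipped test suite and the acceptance script use scaled-down genomes —
typically LSC 6–30 kb, IR 1.5–8 kb, SSC 0.5–1.5 kb, nine taxa for the full
study — which preserve every structural property of the full-size layout
(two IR copies, tiny SSC, realistic per-region GC) while keeping exhaustive
oracles (O(L²) repeat search, full SSR enumeration, all-codon-pair pathway
checks) cheap enough to run on every change. Statistical checks
(substitution envelopes) use 50–200 kb of sequence so binomial intervals
are tight.
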