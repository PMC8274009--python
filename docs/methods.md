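# Methods

This note documents the models, parameter choices and numerical
conventions behind svkit, and what the bundled simulator does and does not
emulate.

## Coordinates and breakend conventions

All internal coordinates are 1-based inclusive (SAM/VCF style); intervals
are closed. A breakend is a locus plus a direction: `HEAD` means the
anchored (reference-supporting) bases lie at coordinates ≤ the breakend
and novel sequence continues to the right on the derivative chromosome
(`+` orientation, `t[p[`-style VCF alleles); `TAIL` is the mirror. A
breakpoint is an ordered pair of breakends plus any non-template inserted
sequence; the canonical form orders breakends lexicographically and
left-normalises the junction through its homology interval, so the same
physical junction assembled from either side deduplicates exactly.

## Evidence extraction

Reads are admitted as evidence under fixed rules: soft/hard clips and
indels of at least 5 bp; mapping quality at least 20 (lower-mapq reads are
treated as unmapped and contribute only as the unmapped mate of their
partner); duplicates and secondary/supplementary records never contribute;
alignment sequence entropy must exceed 0.5 bits (a configurable default
chosen to remove homopolymer/dinucleotide junk while keeping AT-rich
sequence — no published value exists for this threshold); clips matching
bundled Illumina adapter starts (exact ≥ 6 bp, or ≥ 12 bp at ≤ 10%
mismatch) are suppressed; pileups above 50,000x are ignored.

The library profile is estimated from the input file: concordant
fragment-size bounds are the 0.25%/99.75% empirical quantiles (central
99.5% mass) of proper-pair template lengths, with template lengths more
than 10x the median discarded first — those are SV-spanning or chimeric
pairs, not library fragments, and a handful of them would otherwise drag
the upper quantile far outside the true fragment distribution on small
simulated genomes. `max_fragment`, which sizes assembly windows and
phasing neighbourhoods, is likewise the upper concordant bound rather than
the literal maximum observed template length, for the same robustness
reason.

Supplementary-alignment (SA) chains are converted on ingest to an internal
convention in which the chain is expressed in the orientation of the
stored primary sequence; this removes strand bookkeeping from every
downstream consumer.

## Assembly

Breakend contigs are assembled per junction window and direction with a
positional de Bruijn graph (k = 25 by default; k must exceed common
homopolymer runs and stay below the read length). Kmers wholly inside the
anchoring alignment occupy exact junction-relative positions — one node
per (offset, kmer) — while kmers at or beyond the junction (clipped bases,
unmapped-mate sequence, whose true offset is unknown) share a single
positional bucket. Node weight is read count; consensus extension follows
the maximal-weight successor with lexicographic tie-breaking on the kmer,
so assembly is independent of input order. Traversal truncates when a
node is revisited or when two extensions tie in weight: both are
signatures of an unresolved repeat loop (e.g. a satellite unit or polyA
run shorter than k), and truncating is preferred to guessing. Contigs
longer than 1.5x the maximum fragment size, or supporting only the
reference, are discarded; a window is flushed after three contigs each
exceed 50,000 alternative graph paths.

Per-fragment support is tracked per contig base. A fragment supports a
breakpoint only if its support interval extends at least one base beyond
the homology interval on both sides — this keeps matched-normal fragments
that merely share an anchor from counting toward a somatic junction.

When rearrangements cluster, reads primary-align inside short DNA
segments and each window only sees one junction. Contigs are therefore
extended through (k−1)-overlaps with other contigs (both orientations, up
to six joins, capped at 1.5x max fragment). This reconstructs consensus
sequence spanning several junctions and is what produces the ≥ 3-alignment
chains that drive cis phasing.

## Realignment and homology

The built-in aligner is seeded exact-match (16-mer seeds at the query
start, middle and end; both strands) with ungapped diagonal extension
under +1/−4 scoring and no clipping penalty. Effective mapping quality
encodes placement uniqueness, `60·(1 − second_best/best)` clamped to
[0, 60], where only hits covering substantially the same query interval
compete (alignments to other parts of a chimeric query are not
competitors). This formula is a documented stand-in for an external
aligner's unpublished mapq model; any engine honouring the same
`AlignmentHit` contract can be plugged in. The aligner is adequate for
the synthetic references this package targets (≤ a few Mb); it does not
build an FM-index and performs no affine-gap traceback.

Compound realignment seeds the chain with the contig's own anchor
placement — known by construction — and iteratively feeds unaligned
(soft-clipped) bases back to the aligner until everything is aligned or no
confident (mapq ≥ 20) alignment remains. Segments shorter than 30 bp stay
unaligned and become insert sequence. Chains that never touch their
originating locus are discarded. Split bounds between adjacent alignments
are then adjusted to minimise edit distance: candidate boundary moves may
retract over any bases but extend only across exactly matching bases
(preventing boundary migration into random inserted sequence); ties prefer
converting a terminal mismatch into inserted sequence, then the leftmost
split.

Exact homology (CIPOS/HOMLEN/HOMSEQ) is computed by walking matching bases
on both sides of the junction — equivalent to enumerating all junction
placements that yield an identical derivative sequence — bounded at ±2 kb
(well beyond the 50 bp filter threshold). Inexact homology (IHOMPOS) runs
an affine-gap extension DP at scores +1 match, −4 mismatch, 6 gap open,
1 gap extend, with the breakpoint sequence and reference context taken
300 bp from the break and the reference extended a further 10 bp to absorb
indels; the reported length is the furthest breakpoint-sequence position
whose best running score stays positive. IHOMPOS always contains CIPOS.

## Calling

Candidates are (a) precise junctions and single breakends from realigned
contigs and (b) maximal cliques of direct two-sided/one-sided evidence
(networkx clique enumeration over the compatibility graph; two items are
compatible when their local interval × direction overlap and, for
breakpoints, the remote side too). Every evidence item is uniquely
allocated: first to a candidate whose assembly contains the fragment, then
to the highest pre-allocation score, then leftmost. Calls need two unique
supporting fragments (a fragment supporting directly and via assembly
counts once, the VF field); intrachromosomal events below the minimum
event size (default 10 bp; 32 bp for cohort-style running) are suppressed
unless inversion-like, so foldback inversions survive. A contig whose
breakend sequence has no unique alignment becomes a single breakend call
with its candidate alignments recorded (BEALN). Event size is the larger
of the affected reference span and the inserted length, so an insertion
represented with a few duplicated target-site bases is not mistaken for a
tiny duplication.

The quality model combines the stated ingredients (mapping qualities and
empirical signature rates) as `min(cap, −10·log10 rate)`; the combining
formula itself is this package's documented choice, as is retaining the
pre-reallocation sum in CQ. The allele fraction is
`VF/(VF+REF+REFPAIR)` for breakpoints and `BVF/(BVF+REF)` for single
breakends — REFPAIR is undefined at an unpartnered break. REF counts only
reads spanning the whole homology interval; REFPAIR counts concordant
pairs whose fragment, but neither read, spans it.

## Phasing

Chains with at least three non-overlapping alignments phase their adjacent
junctions cis (one link per adjacent pair, sharing the contig id); a chain
aligned to reference across another call's breakend (≥ 10 bp each side)
phases them trans, as does anchoring support extending ≥ 10 bp past a
neighbouring junction (neighbourhood = 1.5x max fragment; phasing reach is
physically bounded by the fragment size distribution). Transitive
collapsing searches the precise-breakpoint graph breadth-first from each
imprecise call's CIPOS-expanded breakend: paths are limited to 1000 bp
total, 4 segments of at least 20 bp each, may not revisit a junction, and
search is budgeted (100,000 paths globally, 1000 per start) with
leftmost-coordinate expansion for determinism. Collapsed calls are
annotated and excluded from the high-confidence set; the links themselves
are emitted as kind TRANSITIVE, leaving the cis/trans interpretation to
the consumer. Phasability reports, per breakend, the distance to the
first facing junction (HEAD at p pairs with the nearest TAIL at q ≤ p);
the uniform-placement baseline follows 1 − exp(−n·d/L).

## Somatic filtering

Thresholds are fixed at their published values: hard filters at 3% normal
support and any normal split read on del/dup under 1000 bp; low-confidence
rules at < 8 normal fragments, < 0.5% tumour AF, imprecise calls, single
breakends without an assembled discordant pair, poly-C/G runs ≥ 16 bp,
split-read strand bias ≥ 0.95 (short del/dup), homology > 50 bp, inexact
homology > 50 bp (non-short events), short del/dup without split-read
support or with normal split reads, long events without read-pair support,
100–800 bp deletions with inexact homology ≥ 6 bp, inversion-like events
≤ 40 bp with ≥ 6 bp homology, and pseudo-deletions whose insert length is
within 5 bp of the deleted length unless the insert is ≥ 0.5/base from the
deleted bases and < 0.2/base from their reverse complement (the exemption
is applied as a carve-out from the filter; the source wording is ambiguous
about ordering). "Breakend coverage" in the normal is VF+REF+REFPAIR
(BVF+REF for single breakends) — the denominator is not defined anywhere,
so this package fixes it. PON entries require precise calls at QUAL ≥ 75
(breakpoints) / ≥ 428 (single breakends) and match within 2 bp with equal
orientation on every breakend. The final quality floor is 350/1000 with
fixed-point rescue through any link kind except equivalence. Simple-event
annotation (35 bp margins, threefold support ratio) tests reciprocal
translocation, then templated insertion, then simple inversion — the
precedence among the three is not specified anywhere and is fixed here in
that order.

## The simulator

`sim_eval` generates a random reference (optionally with tandem satellite
arrays), applies non-overlapping rearrangements (DEL, DUP, INV, INS, TRA,
FOLDBACK, BND_INTO_REPEAT, CLUSTERED_CHAIN) to build derivative
haplotypes, and emits truth-placed, coordinate-sorted SAM: junction
reads carry correct soft clips and SA chains (pieces ≥ 20 bp), reads
wholly inside a repeat array are placed at an arbitrary unit with mapq 0,
and fragments mix reference and derivative haplotypes according to tumour
purity (a tumour cell is one reference plus one derivative haplotype, so
purity 1 gives ~50% junction allele fraction). Defaults emulate a
standard 2x150 bp Illumina WGS library: fragment mean 500 bp, s.d.
100 bp, 60x tumour / 40x normal, error-free bases (uniform substitutions
configurable). Everything is deterministic under the seed.

What the simulator does **not** model: alignment errors other than the
repeat-ambiguity mapq-0 rule, GC and coverage bias, PCR/optical
duplicates, chimeric library artefacts, indel sequencing errors, and
microhomology engineered at junctions (homology arises only by chance in
random sequence). Passing tests therefore demonstrate the correctness of
the calling logic under clean, truth-aligned input — not robustness to
real-world aligner behaviour or library artefacts.

Scale choices: test genomes are 50 kb–200 kb across a handful of
chromosomes, with 20 junctions for the end-to-end benchmark, 10 satellite
junctions for single-breakend recovery, and 500 planted transitions for
the FNR estimator — large enough for every rule and estimator to engage
with comfortable read counts, small enough that the whole suite and the
acceptance script each run in minutes on one CPU.

## Known limitations

* Insertions longer than the read can span minus the 30 bp unique-
  alignment floor (~120 bp at 2x150) cannot be resolved into a single
  breakpoint and surface as facing single breakends — an intrinsic
  short-read limit.
* The seeded aligner requires one exact 16-mer seed; heavily mutated
  segments would be missed (irrelevant for error-free simulation, a real
  limitation on noisy data).
* Assembly truncates at weight ties, which on 2-read windows can truncate
  legitimate disagreement; with the default two-fragment calling floor
  this has no practical effect in the bundled simulations.
* The PON here is constructed from simulated normals; no population-scale
  artefact panel ships with the package.
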