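# Methods

This note records the models, conventions and design choices behind
ssrkit, in the spirit of a methods appendix: what each stage assumes,
which knobs matter, and what the synthetic benchmarks do and do not
demonstrate.

## Coordinates and alphabet

All coordinates are 1-based and inclusive on both ends, everywhere
(the MISA/VCF convention); GFF3 and pysam internals are translated at
the I/O boundary only. Sequences are stored upper-case over
{A,C,G,T,N}; IUPAC ambiguity codes other than N are collapsed to N on
input, and N matches nothing in any downstream search — no repeat run,
primer window or binding site spans an N.

## Microsatellite mining

A perfect SSR of unit length k is a maximal periodic interval: every
base pairs with the base k positions downstream. The miner scans each
k in 1..6 with a vectorised shift-compare, extracts maximal True-runs,
and reports the run anchored at its leftmost phase with
`repeats = floor(interval/k)` complete units (a trailing partial unit
is excluded from the span, but blocks no report). Anchoring at the
leftmost phase means a run has exactly one description per unit
length: the rotated twin one base to the right is suppressed. Units
must be primitive — (AA) or (ATAT) re-describe intervals already
reported under the shorter unit — while overlapping runs with
*different* primitive units (an (AAT) run sliding into an (AT) run)
are both reported; no arbitration rule is imposed, keeping the output
deterministic and oracle-checkable. Mining is forward-strand only: a
repeat and its reverse-complement twin occupy the same interval, so
two-strand scanning would double-count.

Default minimum repeat counts are mono ≥ 10, di ≥ 6, tri/tetra/penta/
hexa ≥ 5; nearby runs merge into a compound locus when the gap is at
most 100 bases. Because the gap criterion is pairwise on adjacent
runs, greedy left-to-right chaining yields exactly the maximal chains.
Summary counters treat a compound as its member runs (the MISA
convention); whether a published total of this kind counts members or
wrappers is ambiguous in general, and member-counting is the
convention we fix. Genome-wide frequency is reported half-up at two
decimals.

## Context partition

An SSR's context is decided by its start coordinate: intergenic if the
start lies in no gene span, exon if it lies in an exon interval of the
first containing gene in sorted order, intron otherwise. The start
rule is deterministic and order-independent for boundary-spanning
repeats; a majority-overlap rule (largest base overlap wins, ties
exon > intron > intergenic) is available as a flag. Compartment sizes
derive from the union of gene spans — overlapping isoforms or genes
never double-count — and intergenic bp is total minus genic.

Per-compartment per-Mb frequencies and the SNP-link/isPCR ratio
statistics are printed truncated (347.55 → 347.5; 75.556 → 75.55),
matching how such surveys conventionally print ratios; the genome-wide
frequency keeps half-up rounding. Repeat-count bin tables split units
into non-triplet (mono, di, tetra, penta) and triplet (tri, hexa)
classes — triplet-length changes preserve reading frame — with fixed
bin edges up to 350 (non-triplet) or 250 (triplet) repeats; runs past
the last edge are dropped and counted. Motif presence sets compare
genic vs intergenic motif inventories after canonicalisation to the
lexicographically smallest rotation, by default also over the reverse
complement (so AAAT and ATTT are one family).

## Primer design

The designer enumerates every candidate window of length 18–27 within
400 bp on each side of the repeat (forward fully left, reverse fully
right), keeps windows with GC in [20, 80]%, nearest-neighbor Tm in
[50, 60] °C and no self-complementary run of 8+ bases (a lightweight
hairpin/self-dimer guard standing in for full duplex thermodynamics),
and scores each feasible pair with product size in [100, 500] by

    penalty = |lenF−20| + |lenR−20| + |TmF−55| + |TmR−55| + |GCF−50| + |GCR−50|

(unit weights, configurable). The minimum-penalty pair wins; exact
ties resolve to the smaller product, then the leftmost forward start,
making the output deterministic and equal to exhaustive search. An SSR
with infeasible geometry (short flank, no window passing the filters)
simply yields no pair — on real assemblies a substantial minority of
repeats fail, which is why marker totals trail repeat totals. Compound
loci are targeted as their full span. The 400 bp search flank is a
cost/feasibility compromise: it must reach 500 bp products but bounds
the enumeration.

Melting temperatures are nearest-neighbor with SantaLucia-1998 unified
parameters, 50 mM monovalent salt, 50 nM oligo concentration, and the
SantaLucia-1998 entropy salt correction (primer3-like conditions),
computed via Biopython's thermodynamic tables; the test suite checks
them against an independently hand-summed implementation. The Wallace
2(A+T)+4(G+C) rule is available behind a flag for cross-checks.

## SNP linking

A marker's flanking region is its amplicon minus the repeat motif (at
most two sub-intervals); the ratio identity regions-with-SNPs /
markers makes clear such regions are primer-defined. Whether
motif-interior SNPs should count is genuinely open — microsatellite
instability makes calls inside the tract less reliable — so the
default excludes them and `include_motif` restores them. A SNP in two
overlapping amplicons counts once per region, consistent with
per-region means. Indel rows in the input are skipped and counted;
multi-allelic rows expand to one record per alternate allele.

## In silico PCR

primersearch semantics: binding sites are every position on either
strand with Hamming distance ≤ floor(pct/100 × primer length) — no
indels, N never matches. Amplimers are all (plus-site, downstream
minus-site) combinations within `max_amplimer` (default 5000 bp,
safely above any plausible PCR product), in both primer-role
orientations, deduplicated on coordinates and reported with outer
5'→5' spans, which is what gel-estimated product lengths correspond
to. The default mismatch budget is 0% — the reproducible choice when a
published setting is unknown — with the percentage exposed.

## Codon analysis

The trinucleotide motif space holds 60 primitive units (64 minus the
four homopolymers). For exon trinucleotide repeats, each distinct
literal unit is read as a codon in its literal frame and reported with
the set of stop codons at Hamming distance 1; the full sense-codon
sweep yields 18 stop-convertible codons, several reaching two stops.
Literal-frame reading matches how such tables are usually presented;
an `include_rotations` flag additionally evaluates the unit's two
rotations, since a repeat tract can be read in any frame. Standard
nuclear genetic code only.

## Synthetic data

The generator emulates the survey's input regime at desk scale:
multi-scaffold genomes (default 4 × 60 kb) with i.i.d. background at
39% GC (date-palm-like), a deterministic gene tiling giving ~32% genic
sequence (three 400 bp exons separated by 600 bp introns per gene,
matching the real assembly's roughly one-third genic fraction), and
Bernoulli SNPs at 0.0092 per bp — the density of the ~3.5 M SNP file
over the ~381 Mb assembly. Planted SSRs are placed in the requested
compartment with ≥ 120 clear bases around each plant (beyond the
100 bp compound-merge distance), and the background is
rejection-resampled until mining recovers exactly the planted set —
incidental threshold-meeting repeats and junction artefacts are
scrubbed. A `guard=False` mode skips the screen for fuzzing against
the brute-force oracle.

What passing on this generator shows: the mining, classification,
design, linking and isPCR machinery is exact on sequences whose truth
is known. What it does not show: behaviour on real genomes'
non-i.i.d. composition (GC isochores, transposon arrays, imperfect
repeats), assembly gaps beyond simple N handling, or the design-rate
shortfall caused by repetitive flanks — those must be assessed on real
assemblies.

## Benchmark problem sizes

The test suite and acceptance script run at desk scale, chosen to
exercise every code path while keeping runs interactive: 50
repeat-enriched 10–20 kb sequences for the miner/oracle comparison,
200 guarded plants over 5 × 80 kb for truth recovery, 45 plants over
3 × 40 kb for the design → isPCR round trip, and 10,000 SNPs × 500
regions for the linking oracle. The full-genome statistics of the
original survey (172,075 SSRs, 111,403 primer pairs, 250,507 linked
SNPs) require downloading the 381 Mb assembly and its SNP file;
the published per-Mb and per-region arithmetic is instead verified
directly from the printed counts.

## Known limitations

Imperfect/approximate microsatellites and units above 6 bp are out of
scope. The primer designer models no cross-pair dimers, probes or
multiplexing, and its hairpin guard is combinatorial, not
thermodynamic. In silico PCR ignores indels in primer binding and
circular templates. Gene annotation uses a single exon union per gene
(no UTR/CDS distinction). Excel output is not produced; TSV/JSON are
canonical.
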