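# ssrkit

A genome-wide SSR (simple sequence repeat / microsatellite) marker
toolkit for draft plant genome assemblies, built around the workflow
used to produce genic and intergenic SSR marker databases for date palm
(*Phoenix dactylifera*): mine perfect and compound microsatellites from
a genome FASTA, classify each repeat by genic context (exon / intron /
intergenic), design one flanking primer pair per repeat, attach known
SNPs to each marker's flanking region, validate primers by in silico
PCR, and emit a marker database plus the survey's summary statistics.
It is aimed at breeders and genome analysts who need locus-specific,
PCR-ready SSR markers — with SNPs in the amplicon as a bonus source of
polymorphism — from any assembly plus (optionally) a gene annotation
and a SNP list.

## The method

**Mining.** A perfect SSR is a maximal uninterrupted run of a primitive
1–6 bp unit with at least *t(k)* repetitions per unit length *k*:
(mono, di, tri, tetra, penta, hexa) ≥ (10, 6, 5, 5, 5, 5).
Runs are found on the forward strand; N never matches; a trailing
partial unit is excluded. Two or more runs separated by ≤ 100 bp merge
into one compound locus. Summary counters follow the MISA convention
(compound members count individually), and the genome-wide rate is
n/Mb = n_SSR / (bp/10⁶).

**Partition.** Each repeat is assigned exon, intron or intergenic
context by its start coordinate against the gene models (majority-
overlap available as a flag); compartment sizes come from the union of
gene spans. Repeat-count bin tables (non-triplet vs triplet classes)
and genic/intergenic motif presence sets use canonicalised motifs
(lexicographically smallest rotation, strand-collapsed).

**Primer design.** For each SSR, candidate primers are enumerated in
400 bp flanks under the classic criteria — length 18–27 (optimum 20),
Tm 50–60 °C (optimum 55, nearest-neighbor SantaLucia-1998 at 50 mM
Na⁺ / 50 nM oligo), GC 20–80% (optimum 50), product 100–500 bp — and
the pair minimising the summed deviation penalty wins. Genic pairs are
named `Pd_G_SSRx`, intergenic `Pd_IG_SSRx`.

**SNP linking.** A marker's flanking region is its amplicon minus the
repeat motif; SNPs falling inside are listed per marker and summarised
(fraction of regions with ≥1 SNP, mean SNPs per linked region).

**In silico PCR.** EMBOSS-primersearch semantics: exhaustive Hamming
site search on both strands within a percent-mismatch budget, amplimers
as outer 5'→5' spans, both primer-role orientations.

**Codon analysis.** The 60 primitive trinucleotide units are
enumerated, and every sense codon reachable to a stop (TAA/TAG/TGA) by
a single substitution is reported for exon trinucleotide repeats —
the repeats whose slippage or point mutation can truncate a protein.

A synthetic-data generator (`ssrkit.simulate`) produces multi-scaffold
genomes with planted SSRs, gene layouts and SNPs carrying exact ground
truth, so the whole pipeline is testable without downloads.

## Worked example

Generate a small synthetic dataset and run the full pipeline:

```bash
ssrkit simulate --seed 7 --n-ssrs 12 --outdir demo/sim
ssrkit run --genome demo/sim/genome.fasta --genes demo/sim/genes.tsv \
           --snps demo/sim/snps.tsv --outdir demo/out
```

The run prints the manifest counters, e.g.:

```json
{
  "amplified_bp": 4947,
  "context_counts": {"exon": 4, "intergenic": 4, "intron": 4},
  "freq_per_mb": 50.0,
  "n_primer_pairs": 12,
  "n_snps_linked": 61,
  "n_ssrs": 12,
  "pct_regions_with_snp": 100.0,
  "total_bp": 240000
}
```

All 12 planted SSRs were mined (`n_ssrs`), split evenly across the
three contexts as planted, every SSR received a primer pair, and 61
simulated SNPs fall in the 12 flanking regions (100% of regions carry
at least one). `demo/out/marker_database.tsv` holds one row per marker:

```text
primer_name  repeat_type  repeat_sequence  ...  product_size  scaffold_id  gene_product           snp_positions
Pd_G_SSR1    penta        CCCGC            ...  492           scf1         hypothetical protein   26916;27021;...
Pd_G_SSR2    tri          TGG              ...  292           scf1         heat shock protein 70  40168;40230
```

`ssrkit query demo/out/marker_database.tsv resistance` filters markers
by gene product, and `ssrkit ispcr` validates any primer panel against
any assembly. Equivalent library calls live in `ssrkit.*` — the CLI is
a thin wrapper.

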