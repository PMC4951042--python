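"""Readers and writers for the toolkit's external formats.

Genomes come in as FASTA, gene models as GFF3 or a simple TSV dialect,
SNPs as VCF or TSV, and the marker database goes out as a fixed-column
TSV.  All coordinates are 1-based and inclusive on both ends throughout
the toolkit (the MISA/VCF convention); the readers here are the only
place where other conventions (GFF3, pysam's 0-based internals) are
translated.

TSV dialects
------------
Gene TSV columns: ``gene_id  scaffold_id  start  end  product  [exons]``
where ``exons`` is a semicolon-joined list of ``start-end`` pairs; when
empty or absent the gene gets a single exon equal to its span.

SNP TSV columns: ``scaffold_id  position  ref  alt`` with 1-based
positions.

Primer-panel TSV columns: ``name  forward  reverse``.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import gffutils
import pysam
from Bio import SeqIO

from ._util import IUPAC_CODES, ValidationError, merge_intervals

logger = logging.getLogger(__name__)

# ambiguity codes other than N are collapsed to N on input; N never
# matches any base in downstream searches
_AMBIG = str.maketrans({c: "N" for c in "RYSWKMBDHV"})


@dataclass(frozen=True)
class GenomeSequence:
    """One scaffold: identifier plus its upper-case ACGTN sequence."""

    scaffold_id: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GeneModel:
    """A gene interval with exon sub-intervals and a product description."""

    gene_id: str
    scaffold_id: str
    start: int
    end: int
    exons: tuple[tuple[int, int], ...]
    product: str = ""

    def __post_init__(self):
        if self.end < self.start:
            raise ValidationError(
                f"gene {self.gene_id}: end {self.end} < start {self.start}"
            )
        for s, e in self.exons:
            if e < s:
                raise ValidationError(f"gene {self.gene_id}: exon end {e} < start {s}")
            if s < self.start or e > self.end:
                raise ValidationError(
                    f"gene {self.gene_id}: exon {s}-{e} outside gene span "
                    f"{self.start}-{self.end}"
                )

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        out = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 > e1 + 1:
                out.append((e1 + 1, s2 - 1))
        return tuple(out)


@dataclass(frozen=True)
class SNPRecord:
    """A single-nucleotide variant at a 1-based scaffold position."""

    scaffold_id: str
    position: int
    ref_allele: str
    alt_allele: str

    def __post_init__(self):
        if self.position < 1:
            raise ValidationError(f"SNP position {self.position} < 1")
        if self.ref_allele == self.alt_allele:
            raise ValidationError(
                f"SNP at {self.scaffold_id}:{self.position}: ref == alt"
            )


class SNPTable(list):
    """A list of :class:`SNPRecord` carrying the count of skipped indels."""

    def __init__(self, records=(), n_indels_skipped: int = 0):
        super().__init__(records)
        self.n_indels_skipped = n_indels_skipped


# Column order of the marker database TSV; exactly the field order below.
DATABASE_COLUMNS = [
    "primer_name",
    "repeat_type",
    "repeat_sequence",
    "repeat_size",
    "repeat_start",
    "repeat_end",
    "forward_seq",
    "reverse_seq",
    "annealing_temperature",
    "gc_percent",
    "product_size",
    "scaffold_id",
    "gene_product",
    "gene_start",
    "gene_end",
    "snp_positions",
]


@dataclass(frozen=True)
class MarkerDatabaseRow:
    """One marker: an SSR, its primer pair, and its genomic annotation.

    ``repeat_start``/``repeat_end`` are 1-based within the amplicon;
    ``gc_percent`` holds forward and reverse values joined by ``;``;
    ``gene_*`` fields are empty (None) for intergenic markers.
    """

    primer_name: str
    repeat_type: str
    repeat_sequence: str
    repeat_size: int
    repeat_start: int
    repeat_end: int
    forward_seq: str
    reverse_seq: str
    annealing_temperature: float
    gc_percent: str
    product_size: int
    scaffold_id: str
    gene_product: str = ""
    gene_start: int | None = None
    gene_end: int | None = None
    snp_positions: tuple[int, ...] = field(default_factory=tuple)

    def __post_init__(self):
        if not (100 <= self.product_size <= 500):
            raise ValidationError(
                f"{self.primer_name}: product size {self.product_size} "
                "outside [100, 500]"
            )
        if not (1 <= self.repeat_start <= self.repeat_end <= self.product_size):
            raise ValidationError(
                f"{self.primer_name}: repeat interval "
                f"{self.repeat_start}-{self.repeat_end} outside amplicon"
            )


def read_fasta(path: str | os.PathLike) -> list[GenomeSequence]:
    """Read a multi-record FASTA into :class:`GenomeSequence` objects.

    Sequences are upper-cased; ambiguity codes other than N are stored
    as N.  Characters outside the IUPAC alphabet are rejected with their
    1-based offset within the record.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    out: list[GenomeSequence] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(path, "fasta"):
        if not rec.id:
            raise ValidationError(f"{path}: record with empty header")
        seq = str(rec.seq).upper()
        for i, c in enumerate(seq):
            if c not in IUPAC_CODES:
                raise ValidationError(
                    f"{path}: record {rec.id}: illegal character {c!r} "
                    f"at offset {i + 1}"
                )
        if rec.id in seen:
            raise ValidationError(f"{path}: duplicate scaffold id {rec.id}")
        seen.add(rec.id)
        out.append(GenomeSequence(rec.id, seq.translate(_AMBIG)))
    return out


def write_fasta(records: list[GenomeSequence], path: str | os.PathLike,
                width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.scaffold_id}\n")
            for i in range(0, rec.length, width):
                fh.write(rec.sequence[i:i + width] + "\n")


def _normalize_exons(exons, gene_id, start, end):
    ivs = merge_intervals(exons) if exons else [(start, end)]
    for s, e in ivs:
        if s < start or e > end:
            raise ValidationError(
                f"gene {gene_id}: exon {s}-{e} outside gene span {start}-{end}"
            )
    return tuple(ivs)


def _read_genes_tsv(path: str) -> list[GeneModel]:
    genes = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 5:
                raise ValidationError(f"{path}:{ln}: expected ≥5 columns")
            gene_id, scaffold, start, end, product = parts[:5]
            try:
                start, end = int(start), int(end)
            except ValueError:
                raise ValidationError(f"{path}:{ln}: non-numeric coordinate")
            exons = []
            if len(parts) > 5 and parts[5]:
                for tok in parts[5].split(";"):
                    a, b = tok.split("-")
                    exons.append((int(a), int(b)))
            genes.append(GeneModel(gene_id, scaffold, start, end,
                                   _normalize_exons(exons, gene_id, start, end),
                                   product))
    return genes


def _read_genes_gff3(path: str) -> list[GeneModel]:
    db = gffutils.create_db(path, ":memory:", merge_strategy="create_unique",
                            keep_order=True)
    genes = []
    for g in db.features_of_type("gene", order_by=("seqid", "start")):
        exons = [(e.start, e.end) for e in db.children(g, featuretype="exon")]
        product = ""
        for key in ("product", "description", "Note"):
            if key in g.attributes:
                product = g.attributes[key][0]
                break
        genes.append(GeneModel(g.id, g.seqid, g.start, g.end,
                               _normalize_exons(exons, g.id, g.start, g.end),
                               product))
    return genes


def read_gene_annotation(path: str | os.PathLike,
                         dialect: str = "tsv") -> list[GeneModel]:
    """Read gene models from GFF3 or the gene TSV dialect.

    Exon intervals are sorted and merged when touching; genes without
    exon rows get a single exon equal to the gene span.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if dialect == "tsv":
        return _read_genes_tsv(path)
    if dialect == "gff3":
        return _read_genes_gff3(path)
    raise ValidationError(f"unknown gene annotation dialect {dialect!r}")


def _read_snps_tsv(path: str) -> SNPTable:
    records, skipped = [], 0
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValidationError(f"{path}:{ln}: expected 4 columns")
            scaffold, pos, ref, alts = parts[:4]
            try:
                pos = int(pos)
            except ValueError:
                raise ValidationError(f"{path}:{ln}: non-numeric position")
            for alt in alts.split(","):
                if len(ref) != 1 or len(alt) != 1:
                    skipped += 1
                    continue
                records.append(SNPRecord(scaffold, pos, ref.upper(), alt.upper()))
    if skipped:
        logger.info("read_snp_table: skipped %d indel rows", skipped)
    return SNPTable(records, skipped)


def _read_snps_vcf(path: str) -> SNPTable:
    records, skipped = [], 0
    with pysam.VariantFile(path) as vf:
        for rec in vf:
            for alt in rec.alts or ():
                if len(rec.ref) != 1 or len(alt) != 1 or alt == "*":
                    skipped += 1
                    continue
                records.append(SNPRecord(rec.chrom, rec.pos, rec.ref.upper(),
                                         alt.upper()))
    if skipped:
        logger.info("read_snp_table: skipped %d indel alleles", skipped)
    return SNPTable(records, skipped)


def read_snp_table(path: str | os.PathLike, dialect: str = "tsv") -> SNPTable:
    """Read SNPs from VCF (CHROM/POS/REF/ALT subset) or the SNP TSV dialect.

    Multi-allelic rows are expanded to one record per alternate allele;
    indel alleles are skipped and counted on the returned table's
    ``n_indels_skipped``.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if dialect == "tsv":
        return _read_snps_tsv(path)
    if dialect == "vcf":
        return _read_snps_vcf(path)
    raise ValidationError(f"unknown SNP dialect {dialect!r}")


def write_snp_vcf(records, path: str | os.PathLike) -> None:
    """Write SNPs as a minimal VCF v4 (CHROM POS ID REF ALT QUAL FILTER INFO)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for r in records:
            fh.write(f"{r.scaffold_id}\t{r.position}\t.\t{r.ref_allele}\t"
                     f"{r.alt_allele}\t.\t.\t.\n")


def _row_to_fields(row: MarkerDatabaseRow) -> list[str]:
    return [
        row.primer_name,
        row.repeat_type,
        row.repeat_sequence,
        str(row.repeat_size),
        str(row.repeat_start),
        str(row.repeat_end),
        row.forward_seq,
        row.reverse_seq,
        f"{row.annealing_temperature:.2f}",
        row.gc_percent,
        str(row.product_size),
        row.scaffold_id,
        row.gene_product,
        "" if row.gene_start is None else str(row.gene_start),
        "" if row.gene_end is None else str(row.gene_end),
        ";".join(str(p) for p in row.snp_positions),
    ]


def write_primer_database(rows, path: str | os.PathLike) -> None:
    """Write the marker database as TSV with the fixed column contract."""
    with open(path, "w") as fh:
        fh.write("\t".join(DATABASE_COLUMNS) + "\n")
        for row in rows:
            fh.write("\t".join(_row_to_fields(row)) + "\n")


def read_primer_database(path: str | os.PathLike) -> list[MarkerDatabaseRow]:
    """Read back a marker database TSV (inverse of :func:`write_primer_database`)."""
    rows = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != DATABASE_COLUMNS:
            raise ValidationError(f"{path}: unexpected database header")
        for line in fh:
            f = line.rstrip("\n").split("\t")
            rows.append(MarkerDatabaseRow(
                primer_name=f[0], repeat_type=f[1], repeat_sequence=f[2],
                repeat_size=int(f[3]), repeat_start=int(f[4]),
                repeat_end=int(f[5]), forward_seq=f[6], reverse_seq=f[7],
                annealing_temperature=float(f[8]), gc_percent=f[9],
                product_size=int(f[10]), scaffold_id=f[11], gene_product=f[12],
                gene_start=int(f[13]) if f[13] else None,
                gene_end=int(f[14]) if f[14] else None,
                snp_positions=tuple(int(p) for p in f[15].split(";") if p),
            ))
    return rows


def read_primer_panel(path: str | os.PathLike) -> list[tuple[str, str, str]]:
    """Read a primer panel TSV: name, forward, reverse."""
    panel = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("name\t"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValidationError(f"{path}:{ln}: expected 3 columns")
            panel.append((parts[0], parts[1].upper(), parts[2].upper()))
    return panel


def filter_by_gene_product(rows, keywords) -> tuple[list[MarkerDatabaseRow], int]:
    """Select database rows whose gene product matches any keyword.

    Case-insensitive substring match.  Returns the matching rows in
    input order together with the number of distinct gene spans they
    fall in (the survey-style "N primers in M genes" count).
    """
    kw = [k.lower() for k in keywords]
    hits = [r for r in rows
            if r.gene_product and any(k in r.gene_product.lower() for k in kw)]
    spans = {(r.scaffold_id, r.gene_start, r.gene_end) for r in hits}
    return hits, len(spans)
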