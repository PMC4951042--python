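"""Genomic-context classification of SSRs and per-compartment statistics.

Each SSR is assigned exon, intron or intergenic context from the gene
models of its scaffold.  Boundary-spanning records are assigned by their
start coordinate by default (deterministic and order-independent); a
majority-overlap rule is available behind a flag.  Compartment sizes
come from the union of gene spans (genic) and total − genic
(intergenic), so overlapping gene models are never double-counted.

Per-Mb compartment frequencies are reported truncated to one decimal,
which is how genome surveys conventionally print them (e.g. a genic
compartment of 42,061 SSRs over 121.02 Mb prints as 347.5 per Mb).
"""

from __future__ import annotations

import logging
from bisect import bisect_right
from dataclasses import dataclass, field

from ._util import ValidationError, floor_decimals, merge_intervals, \
    round_half_up, total_length
from .io import GeneModel, GenomeSequence
from .mining import SSRRecord, normalize_motif

logger = logging.getLogger(__name__)

CONTEXTS = ("exon", "intron", "intergenic")

NON_TRIPLET_BINS = [(5, 9), (10, 15), (16, 20), (21, 25), (26, 30), (31, 35),
                    (36, 45), (46, 55), (56, 70), (71, 100), (101, 150),
                    (151, 200), (201, 350)]
TRIPLET_BINS = [(5, 9), (10, 15), (16, 20), (21, 25), (26, 30), (31, 35),
                (36, 45), (46, 55), (56, 70), (71, 100), (101, 250)]
NON_TRIPLET_CLASSES = ("mono", "di", "tetra", "penta")
TRIPLET_CLASSES = ("tri", "hexa")


def compartment_frequency(count: int, bp: int) -> float:
    """Per-Mb frequency of a compartment, truncated to one decimal."""
    if bp == 0:
        if count:
            raise ValidationError("non-empty compartment with zero bp")
        return 0.0
    return floor_decimals(count / (bp / 1e6), 1)


def genome_frequency(count: int, bp: int) -> float:
    """Genome-wide per-Mb frequency, rounded half-up to two decimals."""
    return round_half_up(count / (bp / 1e6), 2) if bp else 0.0


class GeneIndex:
    """Per-scaffold sorted gene lookup for context classification."""

    def __init__(self, genes: list[GeneModel]):
        self._by_scaffold: dict[str, list[GeneModel]] = {}
        for g in genes:
            self._by_scaffold.setdefault(g.scaffold_id, []).append(g)
        self._starts: dict[str, list[int]] = {}
        for sid, gs in self._by_scaffold.items():
            gs.sort(key=lambda g: (g.start, g.end))
            self._starts[sid] = [g.start for g in gs]

    def overlapping(self, scaffold_id: str, start: int, end: int):
        """Genes overlapping [start, end], in sorted order."""
        gs = self._by_scaffold.get(scaffold_id, [])
        # gene starts are sorted but spans may nest; scan left of the cut
        hi = bisect_right(self._starts.get(scaffold_id, []), end)
        return [g for g in gs[:hi] if g.end >= start]

    def genic_intervals(self, scaffold_id: str) -> list[tuple[int, int]]:
        return merge_intervals(
            (g.start, g.end) for g in self._by_scaffold.get(scaffold_id, []))

    def exon_intervals(self, scaffold_id: str) -> list[tuple[int, int]]:
        ivs = []
        for g in self._by_scaffold.get(scaffold_id, []):
            ivs.extend(g.exons)
        return merge_intervals(ivs) if ivs else []

    def scaffolds(self):
        return self._by_scaffold.keys()


def _overlap(a: tuple[int, int], ivs: list[tuple[int, int]]) -> int:
    return sum(max(0, min(a[1], e) - max(a[0], s) + 1) for s, e in ivs)


def classify_context(ssr: SSRRecord, genes: list[GeneModel] | GeneIndex,
                     rule: str = "start") -> str:
    """Assign exon / intron / intergenic context to one SSR.

    ``rule="start"`` (default): the start coordinate decides — intergenic
    if it lies in no gene span, exon if it lies in an exon of the first
    containing gene (sorted order), intron otherwise.
    ``rule="majority"``: the compartment with the largest base overlap
    with the SSR interval wins, ties broken exon > intron > intergenic.
    """
    index = genes if isinstance(genes, GeneIndex) else GeneIndex(genes)
    if rule == "start":
        for g in index.overlapping(ssr.scaffold_id, ssr.start, ssr.start):
            for s, e in g.exons:
                if s <= ssr.start <= e:
                    return "exon"
            return "intron"
        return "intergenic"
    if rule == "majority":
        span = (ssr.start, ssr.end)
        genic = index.genic_intervals(ssr.scaffold_id)
        exon = index.exon_intervals(ssr.scaffold_id)
        exon_bp = _overlap(span, exon)
        genic_bp = _overlap(span, genic)
        intron_bp = genic_bp - exon_bp
        intergenic_bp = ssr.span - genic_bp
        best = max((exon_bp, 2), (intron_bp, 1), (intergenic_bp, 0),
                   key=lambda t: (t[0], t[1]))
        return {2: "exon", 1: "intron", 0: "intergenic"}[best[1]]
    raise ValidationError(f"unknown classification rule {rule!r}")


def classify_all(records: list[SSRRecord], genes: list[GeneModel] | GeneIndex,
                 rule: str = "start") -> list[SSRRecord]:
    """Classify every record, returning new records with ``context`` set."""
    index = genes if isinstance(genes, GeneIndex) else GeneIndex(genes)
    return [r.with_context(classify_context(r, index, rule)) for r in records]


@dataclass(frozen=True)
class ContextSummary:
    """Per-compartment SSR counts, sizes and frequencies.

    Counts follow the mining convention: a compound record contributes
    its member count.  ``genic`` = exon + intron.
    """

    counts: dict[str, int]                  # exon / intron / intergenic
    genic_bp: int
    intergenic_bp: int
    exon_bp: int
    intron_bp: int
    total_bp: int
    freq_total_per_mb: float                # half-up, 2 decimals
    freq_genic_per_mb: float                # truncated, 1 decimal
    freq_intergenic_per_mb: float           # truncated, 1 decimal
    unit_length_pct: dict[str, dict[int, float]]  # context → {k: %}

    @property
    def genic_count(self) -> int:
        return self.counts["exon"] + self.counts["intron"]

    @property
    def total_count(self) -> int:
        return self.genic_count + self.counts["intergenic"]


def context_summary(records: list[SSRRecord],
                    genes: list[GeneModel] | GeneIndex,
                    genome: list[GenomeSequence]) -> ContextSummary:
    """Compute the genic/intergenic partition statistics.

    Records must already carry a context (see :func:`classify_all`).
    """
    index = genes if isinstance(genes, GeneIndex) else GeneIndex(genes)
    counts = {c: 0 for c in CONTEXTS}
    by_unit: dict[str, dict[int, int]] = {c: {} for c in CONTEXTS}
    for r in records:
        if r.context is None:
            raise ValidationError("context_summary requires classified records")
        counts[r.context] += r.n_members
        for m in r.iter_perfect():
            d = by_unit[r.context]
            d[m.unit_length] = d.get(m.unit_length, 0) + 1
    total_bp = sum(g.length for g in genome)
    genic_bp = sum(total_length(index.genic_intervals(s))
                   for s in index.scaffolds())
    exon_bp = sum(total_length(index.exon_intervals(s))
                  for s in index.scaffolds())
    intergenic_bp = total_bp - genic_bp
    total_count = sum(counts.values())
    pct = {}
    for c in CONTEXTS:
        tot = sum(by_unit[c].values())
        pct[c] = {k: round_half_up(100 * v / tot, 1) if tot else 0.0
                  for k, v in sorted(by_unit[c].items())}
    return ContextSummary(
        counts=counts,
        genic_bp=genic_bp,
        intergenic_bp=intergenic_bp,
        exon_bp=exon_bp,
        intron_bp=genic_bp - exon_bp,
        total_bp=total_bp,
        freq_total_per_mb=genome_frequency(total_count, total_bp),
        freq_genic_per_mb=compartment_frequency(
            counts["exon"] + counts["intron"], genic_bp),
        freq_intergenic_per_mb=compartment_frequency(
            counts["intergenic"], intergenic_bp),
        unit_length_pct=pct,
    )


@dataclass
class RepeatCountBinTable:
    """Counts of perfect runs per (repeat-count bin, unit class, compartment)."""

    kind: str                               # non_triplet | triplet
    bins: list[tuple[int, int]]
    classes: tuple[str, ...]
    cells: dict[tuple[tuple[int, int], str, str], int] = field(
        default_factory=dict)
    n_dropped: int = 0

    def total(self, unit_class: str, compartment: str) -> int:
        return sum(v for (b, u, c), v in self.cells.items()
                   if u == unit_class and c == compartment)


def bin_by_repeat_count(records: list[SSRRecord],
                        table_kind: str) -> RepeatCountBinTable:
    """Histogram perfect runs by repeat count, split genic vs intergenic.

    ``non_triplet`` covers mono/di/tetra/penta units, ``triplet`` tri and
    hexa (unit lengths divisible by three preserve reading frame).
    Compound members are counted individually under the compound's
    context.  Runs above the last bin edge are dropped and counted.
    """
    if table_kind == "non_triplet":
        bins, classes = NON_TRIPLET_BINS, NON_TRIPLET_CLASSES
    elif table_kind == "triplet":
        bins, classes = TRIPLET_BINS, TRIPLET_CLASSES
    else:
        raise ValidationError(f"unknown table kind {table_kind!r}")
    table = RepeatCountBinTable(table_kind, bins, classes)
    for rec in records:
        if rec.context is None:
            raise ValidationError("bin_by_repeat_count requires classified records")
        compartment = "intergenic" if rec.context == "intergenic" else "genic"
        for m in rec.iter_perfect():
            if m.unit_class not in classes:
                continue
            placed = False
            for lo, hi in bins:
                if lo <= m.repeat_count <= hi:
                    key = ((lo, hi), m.unit_class, compartment)
                    table.cells[key] = table.cells.get(key, 0) + 1
                    placed = True
                    break
            if not placed:
                table.n_dropped += 1
    if table.n_dropped:
        logger.info("bin_by_repeat_count(%s): dropped %d out-of-range runs",
                    table_kind, table.n_dropped)
    return table


@dataclass(frozen=True)
class MotifPresenceSets:
    """Normalized motifs seen only genic, only intergenic, or in both."""

    unit_length: int
    genic_only: frozenset[str]
    intergenic_only: frozenset[str]
    shared: frozenset[str]

    @property
    def all_motifs(self) -> frozenset[str]:
        return self.genic_only | self.intergenic_only | self.shared


def motif_presence_sets(records: list[SSRRecord], unit_length: int,
                        collapse_strand: bool = True) -> MotifPresenceSets:
    """Partition observed motifs of one unit-length class by compartment.

    Motifs are canonicalised with :func:`ssrkit.mining.normalize_motif`
    (strand-collapsed by default, so a motif family and its reverse
    complement count once).
    """
    genic: set[str] = set()
    intergenic: set[str] = set()
    for rec in records:
        if rec.context is None:
            raise ValidationError("motif_presence_sets requires classified records")
        bucket = intergenic if rec.context == "intergenic" else genic
        for m in rec.iter_perfect():
            if m.unit_length == unit_length:
                bucket.add(normalize_motif(m.unit, collapse_strand))
    return MotifPresenceSets(
        unit_length=unit_length,
        genic_only=frozenset(genic - intergenic),
        intergenic_only=frozenset(intergenic - genic),
        shared=frozenset(genic & intergenic),
    )
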