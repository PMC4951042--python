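"""Synthetic genomes with planted SSRs, gene models and SNPs.

The generator emulates the inputs of a genome-wide SSR survey at desk
scale: multi-scaffold assemblies with a genic/intergenic layout, a
known set of planted microsatellites, and background SNPs at a fixed
per-base rate.  Defaults mirror the surveyed assembly's character —
~39% GC background, roughly a third of the sequence genic, and a SNP
density of 0.0092 per bp (≈ 3.5 M SNPs over 381 Mb).

Every planted item is recorded in a :class:`TruthTable`.  In guarded
mode (the default) the background is rejection-resampled until the
miner finds *exactly* the planted repeats — no incidental SSR meets the
thresholds anywhere — so precision/recall against the truth is exact.
A dirty mode skips the guard for fuzzing against brute-force oracles.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field as dc_field, replace

import numpy as np

from ._util import ValidationError, is_primitive
from .io import (GeneModel, GenomeSequence, SNPRecord, SNPTable, write_fasta,
                 write_snp_vcf)
from .mining import SSRRecord, ThresholdSet, find_perfect_ssrs, merge_compound, \
    normalize_motif

_GENE_PRODUCTS = [
    "CC-NBS-LRR resistance protein",
    "tubulin alpha chain",
    "protein kinase xa21",
    "hypothetical protein",
    "Mlo family protein",
    "heat shock protein 70",
    "NBS-LRR type resistance protein",
    "ribosomal protein L3",
]


@dataclass(frozen=True)
class PlantedSSR:
    """Request for one perfect SSR at a context of choice."""

    unit: str
    repeat_count: int
    context: str                       # exon | intron | intergenic

    def __post_init__(self):
        if not (1 <= len(self.unit) <= 6) or not is_primitive(self.unit):
            raise ValidationError(f"unit {self.unit!r} must be primitive, 1-6 bp")
        if self.context not in ("exon", "intron", "intergenic"):
            raise ValidationError(f"unknown context {self.context!r}")

    @property
    def length(self) -> int:
        return len(self.unit) * self.repeat_count

    @property
    def members(self) -> tuple[tuple[str, int], ...]:
        return ((self.unit, self.repeat_count),)

    @property
    def gaps(self) -> tuple[int, ...]:
        return ()


@dataclass(frozen=True)
class PlantedCompound:
    """Request for a compound SSR: members with explicit gaps between them."""

    members: tuple[tuple[str, int], ...]    # (unit, repeat_count) per member
    gaps: tuple[int, ...]                   # len(members) - 1 gaps, bases
    context: str

    def __post_init__(self):
        if len(self.gaps) != len(self.members) - 1:
            raise ValidationError("need one gap per adjacent member pair")

    @property
    def length(self) -> int:
        return (sum(len(u) * c for u, c in self.members) + sum(self.gaps))


@dataclass(frozen=True)
class SimulationSpec:
    """Study conditions for one simulated dataset."""

    seed: int
    n_scaffolds: int = 4
    scaffold_length: int = 60_000
    ssr_plants: tuple = ()
    gene_density: float = 0.32          # genic fraction of each scaffold
    n_exons: int = 3
    exon_length: int = 400
    intron_length: int = 600
    snp_rate: float = 0.0092            # per-bp SNP probability
    gc_background: float = 0.39
    thresholds: ThresholdSet = dc_field(default_factory=ThresholdSet)
    guard: bool = True                  # screen out incidental SSRs
    guard_distance: int = 120           # min clear bases around each plant


@dataclass(frozen=True)
class TruthTable:
    """Ground truth of one simulated dataset."""

    records: tuple[SSRRecord, ...]      # planted SSRs with true context
    genes: tuple[GeneModel, ...]
    snps: tuple[SNPRecord, ...]

    def perfect_runs(self) -> list[SSRRecord]:
        out = []
        for r in self.records:
            out.extend(r.iter_perfect())
        return out


@dataclass(frozen=True)
class SimulatedDataset:
    genome: tuple[GenomeSequence, ...]
    genes: tuple[GeneModel, ...]
    snps: SNPTable
    truth: TruthTable


def _gene_layout(spec: SimulationSpec) -> list[list[GeneModel]]:
    """Deterministic tiling of genes along each scaffold."""
    gene_len = spec.n_exons * spec.exon_length \
        + (spec.n_exons - 1) * spec.intron_length
    if spec.gene_density <= 0:
        return [[] for _ in range(spec.n_scaffolds)]
    spacer = max(200, int(gene_len * (1 - spec.gene_density)
                          / spec.gene_density))
    layouts = []
    gi = 0
    for s in range(spec.n_scaffolds):
        genes = []
        pos = spacer // 2 + 1
        while pos + gene_len - 1 <= spec.scaffold_length - spacer // 2:
            gi += 1
            exons = []
            x = pos
            for _ in range(spec.n_exons):
                exons.append((x, x + spec.exon_length - 1))
                x += spec.exon_length + spec.intron_length
            genes.append(GeneModel(
                f"g{gi}", f"scf{s + 1}", pos, pos + gene_len - 1,
                tuple(exons), _GENE_PRODUCTS[(gi - 1) % len(_GENE_PRODUCTS)]))
            pos += gene_len + spacer
        layouts.append(genes)
    return layouts


def _compartment_intervals(genes: list[GeneModel], scaffold_length: int,
                           context: str) -> list[tuple[int, int]]:
    if context == "exon":
        return [iv for g in genes for iv in g.exons]
    if context == "intron":
        return [iv for g in genes for iv in g.introns]
    ivs, pos = [], 1
    for g in genes:
        if g.start > pos:
            ivs.append((pos, g.start - 1))
        pos = g.end + 1
    if pos <= scaffold_length:
        ivs.append((pos, scaffold_length))
    return ivs


def _place_plants(spec: SimulationSpec, layouts, rng) -> list[tuple[int, object, int]]:
    """Choose (scaffold index, request, start) for every plant request."""
    occupied: list[list[tuple[int, int]]] = [[] for _ in range(spec.n_scaffolds)]
    placed = []
    G = spec.guard_distance
    for qi, req in enumerate(spec.ssr_plants):
        length = req.length
        done = False
        for attempt in range(spec.n_scaffolds):
            si = (qi + attempt) % spec.n_scaffolds
            ivs = _compartment_intervals(layouts[si], spec.scaffold_length,
                                         req.context)
            slots = []
            for lo, hi in ivs:
                lo2, hi2 = lo + 2, hi - 2 - length + 1   # margin off boundaries
                if hi2 < lo2:
                    continue
                slots.append((lo2, hi2))
            rng.shuffle(slots)
            for lo2, hi2 in slots:
                # try a handful of random offsets inside the slot
                for _ in range(20):
                    start = int(rng.integers(lo2, hi2 + 1))
                    end = start + length - 1
                    if all(end < s - G or start > e + G
                           for s, e in occupied[si]):
                        occupied[si].append((start, end))
                        placed.append((si, req, start))
                        done = True
                        break
                if done:
                    break
            if done:
                break
        if not done:
            raise ValidationError(
                f"infeasible spec: no room for plant {req} "
                f"({length} bp, context {req.context})")
    return placed


def _random_background(n: int, gc: float, rng) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=n, p=p)


def _realize(req, start: int, scaffold_id: str) -> SSRRecord:
    members = []
    pos = start
    for (unit, count), gap in zip(req.members,
                                  tuple(req.gaps) + (0,)):
        end = pos + len(unit) * count - 1
        members.append(SSRRecord(scaffold_id, pos, end, unit, count,
                                 context=req.context))
        pos = end + 1 + gap
    if len(members) == 1:
        return members[0]
    plain = tuple(m.with_context(None) for m in members)
    return SSRRecord(scaffold_id, members[0].start, members[-1].end,
                     "/".join(m.unit for m in members),
                     sum(m.repeat_count for m in members),
                     kind="compound", members=plain, context=req.context)


def simulate_genome(spec: SimulationSpec) -> SimulatedDataset:
    """Generate one dataset; identical specs give byte-identical outputs."""
    for req in spec.ssr_plants:
        if req.length + 4 > spec.scaffold_length:
            raise ValidationError("plant longer than scaffold")
    rng = np.random.default_rng(spec.seed)
    layouts = _gene_layout(spec)
    placed = _place_plants(spec, layouts, rng)

    truth_records: list[SSRRecord] = []
    scaffolds: list[GenomeSequence] = []
    for si in range(spec.n_scaffolds):
        sid = f"scf{si + 1}"
        arr = _random_background(spec.scaffold_length, spec.gc_background, rng)
        plants_here = [(req, start) for sj, req, start in placed if sj == si]
        planted_runs: list[SSRRecord] = []
        for req, start in plants_here:
            rec = _realize(req, start, sid)
            truth_records.append(rec)
            for m in rec.iter_perfect():
                planted_runs.append(m)
                tract = (m.unit * m.repeat_count).encode("ascii")
                arr[m.start - 1:m.end] = np.frombuffer(tract, dtype=np.uint8)
        plant_ivs = [(m.start, m.end) for m in planted_runs]
        if spec.guard:
            arr = _guard(arr, sid, planted_runs, plant_ivs, spec, rng)
        scaffolds.append(GenomeSequence(sid, arr.tobytes().decode("ascii")))

    genes = tuple(g for layout in layouts for g in layout)
    snps = _draw_snps(scaffolds, spec, rng)
    truth_records.sort(key=lambda r: (r.scaffold_id, r.start))
    truth = TruthTable(tuple(truth_records), genes, tuple(snps))
    return SimulatedDataset(tuple(scaffolds), genes, snps, truth)


def _guard(arr, sid, planted_runs, plant_ivs, spec, rng):
    """Resample background until mining recovers exactly the planted runs."""
    expected = {(m.start, m.end, m.unit) for m in planted_runs}
    in_plant = np.zeros(len(arr), dtype=bool)
    for s, e in plant_ivs:
        in_plant[s - 1:e] = True
    for _ in range(200):
        seq = GenomeSequence(sid, arr.tobytes().decode("ascii"))
        found = {(r.start, r.end, r.unit)
                 for r in find_perfect_ssrs(seq, spec.thresholds)}
        if found == expected:
            return arr
        bad = found - expected
        missing = expected - found
        for s, e, _u in bad:
            lo = max(0, s - 3)
            hi = min(len(arr), e + 2)
            idx = np.arange(lo, hi)
            idx = idx[~in_plant[idx]]
            arr[idx] = _random_background(len(idx), spec.gc_background, rng)
        for s, e, _u in missing:
            # a planted run was extended or absorbed: scrub its borders
            for j in (s - 2, e):       # 0-based base left and right of run
                if 0 <= j < len(arr) and not in_plant[j]:
                    arr[j] = _random_background(1, spec.gc_background, rng)[0]
    raise ValidationError("guard failed to converge; spec too dense")


def _draw_snps(scaffolds, spec, rng) -> SNPTable:
    bases = "ACGT"
    records = []
    for g in scaffolds:
        hits = np.flatnonzero(rng.random(g.length) < spec.snp_rate)
        for pos0 in hits:
            ref = g.sequence[int(pos0)]
            if ref not in bases:
                continue
            alts = [b for b in bases if b != ref]
            alt = alts[int(rng.integers(0, 3))]
            records.append(SNPRecord(g.scaffold_id, int(pos0) + 1, ref, alt))
    return SNPTable(records)


def random_plants(n: int, seed: int,
                  contexts=("exon", "intron", "intergenic"),
                  thresholds: ThresholdSet | None = None) -> tuple[PlantedSSR, ...]:
    """A reproducible batch of plant requests cycling through contexts.

    Units are random primitive 1–6-mers (exon plants are trinucleotide,
    the class that dominates real coding regions) with repeat counts at
    or a little above threshold.
    """
    thresholds = thresholds or ThresholdSet()
    rng = np.random.default_rng(seed)
    bases = "ACGT"
    plants = []
    for i in range(n):
        context = contexts[i % len(contexts)]
        while True:
            k = 3 if context == "exon" else int(rng.integers(1, 7))
            unit = "".join(bases[int(b)] for b in rng.integers(0, 4, size=k))
            if is_primitive(unit):
                break
        count = thresholds.min_repeats[k] + int(rng.integers(0, 5))
        plants.append(PlantedSSR(unit, count, context))
    return tuple(plants)


def truth_compare(mined: list[SSRRecord], truth: TruthTable) -> dict:
    """Precision/recall of a mined record set against the planted truth.

    Both sides are flattened to perfect runs; a match is an identical
    (scaffold, start, end) interval whose unit agrees up to rotation.
    """
    def keyset(runs):
        return {(r.scaffold_id, r.start, r.end, normalize_motif(r.unit))
                for r in runs}

    mined_runs = []
    for r in mined:
        mined_runs.extend(r.iter_perfect())
    mk = keyset(mined_runs)
    tk = keyset(truth.perfect_runs())
    matched = mk & tk
    return {
        "precision": len(matched) / len(mk) if mk else 0.0,
        "recall": len(matched) / len(tk) if tk else 0.0,
        "exact_matches": len(matched),
    }


def write_dataset(ds: SimulatedDataset, outdir: str | os.PathLike,
                  gene_dialect: str = "tsv", snp_dialect: str = "tsv") -> dict:
    """Emit FASTA + annotation + SNP table in io_formats' dialects."""
    outdir = os.fspath(outdir)
    os.makedirs(outdir, exist_ok=True)
    paths = {"fasta": os.path.join(outdir, "genome.fasta")}
    write_fasta(list(ds.genome), paths["fasta"])
    if gene_dialect == "tsv":
        paths["genes"] = os.path.join(outdir, "genes.tsv")
        with open(paths["genes"], "w") as fh:
            for g in ds.genes:
                exons = ";".join(f"{s}-{e}" for s, e in g.exons)
                fh.write(f"{g.gene_id}\t{g.scaffold_id}\t{g.start}\t{g.end}\t"
                         f"{g.product}\t{exons}\n")
    elif gene_dialect == "gff3":
        paths["genes"] = os.path.join(outdir, "genes.gff3")
        with open(paths["genes"], "w") as fh:
            fh.write("##gff-version 3\n")
            for g in ds.genes:
                fh.write(f"{g.scaffold_id}\tssrkit\tgene\t{g.start}\t{g.end}\t"
                         f".\t+\t.\tID={g.gene_id};product={g.product}\n")
                fh.write(f"{g.scaffold_id}\tssrkit\tmRNA\t{g.start}\t{g.end}\t"
                         f".\t+\t.\tID={g.gene_id}.t1;Parent={g.gene_id}\n")
                for i, (s, e) in enumerate(g.exons, 1):
                    fh.write(f"{g.scaffold_id}\tssrkit\texon\t{s}\t{e}\t.\t+\t"
                             f".\tID={g.gene_id}.e{i};Parent={g.gene_id}.t1\n")
    else:
        raise ValidationError(f"unknown gene dialect {gene_dialect!r}")
    if snp_dialect == "tsv":
        paths["snps"] = os.path.join(outdir, "snps.tsv")
        with open(paths["snps"], "w") as fh:
            for s in ds.snps:
                fh.write(f"{s.scaffold_id}\t{s.position}\t{s.ref_allele}\t"
                         f"{s.alt_allele}\n")
    elif snp_dialect == "vcf":
        paths["snps"] = os.path.join(outdir, "snps.vcf")
        write_snp_vcf(ds.snps, paths["snps"])
    else:
        raise ValidationError(f"unknown SNP dialect {snp_dialect!r}")
    return paths
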