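"""End-to-end orchestration: mine → classify → design → link → report.

``run_pipeline`` drives the whole flow from a :class:`RunConfig`,
writes the marker database and summary tables into an output directory,
and returns a machine-readable manifest (also written as
``manifest.json``) with the tool version, a config hash, input
checksums and all headline counters.  Identical inputs reproduce an
identical manifest hash.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field, asdict

from . import __version__
from ._util import ValidationError
from .io import (MarkerDatabaseRow, read_fasta, read_gene_annotation,
                 read_snp_table, write_primer_database)
from .mining import ThresholdSet, mine_genome, summarize_mining, write_misa_tsv
from .partition import (GeneIndex, bin_by_repeat_count, classify_all,
                        context_summary, motif_presence_sets)
from .primers import DesignParams, assign_primer_names, coverage_summary, \
    design_all
from .reports import (context_summary_dict, write_bin_table,
                      write_context_summary, write_mining_summary,
                      write_motif_sets)
from .snplink import link_snps, snp_summary
from .ispcr import ispcr_summary


@dataclass
class RunConfig:
    """Inputs, dialects and parameters for one pipeline run."""

    genome_path: str
    outdir: str
    genes_path: str | None = None
    gene_dialect: str = "tsv"
    snps_path: str | None = None
    snp_dialect: str = "tsv"
    thresholds: ThresholdSet = field(default_factory=ThresholdSet)
    design: DesignParams = field(default_factory=DesignParams)
    context_rule: str = "start"
    include_motif_snps: bool = False
    run_ispcr: bool = False
    mismatch_pct: float = 0.0
    emit_misa: bool = False

    @classmethod
    def from_file(cls, path: str, **overrides) -> "RunConfig":
        """Plain key=value config file; explicit overrides win."""
        kv: dict[str, str] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                if "=" not in line:
                    raise ValidationError(f"{path}: bad config line {line!r}")
                k, v = line.split("=", 1)
                kv[k.strip()] = v.strip()
        kwargs: dict = {}
        for key in ("genome_path", "outdir", "genes_path", "gene_dialect",
                    "snps_path", "snp_dialect", "context_rule"):
            if key in kv:
                kwargs[key] = kv[key]
        for key in ("include_motif_snps", "run_ispcr", "emit_misa"):
            if key in kv:
                kwargs[key] = kv[key].lower() in ("1", "true", "yes")
        if "mismatch_pct" in kv:
            kwargs["mismatch_pct"] = float(kv["mismatch_pct"])
        kwargs.update(overrides)
        return cls(**kwargs)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _config_hash(config: RunConfig) -> str:
    d = asdict(config)
    return hashlib.sha256(
        json.dumps(d, sort_keys=True, default=str).encode()).hexdigest()


def build_database_rows(named_pairs, links_by_name) -> list[MarkerDatabaseRow]:
    """Assemble marker-database rows from named pairs and SNP links."""
    rows = []
    for p in named_pairs:
        ssr = p.ssr
        link = links_by_name.get(p.name)
        snp_positions = tuple(s.position for s in link.snps) if link else ()
        gene_product, gs, ge = "", None, None
        if ssr.context in ("exon", "intron") and getattr(p, "_gene", None):
            gene_product, gs, ge = p._gene
        rows.append(MarkerDatabaseRow(
            primer_name=p.name,
            repeat_type=ssr.unit_class,
            repeat_sequence=ssr.unit,
            repeat_size=ssr.span,
            repeat_start=ssr.start - p.amp_start + 1,
            repeat_end=ssr.end - p.amp_start + 1,
            forward_seq=p.forward_seq,
            reverse_seq=p.reverse_seq,
            annealing_temperature=round((p.fwd_tm + p.rev_tm) / 2, 2),
            gc_percent=f"{p.fwd_gc:.2f};{p.rev_gc:.2f}",
            product_size=p.product_size,
            scaffold_id=ssr.scaffold_id,
            gene_product=gene_product,
            gene_start=gs,
            gene_end=ge,
            snp_positions=snp_positions,
        ))
    return rows


def run_pipeline(config: RunConfig) -> dict:
    """Run the full marker pipeline; returns the manifest dict."""
    stage = "setup"
    try:
        os.makedirs(config.outdir, exist_ok=True)
        checksums = {"genome": _sha256(config.genome_path)}

        stage = "read-genome"
        genome = read_fasta(config.genome_path)
        scaffold_order = [g.scaffold_id for g in genome]

        stage = "read-annotation"
        genes = []
        if config.genes_path:
            genes = read_gene_annotation(config.genes_path, config.gene_dialect)
            checksums["genes"] = _sha256(config.genes_path)
        index = GeneIndex(genes)

        stage = "read-snps"
        snps = []
        if config.snps_path:
            snps = read_snp_table(config.snps_path, config.snp_dialect)
            checksums["snps"] = _sha256(config.snps_path)

        stage = "mine"
        records = mine_genome(genome, config.thresholds)
        mining = summarize_mining(records, genome)
        write_mining_summary(mining, os.path.join(config.outdir,
                                                  "mining_summary.tsv"))
        if config.emit_misa:
            write_misa_tsv(records, os.path.join(config.outdir, "ssrs.misa"))

        stage = "classify"
        records = classify_all(records, index, config.context_rule)
        ctx = context_summary(records, index, genome)
        write_context_summary(ctx, os.path.join(config.outdir,
                                                "context_summary.json"))
        for kind in ("non_triplet", "triplet"):
            table = bin_by_repeat_count(records, kind)
            write_bin_table(table, os.path.join(config.outdir,
                                                f"repeat_bins_{kind}.tsv"))
        for k in (4, 5, 6):
            sets = motif_presence_sets(records, k)
            write_motif_sets(sets, os.path.join(config.outdir,
                                                f"motif_sets_{k}.json"))

        stage = "design"
        pairs = design_all(records, genome, config.design)
        pairs = assign_primer_names(pairs, scaffold_order)
        # attach the enclosing gene for genic markers (database columns)
        for p in pairs:
            gene = None
            if p.ssr.context in ("exon", "intron"):
                hits = index.overlapping(p.scaffold_id, p.ssr.start, p.ssr.start)
                if hits:
                    g = hits[0]
                    gene = (g.product, g.start, g.end)
            object.__setattr__(p, "_gene", gene)
        coverage = coverage_summary(pairs, genome, ctx.genic_bp)

        stage = "link-snps"
        links = link_snps(pairs, snps, config.include_motif_snps)
        contexts = {p.name: p.ssr.context for p in pairs}
        link_summary = snp_summary(links, len(pairs), contexts)
        with open(os.path.join(config.outdir, "snp_links.tsv"), "w") as fh:
            fh.write("primer_name\tn_snps\tpositions\n")
            for ln in links:
                fh.write(f"{ln.primer_name}\t{ln.n_snps}\t"
                         + ";".join(str(s.position) for s in ln.snps) + "\n")

        stage = "database"
        links_by_name = {ln.primer_name: ln for ln in links}
        rows = build_database_rows(pairs, links_by_name)
        db_path = os.path.join(config.outdir, "marker_database.tsv")
        write_primer_database(rows, db_path)

        ispcr_counters = None
        if config.run_ispcr:
            stage = "ispcr"
            panel = [(p.name, p.forward_seq, p.reverse_seq) for p in pairs]
            if panel:
                isp = ispcr_summary(panel, genome, config.mismatch_pct)
                ispcr_counters = {
                    "n_primers_tested": isp.n_primers_tested,
                    "n_primers_with_hits": isp.n_primers_with_hits,
                    "n_amplimers_total": isp.n_amplimers_total,
                    "total_amplimer_bp": isp.total_amplimer_bp,
                    "mean_amplimers_per_hitting_primer":
                        isp.mean_amplimers_per_hitting_primer,
                }

        stage = "manifest"
        manifest = {
            "tool": "ssrkit",
            "version": __version__,
            "config_hash": _config_hash(config),
            "input_checksums": checksums,
            "counters": {
                "n_scaffolds": len(genome),
                "total_bp": mining.total_bp,
                "n_ssrs": mining.n_ssrs,
                "n_ssr_records": len(records),
                "n_compound_members": mining.n_ssrs_in_compound_formation,
                "freq_per_mb": mining.freq_per_mb,
                "context_counts": ctx.counts,
                "freq_genic_per_mb": ctx.freq_genic_per_mb,
                "freq_intergenic_per_mb": ctx.freq_intergenic_per_mb,
                "n_primer_pairs": len(pairs),
                "amplified_bp": coverage.amplified_bp,
                "fraction_of_genome": coverage.fraction_of_genome,
                "n_regions_with_snp": link_summary.n_regions_with_snp,
                "n_snps_linked": link_summary.n_snps_linked,
                "pct_regions_with_snp": link_summary.pct_regions_with_snp,
                "mean_snps_per_linked_region":
                    link_summary.mean_snps_per_linked_region,
                "n_database_rows": len(rows),
                "n_indels_skipped": getattr(snps, "n_indels_skipped", 0),
                "ispcr": ispcr_counters,
            },
        }
        with open(os.path.join(config.outdir, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
        return manifest
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
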