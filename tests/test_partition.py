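"""Context classification, compartment statistics, bins and motif sets."""

import numpy as np
import pytest

from oracles import interval_union_bp
from ssrkit.io import GeneModel, GenomeSequence
from ssrkit.mining import SSRRecord, mine_genome
from ssrkit.partition import (bin_by_repeat_count, classify_all,
                              classify_context, compartment_frequency,
                              context_summary, genome_frequency,
                              motif_presence_sets)

GENE = GeneModel("g1", "s1", 100, 500, ((100, 200), (300, 500)), "kinase")


def _ssr(start, end, unit="AG", count=None, context=None):
    count = count or (end - start + 1) // len(unit)
    return SSRRecord("s1", start, end, unit, count, context=context)


class TestClassify:
    @pytest.mark.parametrize("start,end,expected", [
        (150, 170, "exon"),          # inside first exon
        (600, 620, "intergenic"),    # past the gene
        (195, 230, "exon"),          # starts in exon, ends in intron → start rule
        (250, 270, "intron"),
        (90, 150, "intergenic"),     # starts before the gene span
    ])
    def test_start_rule(self, start, end, expected):
        assert classify_context(_ssr(start, end), [GENE]) == expected

    def test_majority_rule_flips_boundary_spanner(self):
        # starts at exon base 195 but 24 of 30 bases are intronic
        ssr = _ssr(195, 224)
        assert classify_context(ssr, [GENE], rule="start") == "exon"
        assert classify_context(ssr, [GENE], rule="majority") == "intron"

    def test_no_genes_all_intergenic(self):
        assert classify_context(_ssr(5, 20), []) == "intergenic"

    def test_conservation_on_simulation(self, guarded_dataset):
        spec, ds = guarded_dataset
        records = classify_all(mine_genome(list(ds.genome), spec.thresholds),
                               list(ds.genes))
        assert len(records) == len([c for c in (r.context for r in records) if c])

    def test_planted_contexts_recovered(self, guarded_dataset):
        spec, ds = guarded_dataset
        records = classify_all(mine_genome(list(ds.genome), spec.thresholds),
                               list(ds.genes))
        truth = {(r.scaffold_id, r.start, r.end): r.context
                 for r in ds.truth.records}
        for r in records:
            assert r.context == truth[(r.scaffold_id, r.start, r.end)]


class TestContextSummary:
    def test_published_compartment_arithmetic(self):
        # published counts / compartment sizes reproduce the printed rates
        genic_bp = 121_018_751
        total_bp = 381_563_256
        assert compartment_frequency(42_061, genic_bp) == 347.5
        assert compartment_frequency(130_014, total_bp - genic_bp) == 499.0
        assert genome_frequency(172_075, total_bp) == 450.97

    def test_counts_and_bp(self, guarded_dataset):
        spec, ds = guarded_dataset
        records = classify_all(mine_genome(list(ds.genome), spec.thresholds),
                               list(ds.genes))
        s = context_summary(records, list(ds.genes), list(ds.genome))
        expected = {"exon": 0, "intron": 0, "intergenic": 0}
        for r in ds.truth.records:
            expected[r.context] += r.n_members
        assert s.counts == expected
        # genic bp equals the union of gene spans
        ivs = [(g.start, g.end) for g in ds.genes if g.scaffold_id == "scf1"]
        per_scf1 = interval_union_bp(ivs)
        assert s.genic_bp >= per_scf1
        assert s.genic_bp + s.intergenic_bp == s.total_bp
        assert s.exon_bp + s.intron_bp == s.genic_bp

    def test_frequency_reconstructs_total(self, guarded_dataset):
        spec, ds = guarded_dataset
        records = classify_all(mine_genome(list(ds.genome), spec.thresholds),
                               list(ds.genes))
        s = context_summary(records, list(ds.genes), list(ds.genome))
        approx = (s.freq_genic_per_mb * s.genic_bp
                  + s.freq_intergenic_per_mb * s.intergenic_bp) / 1e6
        assert abs(approx - s.total_count) <= 0.1 * s.total_count + 2

    def test_zero_records(self):
        genome = [GenomeSequence("s1", "ACGT" * 1000)]
        s = context_summary([], [GENE], genome)
        assert s.freq_genic_per_mb == 0.0
        assert s.freq_intergenic_per_mb == 0.0

    def test_unit_length_percentages_sum_to_100(self, guarded_dataset):
        spec, ds = guarded_dataset
        records = classify_all(mine_genome(list(ds.genome), spec.thresholds),
                               list(ds.genes))
        s = context_summary(records, list(ds.genes), list(ds.genome))
        for ctx, pcts in s.unit_length_pct.items():
            if pcts:
                assert sum(pcts.values()) == pytest.approx(100, abs=0.2)


class TestBins:
    def test_mono_genic_bin(self):
        rec = _ssr(1, 12, "A", 12, context="intron")
        t = bin_by_repeat_count([rec], "non_triplet")
        assert t.cells[((10, 15), "mono", "genic")] == 1

    def test_tri_intergenic_bin(self):
        rec = _ssr(1, 21, "AAG", 7, context="intergenic")
        t = bin_by_repeat_count([rec], "triplet")
        assert t.cells[((5, 9), "tri", "intergenic")] == 1

    def test_overflow_dropped_and_counted(self):
        rec = _ssr(1, 400, "A", 400, context="intron")
        t = bin_by_repeat_count([rec], "non_triplet")
        assert t.n_dropped == 1 and not t.cells

    def test_histogram_oracle_fuzz(self):
        rng = np.random.default_rng(17)
        units = {"mono": "A", "di": "AG", "tri": "AAG", "tetra": "AAGT",
                 "penta": "AAGTC", "hexa": "AAGTCC"}
        records = []
        for _ in range(1000):
            cls = list(units)[int(rng.integers(0, 6))]
            count = int(rng.integers(5, 360))
            u = units[cls]
            ctx = ["exon", "intron", "intergenic"][int(rng.integers(0, 3))]
            records.append(_ssr(1, len(u) * count, u, count, context=ctx))
        for kind in ("non_triplet", "triplet"):
            t = bin_by_repeat_count(records, kind)
            # brute-force histogram
            expect = {}
            dropped = 0
            for r in records:
                if r.unit_class not in t.classes:
                    continue
                comp = "intergenic" if r.context == "intergenic" else "genic"
                for lo, hi in t.bins:
                    if lo <= r.repeat_count <= hi:
                        key = ((lo, hi), r.unit_class, comp)
                        expect[key] = expect.get(key, 0) + 1
                        break
                else:
                    dropped += 1
            assert t.cells == expect
            assert t.n_dropped == dropped


class TestMotifSets:
    def test_toy_partition(self):
        recs = [_ssr(1, 20, "ACGT", 5, context="intron"),
                _ssr(100, 119, "ACGT", 5, context="intergenic"),
                _ssr(200, 219, "AACG", 5, context="exon")]
        s = motif_presence_sets(recs, 4)
        assert s.shared == {"ACGT"}
        assert s.genic_only == {"AACG"}
        assert s.intergenic_only == set()

    def test_disjoint_sets_no_shared(self):
        recs = [_ssr(1, 20, "AACT", 5, context="intron"),
                _ssr(100, 119, "AGGT", 5, context="intergenic")]
        s = motif_presence_sets(recs, 4)
        assert s.shared == set()
        assert s.genic_only.isdisjoint(s.intergenic_only)

    def test_strand_collapse_merges_families(self):
        # AAAT in genic, its revcomp family ATTT in intergenic → shared
        recs = [_ssr(1, 20, "AAAT", 5, context="exon"),
                _ssr(100, 119, "ATTT", 5, context="intergenic")]
        s = motif_presence_sets(recs, 4, collapse_strand=True)
        assert len(s.shared) == 1
        s2 = motif_presence_sets(recs, 4, collapse_strand=False)
        assert s2.shared == set()

    def test_planted_overlap_count(self):
        rng = np.random.default_rng(23)
        genic_pool = ["AACG", "AACT", "AAGC", "AAGG"]
        inter_pool = ["AACG", "AACT", "ACCT", "ACGG"]   # overlap 2 families
        recs = []
        pos = 1
        for u in genic_pool:
            recs.append(_ssr(pos, pos + 19, u, 5, context="intron"))
            pos += 200
        for u in inter_pool:
            recs.append(_ssr(pos, pos + 19, u, 5, context="intergenic"))
            pos += 200
        s = motif_presence_sets(recs, 4, collapse_strand=False)
        assert len(s.shared) == 2
        assert s.all_motifs == {"AACG", "AACT", "AAGC", "AAGG", "ACCT", "ACGG"}
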