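"""Primer design: GC/Tm arithmetic, candidate search, naming, coverage."""

import numpy as np
import pytest

from oracles import interval_union_bp, nn_tm, rc
from ssrkit._util import ValidationError, revcomp
from ssrkit.io import GenomeSequence
from ssrkit.mining import SSRRecord
from ssrkit.primers import (DesignParams, assign_primer_names,
                            coverage_summary, design_primer_pair, gc_content,
                            melting_temperature)

# reference value computed once with the hand-summed nearest-neighbor
# oracle (SantaLucia 1998 unified, 50 mM Na+, 50 nM oligo)
TM_ATGC_20MER = 57.3787


def _flank(rng, n, gc=0.5):
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=p))


def _clean_flank(rng, n):
    """A flank free of threshold-meeting repeats (regenerate if unlucky)."""
    from ssrkit.mining import ThresholdSet, find_perfect_ssrs
    while True:
        s = _flank(rng, n)
        if not find_perfect_ssrs(GenomeSequence("x", s), ThresholdSet()):
            return s


class TestGcContent:
    @pytest.mark.parametrize("seq,expected", [
        ("ATGC", 50.0), ("GGGG", 100.0), ("ATAT", 0.0)])
    def test_values(self, seq, expected):
        assert gc_content(seq) == expected

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            gc_content("")

    def test_ambiguity_rejected(self):
        with pytest.raises(ValidationError):
            gc_content("ACGN")


class TestMeltingTemperature:
    def test_frozen_reference_20mer(self):
        assert melting_temperature("ATGC" * 5) == pytest.approx(
            TM_ATGC_20MER, abs=0.01)

    def test_matches_independent_nn_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            s = _flank(rng, int(rng.integers(12, 28)))
            assert melting_temperature(s) == pytest.approx(nn_tm(s), abs=1e-6)

    def test_duplex_symmetry(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            s = _flank(rng, 20)
            assert melting_temperature(s) == pytest.approx(
                melting_temperature(revcomp(s)), abs=1e-9)

    def test_gc_rich_melts_higher_than_at_only(self):
        assert melting_temperature("G" * 10 + "C" * 10) > \
            melting_temperature("AT" * 10)

    def test_too_short_rejected(self):
        with pytest.raises(ValidationError):
            melting_temperature("ACGTACG")

    def test_wallace_rule_flag(self):
        # 2(A+T) + 4(G+C) on a 20-mer with 10 GC
        assert melting_temperature("ATGC" * 5, method="wallace") == 60.0


def _locus(rng, left=150, right=150, unit="AGA", count=6):
    tract = unit * count
    seq = _clean_flank(rng, left) + tract + _clean_flank(rng, right)
    ssr = SSRRecord("s1", left + 1, left + len(tract), unit, count)
    return {"s1": GenomeSequence("s1", seq)}, ssr


class TestDesign:
    def test_clean_locus_yields_pair(self):
        genome, ssr = _locus(np.random.default_rng(21))
        pair = design_primer_pair(ssr, genome)
        assert pair is not None
        assert 100 <= pair.product_size <= 500
        assert pair.amp_start < ssr.start and ssr.end < pair.amp_end
        seq = genome["s1"].sequence
        assert pair.forward_seq == seq[pair.amp_start - 1:
                                       pair.amp_start - 1 + len(pair.forward_seq)]
        assert pair.reverse_seq == revcomp(
            seq[pair.amp_end - len(pair.reverse_seq):pair.amp_end])

    def test_primer_constraints_respected(self):
        genome, ssr = _locus(np.random.default_rng(22))
        p = design_primer_pair(ssr, genome)
        params = DesignParams()
        for tm, gc, s in ((p.fwd_tm, p.fwd_gc, p.forward_seq),
                          (p.rev_tm, p.rev_gc, p.reverse_seq)):
            assert params.tm_range[0] <= tm <= params.tm_range[1]
            assert params.gc_range[0] <= gc <= params.gc_range[1]
            assert params.primer_len_range[0] <= len(s) \
                <= params.primer_len_range[1]

    def test_infeasible_left_geometry_returns_none(self):
        # left flank shorter than the minimum primer length: no forward
        # candidate can exist
        rng = np.random.default_rng(23)
        tract = "AGA" * 6
        seq = _clean_flank(rng, 15) + tract + _clean_flank(rng, 200)
        ssr = SSRRecord("s1", 16, 15 + len(tract), "AGA", 6)
        genome = {"s1": GenomeSequence("s1", seq)}
        assert design_primer_pair(ssr, genome) is None

    def test_matches_exhaustive_oracle(self):
        params = DesignParams()
        for seed in (31, 32, 33):
            genome, ssr = _locus(np.random.default_rng(seed),
                                 left=400, right=400)
            got = design_primer_pair(ssr, genome, params)
            want = _exhaustive_best(ssr, genome, params)
            assert (got is None) == (want is None)
            if got:
                assert (got.forward_seq, got.reverse_seq,
                        got.amp_start, got.amp_end) == want

    def test_deterministic(self):
        genome, ssr = _locus(np.random.default_rng(35))
        a = design_primer_pair(ssr, genome)
        b = design_primer_pair(ssr, genome)
        assert a == b


def _exhaustive_best(ssr, genome, params):
    """Independent full enumeration over every (forward, reverse) window."""
    from ssrkit.primers import longest_self_complementary_run
    seq = genome[ssr.scaffold_id].sequence
    n = len(seq)
    lo_len, hi_len = params.primer_len_range

    def candidates(lo, hi, is_fwd):
        out = []
        for start in range(lo, hi + 1):
            for L in range(lo_len, hi_len + 1):
                end = start + L - 1
                if end > hi:
                    continue
                w = seq[start - 1:end]
                if "N" in w:
                    continue
                s = w if is_fwd else rc(w)
                gc = 100.0 * sum(c in "GC" for c in s) / L
                if not params.gc_range[0] <= gc <= params.gc_range[1]:
                    continue
                tm = nn_tm(s)
                if not params.tm_range[0] <= tm <= params.tm_range[1]:
                    continue
                if longest_self_complementary_run(s) > params.max_self_comp:
                    continue
                pen = (abs(L - params.primer_opt_len)
                       + abs(tm - params.tm_opt) + abs(gc - params.gc_opt))
                out.append((start, end, s, pen))
        return out

    fs = candidates(max(1, ssr.start - params.search_flank), ssr.start - 1, True)
    rs = candidates(ssr.end + 1, min(n, ssr.end + params.search_flank), False)
    best = None
    for f in fs:
        for r in rs:
            product = r[1] - f[0] + 1
            if not params.product_range[0] <= product <= params.product_range[1]:
                continue
            key = (f[3] + r[3], product, f[0])
            if best is None or key < best[0]:
                best = (key, (f[2], r[2], f[0], r[1]))
    return best[1] if best else None


class TestNaming:
    def _pair(self, scaffold, start, context, seed=0):
        ssr = SSRRecord(scaffold, start, start + 11, "AG", 6, context=context)
        genome, _ = _locus(np.random.default_rng(seed))
        from ssrkit.primers import PrimerPair
        return PrimerPair("", ssr, "A" * 20, "T" * 20, 55, 55, 50, 50,
                          max(1, start - 60), start + 80, 0.0)

    def test_series_numbering(self):
        pairs = [self._pair("s1", 100, "exon"),
                 self._pair("s1", 900, "intron"),
                 self._pair("s1", 500, "intergenic")]
        named = assign_primer_names(pairs, ["s1"])
        assert sorted(p.name for p in named) == \
            ["Pd_G_SSR1", "Pd_G_SSR2", "Pd_IG_SSR1"]
        by_name = {p.name: p for p in named}
        assert by_name["Pd_G_SSR1"].ssr.start == 100

    def test_empty_input(self):
        assert assign_primer_names([], []) == []

    def test_permutation_invariance(self):
        rng = np.random.default_rng(6)
        pairs = [self._pair("s1", 100 * i + 50,
                            ["exon", "intron", "intergenic"][i % 3])
                 for i in range(9)]
        base = {(p.ssr.scaffold_id, p.ssr.start): p.name
                for p in assign_primer_names(list(pairs), ["s1"])}
        for _ in range(5):
            shuffled = list(pairs)
            rng.shuffle(shuffled)
            got = {(p.ssr.scaffold_id, p.ssr.start): p.name
                   for p in assign_primer_names(shuffled, ["s1"])}
            assert got == base


class TestCoverage:
    def _pair_at(self, start, end, context="intron"):
        from ssrkit.primers import PrimerPair
        ssr = SSRRecord("s1", start + 30, start + 41, "AG", 6, context=context)
        return PrimerPair("p", ssr, "A" * 20, "T" * 20, 55, 55, 50, 50,
                          start, end, 0.0)

    def test_disjoint_amplicons_sum(self):
        genome = [GenomeSequence("s1", "A" * 10_000)]
        pairs = [self._pair_at(1, 200), self._pair_at(1000, 1199)]
        assert coverage_summary(pairs, genome).amplified_bp == 400

    def test_identical_amplicons_counted_once(self):
        genome = [GenomeSequence("s1", "A" * 10_000)]
        pairs = [self._pair_at(1, 200), self._pair_at(1, 200)]
        assert coverage_summary(pairs, genome).amplified_bp == 200

    def test_fuzz_against_sweep_line_oracle(self):
        rng = np.random.default_rng(8)
        genome = [GenomeSequence("s1", "A" * 100_000)]
        for _ in range(10):
            ivs = []
            for _ in range(40):
                s = int(rng.integers(1, 90_000))
                ivs.append((s, s + int(rng.integers(100, 500))))
            pairs = [self._pair_at(s, e) for s, e in ivs]
            assert coverage_summary(pairs, genome).amplified_bp == \
                interval_union_bp(ivs)
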