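"""Flanking primer design for SSR loci.

One best primer pair per SSR, chosen by exhaustive enumeration of
candidate primers in the flanks under the classic SSR-marker criteria:
optimum length 20 bp (range 18–27), optimum melting temperature 55 °C
(range 50–60), optimum GC 50% (range 20–80), product size 100–500 bp.
A pair's penalty is the weighted sum of the two primers' deviations
from the length, Tm and GC optima; the minimum-penalty pair wins, ties
broken by smaller product then leftmost forward start.  Primers whose
longest self-complementary run reaches 8 bases are rejected as hairpin
/ self-dimer risks (a lightweight guard in place of full duplex
thermodynamics).

Melting temperatures are nearest-neighbor (SantaLucia 1998 unified
parameters, 50 mM monovalent salt, 50 nM oligo), computed through
Biopython's thermodynamic tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from Bio.SeqUtils import MeltingTemp as _mt

from ._util import ValidationError, merge_intervals, revcomp, round_half_up
from .io import GenomeSequence
from .mining import SSRRecord


@dataclass(frozen=True)
class DesignParams:
    """Primer design criteria; defaults are the SSR-marker classics."""

    primer_opt_len: int = 20
    primer_len_range: tuple[int, int] = (18, 27)
    tm_opt: float = 55.0
    tm_range: tuple[float, float] = (50.0, 60.0)
    gc_opt: float = 50.0
    gc_range: tuple[float, float] = (20.0, 80.0)
    product_range: tuple[int, int] = (100, 500)
    search_flank: int = 400
    w_len: float = 1.0
    w_tm: float = 1.0
    w_gc: float = 1.0
    max_self_comp: int = 7      # longest allowed self-complementary run

    def __post_init__(self):
        if not (self.primer_len_range[0] <= self.primer_opt_len
                <= self.primer_len_range[1]):
            raise ValidationError("primer_opt_len outside primer_len_range")
        if not (self.tm_range[0] <= self.tm_opt <= self.tm_range[1]):
            raise ValidationError("tm_opt outside tm_range")
        if not (self.gc_range[0] <= self.gc_opt <= self.gc_range[1]):
            raise ValidationError("gc_opt outside gc_range")
        if self.product_range[0] <= 0:
            raise ValidationError("product_range must be positive")


@dataclass(frozen=True)
class PrimerPair:
    """A designed pair with its amplicon on the source scaffold.

    ``reverse_seq`` is given 5'→3' on the minus strand; the amplicon is
    1-based inclusive and spans from the forward primer's first base to
    the reverse primer's genomic 3' end.
    """

    name: str
    ssr: SSRRecord
    forward_seq: str
    reverse_seq: str
    fwd_tm: float
    rev_tm: float
    fwd_gc: float
    rev_gc: float
    amp_start: int
    amp_end: int
    penalty: float

    @property
    def product_size(self) -> int:
        return self.amp_end - self.amp_start + 1

    @property
    def scaffold_id(self) -> str:
        return self.ssr.scaffold_id

    def renamed(self, name: str) -> "PrimerPair":
        return replace(self, name=name)


def gc_content(seq: str) -> float:
    """Percent G+C of an ACGT sequence."""
    if not seq:
        raise ValidationError("gc_content of empty sequence")
    if any(c not in "ACGT" for c in seq):
        raise ValidationError(f"gc_content: non-ACGT base in {seq!r}")
    return 100.0 * sum(c in "GC" for c in seq) / len(seq)


def melting_temperature(seq: str, salt_mM: float = 50.0,
                        primer_nM: float = 50.0,
                        method: str = "nn") -> float:
    """Primer melting temperature in °C.

    ``method="nn"`` (default): nearest-neighbor, SantaLucia-1998 unified
    parameters with the SantaLucia-1998 entropy salt correction at the
    stated monovalent salt and oligo concentration.  ``method="wallace"``
    gives the simple 2(A+T)+4(G+C) rule for cross-checks.
    """
    if any(c not in "ACGT" for c in seq):
        raise ValidationError(f"melting_temperature: non-ACGT base in {seq!r}")
    if method == "wallace":
        return float(_mt.Tm_Wallace(seq))
    if method != "nn":
        raise ValidationError(f"unknown Tm method {method!r}")
    if len(seq) < 8:
        raise ValidationError("melting_temperature requires length ≥ 8")
    return float(_mt.Tm_NN(seq, nn_table=_mt.DNA_NN3, Na=salt_mM,
                           dnac1=primer_nM, dnac2=0, saltcorr=5))


def longest_self_complementary_run(seq: str) -> int:
    """Length of the longest k-mer whose reverse complement also occurs."""
    n = len(seq)
    best = 0
    for k in range(n, 0, -1):
        kmers = {seq[i:i + k] for i in range(n - k + 1)}
        if any(revcomp(km) in kmers for km in kmers):
            best = k
            break
    return best


@dataclass(frozen=True)
class _Candidate:
    start: int          # 1-based genomic start of the window
    end: int            # 1-based genomic end of the window
    seq: str            # primer sequence 5'→3'
    tm: float
    gc: float
    penalty: float


def _enumerate_candidates(genome_seq: str, lo: int, hi: int, side: str,
                          params: DesignParams) -> list[_Candidate]:
    """All acceptable primer windows fully inside [lo, hi] (1-based)."""
    out = []
    min_len, max_len = params.primer_len_range
    for start in range(lo, hi - min_len + 2):
        for length in range(min_len, max_len + 1):
            end = start + length - 1
            if end > hi:
                break
            window = genome_seq[start - 1:end]
            if "N" in window:
                continue
            seq = window if side == "fwd" else revcomp(window)
            gc = gc_content(seq)
            if not (params.gc_range[0] <= gc <= params.gc_range[1]):
                continue
            tm = melting_temperature(seq)
            if not (params.tm_range[0] <= tm <= params.tm_range[1]):
                continue
            if longest_self_complementary_run(seq) > params.max_self_comp:
                continue
            penalty = (params.w_len * abs(length - params.primer_opt_len)
                       + params.w_tm * abs(tm - params.tm_opt)
                       + params.w_gc * abs(gc - params.gc_opt))
            out.append(_Candidate(start, end, seq, tm, gc, penalty))
    return out


def design_primer_pair(ssr: SSRRecord, genome: dict[str, GenomeSequence],
                       params: DesignParams | None = None) -> PrimerPair | None:
    """Design the best flanking primer pair for one SSR, or None.

    Candidates are enumerated in ``search_flank`` bases on each side of
    the SSR (the forward primer fully left of the repeat, the reverse
    fully right), filtered on Tm/GC/self-complementarity, and paired
    under the product-size constraint.  The returned pair minimises the
    penalty; exact ties resolve to the smaller product, then the
    leftmost forward start.  Returns None when no pair is feasible.
    """
    params = params or DesignParams()
    seq = genome[ssr.scaffold_id].sequence
    n = len(seq)
    f_lo = max(1, ssr.start - params.search_flank)
    f_hi = ssr.start - 1
    r_lo = ssr.end + 1
    r_hi = min(n, ssr.end + params.search_flank)
    if f_hi - f_lo + 1 < params.primer_len_range[0]:
        return None
    if r_hi - r_lo + 1 < params.primer_len_range[0]:
        return None
    fwd = sorted(_enumerate_candidates(seq, f_lo, f_hi, "fwd", params),
                 key=lambda c: c.penalty)
    rev = sorted(_enumerate_candidates(seq, r_lo, r_hi, "rev", params),
                 key=lambda c: c.penalty)
    if not fwd or not rev:
        return None
    p_lo, p_hi = params.product_range
    best: tuple[float, int, int] | None = None   # (penalty, product, fwd_start)
    best_pair: tuple[_Candidate, _Candidate] | None = None
    for f in fwd:
        if best is not None and f.penalty > best[0]:
            break
        for r in rev:
            pen = f.penalty + r.penalty
            if best is not None and pen > best[0]:
                break
            product = r.end - f.start + 1
            if not (p_lo <= product <= p_hi):
                continue
            key = (pen, product, f.start)
            if best is None or key < best:
                best, best_pair = key, (f, r)
    if best_pair is None:
        return None
    f, r = best_pair
    return PrimerPair(
        name="", ssr=ssr, forward_seq=f.seq, reverse_seq=r.seq,
        fwd_tm=round_half_up(f.tm, 2), rev_tm=round_half_up(r.tm, 2),
        fwd_gc=round_half_up(f.gc, 2), rev_gc=round_half_up(r.gc, 2),
        amp_start=f.start, amp_end=r.end, penalty=best[0])


def design_all(records: list[SSRRecord], genome: list[GenomeSequence],
               params: DesignParams | None = None) -> list[PrimerPair]:
    """Design pairs for every SSR (compound spans included); drop misses."""
    gmap = {g.scaffold_id: g for g in genome}
    pairs = []
    for rec in records:
        pair = design_primer_pair(rec, gmap, params)
        if pair is not None:
            pairs.append(pair)
    return pairs


def assign_primer_names(pairs: list[PrimerPair],
                        scaffold_order: list[str] | None = None
                        ) -> list[PrimerPair]:
    """Name pairs Pd_G_SSR1..n (genic) and Pd_IG_SSR1..m (intergenic).

    Numbering runs in (scaffold order, then SSR start) independently per
    series; the result is order-independent of the input permutation.
    Records must carry a context.
    """
    if scaffold_order is None:
        rank = {}
    else:
        rank = {sid: i for i, sid in enumerate(scaffold_order)}

    def sort_key(p: PrimerPair):
        return (rank.get(p.scaffold_id, len(rank)), p.scaffold_id, p.ssr.start)

    for p in pairs:
        if p.ssr.context is None:
            raise ValidationError("assign_primer_names requires classified SSRs")
    genic = sorted((p for p in pairs if p.ssr.context != "intergenic"), key=sort_key)
    inter = sorted((p for p in pairs if p.ssr.context == "intergenic"), key=sort_key)
    named = [p.renamed(f"Pd_G_SSR{i}") for i, p in enumerate(genic, 1)]
    named += [p.renamed(f"Pd_IG_SSR{i}") for i, p in enumerate(inter, 1)]
    return named


@dataclass(frozen=True)
class CoverageSummary:
    """Genome bp reachable by amplification, after merging amplicons."""

    amplified_bp: int
    fraction_of_genome: float
    genic_amplified_bp: int | None = None
    intergenic_amplified_bp: int | None = None
    fraction_of_genic: float | None = None
    fraction_of_intergenic: float | None = None


def coverage_summary(pairs: list[PrimerPair], genome: list[GenomeSequence],
                     genic_bp: int | None = None) -> CoverageSummary:
    """Total bp covered by the union of amplicon intervals per scaffold.

    With ``genic_bp`` given, also splits amplified bp by the context of
    each pair's SSR and reports per-compartment fractions.
    """
    total_bp = sum(g.length for g in genome)
    by_scaffold: dict[str, list[tuple[int, int]]] = {}
    for p in pairs:
        by_scaffold.setdefault(p.scaffold_id, []).append((p.amp_start, p.amp_end))
    amplified = sum(sum(e - s + 1 for s, e in merge_intervals(ivs))
                    for ivs in by_scaffold.values())
    frac = amplified / total_bp if total_bp else 0.0
    if genic_bp is None:
        return CoverageSummary(amplified, frac)
    g_ivs: dict[str, list[tuple[int, int]]] = {}
    i_ivs: dict[str, list[tuple[int, int]]] = {}
    for p in pairs:
        tgt = i_ivs if p.ssr.context == "intergenic" else g_ivs
        tgt.setdefault(p.scaffold_id, []).append((p.amp_start, p.amp_end))
    g_bp = sum(sum(e - s + 1 for s, e in merge_intervals(v))
               for v in g_ivs.values())
    i_bp = sum(sum(e - s + 1 for s, e in merge_intervals(v))
               for v in i_ivs.values())
    intergenic_bp = total_bp - genic_bp
    return CoverageSummary(
        amplified, frac, g_bp, i_bp,
        g_bp / genic_bp if genic_bp else 0.0,
        i_bp / intergenic_bp if intergenic_bp else 0.0)
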