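"""In silico PCR with EMBOSS-primersearch semantics.

Primer binding sites are found by exhaustive Hamming-distance scanning
on both strands (no indels; N never matches).  The mismatch budget is
``floor(mismatch_pct / 100 × primer length)``.  Every plus-strand site
of one primer paired with a downstream minus-strand site of the other —
in both role assignments — yields an amplimer, bounded by
``max_amplimer``.  Amplimer coordinates are outer (5' end of the
forward site to 5' end of the reverse site), matching reported PCR
product lengths.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._util import ValidationError, floor_decimals, revcomp
from .io import GenomeSequence


@dataclass(frozen=True)
class PrimerSite:
    """One primer binding site on a template."""

    template_id: str
    strand: str                 # "+" | "-"
    start_5prime: int           # 1-based template position of the primer 5' end
    n_mismatches: int


@dataclass(frozen=True)
class Amplimer:
    """One predicted PCR product (outer 5'-to-5' coordinates)."""

    template_id: str
    start: int
    end: int
    fwd_site: PrimerSite
    rev_site: PrimerSite

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class IspcrSummary:
    """Panel-level counters of an in silico PCR run."""

    n_primers_tested: int
    n_primers_with_hits: int
    n_amplimers_total: int
    total_amplimer_bp: int
    mean_amplimers_per_hitting_primer: float
    amplimer_lengths: dict[str, tuple[int, ...]]    # per primer name


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def find_primer_sites(template: GenomeSequence, primer: str,
                      mismatch_pct: float = 0.0) -> list[PrimerSite]:
    """All binding sites of one primer on both strands of a template.

    Returns sites sorted by template position (plus strand before minus
    at equal position).  A primer longer than the template yields no
    sites.
    """
    primer = primer.upper()
    if len(primer) < 10:
        raise ValidationError("primer length must be ≥ 10")
    if any(c not in "ACGT" for c in primer):
        raise ValidationError(f"non-ACGT base in primer {primer!r}")
    if not 0 <= mismatch_pct <= 50:
        raise ValidationError("mismatch_pct must be in [0, 50]")
    m = len(primer)
    n = template.length
    if m > n:
        return []
    budget = int(mismatch_pct / 100.0 * m)
    tpl = _encode(template.sequence)
    windows = np.lib.stride_tricks.sliding_window_view(tpl, m)
    real = ((tpl == ord("A")) | (tpl == ord("C")) |
            (tpl == ord("G")) | (tpl == ord("T")))
    real_w = np.lib.stride_tricks.sliding_window_view(real, m)
    sites = []
    for strand, probe in (("+", primer), ("-", revcomp(primer))):
        pe = _encode(probe)
        mism = ((windows != pe) | ~real_w).sum(axis=1)
        for off in np.flatnonzero(mism <= budget):
            off = int(off)
            # 5' end of the primer: leftmost base on +, rightmost on −
            pos = off + 1 if strand == "+" else off + m
            sites.append(PrimerSite(template.scaffold_id, strand, pos,
                                    int(mism[off])))
    sites.sort(key=lambda s: (s.start_5prime, s.strand))
    return sites


def predict_amplimers(template: GenomeSequence, forward: str, reverse: str,
                      mismatch_pct: float = 0.0,
                      max_amplimer: int = 5000) -> list[Amplimer]:
    """All products the primer pair would amplify from one template.

    Both role orientations are tried (either primer may act as the
    plus-strand primer, as primersearch does); duplicate coordinate
    pairs arising from both assignments are reported once.  Results are
    sorted by start, then end.
    """
    sites_f = find_primer_sites(template, forward, mismatch_pct)
    sites_r = find_primer_sites(template, reverse, mismatch_pct)
    seen: set[tuple[int, int]] = set()
    out: list[Amplimer] = []
    for plus_sites, minus_sites in ((sites_f, sites_r), (sites_r, sites_f)):
        for ps in plus_sites:
            if ps.strand != "+":
                continue
            for ms in minus_sites:
                if ms.strand != "-" or ms.start_5prime <= ps.start_5prime:
                    continue
                length = ms.start_5prime - ps.start_5prime + 1
                if length > max_amplimer:
                    continue
                key = (ps.start_5prime, ms.start_5prime)
                if key in seen:
                    continue
                seen.add(key)
                out.append(Amplimer(template.scaffold_id, ps.start_5prime,
                                    ms.start_5prime, ps, ms))
    out.sort(key=lambda a: (a.start, a.end))
    return out


def ispcr_summary(panel: list[tuple[str, str, str]],
                  genome_set: list[GenomeSequence],
                  mismatch_pct: float = 0.0,
                  max_amplimer: int = 5000) -> IspcrSummary:
    """Run a named primer panel against a genome set and count hits.

    ``panel`` rows are (name, forward, reverse).  ``n_amplimers_total``
    counts predicted products ("hit sequences"); per-primer amplimer
    length lists are retained for per-assembly comparison reports.
    """
    if not panel:
        raise ValidationError("empty primer panel")
    lengths: dict[str, tuple[int, ...]] = {}
    for name, fwd, rev in panel:
        amps: list[int] = []
        for tpl in genome_set:
            amps.extend(a.length for a in
                        predict_amplimers(tpl, fwd, rev, mismatch_pct,
                                          max_amplimer))
        lengths[name] = tuple(sorted(amps))
    hitting = [n for n, ls in lengths.items() if ls]
    n_amp = sum(len(ls) for ls in lengths.values())
    mean = floor_decimals(n_amp / len(hitting), 2) if hitting else 0.0
    return IspcrSummary(
        n_primers_tested=len(panel),
        n_primers_with_hits=len(hitting),
        n_amplimers_total=n_amp,
        total_amplimer_bp=sum(sum(ls) for ls in lengths.values()),
        mean_amplimers_per_hitting_primer=mean,
        amplimer_lengths=lengths,
    )
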