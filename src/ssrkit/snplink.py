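"""Attach SNPs to the flanking regions of designed primer pairs.

The flanking region of a marker is its amplicon minus the SSR motif
interval (at most two sub-intervals).  A SNP links to a pair when its
position falls inside the amplicon and — unless ``include_motif`` is
set — outside the motif.  A SNP may link to several overlapping
amplicons; within one region it is counted once.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from dataclasses import dataclass

from ._util import ValidationError, floor_decimals
from .io import SNPRecord
from .primers import PrimerPair


@dataclass(frozen=True)
class FlankLink:
    """SNPs found in one marker's flanking region."""

    primer_name: str
    scaffold_id: str
    flank_intervals: tuple[tuple[int, int], ...]
    snps: tuple[SNPRecord, ...]

    @property
    def n_snps(self) -> int:
        return len(self.snps)


@dataclass(frozen=True)
class SnpLinkSummary:
    """Genome-level SNP/flank statistics, split by compartment."""

    n_regions_total: int
    n_regions_with_snp: int
    pct_regions_with_snp: float
    n_snps_linked: int
    mean_snps_per_linked_region: float
    genic_regions_with_snp: int = 0
    intergenic_regions_with_snp: int = 0
    genic_snps_linked: int = 0
    intergenic_snps_linked: int = 0


def flank_intervals(pair: PrimerPair,
                    include_motif: bool = False) -> tuple[tuple[int, int], ...]:
    """The amplicon minus the SSR motif (or the whole amplicon)."""
    if include_motif:
        return ((pair.amp_start, pair.amp_end),)
    ivs = []
    if pair.ssr.start > pair.amp_start:
        ivs.append((pair.amp_start, pair.ssr.start - 1))
    if pair.ssr.end < pair.amp_end:
        ivs.append((pair.ssr.end + 1, pair.amp_end))
    return tuple(ivs)


def link_snps(pairs: list[PrimerPair], snps: list[SNPRecord],
              include_motif: bool = False) -> list[FlankLink]:
    """Link each pair to the SNPs inside its flanking region.

    Positions are reported 1-based on the scaffold; a pair on a scaffold
    absent from the SNP set simply gets zero links.
    """
    by_scaffold: dict[str, list[SNPRecord]] = {}
    for s in snps:
        by_scaffold.setdefault(s.scaffold_id, []).append(s)
    for lst in by_scaffold.values():
        lst.sort(key=lambda s: s.position)
    positions = {sid: [s.position for s in lst]
                 for sid, lst in by_scaffold.items()}
    links = []
    for pair in pairs:
        ivs = flank_intervals(pair, include_motif)
        pos = positions.get(pair.scaffold_id, [])
        lst = by_scaffold.get(pair.scaffold_id, [])
        hit: list[SNPRecord] = []
        for lo, hi in ivs:
            i = bisect_left(pos, lo)
            j = bisect_right(pos, hi)
            hit.extend(lst[i:j])
        hit.sort(key=lambda s: s.position)
        links.append(FlankLink(pair.name, pair.scaffold_id, ivs, tuple(hit)))
    return links


def snp_summary(links: list[FlankLink], n_pairs_total: int,
                contexts: dict[str, str] | None = None) -> SnpLinkSummary:
    """Counters over the links: how many regions carry SNPs, and how many.

    ``contexts`` maps primer name → SSR context for the genic/intergenic
    split; the linked-SNP counts are occurrences (a SNP shared by two
    overlapping regions counts once per region).
    """
    if n_pairs_total < len(links):
        raise ValidationError("n_pairs_total smaller than number of links")
    with_snp = [ln for ln in links if ln.n_snps]
    n_linked = sum(ln.n_snps for ln in with_snp)
    pct = floor_decimals(100 * len(with_snp) / n_pairs_total, 2) \
        if n_pairs_total else 0.0
    mean = floor_decimals(n_linked / len(with_snp), 2) if with_snp else 0.0
    g_regions = i_regions = g_snps = i_snps = 0
    if contexts:
        for ln in with_snp:
            if contexts.get(ln.primer_name) == "intergenic":
                i_regions += 1
                i_snps += ln.n_snps
            else:
                g_regions += 1
                g_snps += ln.n_snps
    return SnpLinkSummary(
        n_regions_total=n_pairs_total,
        n_regions_with_snp=len(with_snp),
        pct_regions_with_snp=pct,
        n_snps_linked=n_linked,
        mean_snps_per_linked_region=mean,
        genic_regions_with_snp=g_regions,
        intergenic_regions_with_snp=i_regions,
        genic_snps_linked=g_snps,
        intergenic_snps_linked=i_snps,
    )
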