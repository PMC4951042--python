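"""Independent brute-force oracles used to check the implementation.

Everything here is deliberately naive — quadratic scans, per-position
enumeration, hand-summed thermodynamics — and shares no code with the
package's algorithms.
"""

from __future__ import annotations

import math

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def rc(seq: str) -> str:
    return "".join(_COMP[c] for c in reversed(seq))


def primitive(unit: str) -> bool:
    n = len(unit)
    return not any(n % d == 0 and unit == unit[:d] * (n // d)
                   for d in range(1, n))


def brute_force_ssrs(seq: str, min_repeats: dict[int, int]) -> set[tuple]:
    """Every maximal perfect repeat run, per (position, unit length).

    A run is reported at start i with unit length k when: the unit is
    primitive and N-free, at least min_repeats[k] complete units follow,
    the run cannot be extended by one base on the left (leftmost phase
    of its maximal periodic interval), and the repeat count is maximal.
    Returns {(start_1based, end_1based, unit)}.
    """
    n = len(seq)
    out = set()
    for k, min_rep in min_repeats.items():
        for i in range(n - k * 2 + 1):
            unit = seq[i:i + k]
            if "N" in unit or not primitive(unit):
                continue
            # leftmost phase: the period must break at i-1
            if i > 0 and seq[i - 1] == seq[i - 1 + k] and seq[i - 1] != "N":
                continue
            reps = 1
            while seq[i + reps * k:i + (reps + 1) * k] == unit:
                reps += 1
            if reps >= min_rep:
                out.add((i + 1, i + reps * k, unit))
    return out


def chain_greedy(intervals: list[tuple[int, int]], max_gap: int) -> list[list[int]]:
    """Greedy left-to-right chaining of sorted intervals; returns index chains."""
    chains: list[list[int]] = []
    for idx, (s, e) in enumerate(intervals):
        if chains and s - intervals[chains[-1][-1]][1] - 1 <= max_gap:
            chains[-1].append(idx)
        else:
            chains.append([idx])
    return chains


# SantaLucia (1998) unified nearest-neighbor parameters:
# ΔH kcal/mol, ΔS cal/(mol·K) per stacked dinucleotide.
_NN = {
    "AA": (-7.9, -22.2), "TT": (-7.9, -22.2),
    "AT": (-7.2, -20.4), "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7), "TG": (-8.5, -22.7),
    "GT": (-8.4, -22.4), "AC": (-8.4, -22.4),
    "CT": (-7.8, -21.0), "AG": (-7.8, -21.0),
    "GA": (-8.2, -22.2), "TC": (-8.2, -22.2),
    "CG": (-10.6, -27.2), "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9), "CC": (-8.0, -19.9),
}
_INIT_GC = (0.1, -2.8)
_INIT_AT = (2.3, 4.1)
_R = 1.987  # cal/(mol·K)


def nn_tm(seq: str, na_mM: float = 50.0, oligo_nM: float = 50.0) -> float:
    """Nearest-neighbor melting temperature, summed by hand.

    Unified SantaLucia-1998 duplex parameters with terminal initiation
    penalties and the SantaLucia-1998 entropy salt correction
    0.368·(N−1)·ln[Na+]; Tm = 1000·ΔH / (ΔS + R·ln C) − 273.15 with the
    excess-oligo concentration C in mol/L.
    """
    dh, ds = 0.0, 0.0
    for i in range(len(seq) - 1):
        h, s = _NN[seq[i:i + 2]]
        dh += h
        ds += s
    for terminal in (seq[0], seq[-1]):
        h, s = _INIT_GC if terminal in "GC" else _INIT_AT
        dh += h
        ds += s
    ds += 0.368 * (len(seq) - 1) * math.log(na_mM / 1000.0)
    c = oligo_nM * 1e-9
    return 1000.0 * dh / (ds + _R * math.log(c)) - 273.15


def sliding_sites(template: str, primer: str, mismatch_pct: float) -> set[tuple]:
    """Naive both-strand Hamming scan: {(strand, five_prime_pos, mism)}."""
    budget = math.floor(mismatch_pct / 100.0 * len(primer))
    m = len(primer)
    out = set()
    for strand, probe in (("+", primer), ("-", rc(primer))):
        for i in range(len(template) - m + 1):
            window = template[i:i + m]
            mism = sum(1 for a, b in zip(window, probe)
                       if a != b or a not in "ACGT")
            if mism <= budget:
                pos = i + 1 if strand == "+" else i + m
                out.add((strand, pos, mism))
    return out


def all_pairs_amplimers(template: str, forward: str, reverse: str,
                        mismatch_pct: float, max_amplimer: int) -> set[tuple]:
    """All (start, end) outer spans from plus/minus site combinations."""
    sf = sliding_sites(template, forward, mismatch_pct)
    sr = sliding_sites(template, reverse, mismatch_pct)
    spans = set()
    for plus, minus in ((sf, sr), (sr, sf)):
        for st1, p1, _ in plus:
            if st1 != "+":
                continue
            for st2, p2, _ in minus:
                if st2 == "-" and p2 > p1 and p2 - p1 + 1 <= max_amplimer:
                    spans.add((p1, p2))
    return spans


def containment_links(regions: dict[str, list[tuple[str, int, int]]],
                      motifs: dict[str, tuple[str, int, int]],
                      snps: list[tuple[str, int]],
                      include_motif: bool) -> dict[str, list[int]]:
    """Quadratic SNP-in-region scan.

    ``regions``: name → [(scaffold, amp_start, amp_end)] (single entry);
    ``motifs``: name → (scaffold, ssr_start, ssr_end).
    """
    out: dict[str, list[int]] = {}
    for name, ivs in regions.items():
        hits = []
        for scaffold, lo, hi in ivs:
            for s_sc, pos in snps:
                if s_sc != scaffold or not (lo <= pos <= hi):
                    continue
                if not include_motif:
                    m_sc, ms, me = motifs[name]
                    if ms <= pos <= me:
                        continue
                hits.append(pos)
        out[name] = sorted(hits)
    return out


def interval_union_bp(intervals: list[tuple[int, int]]) -> int:
    """Sweep-line union length of 1-based inclusive intervals."""
    events = []
    for s, e in intervals:
        events.append((s, 1))
        events.append((e + 1, -1))
    events.sort()
    depth = covered = 0
    prev = None
    for x, d in events:
        if depth > 0:
            covered += x - prev
        depth += d
        prev = x
    return covered


def single_sub_neighbors(codon: str) -> set[str]:
    out = set()
    for i in range(3):
        for b in "ACGT":
            if b != codon[i]:
                out.add(codon[:i] + b + codon[i + 1:])
    return out
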