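"""Perfect microsatellite detection and compound-SSR merging.

A perfect SSR is a maximal run of a primitive 1–6 bp unit meeting a
per-unit-length minimum repeat count (defaults follow the MISA-style
criteria: mono ≥ 10, di ≥ 6, tri/tetra/penta/hexa ≥ 5).  Runs are found
on the forward strand only — a repeat and its reverse-complement twin
occupy the same interval, so dual-strand scanning would double-count.

Each maximal period-k interval is reported once, anchored at its
leftmost phase: the reported start cannot be shifted left by one base,
the unit is the literal first k bases of the run, and only complete unit
repetitions are counted (a trailing partial unit is excluded from the
span).  N never matches any base, so no run spans an N and no reported
unit contains one.  Non-primitive units (AA, ATAT, ...) are suppressed:
their intervals are already described by the shorter primitive unit.

Two or more perfect SSRs separated by at most ``max_interruption`` bases
(default 100) merge into one compound locus.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from decimal import Decimal, ROUND_HALF_UP

import numpy as np

from ._util import ValidationError, is_primitive, round_half_up
from .io import GenomeSequence

UNIT_CLASS_NAMES = {1: "mono", 2: "di", 3: "tri", 4: "tetra", 5: "penta",
                    6: "hexa", 0: "compound"}


@dataclass(frozen=True)
class ThresholdSet:
    """Minimum repeat counts per unit length and the compound gap limit."""

    min_repeats: dict[int, int] = field(
        default_factory=lambda: {1: 10, 2: 6, 3: 5, 4: 5, 5: 5, 6: 5})
    max_interruption: int = 100

    def __post_init__(self):
        if any(v < 2 for v in self.min_repeats.values()):
            raise ValidationError("all minimum repeat counts must be ≥ 2")
        if self.max_interruption < 0:
            raise ValidationError("max_interruption must be ≥ 0")


@dataclass(frozen=True)
class SSRRecord:
    """One perfect or compound microsatellite.

    Coordinates are 1-based inclusive.  For perfect records
    ``end - start + 1 == unit_length * repeat_count``.  Compound records
    carry their constituent perfect runs in ``members`` (unit_length 0,
    unit = members' units joined by ``/``).
    """

    scaffold_id: str
    start: int
    end: int
    unit: str
    repeat_count: int
    kind: str = "perfect"                       # "perfect" | "compound"
    members: tuple["SSRRecord", ...] = ()
    context: str | None = None                  # exon | intron | intergenic

    @property
    def unit_length(self) -> int:
        return 0 if self.kind == "compound" else len(self.unit)

    @property
    def unit_class(self) -> str:
        return UNIT_CLASS_NAMES[self.unit_length]

    @property
    def span(self) -> int:
        return self.end - self.start + 1

    @property
    def n_members(self) -> int:
        """Constituent perfect SSRs: 1 for perfect, len(members) for compound."""
        return len(self.members) if self.kind == "compound" else 1

    def iter_perfect(self):
        """The perfect runs this record stands for (itself, or its members)."""
        return iter(self.members) if self.kind == "compound" else iter((self,))

    def with_context(self, context: str) -> "SSRRecord":
        return replace(self, context=context)


@dataclass(frozen=True)
class MiningSummary:
    """Table-1-style counters for one mining run."""

    n_sequences_examined: int
    total_bp: int
    n_ssrs: int
    n_ssr_containing_sequences: int
    n_sequences_with_more_than_one_ssr: int
    n_ssrs_in_compound_formation: int
    freq_per_mb: float


def find_perfect_ssrs(seq: GenomeSequence,
                      thresholds: ThresholdSet | None = None) -> list[SSRRecord]:
    """Detect all maximal perfect SSRs in one scaffold.

    Returns records sorted by start, ties broken by unit length
    ascending.  An empty sequence yields an empty list.
    """
    thresholds = thresholds or ThresholdSet()
    s = seq.sequence
    n = len(s)
    if n == 0:
        return []
    arr = np.frombuffer(s.encode("ascii"), dtype=np.uint8)
    # positions holding a real base; N (and collapsed ambiguity) matches nothing
    real = ((arr == ord("A")) | (arr == ord("C")) |
            (arr == ord("G")) | (arr == ord("T")))
    records: list[SSRRecord] = []
    for k, min_rep in sorted(thresholds.min_repeats.items()):
        if n < k * min_rep:
            continue
        # m[i] True ⇔ s[i] pairs with s[i+k]; a True-run of length L starting
        # at a gives a maximal period-k interval of L + k bases at a.
        m = (arr[:-k] == arr[k:]) & real[:-k] & real[k:]
        if not m.any():
            continue
        padded = np.concatenate(([False], m, [False]))
        edges = np.flatnonzero(padded[1:] != padded[:-1])
        for a, b in zip(edges[::2], edges[1::2]):       # True-run [a, b)
            a, b = int(a), int(b)
            reps = (b - a + k) // k
            if reps < min_rep:
                continue
            unit = s[a:a + k]
            if not is_primitive(unit):
                continue
            records.append(SSRRecord(seq.scaffold_id, a + 1, a + reps * k,
                                     unit, reps))
    records.sort(key=lambda r: (r.start, r.unit_length))
    return records


def merge_compound(records: list[SSRRecord],
                   max_interruption: int = 100) -> list[SSRRecord]:
    """Collapse chains of nearby perfect SSRs into compound records.

    Input must be perfect records on one scaffold, sorted by start.
    Adjacent records with an inter-record gap (next.start − prev.end − 1)
    of at most ``max_interruption`` chain greedily left-to-right; because
    the gap relation is evaluated pairwise on adjacent records, greedy
    chains are exactly the maximal chains.  Isolated records pass through
    unchanged.
    """
    for prev, nxt in zip(records, records[1:]):
        if nxt.start < prev.start:
            raise ValidationError("merge_compound requires start-sorted input")
    for r in records:
        if r.kind != "perfect":
            raise ValidationError("merge_compound accepts perfect records only")
    out: list[SSRRecord] = []
    chain: list[SSRRecord] = []

    def flush():
        if not chain:
            return
        if len(chain) == 1:
            out.append(chain[0])
        else:
            out.append(SSRRecord(
                chain[0].scaffold_id, chain[0].start, chain[-1].end,
                "/".join(c.unit for c in chain),
                sum(c.repeat_count for c in chain),
                kind="compound", members=tuple(chain)))

    for rec in records:
        if chain and rec.start - chain[-1].end - 1 <= max_interruption:
            chain.append(rec)
        else:
            flush()
            chain = [rec]
    flush()
    return out


def mine_genome(genome: list[GenomeSequence],
                thresholds: ThresholdSet | None = None,
                merge: bool = True) -> list[SSRRecord]:
    """Mine every scaffold; optionally merge compounds per scaffold."""
    thresholds = thresholds or ThresholdSet()
    out: list[SSRRecord] = []
    for seq in genome:
        recs = find_perfect_ssrs(seq, thresholds)
        if merge:
            recs = merge_compound(recs, thresholds.max_interruption)
        out.extend(recs)
    return out


def normalize_motif(unit: str, collapse_strand: bool = False) -> str:
    """Canonical form of a repeat unit.

    The lexicographically smallest rotation; with ``collapse_strand``
    also the smallest over rotations of the reverse complement, so e.g.
    GGC, GCC and CCG all normalise to CCG.
    """
    if not is_primitive(unit):
        raise ValidationError(f"unit {unit!r} is not primitive")
    candidates = [unit[i:] + unit[:i] for i in range(len(unit))]
    if collapse_strand:
        from ._util import revcomp
        rc = revcomp(unit)
        candidates += [rc[i:] + rc[:i] for i in range(len(rc))]
    return min(candidates)


def summarize_mining(records: list[SSRRecord],
                     genome: list[GenomeSequence]) -> MiningSummary:
    """Table-1-style counters over a mined record set.

    A compound record contributes its member count to ``n_ssrs`` (the
    MISA convention: totals count constituent SSRs, not compound
    wrappers).  ``freq_per_mb`` is n_ssrs / (total bp / 10^6), rounded
    half-up to two decimals.
    """
    ids = {g.scaffold_id for g in genome}
    for r in records:
        if r.scaffold_id not in ids:
            raise ValidationError(f"record on unknown scaffold {r.scaffold_id}")
    total_bp = sum(g.length for g in genome)
    n_ssrs = sum(r.n_members for r in records)
    per_scaffold: dict[str, int] = {}
    for r in records:
        per_scaffold[r.scaffold_id] = per_scaffold.get(r.scaffold_id, 0) + r.n_members
    n_compound_members = sum(r.n_members for r in records if r.kind == "compound")
    freq = round_half_up(n_ssrs / (total_bp / 1e6), 2) if total_bp else 0.0
    return MiningSummary(
        n_sequences_examined=len(genome),
        total_bp=total_bp,
        n_ssrs=n_ssrs,
        n_ssr_containing_sequences=len(per_scaffold),
        n_sequences_with_more_than_one_ssr=sum(
            1 for v in per_scaffold.values() if v > 1),
        n_ssrs_in_compound_formation=n_compound_members,
        freq_per_mb=freq,
    )


def write_misa_tsv(records: list[SSRRecord], path: str | os.PathLike) -> None:
    """Emit a MISA-compatible TSV for cross-checking against the original tool."""
    with open(path, "w") as fh:
        fh.write("ID\tSSR nr.\tSSR type\tSSR\tsize\tstart\tend\n")
        counters: dict[str, int] = {}
        for r in records:
            counters[r.scaffold_id] = counters.get(r.scaffold_id, 0) + 1
            if r.kind == "compound":
                ssr_type = "c"
                motif = "".join(f"({m.unit}){m.repeat_count}" for m in r.members)
            else:
                ssr_type = f"p{r.unit_length}"
                motif = f"({r.unit}){r.repeat_count}"
            fh.write(f"{r.scaffold_id}\t{counters[r.scaffold_id]}\t{ssr_type}\t"
                     f"{motif}\t{r.span}\t{r.start}\t{r.end}\n")
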