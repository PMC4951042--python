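"""Small shared helpers: base matching, rounding, interval arithmetic."""

from __future__ import annotations

from decimal import Decimal, ROUND_DOWN, ROUND_HALF_UP
from typing import Iterable

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: IUPAC nucleotide one-letter codes accepted on input.
IUPAC_CODES = frozenset("ACGTNRYSWKMBDHV")


def revcomp(seq: str) -> str:
    """Reverse complement of an upper-case ACGTN string."""
    return seq.translate(_COMPLEMENT)[::-1]


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding (5 rounds away from zero), not banker's."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def floor_decimals(x: float, ndigits: int = 2) -> float:
    """Truncate toward zero at ``ndigits`` decimals (how genome surveys
    conventionally print ratio statistics: 75.556% prints as 75.55)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_DOWN))


def bases_match(a: str, b: str) -> bool:
    """True when two bases pair in a repeat/primer search.

    N (and any ambiguity code collapsed to N on input) never matches
    anything, including another N.
    """
    return a == b and a in "ACGT"


def is_primitive(unit: str) -> bool:
    """True when the unit is not itself a repetition of a shorter unit."""
    n = len(unit)
    for d in range(1, n):
        if n % d == 0 and unit == unit[:d] * (n // d):
            return False
    return True


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of 1-based inclusive intervals; touching intervals merge."""
    ivs = sorted(intervals)
    merged: list[tuple[int, int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def total_length(intervals: Iterable[tuple[int, int]]) -> int:
    """Total bp covered by a union of 1-based inclusive intervals."""
    return sum(e - s + 1 for s, e in merge_intervals(intervals))


class ValidationError(ValueError):
    """Raised on malformed input files or contract violations."""
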