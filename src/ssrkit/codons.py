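"""Genetic-code analyses of trinucleotide repeat units.

Trinucleotide SSRs in exons read as codons in their literal frame; a
single base substitution in such a repeat can turn a sense codon into a
stop (TAA, TAG or TGA) and truncate the protein.  This module
enumerates the trinucleotide motif space and computes, for each sense
codon, the stop codons reachable by exactly one substitution.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from itertools import product

from Bio.Data.CodonTable import standard_dna_table

from ._util import ValidationError, is_primitive
from .mining import SSRRecord

STOP_CODONS = frozenset(standard_dna_table.stop_codons)   # TAA, TAG, TGA

AMINO_ACID_NAMES = {
    "A": "Alanine", "R": "Arginine", "N": "Asparagine", "D": "Aspartic acid",
    "C": "Cysteine", "Q": "Glutamine", "E": "Glutamic acid", "G": "Glycine",
    "H": "Histidine", "I": "Isoleucine", "L": "Leucine", "K": "Lysine",
    "M": "Methionine", "F": "Phenylalanine", "P": "Proline", "S": "Serine",
    "T": "Threonine", "W": "Tryptophan", "Y": "Tyrosine", "V": "Valine",
}


@dataclass(frozen=True)
class CodonReport:
    """One sense codon and the stop codons one substitution away."""

    codon: str
    amino_acid: str
    reachable_stops: frozenset[str]


def enumerate_tri_motifs() -> list[str]:
    """All primitive trinucleotide repeat units, lexicographically.

    The four homopolymer triplets (AAA, CCC, GGG, TTT) repeat a shorter
    unit and are excluded, leaving 60 distinct units.
    """
    return [c for c in ("".join(p) for p in product("ACGT", repeat=3))
            if is_primitive(c)]


def stop_convertible(codon: str) -> frozenset[str]:
    """Stop codons at Hamming distance exactly 1 from a sense codon."""
    codon = codon.upper()
    if len(codon) != 3 or any(c not in "ACGT" for c in codon):
        raise ValidationError(f"not a DNA codon: {codon!r}")
    if codon in STOP_CODONS:
        raise ValidationError(f"{codon} is itself a stop codon")
    reach = set()
    for i in range(3):
        for b in "ACGT":
            if b == codon[i]:
                continue
            mutant = codon[:i] + b + codon[i + 1:]
            if mutant in STOP_CODONS:
                reach.add(mutant)
    return frozenset(reach)


def stop_convertible_sense_codons() -> dict[str, frozenset[str]]:
    """Every sense codon with a non-empty reachable-stop set."""
    out = {}
    for codon in ("".join(p) for p in product("ACGT", repeat=3)):
        if codon in STOP_CODONS:
            continue
        stops = stop_convertible(codon)
        if stops:
            out[codon] = stops
    return out


def survey_exon_tri_stops(records: list[SSRRecord],
                          include_rotations: bool = False) -> list[CodonReport]:
    """Report stop-convertible codons among exon trinucleotide repeat units.

    One report per distinct literal unit whose reachable-stop set is
    non-empty, sorted by amino-acid name then codon.  Units are read in
    their literal frame; ``include_rotations`` additionally evaluates
    each unit's two rotations (a repeat tract can be read in any frame).
    """
    units: set[str] = set()
    for rec in records:
        if rec.context is not None and rec.context != "exon":
            continue
        for m in rec.iter_perfect():
            if m.unit_length != 3:
                continue
            units.add(m.unit)
            if include_rotations:
                units.add(m.unit[1:] + m.unit[:1])
                units.add(m.unit[2:] + m.unit[:2])
    reports = []
    for unit in units:
        if unit in STOP_CODONS:
            continue
        stops = stop_convertible(unit)
        if not stops:
            continue
        aa = standard_dna_table.forward_table[unit]
        reports.append(CodonReport(unit, AMINO_ACID_NAMES[aa], stops))
    reports.sort(key=lambda r: (r.amino_acid, r.codon))
    return reports


def write_codon_report(reports: list[CodonReport],
                       path: str | os.PathLike) -> None:
    """Table-4-style TSV: amino acid, repeat sequence, stop codon(s)."""
    with open(path, "w") as fh:
        fh.write("amino_acid\trepeat_sequence\tstop_codon\n")
        for r in reports:
            for stop in sorted(r.reachable_stops):
                fh.write(f"{r.amino_acid}\t{r.codon}\t{stop}\n")
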