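"""Summary-report writers: TSV table layouts and a JSON roll-up."""

from __future__ import annotations

import json
import os
from dataclasses import asdict

import pandas as pd

from .mining import MiningSummary
from .partition import ContextSummary, MotifPresenceSets, RepeatCountBinTable


def write_mining_summary(summary: MiningSummary, path: str | os.PathLike) -> None:
    """Table-1-style two-column layout."""
    rows = [
        ("Total number of scaffolds examined", summary.n_sequences_examined),
        ("Total size of examined sequences (bp)", summary.total_bp),
        ("Total number of identified SSRs", summary.n_ssrs),
        ("Number of SSR containing sequences", summary.n_ssr_containing_sequences),
        ("Number of sequences containing more than one SSR",
         summary.n_sequences_with_more_than_one_ssr),
        ("Number of SSRs present in compound formation",
         summary.n_ssrs_in_compound_formation),
        ("Frequency of SSRs per Mb", summary.freq_per_mb),
    ]
    pd.DataFrame(rows, columns=["Searching item", "Results"]).to_csv(
        path, sep="\t", index=False)


def write_bin_table(table: RepeatCountBinTable, path: str | os.PathLike) -> None:
    """Table-2/3-style layout: bins × (unit class, compartment)."""
    cols = [(u, c) for u in table.classes for c in ("genic", "intergenic")]
    data = []
    for lo, hi in table.bins:
        row = {"No. of Repeat": f"{lo}-{hi}"}
        for u, c in cols:
            row[f"{u}_{c}"] = table.cells.get(((lo, hi), u, c), 0)
        data.append(row)
    total = {"No. of Repeat": "Total"}
    for u, c in cols:
        total[f"{u}_{c}"] = table.total(u, c)
    data.append(total)
    pd.DataFrame(data).to_csv(path, sep="\t", index=False)


def write_context_summary(summary: ContextSummary,
                          path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        json.dump(context_summary_dict(summary), fh, indent=2)
        fh.write("\n")


def context_summary_dict(summary: ContextSummary) -> dict:
    d = asdict(summary)
    d["genic_count"] = summary.genic_count
    d["total_count"] = summary.total_count
    # JSON keys must be strings
    d["unit_length_pct"] = {c: {str(k): v for k, v in m.items()}
                            for c, m in d["unit_length_pct"].items()}
    return d


def write_motif_sets(sets: MotifPresenceSets, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        json.dump({
            "unit_length": sets.unit_length,
            "genic_only": sorted(sets.genic_only),
            "intergenic_only": sorted(sets.intergenic_only),
            "shared": sorted(sets.shared),
        }, fh, indent=2)
        fh.write("\n")
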