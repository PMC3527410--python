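"""Consolidated pipeline report: count taxonomy, percentages, span, assembly.

The count table mirrors the standard summary of a hairpin-adaptor
paired-end run: raw reads, adaptor-bearing reads, kept pairs, full-length
pairs, non-redundant clusters, mapping classes for all and for
non-redundant pairs, and wrong-orientation chimeras.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import pandas as pd

from .anatomy import DissectionStats
from .mapping import QcReport, summary_percentages
from .scaffold import AssemblyStats

#: The 14 categories of the summary count table, in canonical order.
TABLE_ROW_LABELS = [
    "Total raw data reads",
    "Reads with hairpin adaptor sequences",
    "Read pairs with both ends larger than 40nt",
    "Full length read pairs with both ends larger than 40nt",
    "Non-redundant read pair clusters",
    "Non-redundant full length read pair clusters",
    "Read pairs mapped to multiple genomic locations",
    "Read pairs mapped to a unique genomic location",
    "Read pairs mapped to the same scaffold",
    "Read pairs mapped to different scaffolds",
    "Non-redundant read pairs mapped to a unique genomic location",
    "Non-redundant read pairs mapped to the same scaffold",
    "Non-redundant read pairs mapped to different scaffolds",
    "Chimeric read pairs with wrong orientation",
]


def count_table(
    stats: DissectionStats,
    n_nonredundant: int,
    n_nonredundant_full: int,
    qc_all: QcReport,
    qc_nonredundant: QcReport,
) -> list[tuple[str, int]]:
    values = [
        stats.n_raw,
        stats.n_with_adaptor,
        stats.n_kept,
        stats.n_full_length,
        n_nonredundant,
        n_nonredundant_full,
        qc_all.multiple,
        qc_all.unique,
        qc_all.same_scaffold,
        qc_all.different_scaffolds,
        qc_nonredundant.unique,
        qc_nonredundant.same_scaffold,
        qc_nonredundant.different_scaffolds,
        qc_all.wrong_orientation,
    ]
    return list(zip(TABLE_ROW_LABELS, values))


def _fmt_pct(x: Optional[float]) -> str:
    return "" if x is None else f"{x:.2f}"


def render_report(
    stats: DissectionStats,
    n_nonredundant: int,
    n_nonredundant_full: int,
    qc_all: QcReport,
    qc_nonredundant: QcReport,
    seed: int,
    params: dict | None = None,
    saturation: Optional[pd.DataFrame] = None,
    stats_before: Optional[AssemblyStats] = None,
    stats_after: Optional[AssemblyStats] = None,
) -> str:
    """Render the full text report (deterministic for fixed inputs)."""
    lines = [f"# paired-end pipeline report (seed={seed})"]
    for key, val in sorted((params or {}).items()):
        lines.append(f"# param {key} = {val}")
    lines.append("")
    lines.append("## Summary counts")
    for label, value in count_table(stats, n_nonredundant, n_nonredundant_full, qc_all, qc_nonredundant):
        lines.append(f"{label}\t{value:,}")
    lines.append("")
    lines.append("## Derived percentages (all kept pairs)")
    pcts = qc_all.percentages
    lines.append(f"Both ends mapped (%)\t{_fmt_pct(pcts['both_mapped_pct'])}")
    lines.append(f"Same scaffold (% of both-mapped)\t{_fmt_pct(pcts['same_scaffold_pct'])}")
    lines.append(f"Different scaffolds (% of both-mapped)\t{_fmt_pct(pcts['different_scaffolds_pct'])}")
    lines.append(f"Wrong orientation (% of same-scaffold)\t{_fmt_pct(pcts['wrong_orientation_pct'])}")
    lines.append("")
    lines.append("## Span of proper same-scaffold pairs (non-redundant)")
    if qc_nonredundant.span_median is not None:
        lines.append(f"mean (bp)\t{qc_nonredundant.span_mean:.1f}")
        lines.append(f"median (bp)\t{qc_nonredundant.span_median:.1f}")
        for lo, hi, n in qc_nonredundant.span_histogram:
            lines.append(f"bin\t{lo}\t{hi}\t{n}")
    else:
        lines.append("no proper same-scaffold pairs")
    if saturation is not None:
        lines.append("")
        lines.append("## Saturation of non-redundant pairs")
        lines.append("sample_size\treplicate\tcluster_count\tincrement")
        for _, row in saturation.iterrows():
            lines.append(
                f"{row['sample_size']}\t{row['replicate']}\t{row['cluster_count']}\t{row['increment_vs_previous_size']}"
            )
    if stats_before is not None and stats_after is not None:
        lines.append("")
        lines.append("## Assembly improvement")
        lines.append("\tbefore\tafter")
        lines.append(f"Number of scaffolds\t{stats_before.n_scaffolds:,}\t{stats_after.n_scaffolds:,}")
        lines.append(f"Span (bp)\t{stats_before.total_span:,}\t{stats_after.total_span:,}")
        lines.append(f"N50 scaffold (bp)\t{stats_before.n50:,}\t{stats_after.n50:,}")
    lines.append("")
    return "\n".join(lines)
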