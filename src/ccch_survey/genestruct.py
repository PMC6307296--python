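"""Gene-structure and chromosomal-distribution statistics for a gene family.

Covers per-gene exon counts with per-subfamily summaries, per-chromosome
census and density, and detection of long chromosome intervals free of
family members (such as pericentromeric stretches where a family is
absent).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .records import GeneModel

UNPLACED = "unplaced"


def exon_stats(models: Sequence[GeneModel]) -> tuple[pd.DataFrame, dict]:
    """Per-gene exon counts plus min/max/mean summary.

    Returns a table (gene_id, chromosome, exon_count, subfamily) and a
    summary dict with ``min``, ``max`` and ``mean`` (2 decimals). When
    subfamily labels are present a ``per_subfamily`` sub-dict summarizes
    each label the same way.
    """
    rows = []
    for m in models:
        if m.exon_count == 0:
            raise ValueError(f"gene {m.gene_id!r} has zero exons")
        rows.append((m.gene_id, m.chromosome, m.exon_count, m.subfamily))
    table = pd.DataFrame(rows, columns=["gene_id", "chromosome", "exon_count", "subfamily"])
    if table.empty:
        return table, {"min": None, "max": None, "mean": None}
    counts = table["exon_count"]
    summary: dict = {
        "min": int(counts.min()),
        "max": int(counts.max()),
        "mean": round(float(counts.mean()), 2),
    }
    labeled = table.dropna(subset=["subfamily"])
    if not labeled.empty:
        summary["per_subfamily"] = {
            str(sub): {
                "min": int(g["exon_count"].min()),
                "max": int(g["exon_count"].max()),
                "mean": round(float(g["exon_count"].mean()), 2),
            }
            for sub, g in labeled.groupby("subfamily")
        }
    return table, summary


@dataclass
class ChromosomeCensus:
    """Gene counts per chromosome, with density where lengths are known."""

    counts: dict[str, int]
    lengths: dict[str, int]
    density_per_mb: dict[str, float]

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def placed(self) -> int:
        return sum(n for chrom, n in self.counts.items() if chrom != UNPLACED)


def chromosome_census(
    models: Iterable[GeneModel],
    lengths: Optional[Mapping[str, int]] = None,
    unplaced_prefixes: tuple[str, ...] = ("Scaffold", "scaffold", "Ann", "nn"),
) -> ChromosomeCensus:
    """Count family genes per chromosome; unplaced contigs pool together.

    A gene counts as unplaced when its seqid starts with one of
    ``unplaced_prefixes`` (scaffolds and the ``Ann`` pseudo-chromosome of
    unanchored *B. rapa* genes).
    """
    counts: dict[str, int] = {}
    for m in models:
        chrom = m.chromosome
        if any(chrom.startswith(p) for p in unplaced_prefixes):
            chrom = UNPLACED
        counts[chrom] = counts.get(chrom, 0) + 1
    lengths = dict(lengths or {})
    density = {
        chrom: counts[chrom] / (lengths[chrom] / 1e6)
        for chrom in counts
        if chrom in lengths and lengths[chrom] > 0
    }
    return ChromosomeCensus(counts=counts, lengths=lengths, density_per_mb=density)


def family_free_intervals(
    models: Iterable[GeneModel],
    lengths: Mapping[str, int],
    min_len: int = 10_000_000,
) -> dict[str, list[tuple[int, int]]]:
    """Maximal intervals without any family gene, per chromosome.

    Intervals are 0-based half-open and reported only when at least
    ``min_len`` bp long (default 10 Mb). A chromosome with no family gene
    yields one interval covering its whole length.
    """
    spans: dict[str, list[tuple[int, int]]] = {chrom: [] for chrom in lengths}
    for m in models:
        if m.chromosome in spans:
            spans[m.chromosome].append((m.start, m.end))
    out: dict[str, list[tuple[int, int]]] = {}
    for chrom, length in lengths.items():
        gaps: list[tuple[int, int]] = []
        cursor = 0
        for s, e in sorted(spans[chrom]):
            if s > cursor:
                gaps.append((cursor, s))
            cursor = max(cursor, e)
        if cursor < length:
            gaps.append((cursor, length))
        kept = [(s, e) for s, e in gaps if e - s >= min_len]
        if kept:
            out[chrom] = kept
    return out


def write_intervals_bed(intervals: Mapping[str, list[tuple[int, int]]], path: str) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(intervals):
            for s, e in intervals[chrom]:
                fh.write(f"{chrom}\t{s}\t{e}\n")
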