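"""Core sequence and gene-model record types shared across the pipeline.

All coordinates are 0-based half-open internally; GFF3 I/O converts from
and to 1-based inclusive at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")
NUCLEOTIDE_ALPHABET = set("ACGTN")


@dataclass(frozen=True)
class DomainAnnotation:
    """An externally supplied domain call (e.g. WD40, ANK, RRM) on a protein."""

    name: str
    start: int  # 0-based
    end: int  # half-open


@dataclass
class ProteinRecord:
    """An identified protein sequence with optional gene linkage and annotations."""

    id: str
    sequence: str
    gene_id: str | None = None
    annotations: list[DomainAnnotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("protein record requires a non-empty id")
        if len(self.sequence) < 1:
            raise ValueError(f"protein {self.id!r}: empty sequence")
        bad = set(self.sequence) - PROTEIN_ALPHABET
        if bad:
            pos = next(i for i, c in enumerate(self.sequence) if c in bad)
            raise ValueError(
                f"protein {self.id!r}: invalid character {self.sequence[pos]!r} at position {pos}"
            )
        for ann in self.annotations:
            if not (0 <= ann.start < ann.end <= len(self.sequence)):
                raise ValueError(
                    f"protein {self.id!r}: annotation {ann.name} interval "
                    f"[{ann.start},{ann.end}) outside sequence of length {len(self.sequence)}"
                )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class CdsRecord:
    """A coding sequence (full-length CDS) for one gene."""

    id: str
    sequence: str
    gene_id: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("CDS record requires a non-empty id")
        if len(self.sequence) < 3:
            raise ValueError(f"CDS {self.id!r}: length < 3")
        bad = set(self.sequence) - NUCLEOTIDE_ALPHABET
        if bad:
            pos = next(i for i, c in enumerate(self.sequence) if c in bad)
            raise ValueError(
                f"CDS {self.id!r}: invalid character {self.sequence[pos]!r} at position {pos}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class GeneModel:
    """A gene span with its exon chain on a chromosome.

    ``start``/``end`` and exon intervals are 0-based half-open; exons are
    disjoint and sorted by start coordinate.
    """

    gene_id: str
    chromosome: str
    strand: str
    start: int
    end: int
    exons: list[tuple[int, int]] = field(default_factory=list)
    subfamily: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id!r}: strand must be '+' or '-'")
        if not (0 <= self.start < self.end):
            raise ValueError(f"gene {self.gene_id!r}: invalid span [{self.start},{self.end})")
        prev_end = None
        for s, e in self.exons:
            if not (self.start <= s < e <= self.end):
                raise ValueError(f"gene {self.gene_id!r}: exon [{s},{e}) outside gene span")
            if prev_end is not None and s < prev_end:
                raise ValueError(f"gene {self.gene_id!r}: exons overlap or are unsorted")
            prev_end = e

    @property
    def exon_count(self) -> int:
        return len(self.exons)
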