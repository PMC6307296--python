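"""CCCH zinc-finger motif scanning, typing, and census building.

A CCCH motif is written C-Xa-C-Xb-C-Xc-H: three cysteines and one histidine
with variable spacers. The family-defining bounds used here are
a ∈ [3,17], b ∈ [4,10], c ∈ [1,5], which cover all spacer types observed in
Brassicaceae surveys. The scanner also recognizes the tandem-zinc-finger
(TZF) arrangement of subfamily-IX proteins — a C-X7/8-C-X5-C-X3-H motif
followed 16–18 residues later by a C-X5-C-X4-C-X3-H motif, preceded by an
arginine-rich region carrying a C-X5-H-X4-C-X3-H signature — and leucine-rich
nuclear export signals (NES).

The unknown residue X matches spacer positions but never certifies a C/H
anchor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional, Sequence

from .records import ProteinRecord

Triple = tuple[int, int, int]

HYDROPHOBIC = frozenset("LIVFM")


@dataclass(frozen=True)
class ScanConfig:
    """Spacer bounds and overlap policy for the CCCH scanner."""

    a_range: tuple[int, int] = (3, 17)
    b_range: tuple[int, int] = (4, 10)
    c_range: tuple[int, int] = (1, 5)
    overlap_policy: Literal["non_overlapping", "report_all"] = "non_overlapping"

    def __post_init__(self) -> None:
        for lo, hi in (self.a_range, self.b_range, self.c_range):
            if lo < 0 or lo > hi:
                raise ValueError(f"invalid spacer range [{lo},{hi}]")
        if self.overlap_policy not in ("non_overlapping", "report_all"):
            raise ValueError(f"unknown overlap policy {self.overlap_policy!r}")


def type_label(spacers: Triple) -> str:
    a, b, c = spacers
    return f"C-X{a}-C-X{b}-C-X{c}-H"


@dataclass(frozen=True)
class MotifHit:
    """One located CCCH motif (0-based half-open span)."""

    protein_id: str
    start: int
    end: int
    spacers: Triple
    subsequence: str

    @property
    def type_label(self) -> str:
        return type_label(self.spacers)

    def __post_init__(self) -> None:
        a, b, c = self.spacers
        if self.end - self.start != a + b + c + 4:
            raise ValueError("motif span inconsistent with spacers")


def _parses_at(seq: str, start: int, config: ScanConfig) -> list[Triple]:
    """All (a,b,c) with C/C/C/H anchors at start under the config's bounds."""
    n = len(seq)
    if seq[start] != "C":
        return []
    out: list[Triple] = []
    for a in range(config.a_range[0], config.a_range[1] + 1):
        i2 = start + a + 1
        if i2 >= n or seq[i2] != "C":
            continue
        for b in range(config.b_range[0], config.b_range[1] + 1):
            i3 = i2 + b + 1
            if i3 >= n or seq[i3] != "C":
                continue
            for c in range(config.c_range[0], config.c_range[1] + 1):
                i4 = i3 + c + 1
                if i4 >= n or seq[i4] != "H":
                    continue
                out.append((a, b, c))
    return out


def scan_protein(protein: ProteinRecord, config: ScanConfig = ScanConfig()) -> list[MotifHit]:
    """Locate CCCH motifs in one protein.

    Under ``report_all`` every anchored parse within the spacer bounds is
    returned (sorted by start, then spacers). Under ``non_overlapping`` the
    scan proceeds left to right: at the leftmost anchored start the parse
    with minimal total spacer a+b+c is chosen (ties: smallest a, then b,
    then c), and scanning resumes after the terminal histidine, so hits are
    disjoint.
    """
    seq = protein.sequence
    hits: list[MotifHit] = []
    if config.overlap_policy == "report_all":
        for start in range(len(seq)):
            for trip in sorted(_parses_at(seq, start, config)):
                a, b, c = trip
                end = start + a + b + c + 4
                hits.append(MotifHit(protein.id, start, end, trip, seq[start:end]))
        return hits
    pos = 0
    n = len(seq)
    while pos < n:
        parses = _parses_at(seq, pos, config)
        if not parses:
            pos += 1
            continue
        trip = min(parses, key=lambda t: (sum(t), t))
        a, b, c = trip
        end = pos + a + b + c + 4
        hits.append(MotifHit(protein.id, pos, end, trip, seq[pos:end]))
        pos = end
    return hits


@dataclass
class MotifCensus:
    """Family-wide motif type counts and per-protein copy numbers."""

    counts: dict[Triple, int]
    total: int
    fractions: dict[Triple, float]
    per_protein_copy_number: dict[str, int]

    @property
    def n_types(self) -> int:
        return len(self.counts)

    def merged_fraction(self, triples: Iterable[Triple]) -> float:
        """Combined fraction of a display group (e.g. the 7/8 grouping)."""
        if self.total == 0:
            return 0.0
        return sum(self.counts.get(t, 0) for t in triples) / self.total


def build_census(
    hits: Iterable[MotifHit], include_proteins: Optional[Sequence[str]] = None
) -> MotifCensus:
    """Aggregate non-overlapping hits into a census.

    Types are keyed by exact spacer triple; display-level merges (such as the
    conventional C-X7/8-C-X5-C-X3-H grouping) are left to presentation via
    :meth:`MotifCensus.merged_fraction`. Zero-hit proteins appear in the
    copy-number map only when listed in ``include_proteins``.
    """
    counts: dict[Triple, int] = {}
    per_protein: dict[str, int] = {}
    if include_proteins is not None:
        per_protein = {pid: 0 for pid in include_proteins}
    total = 0
    for hit in hits:
        counts[hit.spacers] = counts.get(hit.spacers, 0) + 1
        per_protein[hit.protein_id] = per_protein.get(hit.protein_id, 0) + 1
        total += 1
    fractions = {t: n / total for t, n in counts.items()} if total else {}
    return MotifCensus(counts=counts, total=total, fractions=fractions,
                       per_protein_copy_number=per_protein)


# ---------------------------------------------------------------------------
# RR-TZF detection

TZF_FIRST_TRIPLES = {(7, 5, 3), (8, 5, 3)}
TZF_SECOND_TRIPLE = (5, 4, 3)
TZF_SPACING = (16, 18)

# RR signature C-X5-H-X4-C-X3-H: anchors at offsets 0, 6, 11, 15
_RR_LEN = 16


@dataclass(frozen=True)
class TzfCall:
    """A detected tandem-zinc-finger arrangement with its RR-region status."""

    protein_id: str
    motif1: MotifHit
    motif2: MotifHit
    inter_motif_spacing: int
    rr_motif_present: bool
    rr_motif_span: Optional[tuple[int, int]] = None


def _find_rr_motif(seq: str, before: int) -> Optional[tuple[int, int]]:
    """Leftmost C-X5-H-X4-C-X3-H signature ending at or before ``before``."""
    for start in range(0, before - _RR_LEN + 1):
        if (
            seq[start] == "C"
            and seq[start + 6] == "H"
            and seq[start + 11] == "C"
            and seq[start + 15] == "H"
        ):
            return (start, start + _RR_LEN)
    return None


def detect_rrtzf(
    protein: ProteinRecord, hits: Sequence[MotifHit], config: ScanConfig = ScanConfig()
) -> Optional[TzfCall]:
    """Call an RR-TZF arrangement from a protein's scanned hits.

    A call requires a C-X7/8-C-X5-C-X3-H hit followed by a C-X5-C-X4-C-X3-H
    hit whose start lies 16–18 residues after the first hit's end. The
    arginine-region signature is searched upstream of the first motif.
    """
    ordered = sorted(hits, key=lambda h: h.start)
    for i, m1 in enumerate(ordered):
        if m1.spacers not in TZF_FIRST_TRIPLES:
            continue
        for m2 in ordered[i + 1:]:
            if m2.spacers != TZF_SECOND_TRIPLE:
                continue
            spacing = m2.start - m1.end
            if TZF_SPACING[0] <= spacing <= TZF_SPACING[1]:
                rr_span = _find_rr_motif(protein.sequence, m1.start)
                return TzfCall(
                    protein_id=protein.id,
                    motif1=m1,
                    motif2=m2,
                    inter_motif_spacing=spacing,
                    rr_motif_present=rr_span is not None,
                    rr_motif_span=rr_span,
                )
    return None


# ---------------------------------------------------------------------------
# NES scanning


@dataclass(frozen=True)
class NesHit:
    """A putative leucine-rich nuclear export signal."""

    protein_id: str
    start: int
    end: int
    subsequence: str


def _nes_windows_at(seq: str, start: int) -> list[int]:
    """End positions of consensus matches Φ-X(2,3)-Φ-X(2,3)-Φ-X-Φ at start.

    Returned sorted ascending (shortest window first).
    """
    ends = []
    n = len(seq)
    if start >= n or seq[start] not in HYDROPHOBIC:
        return ends
    for g1 in (2, 3):
        i1 = start + 1 + g1
        if i1 >= n or seq[i1] not in HYDROPHOBIC:
            continue
        for g2 in (2, 3):
            i2 = i1 + 1 + g2
            i3 = i2 + 2
            if i3 >= n:
                continue
            if seq[i2] in HYDROPHOBIC and seq[i3] in HYDROPHOBIC:
                ends.append(i3 + 1)
    return sorted(ends)


def scan_nes(protein: ProteinRecord) -> list[NesHit]:
    """Scan for the classical leucine-rich CRM1-type NES consensus.

    Consensus Φ-X(2,3)-Φ-X(2,3)-Φ-X-Φ with Φ ∈ {L,I,V,F,M}. Matches are
    reported leftmost-first and non-overlapping; at a given start the
    shortest window is taken.
    """
    seq = protein.sequence
    hits: list[NesHit] = []
    pos = 0
    while pos < len(seq):
        ends = _nes_windows_at(seq, pos)
        if ends:
            end = ends[0]
            hits.append(NesHit(protein.id, pos, end, seq[pos:end]))
            pos = end
        else:
            pos += 1
    return hits
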