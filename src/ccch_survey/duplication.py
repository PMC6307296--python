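"""Duplicate-gene calling, tandem/segmental classification, Ka/Ks, and dating.

Two genes are duplicates when, on global alignments, the shorter full-length
CDS is covered > 70% and the encoded proteins are > 70% identical (strict
inequalities). Duplicate groups are connected components of that relation.
Tandem duplicates lie within 100 kb on one chromosome with at most ten
intervening non-homologues; everything else is segmental.

Ka and Ks are estimated with the Nei–Gojobori (1986) method: fractional
synonymous/nonsynonymous site counts per codon averaged over the two
sequences, observed differences averaged over all minimal mutational
pathways with equal weight, and Jukes–Cantor correction of the proportions.
Duplication age follows the molecular clock T = Ks/(2λ) with λ the
synonymous substitution rate per site per year (default 1.5e-8 for
*Brassica rapa*).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import networkx as nx
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Data.CodonTable import standard_dna_table

from .records import CdsRecord, GeneModel, ProteinRecord

_CODON_TABLE = dict(standard_dna_table.forward_table)
_STOP_CODONS = set(standard_dna_table.stop_codons)
_BASES = "ACGT"


@dataclass(frozen=True)
class DuplicationConfig:
    """Thresholds for duplicate calling, the tandem rule, and the clock rate."""

    min_cds_coverage: float = 0.70
    min_protein_identity: float = 0.70
    tandem_max_distance: int = 100_000
    tandem_max_intervening: int = 10
    clock_rate: float = 1.5e-8  # synonymous substitutions / site / year

    def __post_init__(self) -> None:
        for frac in (self.min_cds_coverage, self.min_protein_identity):
            if not (0 < frac <= 1):
                raise ValueError("thresholds must lie in (0,1]")
        if self.tandem_max_distance < 0 or self.tandem_max_intervening < 0:
            raise ValueError("tandem limits must be non-negative")
        if self.clock_rate <= 0:
            raise ValueError("clock rate must be positive")


# ---------------------------------------------------------------------------
# Pairwise similarity


def _protein_aligner() -> PairwiseAligner:
    # BLASTp-like scoring on a deterministic global (Needleman-Wunsch) path
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    return aligner


def _nucleotide_aligner() -> PairwiseAligner:
    # megablast-like scoring, end-to-end
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2
    aligner.mismatch_score = -3
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -2
    return aligner


@dataclass(frozen=True)
class PairSimilarity:
    gene_a: str
    gene_b: str
    cds_coverage: float
    protein_identity: float


def aligned_rows(aligner: PairwiseAligner, a: str, b: str) -> tuple[str, str]:
    """The two gapped rows of the first optimal global alignment."""
    alignment = aligner.align(a, b)[0]
    return str(alignment[0]), str(alignment[1])


def pair_similarity(
    cds_a: CdsRecord, cds_b: CdsRecord, prot_a: ProteinRecord, prot_b: ProteinRecord
) -> PairSimilarity:
    """Coverage/identity of a candidate duplicate pair from global alignments.

    Coverage is the fraction of the shorter CDS aligned against a residue
    (not a gap) in the nucleotide alignment; identity is identical residues
    over columns where both protein rows carry a residue.
    """
    if not cds_a.sequence or not cds_b.sequence or not prot_a.sequence or not prot_b.sequence:
        raise ValueError("empty sequence in similarity computation")
    row_a, row_b = aligned_rows(_nucleotide_aligner(), cds_a.sequence, cds_b.sequence)
    shorter_is_a = len(cds_a) <= len(cds_b)
    shorter_len = min(len(cds_a), len(cds_b))
    covered = sum(
        1
        for ca, cb in zip(row_a, row_b)
        if ca != "-" and cb != "-"
    )
    # columns where the shorter sequence is aligned to a residue of the other
    coverage = covered / shorter_len

    pa, pb = aligned_rows(_protein_aligner(), prot_a.sequence, prot_b.sequence)
    both = [(x, y) for x, y in zip(pa, pb) if x != "-" and y != "-"]
    identity = (sum(1 for x, y in both if x == y) / len(both)) if both else 0.0
    return PairSimilarity(cds_a.gene_id or cds_a.id, cds_b.gene_id or cds_b.id,
                          coverage, identity)


def is_duplicate(sim: PairSimilarity, config: DuplicationConfig = DuplicationConfig()) -> bool:
    """Strict >70%/>70% rule on CDS coverage and protein identity."""
    return (
        sim.cds_coverage > config.min_cds_coverage
        and sim.protein_identity > config.min_protein_identity
    )


def call_duplicates(
    similarities: Iterable[PairSimilarity],
    config: DuplicationConfig = DuplicationConfig(),
) -> list[frozenset[str]]:
    """Duplicate groups as connected components of the duplicate relation.

    Pairs, triplets, and larger groups arise naturally: if A–B and B–C pass
    the thresholds, {A,B,C} is one group even when A–C does not.
    """
    graph = nx.Graph()
    for sim in similarities:
        if is_duplicate(sim, config):
            graph.add_edge(sim.gene_a, sim.gene_b)
    return sorted((frozenset(c) for c in nx.connected_components(graph)), key=sorted)


# ---------------------------------------------------------------------------
# Tandem vs segmental


def classify_pair(
    gene_a: GeneModel,
    gene_b: GeneModel,
    chromosome_genes: Sequence[GeneModel],
    family_members: frozenset[str] | set[str],
    config: DuplicationConfig = DuplicationConfig(),
) -> str:
    """Classify a duplicate pair as ``tandem`` or ``segmental``.

    Tandem requires the same chromosome, a start-to-start distance within
    the configured window (100 kb), and at most ``tandem_max_intervening``
    genes strictly between the two that are not members of the duplicate
    group. ``chromosome_genes`` must be the full ordered annotation of the
    chromosome so intervening genes can be counted.
    """
    if gene_a.chromosome is None or gene_b.chromosome is None:
        missing = gene_a.gene_id if gene_a.chromosome is None else gene_b.gene_id
        raise ValueError(f"gene {missing!r} lacks chromosome coordinates")
    if gene_a.chromosome != gene_b.chromosome:
        return "segmental"
    if abs(gene_a.start - gene_b.start) > config.tandem_max_distance:
        return "segmental"
    lo, hi = sorted((gene_a.start, gene_b.start))
    intervening = sum(
        1
        for g in chromosome_genes
        if lo < g.start < hi
        and g.gene_id not in (gene_a.gene_id, gene_b.gene_id)
        and g.gene_id not in family_members
    )
    return "tandem" if intervening <= config.tandem_max_intervening else "segmental"


# ---------------------------------------------------------------------------
# Nei-Gojobori (1986)


def _syn_fraction(codon: str, pos: int) -> float:
    """Fraction of the three possible changes at one codon position that are
    synonymous. Changes to stop codons count as nonsynonymous so every
    position contributes exactly one site (N+S conservation)."""
    aa = _CODON_TABLE.get(codon)
    syn = 0
    for base in _BASES:
        if base == codon[pos]:
            continue
        alt = codon[:pos] + base + codon[pos + 1:]
        if _CODON_TABLE.get(alt) == aa and alt not in _STOP_CODONS:
            syn += 1
    return syn / 3.0


def _codon_sites(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts of one codon; sums to 3."""
    s = sum(_syn_fraction(codon, p) for p in range(3))
    return s, 3.0 - s


def _step_class(codon_from: str, codon_to: str) -> float:
    """Synonymous weight (0 or 1) of a single-nucleotide codon change."""
    return 1.0 if _CODON_TABLE[codon_from] == _CODON_TABLE[codon_to] else 0.0


def _pair_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """(Sd, Nd) for one codon pair, averaged over all minimal mutational
    pathways with equal weight.

    A step through a stop codon counts as nonsynonymous (a stop encodes no
    residue), so every pathway contributes and the averaging needs no
    special cases.
    """
    diff_pos = [p for p in range(3) if codon_a[p] != codon_b[p]]
    if not diff_pos:
        return 0.0, 0.0
    pathways: list[tuple[float, float]] = []
    for order in itertools.permutations(diff_pos):
        current = codon_a
        syn = nonsyn = 0.0
        for p in order:
            nxt = current[:p] + codon_b[p] + current[p + 1:]
            if (
                current not in _STOP_CODONS
                and nxt not in _STOP_CODONS
                and _step_class(current, nxt)
            ):
                syn += 1.0
            else:
                nonsyn += 1.0
            current = nxt
        pathways.append((syn, nonsyn))
    sd = sum(p[0] for p in pathways) / len(pathways)
    nd = sum(p[1] for p in pathways) / len(pathways)
    return sd, nd


def _jukes_cantor(p: float) -> tuple[float, bool]:
    """JC-corrected distance and a saturation flag (p >= 3/4)."""
    if p >= 0.75:
        return math.nan, True
    return -0.75 * math.log1p(-4.0 * p / 3.0), False


@dataclass
class KaKsResult:
    """Nei-Gojobori site counts, difference counts, and corrected distances."""

    N: float
    S: float
    Nd: float
    Sd: float
    pN: float
    pS: float
    Ka: float
    Ks: float
    omega: Optional[float]
    saturated: bool
    codons_compared: int = 0

    @property
    def selection_mode(self) -> Optional[str]:
        """negative (ω<1), neutral (ω=1), or positive (ω>1) selection."""
        if self.omega is None:
            return None
        if self.omega < 1:
            return "negative"
        if self.omega > 1:
            return "positive"
        return "neutral"


def ng86(cds_a: str | CdsRecord, cds_b: str | CdsRecord) -> KaKsResult:
    """Nei-Gojobori (1986) Ka/Ks on an aligned equal-length CDS pair.

    Codons containing a gap, an N, or a stop in either sequence are excluded
    pairwise; remaining codons must number at least one. Site counts are the
    average of the two sequences' fractional counts, so N+S equals three
    times the number of compared codons exactly.
    """
    a = cds_a.sequence if isinstance(cds_a, CdsRecord) else cds_a
    b = cds_b.sequence if isinstance(cds_b, CdsRecord) else cds_b
    a, b = a.upper(), b.upper()
    if len(a) != len(b):
        raise ValueError(f"aligned CDS lengths differ ({len(a)} vs {len(b)})")
    if len(a) % 3:
        raise ValueError(f"aligned CDS length {len(a)} is not a multiple of 3")
    S = N = Sd = Nd = 0.0
    compared = 0
    for i in range(0, len(a), 3):
        ca, cb = a[i:i + 3], b[i:i + 3]
        if (
            "-" in ca or "-" in cb or "N" in ca or "N" in cb
            or ca in _STOP_CODONS or cb in _STOP_CODONS
        ):
            continue
        sa, na = _codon_sites(ca)
        sb, nb = _codon_sites(cb)
        S += (sa + sb) / 2
        N += (na + nb) / 2
        sd, nd = _pair_differences(ca, cb)
        Sd += sd
        Nd += nd
        compared += 1
    if compared == 0:
        raise ValueError("no comparable codons after exclusions")
    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    Ks, sat_s = _jukes_cantor(pS)
    Ka, sat_n = _jukes_cantor(pN)
    saturated = sat_s or sat_n
    omega: Optional[float] = None
    if not saturated and Ks > 0:
        omega = Ka / Ks
    return KaKsResult(N=N, S=S, Nd=Nd, Sd=Sd, pN=pN, pS=pS, Ka=Ka, Ks=Ks,
                      omega=omega, saturated=saturated, codons_compared=compared)


def estimate_age(ks: float, clock_rate: float = 1.5e-8) -> float:
    """Duplication age in million years: T = Ks / (2 λ) × 10⁻⁶."""
    if ks < 0:
        raise ValueError("Ks must be non-negative")
    if clock_rate <= 0:
        raise ValueError("clock rate must be positive")
    return ks / (2.0 * clock_rate) * 1e-6


# ---------------------------------------------------------------------------
# Codon-aware alignment utility


def codon_align(
    cds_a: CdsRecord, cds_b: CdsRecord, prot_a: ProteinRecord, prot_b: ProteinRecord
) -> tuple[str, str]:
    """Thread two CDSs through their proteins' global alignment.

    Returns equal-length gapped CDS strings suitable for :func:`ng86`.
    Trailing stop codons (one codon beyond 3x the protein length) are
    dropped before threading.
    """
    ca = cds_a.sequence[: 3 * len(prot_a.sequence)]
    cb = cds_b.sequence[: 3 * len(prot_b.sequence)]
    if len(ca) < 3 * len(prot_a.sequence) or len(cb) < 3 * len(prot_b.sequence):
        raise ValueError("CDS shorter than 3x its protein; cannot codon-align")
    row_a, row_b = aligned_rows(_protein_aligner(), prot_a.sequence, prot_b.sequence)
    out_a: list[str] = []
    out_b: list[str] = []
    ia = ib = 0
    for x, y in zip(row_a, row_b):
        if x == "-":
            out_a.append("---")
        else:
            out_a.append(ca[3 * ia: 3 * ia + 3])
            ia += 1
        if y == "-":
            out_b.append("---")
        else:
            out_b.append(cb[3 * ib: 3 * ib + 3])
            ib += 1
    return "".join(out_a), "".join(out_b)


# ---------------------------------------------------------------------------
# Pair records


@dataclass
class DuplicatePair:
    """A called duplicate relationship with classification, Ka/Ks, and age."""

    gene_a: str
    gene_b: str
    similarity: PairSimilarity
    duplication_class: str  # tandem | segmental
    kaks: Optional[KaKsResult] = None
    age_mya: Optional[float] = None
    group_id: int = 0
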