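"""Seeded generators for every input the survey pipeline consumes.

Each generator is a pure function of (spec, seed) and returns machine-
readable ground truth alongside its output, so downstream stages can be
tested against the generator's bookkeeping without any external data.

The module also builds a full synthetic CCCH family configured to the
published *B. rapa* census (103 proteins carrying 257 motifs in 15 exact
spacer types, the C-X7/8-C-X5-C-X3-H group at 211/257 of motifs, copy
numbers 1–6, and 102 of 103 genes anchored to chromosomes A01–A10), which
serves as the pipeline's reference workload.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .duplication import _CODON_TABLE, _STOP_CODONS, _codon_sites
from .motifs import HYDROPHOBIC, ScanConfig, MotifHit, scan_protein
from .records import CdsRecord, GeneModel, ProteinRecord

Triple = tuple[int, int, int]

# Background letters: the 18 standard residues that are not motif anchors
_NON_ANCHOR = "ADEFGIKLMNPQRSTVWY"

# gaps at or above this length cannot complete a spacer across two implants
_SAFE_GAP = 19

_RR_BLOCK_LEN = 17  # C-X5-H-X4-C-X3-H


@dataclass(frozen=True)
class ImplantSpec:
    """What to implant into one synthetic protein.

    ``positions`` gives explicit motif start coordinates, or None for random
    placement with inter-implant gaps of at least 19 residues (which cannot
    combine anchors from two implants into a spurious motif). ``reject``
    resamples the background until the scanner finds exactly the implanted
    hits.
    """

    motifs: tuple[Triple, ...]
    length: int = 300
    positions: Optional[tuple[int, ...]] = None
    reject: bool = True
    ch_weight: float = 0.02  # background probability weight of C and H
    with_rr_block: bool = False  # prepend an RR-region C-X5-H-X4-C-X3-H signature
    with_nes: bool = False  # implant a leucine-rich NES block

    def __post_init__(self) -> None:
        config = ScanConfig()
        for a, b, c in self.motifs:
            if not (
                config.a_range[0] <= a <= config.a_range[1]
                and config.b_range[0] <= b <= config.b_range[1]
                and config.c_range[0] <= c <= config.c_range[1]
            ):
                raise ValueError(f"implant triple {(a, b, c)} outside scanner bounds")


def _motif_string(triple: Triple, rng: np.random.Generator) -> str:
    a, b, c = triple
    spacer = lambda k: "".join(rng.choice(list(_NON_ANCHOR), size=k))
    return "C" + spacer(a) + "C" + spacer(b) + "C" + spacer(c) + "H"


_NES_BLOCK = "LAALAALAL"


def _rr_string(rng: np.random.Generator) -> str:
    spacer = lambda k: "".join(rng.choice(list(_NON_ANCHOR), size=k))
    return "C" + spacer(5) + "H" + spacer(4) + "C" + spacer(3) + "H"


def _background(rng: np.random.Generator, k: int, ch_weight: float) -> str:
    letters = list(_NON_ANCHOR) + ["C", "H"]
    w = np.array([1.0] * len(_NON_ANCHOR) + [ch_weight, ch_weight])
    w /= w.sum()
    return "".join(rng.choice(letters, size=k, p=w)) if k else ""


def gen_protein_with_motifs(
    spec: ImplantSpec, seed: int, protein_id: str = "synth1"
) -> tuple[ProteinRecord, list[MotifHit]]:
    """Generate one protein with implanted CCCH motifs plus ground truth.

    With rejection on, the emitted sequence scans (report_all) to exactly
    the implanted hit list. Rejection failing after 200 background resamples
    raises, advising a lower background C/H frequency.
    """
    rng = np.random.default_rng(seed)
    blocks: list[tuple[str, str]] = []  # (kind, text); kind "motif" carries truth
    if spec.with_rr_block:
        blocks.append(("rr", _rr_string(rng)))
    if spec.with_nes:
        blocks.append(("nes", _NES_BLOCK))
    triples = list(spec.motifs)
    motif_strings = [_motif_string(t, rng) for t in triples]

    if spec.positions is not None:
        if len(spec.positions) != len(triples):
            raise ValueError("positions and motifs differ in length")
        layout = sorted(zip(spec.positions, motif_strings, triples))
        prefix_blocks = blocks
    else:
        layout = None
        prefix_blocks = blocks

    def assemble(background: str) -> tuple[str, list[tuple[int, Triple]]]:
        # place fixed blocks then motifs left to right, consuming background
        out: list[str] = []
        truth: list[tuple[int, Triple]] = []
        cursor = 0
        bg_iter = iter(background)

        def take(k: int) -> str:
            return "".join(next(bg_iter) for _ in range(k))

        if layout is not None:
            pos_cursor = 0
            for kind, text in prefix_blocks:
                out.append(text)
                pos_cursor += len(text)
                out.append(take(_SAFE_GAP))
                pos_cursor += _SAFE_GAP
            base = pos_cursor
            # explicit positions are relative to the end of the prefix blocks
            for start, mstring, triple in layout:
                gap = base + start - pos_cursor
                if gap < 0:
                    raise ValueError("explicit implant positions overlap")
                out.append(take(gap))
                pos_cursor += gap
                truth.append((pos_cursor, triple))
                out.append(mstring)
                pos_cursor += len(mstring)
            remaining = max(0, spec.length - pos_cursor)
            out.append(take(remaining))
            return "".join(out), truth
        # random placement
        for kind, text in prefix_blocks:
            out.append(text)
            cursor += len(text)
            out.append(take(_SAFE_GAP))
            cursor += _SAFE_GAP
        n = len(motif_strings)
        motif_len = sum(len(s) for s in motif_strings)
        fixed = cursor + motif_len + (n - 1) * _SAFE_GAP if n else cursor
        slack = max(0, spec.length - fixed)
        cuts = np.sort(rng.integers(0, slack + 1, size=n + 1)) if n else np.array([slack])
        gaps = np.diff(np.concatenate([[0], cuts]))  # n+1 extra gaps summing <= slack
        for k, (mstring, triple) in enumerate(zip(motif_strings, triples)):
            extra = int(gaps[k]) if k < len(gaps) else 0
            gap = extra + (_SAFE_GAP if k > 0 else 0)
            out.append(take(gap))
            cursor += gap
            truth.append((cursor, triple))
            out.append(mstring)
            cursor += len(mstring)
        tail = max(0, spec.length - cursor)
        out.append(take(tail))
        return "".join(out), truth

    for attempt in range(200):
        background = _background(rng, spec.length + 400, spec.ch_weight)
        sequence, truth_pos = assemble(background)
        record = ProteinRecord(id=protein_id, sequence=sequence)
        expected = [
            MotifHit(protein_id, start, start + sum(t) + 4, t,
                     sequence[start:start + sum(t) + 4])
            for start, t in truth_pos
        ]
        if not spec.reject:
            return record, expected
        found = scan_protein(record, ScanConfig(overlap_policy="report_all"))
        if [(h.start, h.spacers) for h in found] == [(h.start, h.spacers) for h in expected]:
            return record, expected
    raise RuntimeError(
        "implant rejection failed after 200 background resamples; "
        "lower the background C/H frequency (ch_weight)"
    )


# ---------------------------------------------------------------------------
# Duplicate CDS pairs at target (Ks, omega)


@dataclass(frozen=True)
class DivergenceSpec:
    """Target divergence for one simulated duplicate pair."""

    n_codons: int = 300
    ks: float = 0.2
    omega: float = 0.2

    def __post_init__(self) -> None:
        if self.n_codons < 100:
            raise ValueError("ancestor must be at least 100 codons")
        if self.ks < 0 or self.omega < 0:
            raise ValueError("Ks and omega must be non-negative")


def _random_ancestor(n_codons: int, rng: np.random.Generator) -> str:
    codons = [c for c in _CODON_TABLE if c not in _STOP_CODONS]
    return "".join(rng.choice(codons, size=n_codons))


def _mutation_options(codon: str, synonymous: bool) -> list[tuple[int, str]]:
    aa = _CODON_TABLE[codon]
    out = []
    for pos in range(3):
        for base in "ACGT":
            if base == codon[pos]:
                continue
            alt = codon[:pos] + base + codon[pos + 1:]
            if alt in _STOP_CODONS:
                continue
            if (_CODON_TABLE[alt] == aa) == synonymous:
                out.append((pos, base))
    return out


def _apply_events(
    codons: list[str], n_events: int, synonymous: bool, rng: np.random.Generator
) -> None:
    """Apply point substitutions uniformly over the current set of
    synonymous (or nonsynonymous) single-nucleotide options.

    Sampling is by rejection: a uniform (codon, position, base) proposal is
    accepted when it falls in the wanted class, which weights each site by
    its number of eligible changes — the same weighting Nei-Gojobori site
    counting uses.
    """
    n = len(codons)
    applied = 0
    guard = 0
    while applied < n_events:
        guard += 1
        if guard > 1000 * max(n_events, 1):
            raise RuntimeError("mutation sampling failed to find eligible sites")
        idx = int(rng.integers(0, n))
        pos = int(rng.integers(0, 3))
        base = "ACGT"[int(rng.integers(0, 4))]
        codon = codons[idx]
        if base == codon[pos]:
            continue
        alt = codon[:pos] + base + codon[pos + 1:]
        if alt in _STOP_CODONS:
            continue
        if (_CODON_TABLE[alt] == _CODON_TABLE[codon]) != synonymous:
            continue
        codons[idx] = alt
        applied += 1


def gen_duplicate_cds(
    spec: DivergenceSpec, seed: int
) -> tuple[CdsRecord, CdsRecord, CdsRecord, float, float]:
    """Simulate a duplicate CDS pair diverged to target (Ks, omega).

    A stop-free random ancestor is mutated independently along two lineages;
    each lineage carries half the target divergence, with event counts
    Poisson-distributed around Ks/2 x S synonymous and Ka/2 x N
    nonsynonymous sites of the ancestor. The pair is emitted aligned (equal
    length, no indels). Returns (ancestor, copy_a, copy_b, true_ks,
    true_omega).
    """
    rng = np.random.default_rng(seed)
    ancestor = _random_ancestor(spec.n_codons, rng)
    anc_codons = [ancestor[i:i + 3] for i in range(0, len(ancestor), 3)]
    S = sum(_codon_sites(c)[0] for c in anc_codons)
    N = sum(_codon_sites(c)[1] for c in anc_codons)
    ka = spec.omega * spec.ks
    if ka > 0 and N == 0:
        raise ValueError("nonsynonymous divergence requested but no nonsynonymous sites")
    copies = []
    for _ in range(2):
        codons = list(anc_codons)
        n_syn = int(rng.poisson(spec.ks / 2 * S)) if spec.ks > 0 else 0
        n_non = int(rng.poisson(ka / 2 * N)) if ka > 0 else 0
        _apply_events(codons, n_syn, synonymous=True, rng=rng)
        _apply_events(codons, n_non, synonymous=False, rng=rng)
        copies.append("".join(codons))
    return (
        CdsRecord(id="ancestor", sequence=ancestor),
        CdsRecord(id="copy_a", sequence=copies[0]),
        CdsRecord(id="copy_b", sequence=copies[1]),
        spec.ks,
        spec.omega,
    )


# ---------------------------------------------------------------------------
# Gene models


def gen_gene_models(
    counts_per_chromosome: dict[str, int],
    chromosome_lengths: dict[str, int],
    exon_counts: Sequence[int],
    seed: int,
    allowed_windows: Optional[dict[str, list[tuple[int, int]]]] = None,
    gene_length: int = 3000,
    id_prefix: str = "GENE",
) -> list[GeneModel]:
    """Place non-overlapping multi-exon gene models on chromosomes.

    ``exon_counts`` supplies one exon count per gene in placement order.
    ``allowed_windows`` restricts placement per chromosome (used to leave
    family-free regions). Gene IDs encode the chromosome and an ordinal.
    """
    if sum(counts_per_chromosome.values()) != len(exon_counts):
        raise ValueError("exon_counts length must equal total gene count")
    if any(k < 1 for k in exon_counts):
        raise ValueError("exon counts must be >= 1")
    rng = np.random.default_rng(seed)
    models: list[GeneModel] = []
    it = iter(exon_counts)
    for chrom in sorted(counts_per_chromosome):
        n = counts_per_chromosome[chrom]
        length = chromosome_lengths[chrom]
        windows = (allowed_windows or {}).get(chrom, [(0, length)])
        starts: list[int] = []
        span_total = sum(e - s for s, e in windows)
        if n * (gene_length + 1000) > span_total:
            raise ValueError(f"chromosome {chrom}: not enough room for {n} genes")
        # draw starts uniformly inside the windows, retry on overlap
        while len(starts) < n:
            offset = int(rng.integers(0, span_total - gene_length))
            for s, e in windows:
                if offset < e - s:
                    cand = s + offset
                    break
                offset -= e - s
            if cand + gene_length > e:
                continue
            if all(abs(cand - other) >= gene_length + 500 for other in starts):
                starts.append(cand)
        starts.sort()
        for i, start in enumerate(starts, 1):
            k = next(it)
            exons = _exon_chain(start, gene_length, k, rng)
            models.append(
                GeneModel(
                    gene_id=f"{id_prefix}{chrom}g{i:05d}",
                    chromosome=chrom,
                    strand="+" if rng.random() < 0.5 else "-",
                    start=start,
                    end=start + gene_length,
                    exons=exons,
                )
            )
    return models


def _exon_chain(start: int, gene_length: int, k: int, rng: np.random.Generator) -> list[tuple[int, int]]:
    """Split a gene span into k exons separated by introns."""
    if k == 1:
        return [(start, start + gene_length)]
    # 2k-1 alternating blocks (exon/intron/...), each at least 50 bp
    blocks = 2 * k - 1
    minimum = 50 * blocks
    extra = gene_length - minimum
    if extra < 0:
        raise ValueError("gene too short for requested exon count")
    cuts = np.sort(rng.integers(0, extra + 1, size=blocks - 1))
    sizes = np.diff(np.concatenate([[0], cuts, [extra]])) + 50
    exons = []
    pos = start
    for i, size in enumerate(sizes):
        if i % 2 == 0:
            exons.append((pos, pos + int(size)))
        pos += int(size)
    # stretch the last exon to the gene end so the span is exact
    exons[-1] = (exons[-1][0], start + gene_length)
    return exons


# ---------------------------------------------------------------------------
# Cq tables


def gen_cq_table(
    genes: Sequence[str],
    conditions: Sequence[str],
    times: Sequence[float],
    true_folds: dict[tuple[str, str, float], float],
    noise_sd: float,
    seed: int,
    reference_gene: str = "REF",
    replicates: int = 3,
    reference_cq: float = 18.0,
    baseline_cq: float = 24.0,
) -> tuple[pd.DataFrame, dict[tuple[str, str, float], float]]:
    """Simulate a replicate Cq table with known fold changes.

    The reference gene sits at a constant Cq in every stratum (up to noise);
    each target's treated Cq is shifted by -log2(fold) relative to its
    control at the same time point. Returns the table and the truth map
    keyed by (gene, condition, time).
    """
    if noise_sd < 0:
        raise ValueError("noise sd must be non-negative")
    if any(f <= 0 for f in true_folds.values()):
        raise ValueError("true folds must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    all_conditions = ["control"] + [c for c in conditions if c != "control"]
    for condition in all_conditions:
        for t in times:
            for rep in range(1, replicates + 1):
                rows.append((reference_gene, condition, t, rep,
                             reference_cq + rng.normal(0, noise_sd), True))
            for gene in genes:
                cq = baseline_cq
                if condition != "control":
                    fold = true_folds.get((gene, condition, t), 1.0)
                    cq = baseline_cq - math.log2(fold)
                for rep in range(1, replicates + 1):
                    rows.append((gene, condition, t, rep,
                                 cq + rng.normal(0, noise_sd), False))
    table = pd.DataFrame(
        rows, columns=["gene_id", "condition", "time_h", "replicate", "cq", "is_reference"]
    )
    return table, dict(true_folds)


# ---------------------------------------------------------------------------
# Labeled reference panels for subfamily assignment


def gen_reference_set(
    subfamilies: Sequence[str], per_subfamily: int, length: int, seed: int
) -> tuple[list[ProteinRecord], dict[str, str]]:
    """Random labeled reference proteins, one panel per subfamily label."""
    rng = np.random.default_rng(seed)
    refs: list[ProteinRecord] = []
    labels: dict[str, str] = {}
    letters = list(_NON_ANCHOR + "CH")
    for sub in subfamilies:
        for i in range(per_subfamily):
            rid = f"REF_{sub}_{i + 1}"
            seq = "".join(rng.choice(letters, size=length))
            refs.append(ProteinRecord(id=rid, sequence=seq))
            labels[rid] = sub
    return refs, labels


def mutate_protein(
    protein: ProteinRecord, fraction: float, seed: int, new_id: Optional[str] = None
) -> ProteinRecord:
    """Substitute a fixed fraction of residues (uniform random replacements)."""
    rng = np.random.default_rng(seed)
    seq = list(protein.sequence)
    k = int(round(fraction * len(seq)))
    sites = rng.choice(len(seq), size=k, replace=False)
    letters = _NON_ANCHOR + "CH"
    for site in sites:
        choices = [c for c in letters if c != seq[site]]
        seq[site] = choices[int(rng.integers(0, len(choices)))]
    return ProteinRecord(id=new_id or protein.id + "_mut", sequence="".join(seq))


# ---------------------------------------------------------------------------
# The reference workload: a family at the published B. rapa census


#: Exact spacer types and counts: 257 motifs, 15 types, with the
#: C-X7/8-C-X5-C-X3-H group at 211/257 = 82.10% and 17 tandem-zinc-finger
#: proteins carrying the C-X5-C-X4-C-X3-H second motif.
FAMILY_TYPE_COUNTS: dict[Triple, int] = {
    (7, 5, 3): 105,
    (8, 5, 3): 106,
    (5, 4, 3): 17,
    (17, 6, 3): 2,
    (3, 5, 1): 1,
    (8, 5, 5): 1,
    (4, 10, 2): 1,
    (8, 6, 3): 2,
    (4, 5, 3): 3,
    (5, 5, 3): 4,
    (6, 5, 3): 3,
    (9, 5, 3): 3,
    (11, 5, 3): 3,
    (7, 4, 3): 3,
    (7, 5, 5): 3,
}

#: Copy-number plan for the 86 non-TZF proteins (the 17 TZF proteins carry
#: 2 motifs each); totals 223 motifs over 86 proteins, max 6 copies.
_NON_TZF_COPY_PLAN = [6] * 5 + [5] * 5 + [4] * 10 + [3] * 19 + [2] * 24 + [1] * 23

#: Genes anchored per chromosome (102 placed + 1 unanchored), with A09 and
#: A03 carrying 16 members, A07 13, and the short A10 11.
FAMILY_CHROMOSOME_COUNTS: dict[str, int] = {
    "A01": 9, "A02": 5, "A03": 16, "A04": 6, "A05": 9,
    "A06": 7, "A07": 13, "A08": 10, "A09": 16, "A10": 11,
    "Ann": 1,
}

#: Chromosome lengths in bp (A10 shortest at 20.72 Mb).
FAMILY_CHROMOSOME_LENGTHS: dict[str, int] = {
    "A01": 28_600_000, "A02": 27_800_000, "A03": 31_700_000,
    "A04": 21_200_000, "A05": 23_900_000, "A06": 26_200_000,
    "A07": 24_400_000, "A08": 22_500_000, "A09": 37_100_000,
    "A10": 20_720_000, "Ann": 2_000_000,
}

#: Middle stretches of A01 and A02 kept free of family genes (>10 Mb).
FAMILY_FREE_WINDOWS: dict[str, list[tuple[int, int]]] = {
    "A01": [(0, 8_500_000), (19_600_000, 28_600_000)],
    "A02": [(0, 8_000_000), (19_000_000, 27_800_000)],
}

TZF_COUNT = 17


def brassica_family_plan() -> list[tuple[str, tuple[Triple, ...], bool]]:
    """Deterministic per-protein implant plan realizing FAMILY_TYPE_COUNTS.

    Returns (protein_id, motif triples, is_tzf) for 103 proteins. TZF
    proteins pair a C-X7/8-C-X5-C-X3-H motif with the C-X5-C-X4-C-X3-H
    motif; remaining motifs are dealt round-robin so copy numbers span 1-6.
    """
    pool: dict[Triple, int] = dict(FAMILY_TYPE_COUNTS)
    plan: list[tuple[str, tuple[Triple, ...], bool]] = []
    idx = 1
    for i in range(TZF_COUNT):
        first = (7, 5, 3) if i % 2 == 0 else (8, 5, 3)
        pool[first] -= 1
        pool[(5, 4, 3)] -= 1
        plan.append((f"SYN{idx:03d}", (first, (5, 4, 3)), True))
        idx += 1
    # deal remaining types largest-first so rare types land on low-copy proteins
    remaining: list[Triple] = []
    for triple, count in sorted(pool.items(), key=lambda kv: -kv[1]):
        remaining.extend([triple] * count)
    assert len(remaining) == sum(_NON_TZF_COPY_PLAN)
    cursor = 0
    for copies in _NON_TZF_COPY_PLAN:
        triples = tuple(remaining[cursor:cursor + copies])
        cursor += copies
        plan.append((f"SYN{idx:03d}", triples, False))
        idx += 1
    return plan


def gen_brassica_family(seed: int) -> tuple[list[ProteinRecord], dict[str, list[MotifHit]]]:
    """Generate the 103-protein reference family with its ground-truth hits.

    Every TZF protein carries an upstream RR-region signature and a
    leucine-rich NES block in addition to its motif pair (inter-motif
    spacing fixed at 16 residues by explicit placement).
    """
    rng = np.random.default_rng(seed)
    proteins: list[ProteinRecord] = []
    truth: dict[str, list[MotifHit]] = {}
    for pid, triples, is_tzf in brassica_family_plan():
        sub_seed = int(rng.integers(0, 2**31 - 1))
        if is_tzf:
            first = triples[0]
            # motif1 at 0, motif2 16 residues after motif1's end
            positions = (0, sum(first) + 4 + 16)
            spec = ImplantSpec(
                motifs=triples,
                length=220,
                positions=positions,
                with_rr_block=True,
                with_nes=True,
            )
        else:
            spec = ImplantSpec(motifs=triples, length=120 + 60 * len(triples))
        record, hits = gen_protein_with_motifs(spec, sub_seed, protein_id=pid)
        proteins.append(record)
        truth[pid] = hits
    return proteins, truth


def gen_brassica_gene_models(seed: int) -> list[GeneModel]:
    """Gene models for the reference family's 103 genes.

    Exon counts span 1-16; the 17 TZF genes (subfamily IX) are single-exon.
    """
    rng = np.random.default_rng(seed)
    plan = brassica_family_plan()
    n = len(plan)
    exon_counts: list[int] = []
    for i in range(n):
        if i < TZF_COUNT:
            exon_counts.append(1)
        elif i == TZF_COUNT:
            exon_counts.append(16)  # realize the family's upper bound
        else:
            exon_counts.append(int(rng.integers(1, 13)))
    # placement order is chromosome-sorted; shuffle counts to decouple
    rng.shuffle(exon_counts)
    if 16 not in exon_counts:
        exon_counts[0] = 16
    models = gen_gene_models(
        FAMILY_CHROMOSOME_COUNTS,
        FAMILY_CHROMOSOME_LENGTHS,
        exon_counts,
        seed=int(rng.integers(0, 2**31 - 1)),
        allowed_windows=FAMILY_FREE_WINDOWS,
        gene_length=3000,
        id_prefix="SYN",
    )
    # first 17 single-exon genes stand in for subfamily IX
    tzf_assigned = 0
    for m in models:
        if m.exon_count == 1 and tzf_assigned < TZF_COUNT:
            m.subfamily = "IX"
            tzf_assigned += 1
    return models
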