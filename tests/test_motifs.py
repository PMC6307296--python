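"""Scanner correctness against an independent brute-force enumeration."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ccch_survey.motifs import (
    HYDROPHOBIC,
    ScanConfig,
    build_census,
    detect_rrtzf,
    scan_nes,
    scan_protein,
)
from ccch_survey.records import ProteinRecord

REPORT_ALL = ScanConfig(overlap_policy="report_all")


def brute_force_ccch(seq: str, config: ScanConfig = ScanConfig()):
    """Quadruple loop over (start, a, b, c) checking the four anchors."""
    out = []
    n = len(seq)
    for start in range(n):
        for a in range(config.a_range[0], config.a_range[1] + 1):
            for b in range(config.b_range[0], config.b_range[1] + 1):
                for c in range(config.c_range[0], config.c_range[1] + 1):
                    p2, p3, p4 = start + a + 1, start + a + b + 2, start + a + b + c + 3
                    if p4 >= n:
                        continue
                    if seq[start] == "C" and seq[p2] == "C" and seq[p3] == "C" and seq[p4] == "H":
                        out.append((start, (a, b, c)))
    return out


def brute_force_nes_windows(seq: str):
    """All consensus windows (start, end) of Φ-X(2,3)-Φ-X(2,3)-Φ-X-Φ."""
    out = []
    for start in range(len(seq)):
        for g1 in (2, 3):
            for g2 in (2, 3):
                idx = [start, start + 1 + g1, start + 2 + g1 + g2, start + 4 + g1 + g2]
                if idx[-1] >= len(seq):
                    continue
                if all(seq[i] in HYDROPHOBIC for i in idx):
                    out.append((start, idx[-1] + 1))
    return out


def test_no_anchor_no_hits():
    assert scan_protein(ProteinRecord(id="p", sequence="MKKKKKAAA")) == []


def test_constructed_exact_match():
    seq = "C" + "A" * 8 + "C" + "A" * 5 + "C" + "A" * 3 + "H"
    (hit,) = scan_protein(ProteinRecord(id="p", sequence=seq))
    assert (hit.start, hit.end, hit.spacers) == (0, 20, (8, 5, 3))
    assert hit.subsequence == seq


def test_x_matches_spacers_but_not_anchors():
    good = "C" + "X" * 8 + "C" + "X" * 5 + "C" + "X" * 3 + "H"
    assert len(scan_protein(ProteinRecord(id="p", sequence=good))) == 1
    # X in place of the terminal H must not match
    bad = good[:-1] + "X"
    assert scan_protein(ProteinRecord(id="p", sequence=bad)) == []


@pytest.mark.parametrize("seed", range(20))
def test_report_all_equals_brute_force(seed):
    rng = np.random.default_rng(seed)
    length = int(rng.integers(50, 501))
    # C/H-rich alphabet to provoke many overlapping parses
    seq = "".join(rng.choice(list("ACDEFGHKLCHCH"), size=length))
    protein = ProteinRecord(id=f"r{seed}", sequence=seq)
    got = [(h.start, h.spacers) for h in scan_protein(protein, REPORT_ALL)]
    assert got == sorted(brute_force_ccch(seq))


@given(st.text(alphabet="ACH", min_size=1, max_size=120))
@settings(max_examples=200, deadline=None)
def test_report_all_matches_oracle_on_adversarial_alphabet(seq):
    protein = ProteinRecord(id="h", sequence=seq)
    got = [(h.start, h.spacers) for h in scan_protein(protein, REPORT_ALL)]
    assert got == sorted(brute_force_ccch(seq))


@given(st.text(alphabet="ACHLX", min_size=1, max_size=150))
@settings(max_examples=200, deadline=None)
def test_non_overlapping_is_sound_subset(seq):
    protein = ProteinRecord(id="h", sequence=seq)
    chosen = scan_protein(protein, ScanConfig())
    all_parses = set(brute_force_ccch(seq))
    last_end = -1
    for hit in chosen:
        assert (hit.start, hit.spacers) in all_parses
        assert hit.start >= last_end  # disjoint, sorted
        last_end = hit.end
    # leftmost-minimal rule: each chosen hit has the minimal total spacer
    # among parses anchored at its own start
    for hit in chosen:
        at_start = [t for s, t in all_parses if s == hit.start]
        assert hit.spacers == min(at_start, key=lambda t: (sum(t), t))


def test_census_counts_and_fractions(family):
    proteins, truth = family
    hits = [h for p in proteins for h in scan_protein(p)]
    census = build_census(hits, include_proteins=[p.id for p in proteins])
    assert census.total == sum(census.counts.values()) == len(hits)
    assert abs(sum(census.fractions.values()) - 1.0) < 1e-12
    assert census.per_protein_copy_number.keys() == {p.id for p in proteins}


def test_census_empty():
    census = build_census([])
    assert census.total == 0 and census.fractions == {}


def test_census_single_type():
    seq = "C" + "A" * 8 + "C" + "A" * 5 + "C" + "A" * 3 + "H"
    hits = [h for pid in ("p1", "p2")
            for h in scan_protein(ProteinRecord(id=pid, sequence=seq))]
    census = build_census(hits)
    assert census.counts == {(8, 5, 3): 2}
    assert census.fractions[(8, 5, 3)] == 1.0


def _tzf_sequence(spacing: int, with_rr: bool = False) -> str:
    m1 = "C" + "A" * 7 + "C" + "A" * 5 + "C" + "A" * 3 + "H"
    m2 = "C" + "A" * 5 + "C" + "A" * 4 + "C" + "A" * 3 + "H"
    prefix = ("C" + "A" * 5 + "H" + "A" * 4 + "C" + "A" * 3 + "H" + "A" * 20) if with_rr else ""
    return prefix + m1 + "A" * spacing + m2


@pytest.mark.parametrize("spacing,expected", [(16, True), (17, True), (18, True), (15, False), (25, False)])
def test_tzf_spacing_bounds(spacing, expected):
    seq = _tzf_sequence(spacing)
    protein = ProteinRecord(id="t", sequence=seq)
    call = detect_rrtzf(protein, scan_protein(protein))
    assert (call is not None) is expected
    if call:
        assert call.inter_motif_spacing == spacing
        assert not call.rr_motif_present


def test_tzf_rr_motif_detected_upstream():
    protein = ProteinRecord(id="t", sequence=_tzf_sequence(16, with_rr=True))
    call = detect_rrtzf(protein, scan_protein(protein))
    assert call is not None and call.rr_motif_present
    assert call.rr_motif_span == (0, 16)


def test_nes_examples():
    (hit,) = scan_nes(ProteinRecord(id="n", sequence="LAALAALAL"))
    assert (hit.start, hit.end) == (0, 9)
    assert scan_nes(ProteinRecord(id="n", sequence="AAAAAAA")) == []
    hits = scan_nes(ProteinRecord(id="n", sequence="LLLLLLLLL"))
    assert len(hits) == 1 and hits[0].start == 0


@given(st.text(alphabet="LIVFMAG", min_size=1, max_size=80))
@settings(max_examples=200, deadline=None)
def test_nes_hits_are_leftmost_nonoverlapping_consensus_windows(seq):
    windows = brute_force_nes_windows(seq)
    hits = scan_nes(ProteinRecord(id="n", sequence=seq))
    cursor = 0
    expected = []
    starts = sorted({s for s, _ in windows})
    while True:
        nxt = [(s, e) for s, e in windows if s >= cursor]
        if not nxt:
            break
        s0 = min(s for s, _ in nxt)
        e0 = min(e for s, e in nxt if s == s0)
        expected.append((s0, e0))
        cursor = e0
    assert [(h.start, h.end) for h in hits] == expected
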