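"""Duplicate calling, tandem rule, and Nei-Gojobori estimator checks.

The NG86 implementation is cross-checked against Biopython's independent
codon-alignment estimator on random codon pairs.
"""

import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ccch_survey.duplication import (
    DuplicationConfig,
    PairSimilarity,
    call_duplicates,
    classify_pair,
    codon_align,
    estimate_age,
    is_duplicate,
    ng86,
    pair_similarity,
)
from ccch_survey.records import CdsRecord, GeneModel, ProteinRecord
from ccch_survey.synthetic import DivergenceSpec, gen_duplicate_cds

CODONS = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"
          if a + b + c not in ("TAA", "TAG", "TGA")]


# ---------------------------------------------------------------------------
# NG86


def test_ng86_identical_sequences():
    r = ng86("ATGGCTTGC", "ATGGCTTGC")
    assert r.Ka == 0 and r.Ks == 0 and r.omega is None
    assert r.Sd == 0 and r.Nd == 0


def test_ng86_phe_leu_hand_enumeration():
    # TTT: only the third position admits a synonymous change (TTC), 1/3 site;
    # TTA: 1/3 at position one (CTA) plus 1/3 at position three (TTG) = 2/3.
    r = ng86("TTT", "TTA")
    assert r.S == pytest.approx(0.5)
    assert r.N == pytest.approx(2.5)
    assert r.Sd == 0 and r.Nd == 1


def test_ng86_fourfold_third_position():
    r = ng86("GGG", "GGA")  # Gly -> Gly
    assert r.Sd == 1 and r.Nd == 0
    assert r.Ka == 0
    assert r.saturated  # pS = 1 on a single codon exceeds the JC bound


def test_ng86_site_conservation_and_symmetry_random_pairs(rng):
    for _ in range(50):
        n = int(rng.integers(2, 40))
        a = "".join(rng.choice(CODONS, size=n))
        b = "".join(rng.choice(CODONS, size=n))
        try:
            r1 = ng86(a, b)
        except ValueError:
            continue  # saturated/zero-codon corner
        r2 = ng86(b, a)
        assert r1.N + r1.S == pytest.approx(3 * r1.codons_compared, abs=1e-9)
        assert (r1.Sd, r1.Nd, r1.S, r1.N) == (r2.Sd, r2.Nd, r2.S, r2.N)


def test_ng86_matches_biopython_reference():
    """Cross-check against Biopython's independent NG86 implementation.

    Restricted to codons with a non-T first base: no mutational pathway can
    then pass through a stop codon, the one case where stop-step conventions
    differ between implementations.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        from Bio.codonalign.codonseq import CodonSeq, cal_dn_ds
    safe = [c for c in CODONS if c[0] != "T"]
    rng = np.random.default_rng(7)
    checked = 0
    while checked < 10:
        n = int(rng.integers(30, 80))
        a = "".join(rng.choice(safe, size=n))
        codons = [a[i:i + 3] for i in range(0, len(a), 3)]
        # mutate a handful of codons to other sense codons
        for idx in rng.choice(n, size=max(2, n // 8), replace=False):
            codons[int(idx)] = str(rng.choice(safe))
        b = "".join(codons)
        mine = ng86(a, b)
        if mine.saturated:
            continue
        dn, ds = cal_dn_ds(CodonSeq(a), CodonSeq(b), method="NG86")
        assert mine.Ka == pytest.approx(dn, abs=1e-9)
        assert mine.Ks == pytest.approx(ds, abs=1e-9)
        checked += 1


def test_ng86_excludes_gap_n_and_stop_codons():
    r = ng86("ATG---TTTNNNTAA", "ATGGCGTTANNNTAA")
    # only ATG/ATG and TTT/TTA codons compared
    assert r.codons_compared == 2
    assert r.Nd == 1 and r.Sd == 0


def test_ng86_input_validation():
    with pytest.raises(ValueError, match="lengths differ"):
        ng86("ATG", "ATGGCG")
    with pytest.raises(ValueError, match="multiple of 3"):
        ng86("ATGC", "ATGC")
    with pytest.raises(ValueError, match="comparable"):
        ng86("TAA", "TAA")


def test_ng86_recovers_simulated_divergence():
    """Median (Ks, omega) over simulated pairs within 10% of target."""
    ks_hat, om_hat = [], []
    for i in range(60):
        _, a, b, _, _ = gen_duplicate_cds(
            DivergenceSpec(n_codons=900, ks=0.2, omega=0.2), seed=5000 + i
        )
        r = ng86(a.sequence, b.sequence)
        ks_hat.append(r.Ks)
        om_hat.append(r.omega)
    assert abs(np.median(ks_hat) - 0.2) / 0.2 < 0.10
    assert abs(np.median(om_hat) - 0.2) / 0.2 < 0.10


def test_selection_mode_labels():
    assert ng86("TTT", "TTA").selection_mode is None  # Ks=0 -> omega undefined
    r = ng86("GGG" + "TTT" * 5, "GGA" + "TTT" * 5)
    assert r.omega == 0 and r.selection_mode == "negative"


# ---------------------------------------------------------------------------
# Dating


def test_estimate_age_closed_form():
    assert estimate_age(0.0) == 0.0
    assert estimate_age(0.03, 1.5e-8) == pytest.approx(1.0)
    assert estimate_age(0.5874, 1.5e-8) == pytest.approx(19.58)
    assert estimate_age(0.0087, 1.5e-8) == pytest.approx(0.29)
    with pytest.raises(ValueError):
        estimate_age(-0.1)


@given(st.floats(min_value=0, max_value=2), st.floats(min_value=1e-4, max_value=2))
@settings(max_examples=100, deadline=None)
def test_estimate_age_strictly_increasing(ks, delta):
    assert estimate_age(ks + delta) > estimate_age(ks)


# ---------------------------------------------------------------------------
# Similarity and calling


def test_pair_similarity_identity_case():
    cds = CdsRecord(id="c", sequence="ATGGCTTGCGAT" * 25)
    prot = ProteinRecord(id="p", sequence="MACD" * 25)
    sim = pair_similarity(cds, cds, prot, prot)
    assert sim.cds_coverage == 1.0 and sim.protein_identity == 1.0


def test_pair_similarity_counted_on_emitted_alignment(rng):
    """Identity equals a direct recount over the aligner's own rows."""
    from ccch_survey.duplication import _protein_aligner, aligned_rows

    letters = list("ACDEFGHIKLMNPQRSTVWY")
    a = "".join(rng.choice(letters, size=120))
    b = "".join(rng.choice(letters, size=110))
    pa = ProteinRecord(id="a", sequence=a)
    pb = ProteinRecord(id="b", sequence=b)
    ca = CdsRecord(id="a", sequence="".join(rng.choice(list("ACGT"), size=360)))
    cb = CdsRecord(id="b", sequence="".join(rng.choice(list("ACGT"), size=330)))
    sim = pair_similarity(ca, cb, pa, pb)
    row_a, row_b = aligned_rows(_protein_aligner(), a, b)
    both = [(x, y) for x, y in zip(row_a, row_b) if x != "-" and y != "-"]
    expected = sum(1 for x, y in both if x == y) / len(both)
    assert sim.protein_identity == pytest.approx(expected)


def test_duplicate_threshold_is_strict():
    config = DuplicationConfig()
    at = PairSimilarity("a", "b", 0.70, 0.70)
    above = PairSimilarity("a", "b", 0.71, 0.71)
    coverage_only = PairSimilarity("a", "b", 0.70, 0.99)
    assert not is_duplicate(at, config)
    assert is_duplicate(above, config)
    assert not is_duplicate(coverage_only, config)


def test_duplicate_groups_are_connected_components():
    sims = [
        PairSimilarity("A", "B", 0.9, 0.9),
        PairSimilarity("B", "C", 0.9, 0.9),
        PairSimilarity("A", "C", 0.5, 0.5),  # fails, but A,B,C still one group
        PairSimilarity("D", "E", 0.8, 0.8),
    ]
    groups = call_duplicates(sims)
    assert groups == [frozenset({"A", "B", "C"}), frozenset({"D", "E"})]


def _gene(gid, chrom, start, end=None):
    return GeneModel(gene_id=gid, chromosome=chrom, strand="+",
                     start=start, end=end or start + 2000)


def test_classify_tandem_cluster():
    a = _gene("g1", "A09", 100_000)
    b = _gene("g2", "A09", 140_000)
    chrom = [a, _gene("x1", "A09", 110_000), _gene("x2", "A09", 120_000), b]
    assert classify_pair(a, b, chrom, frozenset({"g1", "g2"})) == "tandem"


def test_classify_segmental_by_distance_and_chromosome():
    a = _gene("g1", "A09", 1_000_000)
    b = _gene("g2", "A09", 6_000_000)
    assert classify_pair(a, b, [a, b], frozenset({"g1", "g2"})) == "segmental"
    c = _gene("g3", "A03", 1_000_000)
    assert classify_pair(a, c, [a], frozenset({"g1", "g3"})) == "segmental"


def test_classify_tandem_intervening_rule():
    a = _gene("g1", "A09", 0)
    b = _gene("g2", "A09", 90_000)
    fillers = [_gene(f"f{i}", "A09", 2_000 + 7_000 * i) for i in range(12)]
    family = frozenset({"g1", "g2"})
    assert classify_pair(a, b, [a, b] + fillers, family) == "segmental"
    # the same cluster with intervening homologues does stay tandem
    family_all = family | {f.gene_id for f in fillers}
    assert classify_pair(a, b, [a, b] + fillers, family_all) == "tandem"


def test_codon_align_threads_cds_through_protein_alignment():
    cds_a = CdsRecord(id="a", sequence="ATGGCTTGCGATGAA" + "TTT" * 95)
    cds_b = CdsRecord(id="b", sequence="ATGTGCGATGAA" + "TTT" * 95)  # Ala codon deleted
    prot_a = ProteinRecord(id="a", sequence="MACDE" + "F" * 95)
    prot_b = ProteinRecord(id="b", sequence="MCDE" + "F" * 95)
    row_a, row_b = codon_align(cds_a, cds_b, prot_a, prot_b)
    assert len(row_a) == len(row_b)
    assert row_b.count("-") == 3 and row_a.count("-") == 0
    r = ng86(row_a, row_b)
    assert r.codons_compared == 99  # gap codon excluded
    assert r.Nd == 0 and r.Sd == 0
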