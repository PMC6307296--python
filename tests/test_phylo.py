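"""p-distance, neighbor joining, and subfamily assignment.

NJ is checked two ways: exact recovery of additive matrices from random
trees, and agreement of patristic distances with scikit-bio's independent
NJ implementation.
"""

import itertools

import networkx as nx
import numpy as np
import pytest

from ccch_survey.phylo import (
    DistanceMatrix,
    SubfamilyAssignment,
    alignment_p_distance,
    assign_subfamilies,
    nj_tree,
    p_distance,
)
from ccch_survey.records import ProteinRecord
from ccch_survey.synthetic import gen_reference_set, mutate_protein


def random_additive_matrix(n: int, rng: np.random.Generator) -> np.ndarray:
    """Distances on a random binary tree with positive branch lengths."""
    graph = nx.Graph()
    pool = list(range(n))
    nxt = n
    while len(pool) > 1:
        i = pool.pop(int(rng.integers(len(pool))))
        j = pool.pop(int(rng.integers(len(pool))))
        graph.add_edge(i, nxt, weight=float(rng.uniform(0.05, 1.0)))
        graph.add_edge(j, nxt, weight=float(rng.uniform(0.05, 1.0)))
        pool.append(nxt)
        nxt += 1
    lengths = dict(nx.all_pairs_dijkstra_path_length(graph))
    d = np.zeros((n, n))
    for a in range(n):
        for b in range(n):
            if a != b:
                d[a, b] = lengths[a][b]
    return (d + d.T) / 2  # remove float asymmetry from path summation


def test_p_distance_examples():
    assert p_distance("MKWH", "MKWH") == 0.0
    assert p_distance("AAAA", "AAAT") == 0.25
    assert p_distance("A-AA", "AAAA") == 0.0  # gap column excluded
    with pytest.raises(ValueError):
        p_distance("AA", "AAA")
    with pytest.raises(ValueError):
        p_distance("--", "AA")


def test_p_distance_bounded(rng):
    for _ in range(50):
        n = int(rng.integers(1, 60))
        a = "".join(rng.choice(list("ACDEF-"), size=n))
        b = "".join(rng.choice(list("ACDEF-"), size=n))
        try:
            d = p_distance(a, b)
        except ValueError:
            continue
        assert 0.0 <= d <= 1.0


def test_nj_two_taxa_split_equally():
    tree = nj_tree(DistanceMatrix(["a", "b"], np.array([[0, 0.2], [0.2, 0]])))
    assert tree.path_lengths()[("a", "b")] == pytest.approx(0.2)
    leaves = {leaf.name: leaf.length for leaf in tree.leaves()}
    assert leaves == {"a": pytest.approx(0.1), "b": pytest.approx(0.1)}


def test_nj_rejects_bad_input():
    with pytest.raises(ValueError):
        DistanceMatrix(["a", "b"], np.array([[0, 1], [2, 0]]))
    with pytest.raises(ValueError):
        DistanceMatrix(["a", "b"], np.array([[0, -1], [-1, 0]]))
    with pytest.raises(ValueError):
        nj_tree(DistanceMatrix(["a"], np.zeros((1, 1))))


def test_nj_recovers_additive_matrices(rng):
    for _ in range(100):
        n = int(rng.integers(4, 9))
        d = random_additive_matrix(n, rng)
        taxa = [f"t{i}" for i in range(n)]
        tree = nj_tree(DistanceMatrix(taxa, d))
        paths = tree.path_lengths()
        for i, j in itertools.combinations(range(n), 2):
            assert paths[(f"t{i}", f"t{j}")] == pytest.approx(d[i, j], abs=1e-9)


def test_nj_agrees_with_scikit_bio(rng):
    from skbio import DistanceMatrix as SkDM
    from skbio.tree import nj as sknj

    for _ in range(10):
        n = int(rng.integers(4, 8))
        d = random_additive_matrix(n, rng)
        taxa = [f"t{i}" for i in range(n)]
        mine = nj_tree(DistanceMatrix(taxa, d)).path_lengths()
        sk = sknj(SkDM(d, taxa))
        for i, j in itertools.combinations(range(n), 2):
            expected = sk.find(f"t{i}").distance(sk.find(f"t{j}"))
            assert mine[(f"t{i}", f"t{j}")] == pytest.approx(expected, abs=1e-6)


def test_nj_all_zero_matrix_degenerates_gracefully():
    tree = nj_tree(DistanceMatrix(["a", "b", "c", "d"], np.zeros((4, 4))))
    assert all(d == pytest.approx(0.0, abs=1e-12) for d in tree.path_lengths().values())


def test_nj_negative_branch_clamped():
    # classic matrix producing a negative NJ branch estimate
    d = np.array([
        [0.0, 0.1, 0.4, 0.4],
        [0.1, 0.0, 0.4, 0.4],
        [0.4, 0.4, 0.0, 0.05],
        [0.4, 0.4, 0.05, 0.0],
    ])
    tree = nj_tree(DistanceMatrix(list("abcd"), d))
    def lengths(node):
        yield node.length
        for child in node.children:
            yield from lengths(child)
    assert all(v >= 0 for v in lengths(tree.root))


def test_assign_subfamilies_identity_and_ceiling():
    refs, labels = gen_reference_set(["I", "IX"], per_subfamily=2, length=80, seed=3)
    query_same = ProteinRecord(id="q1", sequence=refs[2].sequence)  # first IX ref
    (assignment,) = assign_subfamilies([query_same], refs, labels)
    assert assignment.subfamily == "IX" and assignment.distance == 0.0
    far = ProteinRecord(id="q2", sequence="W" * 80)
    (ungrouped,) = assign_subfamilies([far], refs, labels)
    assert ungrouped.subfamily == "ungrouped"


def test_assign_subfamilies_recovers_mutated_references():
    refs, labels = gen_reference_set(["I", "V", "IX"], per_subfamily=3, length=150, seed=11)
    queries = [
        mutate_protein(ref, fraction=0.10, seed=100 + i, new_id=f"q{i}")
        for i, ref in enumerate(refs)
    ]
    assignments = assign_subfamilies(queries, refs, labels)
    for ref, assignment in zip(refs, assignments):
        assert assignment.subfamily == labels[ref.id]


def test_assign_subfamilies_order_invariant():
    refs, labels = gen_reference_set(["I", "II"], per_subfamily=2, length=100, seed=5)
    queries = [mutate_protein(refs[i], 0.05, seed=i, new_id=f"q{i}") for i in range(4)]
    forward = assign_subfamilies(queries, refs, labels)
    backward = assign_subfamilies(list(reversed(queries)), refs, labels)
    assert {a.protein_id: a.subfamily for a in forward} == \
           {a.protein_id: a.subfamily for a in backward}


def test_assign_subfamilies_requires_references():
    with pytest.raises(ValueError):
        assign_subfamilies([ProteinRecord(id="q", sequence="MK")], [], {})
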