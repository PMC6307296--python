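"""Distance-based phylogenetics: p-distances, neighbor joining, subfamilies.

Classification is nearest-reference by pairwise-alignment p-distance against
a labeled reference panel (the Arabidopsis subfamily system in real use),
with an "ungrouped" ceiling for queries too far from every reference. The
NJ implementation follows Saitou & Nei's Q-criterion agglomeration with
deterministic tie-breaking so trees are reproducible.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .duplication import _protein_aligner, aligned_rows
from .records import ProteinRecord


def p_distance(seq_a: str, seq_b: str) -> float:
    """Proportion of differing residues over compared columns.

    Inputs are aligned rows of equal length; columns where either row has a
    gap are excluded (complete deletion across the pair).
    """
    if len(seq_a) != len(seq_b):
        raise ValueError(f"aligned rows differ in length ({len(seq_a)} vs {len(seq_b)})")
    compared = mismatches = 0
    for x, y in zip(seq_a, seq_b):
        if x == "-" or y == "-":
            continue
        compared += 1
        if x != y:
            mismatches += 1
    if compared == 0:
        raise ValueError("no comparable columns (all-gap overlap)")
    return mismatches / compared


@dataclass
class DistanceMatrix:
    """A symmetric pairwise distance matrix over an ordered taxon list."""

    taxa: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.taxa)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match taxon count")
        if (self.d < 0).any():
            raise ValueError("distances must be non-negative")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.d), 0, atol=1e-12):
            raise ValueError("diagonal must be zero")


@dataclass
class TreeNode:
    """Node of an (un)rooted tree; ``length`` is the edge to the parent."""

    name: Optional[str] = None
    length: float = 0.0
    children: list["TreeNode"] = field(default_factory=list)

    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class PhyloTree:
    """An unrooted tree stored with an arbitrary internal root for traversal."""

    root: TreeNode

    def leaves(self) -> list[TreeNode]:
        out: list[TreeNode] = []

        def walk(node: TreeNode) -> None:
            if node.is_leaf():
                out.append(node)
            for child in node.children:
                walk(child)

        walk(self.root)
        return out

    def leaf_names(self) -> list[str]:
        return [leaf.name or "" for leaf in self.leaves()]

    def path_lengths(self) -> dict[tuple[str, str], float]:
        """Patristic distance between every pair of leaves."""
        # distances from root to every node, then LCA via recorded parents
        parent: dict[int, TreeNode] = {}
        depth: dict[int, float] = {id(self.root): 0.0}
        order: list[TreeNode] = []

        def walk(node: TreeNode) -> None:
            order.append(node)
            for child in node.children:
                parent[id(child)] = node
                depth[id(child)] = depth[id(node)] + child.length
                walk(child)

        walk(self.root)
        leaves = [n for n in order if n.is_leaf()]
        out: dict[tuple[str, str], float] = {}
        for u, v in itertools.combinations(leaves, 2):
            ancestors = {}
            node: Optional[TreeNode] = u
            while node is not None:
                ancestors[id(node)] = node
                node = parent.get(id(node))
            node = v
            while id(node) not in ancestors:
                node = parent[id(node)]
            lca = node
            dist = depth[id(u)] + depth[id(v)] - 2 * depth[id(lca)]
            key = tuple(sorted((u.name or "", v.name or "")))
            out[key] = dist
        return out

    def newick(self) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_leaf():
                return f"{node.name}:{node.length:.10g}"
            inner = ",".join(fmt(c) for c in node.children)
            return f"({inner}):{node.length:.10g}"

        inner = ",".join(fmt(c) for c in self.root.children)
        return f"({inner});"


def nj_tree(matrix: DistanceMatrix) -> PhyloTree:
    """Neighbor joining (Saitou-Nei) with deterministic tie-breaking.

    At each step the pair minimizing Q(i,j) = (n-2)·d(i,j) − r(i) − r(j) is
    joined; ties go to the smallest (i,j) index pair in the current node
    ordering. Negative branch-length estimates are clamped to zero with the
    deficit transferred to the sibling edge. Two taxa yield a single edge
    split equally.
    """
    n = len(matrix.taxa)
    if n < 2:
        raise ValueError("need at least 2 taxa")
    nodes: list[TreeNode] = [TreeNode(name=t) for t in matrix.taxa]
    d = matrix.d.astype(float).copy()

    while len(nodes) > 2:
        m = len(nodes)
        r = d.sum(axis=1)
        best = None
        best_q = np.inf
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * d[i, j] - r[i] - r[j]
                if q < best_q - 1e-15:
                    best_q = q
                    best = (i, j)
        i, j = best  # type: ignore[misc]
        vi = 0.5 * d[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        vj = d[i, j] - vi
        # clamp negatives, moving the deficit to the sibling edge
        if vi < 0:
            vj += vi
            vi = 0.0
        if vj < 0:
            vi += vj
            vj = 0.0
        vj = max(vj, 0.0)
        ni, nj_ = nodes[i], nodes[j]
        ni.length, nj_.length = vi, vj
        new = TreeNode(children=[ni, nj_])
        new_d = np.empty(m - 2)
        keep = [k for k in range(m) if k not in (i, j)]
        for idx, k in enumerate(keep):
            new_d[idx] = 0.5 * (d[i, k] + d[j, k] - d[i, j])
        d = d[np.ix_(keep, keep)]
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, :-1] = np.maximum(new_d, 0.0)
        d[:-1, -1] = d[-1, :-1]
        nodes = [nodes[k] for k in keep] + [new]

    a, b = nodes
    if a.is_leaf() and b.is_leaf():
        # two-taxon tree: one edge split equally across a formal root
        half = d[0, 1] / 2
        a.length = half
        b.length = half
        return PhyloTree(root=TreeNode(children=[a, b]))
    # attach the remaining edge between the two subtrees
    if b.is_leaf():
        a, b = b, a
    a.length += d[0, 1]
    b.children.append(a)
    b.length = 0.0
    return PhyloTree(root=b)


# ---------------------------------------------------------------------------
# Subfamily assignment


@dataclass(frozen=True)
class SubfamilyAssignment:
    protein_id: str
    subfamily: str
    nearest_reference: Optional[str]
    distance: float


def alignment_p_distance(query: ProteinRecord, reference: ProteinRecord) -> float:
    """p-distance over the pairwise global alignment of two proteins."""
    row_q, row_r = aligned_rows(_protein_aligner(), query.sequence, reference.sequence)
    return p_distance(row_q, row_r)


def assign_subfamilies(
    queries: Sequence[ProteinRecord],
    references: Sequence[ProteinRecord],
    reference_labels: dict[str, str],
    ungrouped_ceiling: float = 0.7,
) -> list[SubfamilyAssignment]:
    """Label each query with its nearest reference's subfamily.

    Distances are p-distances over pairwise global alignments. Queries whose
    nearest reference exceeds ``ungrouped_ceiling`` are labeled
    ``ungrouped``, mirroring the proteins a tree-based analysis would leave
    unassorted. Output order follows the query order; the result is
    invariant to it otherwise (ties go to the first reference in panel
    order).
    """
    if not references:
        raise ValueError("empty reference set")
    missing = [r.id for r in references if r.id not in reference_labels]
    if missing:
        raise ValueError(f"references without subfamily labels: {missing}")
    out: list[SubfamilyAssignment] = []
    for query in queries:
        best_ref: Optional[str] = None
        best_d = np.inf
        for ref in references:
            dist = alignment_p_distance(query, ref)
            if dist < best_d - 1e-15:
                best_d = dist
                best_ref = ref.id
        if best_d > ungrouped_ceiling:
            out.append(SubfamilyAssignment(query.id, "ungrouped", best_ref, float(best_d)))
        else:
            out.append(
                SubfamilyAssignment(query.id, reference_labels[best_ref], best_ref, float(best_d))
            )
    return out
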