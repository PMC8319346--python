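"""Pairwise OSA gene-content comparison and single-linkage clustering.

Strains are compared by the Jaccard distance between the orthogroup
sets of their O-specific antigen clusters: 1 minus the number of
orthogroups present in both strains' OSA clusters divided by the number
present in either. The resulting distance matrix is clustered by
single-linkage agglomeration, so strains with identical OSA content
merge at height 0 and clades correspond to low cut heights.

The agglomeration here is the textbook O(n^3) procedure with an
explicit deterministic tie-break — among equal-distance merges the pair
containing the least original leaf index wins — so trees are exactly
reproducible across runs and platforms. Panels in this domain are a few
hundred strains at most, where the cubic cost is negligible.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "jaccard_distance",
    "distance_matrix",
    "DendroNode",
    "Dendrogram",
    "single_linkage",
    "cut_clusters",
]


def jaccard_distance(set_a: set, set_b: set) -> float:
    """1 - |A∩B| / |A∪B|; two empty sets are indistinguishable (0, with
    a warning), a single empty set is maximally distant (1)."""
    if not set_a and not set_b:
        warnings.warn("Jaccard distance of two empty sets defined as 0", stacklevel=2)
        return 0.0
    union = len(set_a | set_b)
    return 1.0 - len(set_a & set_b) / union


def distance_matrix(sets: dict[str, set]) -> pd.DataFrame:
    """Symmetric strain x strain Jaccard distance matrix, zero diagonal."""
    strains = list(sets)
    n = len(strains)
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        d[i, j] = d[j, i] = jaccard_distance(sets[strains[i]], sets[strains[j]])
    return pd.DataFrame(d, index=strains, columns=strains)


@dataclass
class DendroNode:
    """Node of a merge tree; leaves have height 0 and carry a label."""

    height: float
    label: str | None = None
    children: tuple["DendroNode", "DendroNode"] | None = None

    @property
    def is_leaf(self) -> bool:
        return self.children is None

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.label]
        return self.children[0].leaves() + self.children[1].leaves()


@dataclass
class Dendrogram:
    """Single-linkage merge tree over strains.

    ``merges`` lists (height, members_a, members_b) in merge order;
    heights are non-decreasing (single linkage is monotone, so the tree
    is ultrametric). Leaf order is deterministic: children ordered by
    their least original leaf index.
    """

    root: DendroNode
    labels: list[str]
    merges: list[tuple[float, frozenset, frozenset]] = field(default_factory=list)

    @property
    def heights(self) -> list[float]:
        return [h for h, _, _ in self.merges]

    def leaf_order(self) -> list[str]:
        return self.root.leaves()

    def to_newick(self) -> str:
        """Newick string; branch length = parent height - child height."""

        def render(node: DendroNode, parent_height: float) -> str:
            bl = parent_height - node.height
            if node.is_leaf:
                return f"{node.label}:{bl:.10g}"
            inner = ",".join(render(c, node.height) for c in node.children)
            return f"({inner}):{bl:.10g}"

        if self.root.is_leaf:
            return f"{self.root.label}:0;"
        inner = ",".join(render(c, self.root.height) for c in self.root.children)
        return f"({inner});"

    @classmethod
    def from_newick(cls, text: str) -> "Dendrogram":
        """Parse an ultrametric newick tree back into a merge tree."""
        import dendropy

        tree = dendropy.Tree.get(data=text, schema="newick")

        def build(node) -> DendroNode:
            if node.is_leaf():
                return DendroNode(height=0.0, label=node.taxon.label.replace(" ", "_"))
            kids = [build(c) for c in node.child_nodes()]
            heights = [
                k.height + (c.edge.length or 0.0)
                for k, c in zip(kids, node.child_nodes())
            ]
            h = max(heights)
            # fold multifurcations left-to-right at the same height
            cur = kids[0]
            for k in kids[1:]:
                cur = DendroNode(height=h, children=(cur, k))
            return cur

        root = build(tree.seed_node)
        merges: list[tuple[float, frozenset, frozenset]] = []

        def collect(node: DendroNode) -> frozenset:
            if node.is_leaf:
                return frozenset([node.label])
            a = collect(node.children[0])
            b = collect(node.children[1])
            merges.append((node.height, a, b))
            return a | b

        collect(root)
        merges.sort(key=lambda m: m[0])
        return cls(root=root, labels=sorted(root.leaves()), merges=merges)


def single_linkage(dist: pd.DataFrame) -> Dendrogram:
    """Agglomerative single-linkage clustering of a distance matrix.

    Validates symmetry (to 1e-9) and a zero diagonal. Tie-break: among
    pairs at the minimal inter-cluster distance, the pair whose least
    original member index is smallest wins (then the least index of the
    other cluster).
    """
    d = dist.to_numpy(dtype=float)
    labels = [str(x) for x in dist.index]
    n = len(labels)
    if d.shape != (n, n) or list(dist.columns.astype(str)) != labels:
        raise ValueError("distance matrix must be square with matching row/column labels")
    if np.abs(d - d.T).max(initial=0.0) > 1e-9:
        raise ValueError("distance matrix asymmetric beyond 1e-9")
    if np.abs(np.diag(d)).max(initial=0.0) > 0:
        raise ValueError("distance matrix diagonal must be zero")

    if n == 1:
        return Dendrogram(root=DendroNode(0.0, label=labels[0]), labels=labels)

    nodes: dict[int, DendroNode] = {i: DendroNode(0.0, label=labels[i]) for i in range(n)}
    members: dict[int, list[int]] = {i: [i] for i in range(n)}  # sorted original indices
    # inter-cluster single-linkage distances, keyed by cluster id (= least member)
    cd: dict[tuple[int, int], float] = {
        (i, j): d[i, j] for i, j in itertools.combinations(range(n), 2)
    }
    merges: list[tuple[float, frozenset, frozenset]] = []

    while len(members) > 1:
        # minimal distance, tie-broken by (least member of pair, least member of other)
        (a, b), h = min(cd.items(), key=lambda kv: (kv[1], min(kv[0]), max(kv[0])))
        a, b = min(a, b), max(a, b)
        merges.append((h, frozenset(labels[i] for i in members[a]), frozenset(labels[i] for i in members[b])))
        nodes[a] = DendroNode(height=h, children=(nodes[a], nodes[b]))
        members[a] = sorted(members[a] + members[b])
        del nodes[b], members[b]
        # update distances: single linkage = min
        for c in list(members):
            if c == a:
                continue
            key_ac = (min(a, c), max(a, c))
            key_bc = (min(b, c), max(b, c))
            d_ac = cd.get(key_ac, np.inf)
            d_bc = cd.pop(key_bc, np.inf)
            cd[key_ac] = min(d_ac, d_bc)
        cd = {k: v for k, v in cd.items() if b not in k}

    root = nodes[min(nodes)]
    return Dendrogram(root=root, labels=labels, merges=merges)


def cut_clusters(dendrogram: Dendrogram, height: float) -> dict[str, int]:
    """Partition strains by cutting the tree at ``height``.

    Two strains share a cluster iff they are joined by merges at height
    <= ``height`` (so ``height=0`` groups exactly the identical-set
    strains). Cluster ids are 0..k-1 in order of each cluster's first
    strain in ``labels`` order.
    """
    if height < 0:
        raise ValueError("cut height must be >= 0")
    parent = {s: s for s in dendrogram.labels}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for h, a, b in dendrogram.merges:
        if h <= height:
            ra, rb = find(next(iter(a))), find(next(iter(b)))
            # union the full member sets, not just representatives
            for s in a | b:
                parent[find(s)] = ra
    roots: dict[str, int] = {}
    out: dict[str, int] = {}
    for s in dendrogram.labels:
        r = find(s)
        if r not in roots:
            roots[r] = len(roots)
        out[s] = roots[r]
    return out
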