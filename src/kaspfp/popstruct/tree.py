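"""Neighbor-joining trees with bootstrap support.

Saitou & Nei's agglomeration with the standard Q-criterion:

    Q(i, j) = (r - 2) d(i, j) - R_i - R_j,   R_i = sum_k d(i, k)

at each step the pair minimising Q is joined; branch lengths to the new node
follow the usual rate-corrected split, and the final three nodes are joined
at an unrooted trifurcation. NJ recovers the generating tree exactly on
additive distance matrices. Ties in Q are broken deterministically by the
label-sorted pair. Negative branch-length estimates (possible on
non-additive input) are clamped to zero and flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..errors import ArityError
from ..genotypes import GenotypeMatrix
from .distance import DistanceMatrix, allele_sharing_distance


@dataclass
class TreeNode:
    """Node of an (un)rooted tree; leaves carry a name."""

    name: str | None = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)
    support: float | None = None  # bootstrap % for the edge above this node

    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf():
            return [self.name]
        out = []
        for c, _ in self.children:
            out.extend(c.leaves())
        return out


@dataclass
class PhyloTree:
    """Unrooted tree over accession labels (root is a trifurcation)."""

    root: TreeNode
    labels: list[str]
    clamped_branches: int = 0  # negative NJ estimates clamped to 0
    supports: dict = field(default_factory=dict)  # bipartition -> bootstrap %

    def to_newick(self, with_support: bool = True) -> str:
        return _newick(self.root, with_support) + ";"

    def bipartitions(self) -> set[frozenset]:
        """Non-trivial bipartitions, each as the frozenset of the smaller side."""
        full = frozenset(self.labels)
        out: set[frozenset] = set()

        def walk(node: TreeNode) -> frozenset:
            if node.is_leaf():
                return frozenset([node.name])
            below = frozenset()
            for c, _ in node.children:
                below |= walk(c)
            if node is not self.root and 1 < len(below) < len(self.labels) - 1:
                side = below if len(below) <= len(full - below) else full - below
                # at even splits pick the lexicographically smaller side
                if 2 * len(side) == len(full) and min(side) > min(full - side):
                    side = full - side
                out.add(side)
            return below

        walk(self.root)
        return out

    def annotate_support(self, support: dict[frozenset, float]) -> None:
        full = frozenset(self.labels)

        def walk(node: TreeNode) -> frozenset:
            if node.is_leaf():
                return frozenset([node.name])
            below = frozenset()
            for c, _ in node.children:
                below |= walk(c)
            if node is not self.root and 1 < len(below) < len(self.labels) - 1:
                side = below if len(below) <= len(full - below) else full - below
                if 2 * len(side) == len(full) and min(side) > min(full - side):
                    side = full - side
                node.support = support.get(side)
            return below

        walk(self.root)


def _newick(node: TreeNode, with_support: bool) -> str:
    if node.is_leaf():
        return node.name
    parts = []
    for child, bl in node.children:
        s = _newick(child, with_support)
        if with_support and not child.is_leaf() and child.support is not None:
            s += f"{child.support:g}"
        parts.append(f"{s}:{bl:.6f}")
    return "(" + ",".join(parts) + ")"


def nj_tree(dist: DistanceMatrix) -> PhyloTree:
    """Build the neighbor-joining tree from a complete distance matrix."""
    undefined = dist.undefined_pairs()
    if undefined:
        raise ValueError(f"undefined distances for pairs: {undefined}")
    n = dist.n
    if n < 3:
        raise ArityError("neighbor joining needs at least three taxa")
    d = dist.d.astype(float).copy()
    nodes: list[TreeNode] = [TreeNode(name=l) for l in dist.labels]
    # sort key per active node: smallest leaf label underneath, for tie-breaks
    keys: list[str] = list(dist.labels)
    active = list(range(n))
    clamped = 0

    while len(active) > 3:
        r = len(active)
        sub = d[np.ix_(active, active)]
        R = sub.sum(axis=1)
        best = None
        for ai in range(r):
            for aj in range(ai + 1, r):
                q = (r - 2) * sub[ai, aj] - R[ai] - R[aj]
                pair_key = tuple(sorted((keys[active[ai]], keys[active[aj]])))
                cand = (q, pair_key, ai, aj)
                if best is None or cand[:2] < best[:2]:
                    best = cand
        _, _, ai, aj = best
        i, j = active[ai], active[aj]
        dij = d[i, j]
        li = 0.5 * dij + (R[ai] - R[aj]) / (2 * (r - 2))
        lj = dij - li
        if li < 0:
            li, lj, clamped = 0.0, dij, clamped + 1
        elif lj < 0:
            lj, li, clamped = 0.0, dij, clamped + 1
        parent = TreeNode(children=[(nodes[i], li), (nodes[j], lj)])
        # distances from the new node to every other active node
        new_row = np.zeros(d.shape[0] + 1)
        for ak in range(r):
            k = active[ak]
            if k in (i, j):
                continue
            new_row[k] = 0.5 * (d[i, k] + d[j, k] - dij)
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, :-1] = new_row[:-1]
        d[:-1, -1] = new_row[:-1]
        nodes.append(parent)
        keys.append(min(keys[i], keys[j]))
        active = [a for a in active if a not in (i, j)] + [len(nodes) - 1]

    # join the last three at an unrooted trifurcation
    i, j, k = active
    a = 0.5 * (d[i, j] + d[i, k] - d[j, k])
    b = 0.5 * (d[i, j] + d[j, k] - d[i, k])
    c = 0.5 * (d[i, k] + d[j, k] - d[i, j])
    lengths = []
    for x in (a, b, c):
        if x < 0:
            clamped += 1
            x = 0.0
        lengths.append(x)
    root = TreeNode(
        children=[(nodes[i], lengths[0]), (nodes[j], lengths[1]), (nodes[k], lengths[2])]
    )
    return PhyloTree(root=root, labels=list(dist.labels), clamped_branches=clamped)


def bootstrap_support(
    gm: GenotypeMatrix,
    B: int = 1000,
    seed: int | None = None,
    distance=allele_sharing_distance,
) -> PhyloTree:
    """Point-estimate NJ tree with bootstrap support percentages.

    Loci are resampled with replacement B times; each replicate matrix is
    re-distanced and re-joined, and the support of an internal edge of the
    point tree is the percentage of replicate trees containing the same
    bipartition.
    """
    if B < 1:
        raise ArityError("B must be >= 1")
    if len(gm.accessions) < 4:
        raise ArityError("bootstrap support needs at least four accessions")
    rng = np.random.default_rng(seed)
    point = nj_tree(distance(gm))
    target = point.bipartitions()
    hits = {bp: 0 for bp in target}
    markers = gm.markers
    L = len(markers)
    for _ in range(B):
        cols = [markers[t] for t in rng.integers(L, size=L)]
        rep = GenotypeMatrix(
            gm.df[cols].set_axis([f"b{t}" for t in range(L)], axis=1)
        )
        try:
            rep_tree = nj_tree(distance(rep))
        except ValueError:  # replicate with an undefined pair: counts as a miss
            continue
        found = rep_tree.bipartitions()
        for bp in target:
            if bp in found:
                hits[bp] += 1
    support = {bp: 100.0 * h / B for bp, h in hits.items()}
    point.annotate_support(support)
    point.supports = support
    return point
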