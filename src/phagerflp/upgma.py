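"""UPGMA clustering of band-profile distances and Newick serialization.

UPGMA (unweighted pair-group method with arithmetic mean) repeatedly merges
the closest pair of clusters; the distance from a merged cluster AB to any
other cluster C is the size-weighted mean

    d(AB, C) = (|A|·d(A, C) + |B|·d(B, C)) / (|A| + |B|),

i.e. the plain average over all leaf pairs.  Each merge creates a node at
height d_min / 2, so the result is a rooted ultrametric dendrogram: every
root-to-leaf path has the same length.  Ties between equally close pairs
are broken on the lexicographically smallest pair of cluster labels, making
the output deterministic across platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fingerprint import DistanceMatrix

__all__ = ["Node", "Dendrogram", "upgma", "cophenetic", "to_newick", "render_ascii"]

_NEWICK_META = set("(),:;'\"[] \t\n")


@dataclass
class Node:
    """A dendrogram node; leaves carry a name and height 0."""

    height: float
    name: str | None = None
    children: list["Node"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.name]  # type: ignore[list-item]
        return [x for c in self.children for x in c.leaves()]

    def min_label(self) -> str:
        return min(self.leaves())


@dataclass(frozen=True)
class Dendrogram:
    """Rooted ultrametric tree; branch length = parent height − child height."""

    root: Node

    @property
    def labels(self) -> list[str]:
        return self.root.leaves()

    @property
    def height(self) -> float:
        return self.root.height


def upgma(dm: DistanceMatrix) -> Dendrogram:
    """Classic (size-weighted average) UPGMA on a distance matrix."""
    n = len(dm.labels)
    if n < 2:
        raise ValueError("need at least 2 taxa")
    D = np.asarray(dm.D, dtype=float)
    if np.any(D < 0):
        raise ValueError("distances must be non-negative")
    if not np.allclose(D, D.T):
        raise ValueError("distance matrix must be symmetric")

    nodes = {i: Node(0.0, name=lab) for i, lab in enumerate(dm.labels)}
    sizes = {i: 1 for i in nodes}
    dist = {
        (i, j): float(D[i, j]) for i in range(n) for j in range(i + 1, n)
    }
    next_id = n

    def pair_key(i: int, j: int) -> tuple[str, str]:
        return tuple(sorted((nodes[i].min_label(), nodes[j].min_label())))  # type: ignore[return-value]

    while len(nodes) > 1:
        (i, j) = min(dist, key=lambda ij: (dist[ij], pair_key(*ij)))
        d_min = dist[(i, j)]
        a, b = nodes.pop(i), nodes.pop(j)
        children = sorted((a, b), key=Node.min_label)
        merged = Node(height=d_min / 2.0, children=children)
        sa, sb = sizes.pop(i), sizes.pop(j)

        new_dist = {}
        for k in nodes:
            dik = dist[tuple(sorted((i, k)))]
            djk = dist[tuple(sorted((j, k)))]
            new_dist[(k, next_id)] = (sa * dik + sb * djk) / (sa + sb)
        dist = {
            ij: v for ij, v in dist.items() if i not in ij and j not in ij
        }
        dist.update(new_dist)
        nodes[next_id] = merged
        sizes[next_id] = sa + sb
        next_id += 1

    return Dendrogram(root=next(iter(nodes.values())))


def cophenetic(tree: Dendrogram) -> DistanceMatrix:
    """Cophenetic distances: (i, j) ↦ 2 × height of their lowest common
    ancestor.  For an ultrametric input matrix, ``cophenetic(upgma(D))``
    reproduces D exactly."""
    labels = sorted(tree.labels)
    index = {lab: k for k, lab in enumerate(labels)}
    n = len(labels)
    D = np.zeros((n, n))

    def visit(node: Node) -> list[str]:
        if node.is_leaf:
            return [node.name]  # type: ignore[list-item]
        groups = [visit(c) for c in node.children]
        for gi in range(len(groups)):
            for gj in range(gi + 1, len(groups)):
                for u in groups[gi]:
                    for v in groups[gj]:
                        a, b = index[u], index[v]
                        D[a, b] = D[b, a] = 2.0 * node.height
        return [x for g in groups for x in g]

    visit(tree.root)
    return DistanceMatrix(labels=tuple(labels), D=D, unit_interval=False)


def _format_label(label: str) -> str:
    if set(label) & _NEWICK_META:
        return "'" + label.replace("'", "''") + "'"
    return label


def to_newick(tree: Dendrogram, decimals: int = 6) -> str:
    """Serialize with branch lengths; children ordered by smallest leaf label."""

    def fmt(node: Node, parent_height: float) -> str:
        bl = f"{parent_height - node.height:.{decimals}f}"
        if node.is_leaf:
            return f"{_format_label(node.name)}:{bl}"  # type: ignore[arg-type]
        inner = ",".join(
            fmt(c, node.height)
            for c in sorted(node.children, key=Node.min_label)
        )
        return f"({inner}):{bl}"

    root = tree.root
    inner = ",".join(
        fmt(c, root.height) for c in sorted(root.children, key=Node.min_label)
    )
    return f"({inner});"


def render_ascii(tree: Dendrogram, width: int = 60) -> str:
    """Crude text dendrogram for run logs."""
    lines: list[str] = []
    scale = (width - 2) / tree.height if tree.height > 0 else 0.0

    def visit(node: Node, prefix: str, is_last: bool) -> None:
        depth = int(round((tree.height - node.height) * scale))
        joint = "`-" if is_last else "|-"
        label = node.name if node.is_leaf else f"[h={node.height:.4f}]"
        lines.append(prefix + joint + "-" * max(0, depth // 4) + " " + str(label))
        kids = sorted(node.children, key=Node.min_label)
        for k, child in enumerate(kids):
            visit(child, prefix + ("  " if is_last else "| "), k == len(kids) - 1)

    visit(tree.root, "", True)
    return "\n".join(lines)
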