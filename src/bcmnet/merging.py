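"""Agglomerative merging of BiNets into macro bipartite networks.

BiNets mined from the same underlying co-expression structure overlap
heavily; merging summarizes them into a small number of macro networks.
The scheme is best-first agglomerative: start with one macro network per
BiNet, repeatedly merge the pair whose merged density (density of the
union vertex sets, recomputed exactly against the graph) is maximal, and
form macro networks from the merges whose density reaches the threshold
(default 0.3).  Merging continues past the threshold only to complete the
dendrogram.  Every macro network containing two or more BiNets therefore
has recomputed density at least the threshold — the guarantee this
adaptation preserves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .graph import WeightedBipartiteGraph
from .mining import BiNet, density

__all__ = [
    "MacroNetwork",
    "DendrogramNode",
    "merged_density",
    "merge_to_macro",
    "dendrogram_to_newick",
]


@dataclass
class MacroNetwork:
    """A cluster of BiNets with union vertex sets and recomputed density."""

    member_binet_ids: list[int]
    x_union: set[str]
    y_union: set[str]
    density: float

    @property
    def n_members(self) -> int:
        return len(self.member_binet_ids)


@dataclass
class DendrogramNode:
    """Binary merge-tree node; leaves carry a BiNet id and no children."""

    binet_id: int | None = None
    left: "DendrogramNode | None" = None
    right: "DendrogramNode | None" = None
    merge_density: float | None = None
    height: float = 0.0

    @property
    def is_leaf(self) -> bool:
        return self.binet_id is not None

    def leaves(self) -> list[int]:
        if self.is_leaf:
            return [self.binet_id]
        return self.left.leaves() + self.right.leaves()

    def merge_densities(self) -> list[float]:
        """Merge densities in merge order (post-order, deepest first)."""
        if self.is_leaf:
            return []
        return (
            self.left.merge_densities()
            + self.right.merge_densities()
            + [self.merge_density]
        )


def merged_density(
    a: MacroNetwork, b: MacroNetwork, graph: WeightedBipartiteGraph
) -> float:
    """Density of the union of two macro networks' vertex sets."""
    return density(
        sorted(a.x_union | b.x_union), sorted(a.y_union | b.y_union), graph
    )


def _macro_from_binet(bid: int, binet: BiNet) -> MacroNetwork:
    return MacroNetwork(
        member_binet_ids=[bid],
        x_union=set(binet.x_members),
        y_union=set(binet.y_members),
        density=binet.density,
    )


def merge_to_macro(
    binets: list[BiNet],
    graph: WeightedBipartiteGraph,
    threshold: float = 0.3,
) -> tuple[list[MacroNetwork], DendrogramNode | None]:
    """Best-first agglomerative merge of BiNets.

    Returns the macro-network partition obtained by merging while the best
    merged density is >= ``threshold`` (ties broken by the smallest id
    pair), together with the complete dendrogram (merging continued
    without the threshold until a single root remains).  The partition is
    a partition of BiNet ids; gene sets may still overlap across macro
    networks because BiNets share vertices.
    """
    if not (0 < threshold <= 1):
        raise ValueError("threshold must be in (0, 1]")
    if not binets:
        return [], None

    clusters: dict[int, MacroNetwork] = {
        i: _macro_from_binet(i, b) for i, b in enumerate(binets)
    }
    nodes: dict[int, DendrogramNode] = {
        i: DendrogramNode(binet_id=i) for i in clusters
    }
    partition: dict[int, MacroNetwork] | None = None
    next_id = len(binets)

    while len(clusters) > 1:
        ids = sorted(clusters)
        best = None  # (density, id_a, id_b)
        for ai in range(len(ids)):
            for bi in range(ai + 1, len(ids)):
                d = merged_density(clusters[ids[ai]], clusters[ids[bi]], graph)
                if best is None or d > best[0]:
                    best = (d, ids[ai], ids[bi])
        d, ia, ib = best
        if partition is None and d < threshold:
            # threshold crossed: freeze the macro-network partition,
            # keep merging for the dendrogram only
            partition = {k: v for k, v in clusters.items()}
        a, b = clusters.pop(ia), clusters.pop(ib)
        merged = MacroNetwork(
            member_binet_ids=sorted(a.member_binet_ids + b.member_binet_ids),
            x_union=a.x_union | b.x_union,
            y_union=a.y_union | b.y_union,
            density=d,
        )
        node = DendrogramNode(
            left=nodes.pop(ia),
            right=nodes.pop(ib),
            merge_density=d,
            height=1.0 - d,
        )
        clusters[next_id] = merged
        nodes[next_id] = node
        next_id += 1

    if partition is None:  # every merge met the threshold
        partition = clusters
    root = next(iter(nodes.values()))
    macros = sorted(partition.values(), key=lambda m: m.member_binet_ids[0])
    return macros, root


def dendrogram_to_newick(root: DendrogramNode, labels: list[str] | None = None) -> str:
    """Newick serialization with branch length = the child's merge density.

    Leaves use ``labels`` (default ``binet<N>``) and branch length equal to
    their parent's merge density.
    """

    def name(bid: int) -> str:
        return labels[bid] if labels is not None else f"binet{bid}"

    def render(node: DendrogramNode, parent_density: float | None) -> str:
        length = "" if parent_density is None else f":{parent_density:.6g}"
        if node.is_leaf:
            return f"{name(node.binet_id)}{length}"
        left = render(node.left, node.merge_density)
        right = render(node.right, node.merge_density)
        return f"({left},{right}){length}"

    return render(root, None) + ";"
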