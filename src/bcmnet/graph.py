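"""Weighted bipartite graph container for tumor-stroma co-expression networks.

The graph connects genes measured in one tissue compartment (the X side,
conventionally tumor) to genes measured in a second compartment (the Y side,
conventionally stroma).  Edge weights are correlation-derived and live in
(0, 1]; a stored weight of 0 means "no edge", and all density arithmetic
downstream treats absent edges as contributing 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np


@dataclass
class WeightedBipartiteGraph:
    """Dense-matrix representation of a weighted bipartite graph.

    Parameters
    ----------
    x_ids : sequence of str
        Vertex identifiers on the X (tumor) side.
    y_ids : sequence of str
        Vertex identifiers on the Y (stroma) side.
    weights : ndarray of shape (len(x_ids), len(y_ids))
        Edge weights in (0, 1]; entries equal to 0 denote absent edges.
    """

    x_ids: list[str]
    y_ids: list[str]
    weights: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.x_ids = list(self.x_ids)
        self.y_ids = list(self.y_ids)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (len(self.x_ids), len(self.y_ids)):
            raise ValueError(
                f"weight matrix shape {self.weights.shape} does not match "
                f"({len(self.x_ids)}, {len(self.y_ids)}) vertex lists"
            )
        if len(set(self.x_ids)) != len(self.x_ids):
            raise ValueError("duplicate x vertex ids")
        if len(set(self.y_ids)) != len(self.y_ids):
            raise ValueError("duplicate y vertex ids")
        if np.any(~np.isfinite(self.weights)):
            raise ValueError("non-finite edge weights")
        if np.any(self.weights < 0) or np.any(self.weights > 1):
            raise ValueError("edge weights must lie in [0, 1] (0 = absent)")

    @property
    def n_x(self) -> int:
        return len(self.x_ids)

    @property
    def n_y(self) -> int:
        return len(self.y_ids)

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(self.weights))

    def edges(self) -> Iterator[tuple[str, str, float]]:
        """Yield (x_id, y_id, weight) for every present edge."""
        for i, j in zip(*np.nonzero(self.weights)):
            yield self.x_ids[i], self.y_ids[j], float(self.weights[i, j])

    @classmethod
    def from_edges(
        cls,
        x_ids: Sequence[str],
        y_ids: Sequence[str],
        edges: Sequence[tuple[str, str, float]],
    ) -> "WeightedBipartiteGraph":
        """Build from an explicit edge list; duplicate (x, y) pairs rejected."""
        xi = {g: i for i, g in enumerate(x_ids)}
        yi = {g: j for j, g in enumerate(y_ids)}
        w = np.zeros((len(x_ids), len(y_ids)))
        for x, y, wt in edges:
            if x not in xi or y not in yi:
                raise KeyError(f"edge endpoint ({x!r}, {y!r}) not in vertex lists")
            if w[xi[x], yi[y]] != 0:
                raise ValueError(f"duplicate edge ({x!r}, {y!r})")
            if not (0 < wt <= 1):
                raise ValueError(f"edge weight {wt} outside (0, 1]")
            w[xi[x], yi[y]] = wt
        return cls(list(x_ids), list(y_ids), w)

    def to_networkx(self):
        """Export as a networkx.Graph with a ``bipartite`` node attribute.

        Node names are (side, id) tuples so the same gene symbol may appear
        on both tissue sides without collision.
        """
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from((("x", v) for v in self.x_ids), bipartite=0)
        g.add_nodes_from((("y", v) for v in self.y_ids), bipartite=1)
        g.add_weighted_edges_from(
            (("x", x), ("y", y), wt) for x, y, wt in self.edges()
        )
        return g
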