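"""Bipartite Component Mining (BCM) with a provable density guarantee.

BCM grows dense bipartite sub-networks (BiNets) from heavy seed edges of a
weighted bipartite graph.  At each growth step the candidate vertex with the
largest *density contribution* on each side is found; the overall winner is
admitted only if its contribution is at least ``alpha`` times the current
density, where ``alpha`` follows a size-dependent schedule

    alpha(size) = 1 - 1 / (lambda * (size + tau + 1)),
    lambda      = max(1, C / (size + tau + 1)**2).

This schedule guarantees that the final density of every mined BiNet is at
least ``density_bound_F(C, tau)`` times the weight of its seed edge.

Definitions
-----------
density d(B)
    Average weight over all a*b vertex pairs of the BiNet, absent edges
    counting 0:  d(B) = sum(w(e) for induced e) / (a*b).
contribution d(v, B)
    Mean edge weight from a candidate vertex v to the BiNet's opposite-side
    member set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from sklearn.base import BaseEstimator

from .graph import WeightedBipartiteGraph

__all__ = [
    "BCMParams",
    "BiNet",
    "MiningResult",
    "GuaranteeReport",
    "alpha",
    "density",
    "contribution",
    "density_bound_F",
    "bcm_mine",
    "filter_min_distinct_genes",
    "verify_density_guarantee",
    "BCMMiner",
]


@dataclass(frozen=True)
class BCMParams:
    """Parameters of the BCM algorithm.

    C : int
        Bound-tuning constant; must exceed (tau + 2)**2.
    tau : int
        Nonnegative offset in the alpha/lambda schedule.  Larger tau admits
        vertices more easily early on, lowering the density bound.
    beta : float
        Seed threshold in (0, 1]: only edges with weight >= beta * w_max are
        used as seeds.
    min_seed_weight : float, optional
        Absolute floor on seed-edge weight, applied on top of beta * w_max.
    """

    C: int = 36
    tau: int = 2
    beta: float = 0.7
    min_seed_weight: float | None = None

    def __post_init__(self) -> None:
        if self.tau < 0 or int(self.tau) != self.tau:
            raise ValueError("tau must be a nonnegative integer")
        if int(self.C) != self.C or self.C <= (self.tau + 2) ** 2:
            raise ValueError("C must be an integer larger than (tau + 2)**2")
        if not (0 < self.beta <= 1):
            raise ValueError("beta must lie in (0, 1]")
        if self.min_seed_weight is not None and not (0 <= self.min_seed_weight <= 1):
            raise ValueError("min_seed_weight must lie in [0, 1]")


@dataclass
class BiNet:
    """A mined bipartite sub-network.

    growth_trace records, per admitted vertex in order:
    (vertex_id, side, contribution, alpha_used, density_after).
    """

    x_members: list[str]
    y_members: list[str]
    seed_edge: tuple[str, str, float]
    density: float
    growth_trace: list[tuple[str, str, float, float, float]] = field(
        default_factory=list
    )

    @property
    def genes(self) -> set[str]:
        """Union gene set; a symbol present on both sides counts once."""
        return set(self.x_members) | set(self.y_members)

    @property
    def n_distinct_genes(self) -> int:
        return len(self.genes)

    @property
    def size(self) -> tuple[int, int]:
        return len(self.x_members), len(self.y_members)


@dataclass
class MiningResult:
    binets: list[BiNet]
    selected_edge_count: int
    params: BCMParams
    w_max: float

    def __len__(self) -> int:
        return len(self.binets)


def alpha(size: int, C: int, tau: int) -> float:
    """Admission threshold for a side currently holding ``size`` vertices."""
    if size < 1:
        raise ValueError("size must be >= 1")
    m = size + tau + 1
    lam = max(1.0, C / m**2)
    return 1.0 - 1.0 / (lam * m)


def density(
    x_members: Sequence[str],
    y_members: Sequence[str],
    graph: WeightedBipartiteGraph,
) -> float:
    """Average induced edge weight over all |X|*|Y| vertex pairs."""
    if len(x_members) == 0 or len(y_members) == 0:
        raise ValueError("density undefined for an empty side")
    xi = [graph.x_ids.index(v) for v in x_members]
    yi = [graph.y_ids.index(v) for v in y_members]
    return float(graph.weights[np.ix_(xi, yi)].sum() / (len(xi) * len(yi)))


def contribution(
    v: str,
    side: Literal["x", "y"],
    binet: BiNet,
    graph: WeightedBipartiteGraph,
) -> float:
    """Mean edge weight from candidate ``v`` to the opposite member set."""
    if side == "x":
        if v in binet.x_members:
            raise ValueError(f"{v!r} is already an x member")
        i = graph.x_ids.index(v)
        yi = [graph.y_ids.index(u) for u in binet.y_members]
        return float(graph.weights[i, yi].sum() / len(yi))
    elif side == "y":
        if v in binet.y_members:
            raise ValueError(f"{v!r} is already a y member")
        j = graph.y_ids.index(v)
        xi = [graph.x_ids.index(u) for u in binet.x_members]
        return float(graph.weights[xi, j].sum() / len(xi))
    raise ValueError("side must be 'x' or 'y'")


def density_bound_F(C: int, tau: int) -> float:
    """Analytic lower bound on final-density / seed-weight for BCM.

    With s = sqrt(C) and k the number of side sizes i >= 1 satisfying
    (i + tau + 1)**2 < C (the sizes where lambda > 1):

        F = ((2C - tau - 2) / (2C))**(2k) * ((s - tau - 1) / (s - tau))**2

    Every BiNet mined with parameters (C, tau) has density at least F times
    the weight of its seed edge.
    """
    if tau < 0 or C <= (tau + 2) ** 2:
        raise ValueError("requires tau >= 0 and C > (tau + 2)**2")
    s = math.sqrt(C)
    k = 0
    i = 1
    while (i + tau + 1) ** 2 < C:
        k += 1
        i += 1
    head = ((2 * C - tau - 2) / (2 * C)) ** (2 * k)
    tail = ((s - tau - 1) / (s - tau)) ** 2
    return head * tail


def _best_candidate(
    sums: np.ndarray, member_mask: np.ndarray, opp_size: int, ids: list[str]
) -> tuple[int, float]:
    """Index and contribution of the max-contribution non-member vertex.

    Ties broken by smallest vertex id; (-1, -inf) when no candidate remains.
    """
    free = ~member_mask
    if not free.any():
        return -1, -math.inf
    contrib = sums / opp_size
    contrib = np.where(free, contrib, -math.inf)
    best = contrib.max()
    tied = np.nonzero(contrib == best)[0]
    idx = min(tied, key=lambda i: ids[i])
    return int(idx), float(best)


def bcm_mine(graph: WeightedBipartiteGraph, params: BCMParams | None = None) -> MiningResult:
    """Mine all BiNets of a weighted bipartite graph.

    Edges are visited in descending weight order (ties broken
    lexicographically by endpoint ids).  Seeding stops at the first edge
    lighter than ``beta * w_max``; edges already covered by an earlier BiNet
    (the Selected set) are skipped as seeds but vertices may be shared
    across BiNets.  Each BiNet grows by admitting, between the two sides'
    best candidates, the strictly-larger contribution (ties go to the Y
    side); growth stops as soon as the winning candidate fails its alpha
    test, even if the other side's candidate might pass.
    """
    if params is None:
        params = BCMParams()
    W = graph.weights
    n_x, n_y = W.shape
    order = sorted(
        zip(*np.nonzero(W)),
        key=lambda ij: (-W[ij], graph.x_ids[ij[0]], graph.y_ids[ij[1]]),
    )
    if not order:
        return MiningResult([], 0, params, 0.0)
    w_max = float(W[order[0]])
    threshold = params.beta * w_max
    if params.min_seed_weight is not None:
        threshold = max(threshold, params.min_seed_weight)

    selected: set[tuple[int, int]] = set()
    binets: list[BiNet] = []
    for i0, j0 in order:
        w_seed = float(W[i0, j0])
        if w_seed < threshold:
            break
        if (i0, j0) in selected:
            continue
        selected.add((i0, j0))

        x_mask = np.zeros(n_x, dtype=bool)
        y_mask = np.zeros(n_y, dtype=bool)
        x_mask[i0] = True
        y_mask[j0] = True
        x_order = [i0]
        y_order = [j0]
        # sums_x[p] = total weight from x-vertex p into current Y members
        sums_x = W[:, j0].copy()
        sums_y = W[i0, :].copy()
        total_w = w_seed
        trace: list[tuple[str, str, float, float, float]] = []

        while True:
            a, b = len(x_order), len(y_order)
            d = total_w / (a * b)
            p, cx = _best_candidate(sums_x, x_mask, b, graph.x_ids)
            q, cy = _best_candidate(sums_y, y_mask, a, graph.y_ids)
            if cx > cy:
                a_thr = alpha(a, params.C, params.tau)
                if cx >= a_thr * d:
                    x_mask[p] = True
                    x_order.append(p)
                    total_w += sums_x[p]
                    sums_y += W[p, :]
                    for j in np.nonzero(y_mask)[0]:
                        if W[p, j] > 0:
                            selected.add((p, int(j)))
                    trace.append(
                        (graph.x_ids[p], "x", cx, a_thr, float(total_w / ((a + 1) * b)))
                    )
                else:
                    break
            else:
                if q < 0:
                    break
                b_thr = alpha(b, params.C, params.tau)
                if cy >= b_thr * d:
                    y_mask[q] = True
                    y_order.append(q)
                    total_w += sums_y[q]
                    sums_x += W[:, q]
                    for i in np.nonzero(x_mask)[0]:
                        if W[i, q] > 0:
                            selected.add((int(i), q))
                    trace.append(
                        (graph.y_ids[q], "y", cy, b_thr, float(total_w / (a * (b + 1))))
                    )
                else:
                    break

        binets.append(
            BiNet(
                x_members=[graph.x_ids[i] for i in x_order],
                y_members=[graph.y_ids[j] for j in y_order],
                seed_edge=(graph.x_ids[i0], graph.y_ids[j0], w_seed),
                density=float(total_w / (len(x_order) * len(y_order))),
                growth_trace=trace,
            )
        )
    return MiningResult(binets, len(selected), params, w_max)


def filter_min_distinct_genes(result: MiningResult, min_genes: int = 10) -> MiningResult:
    """Keep BiNets whose union gene set has at least ``min_genes`` members."""
    kept = [b for b in result.binets if b.n_distinct_genes >= min_genes]
    return MiningResult(kept, result.selected_edge_count, result.params, result.w_max)


@dataclass
class GuaranteeReport:
    ratios: list[float]
    bound: float
    per_binet_pass: list[bool]
    all_pass: bool


def verify_density_guarantee(
    result: MiningResult,
    graph: WeightedBipartiteGraph,
    params: BCMParams | None = None,
    atol: float = 1e-9,
) -> GuaranteeReport:
    """Check density / seed-weight >= density_bound_F for every BiNet.

    Densities are recomputed from the graph; a stored density that does not
    match its recomputation signals a result/graph mismatch and raises.
    """
    if params is None:
        params = result.params
    bound = density_bound_F(params.C, params.tau)
    ratios: list[float] = []
    flags: list[bool] = []
    for b in result.binets:
        try:
            d = density(b.x_members, b.y_members, graph)
        except ValueError as exc:
            raise ValueError("mining result does not match graph") from exc
        if abs(d - b.density) > 1e-9:
            raise ValueError("mining result does not match graph")
        ratio = d / b.seed_edge[2]
        ratios.append(ratio)
        flags.append(ratio >= bound - atol)
    return GuaranteeReport(ratios, bound, flags, all(flags))


class BCMMiner(BaseEstimator):
    """Biclustering-style estimator interface to BCM.

    Fit on a weight matrix (rows = X-side vertices, columns = Y-side
    vertices, entries in [0, 1] with 0 meaning no edge) or directly on a
    :class:`~bcmnet.graph.WeightedBipartiteGraph`.

    Parameters
    ----------
    C, tau, beta, min_seed_weight
        See :class:`BCMParams`.

    Attributes
    ----------
    binets_ : list of BiNet
        Mined BiNets in seed order.
    rows_, columns_ : bool ndarrays, shape (n_binets, n_x) / (n_binets, n_y)
        Membership indicators in the sklearn biclustering convention.
    w_max_ : float
        Weight of the heaviest edge.
    result_ : MiningResult
        Full mining result including the Selected-edge count.

    Examples
    --------
    >>> import numpy as np
    >>> W = np.array([[1.0, 0.9], [0.95, 0.9]])
    >>> miner = BCMMiner(C=36, tau=2, beta=0.7).fit(W)
    >>> miner.binets_[0].size
    (2, 2)
    """

    def __init__(
        self,
        C: int = 36,
        tau: int = 2,
        beta: float = 0.7,
        min_seed_weight: float | None = None,
    ):
        self.C = C
        self.tau = tau
        self.beta = beta
        self.min_seed_weight = min_seed_weight

    def _as_graph(self, X) -> WeightedBipartiteGraph:
        if isinstance(X, WeightedBipartiteGraph):
            return X
        W = np.asarray(X, dtype=float)
        if W.ndim != 2:
            raise ValueError("X must be a 2-D weight matrix or a graph")
        nx_, ny_ = W.shape
        return WeightedBipartiteGraph(
            [f"x{i}" for i in range(nx_)], [f"y{j}" for j in range(ny_)], W
        )

    def fit(self, X, y=None) -> "BCMMiner":
        graph = self._as_graph(X)
        params = BCMParams(
            C=self.C, tau=self.tau, beta=self.beta, min_seed_weight=self.min_seed_weight
        )
        result = bcm_mine(graph, params)
        self.graph_ = graph
        self.result_ = result
        self.binets_ = result.binets
        self.w_max_ = result.w_max
        xi = {v: i for i, v in enumerate(graph.x_ids)}
        yi = {v: j for j, v in enumerate(graph.y_ids)}
        n = len(result.binets)
        self.rows_ = np.zeros((n, graph.n_x), dtype=bool)
        self.columns_ = np.zeros((n, graph.n_y), dtype=bool)
        for k, b in enumerate(result.binets):
            self.rows_[k, [xi[v] for v in b.x_members]] = True
            self.columns_[k, [yi[v] for v in b.y_members]] = True
        return self

    def density_bound_(self) -> float:
        """Theorem lower bound F for this estimator's (C, tau)."""
        return density_bound_F(self.C, self.tau)
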