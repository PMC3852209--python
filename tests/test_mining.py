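"""BCM algorithm, density arithmetic, and the analytic density bound."""

import math

import numpy as np
import pytest
from sklearn.base import clone

from bcmnet import (
    BCMMiner,
    BCMParams,
    WeightedBipartiteGraph,
    alpha,
    bcm_mine,
    contribution,
    density,
    density_bound_F,
    filter_min_distinct_genes,
    verify_density_guarantee,
)
from conftest import random_graph


def brute_density(graph, x_members, y_members):
    """Independent exhaustive pairwise-sum oracle."""
    total = 0.0
    lookup = {(x, y): w for x, y, w in graph.edges()}
    for x in x_members:
        for y in y_members:
            total += lookup.get((x, y), 0.0)
    return total / (len(x_members) * len(y_members))


class TestDensity:
    def test_seed_case_is_edge_weight(self, toy_graph):
        assert density(["x3"], ["y3"], toy_graph) == pytest.approx(0.85)

    def test_two_by_one(self, toy_graph):
        # weights 1.0 and 0.95 over 2*1 pairs
        assert density(["x1", "x2"], ["y1"], toy_graph) == pytest.approx(0.975)

    def test_absent_edges_count_zero(self):
        g = WeightedBipartiteGraph.from_edges(
            ["a", "b"], ["c"], [("a", "c", 0.8)]
        )
        assert density(["a", "b"], ["c"], g) == pytest.approx(0.4)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle(self, seed):
        g = random_graph(seed)
        rng = np.random.default_rng(seed + 100)
        xs = list(rng.choice(g.x_ids, size=3, replace=False))
        ys = list(rng.choice(g.y_ids, size=4, replace=False))
        assert density(xs, ys, g) == pytest.approx(
            brute_density(g, xs, ys), abs=1e-12
        )

    def test_empty_side_rejected(self, toy_graph):
        with pytest.raises(ValueError):
            density([], ["y1"], toy_graph)


class TestContribution:
    def test_mean_over_opposite_members(self, toy_graph):
        result = bcm_mine(toy_graph)
        binet = result.binets[0]  # x={x1,x2}, y={y1,y2}
        # x3 connects to y1 and y2 with weight 0.1 each
        assert contribution("x3", "x", binet, toy_graph) == pytest.approx(0.1)

    def test_no_edges_gives_zero(self):
        g = WeightedBipartiteGraph.from_edges(
            ["a", "b"], ["c"], [("a", "c", 0.9)]
        )
        binet = bcm_mine(g).binets[0]
        assert contribution("b", "x", binet, g) == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_mean(self, seed):
        g = random_graph(seed)
        binet = bcm_mine(g).binets[0]
        lookup = {(x, y): w for x, y, w in g.edges()}
        for v in g.x_ids:
            if v in binet.x_members:
                continue
            expected = sum(
                lookup.get((v, u), 0.0) for u in binet.y_members
            ) / len(binet.y_members)
            assert contribution(v, "x", binet, g) == pytest.approx(
                expected, abs=1e-12
            )


class TestAlphaSchedule:
    def test_lambda_greater_one_branch(self):
        # size=1, C=100, tau=1: lambda = 100/9 -> alpha = 1 - 3/100
        assert alpha(1, 100, 1) == pytest.approx(0.97)

    def test_lambda_one_branch(self):
        # size=9, C=100, tau=1: (9+2)^2 > 100 -> alpha = 1 - 1/11
        assert alpha(9, 100, 1) == pytest.approx(1 - 1 / 11)

    def test_monotone_in_each_regime(self):
        # lambda > 1 ((s+2)^2 < 100): alpha = 1 - (s+2)/100, decreasing
        early = [alpha(s, 100, 1) for s in range(1, 8)]
        assert all(b < a for a, b in zip(early, early[1:]))
        # lambda = 1: alpha = 1 - 1/(s+2), increasing toward 1
        late = [alpha(s, 100, 1) for s in range(9, 20)]
        assert all(b > a for a, b in zip(late, late[1:]))


class TestDensityBound:
    def test_worked_value_c100(self):
        # (197/200)^14 * (8/9)^2
        expected = (197 / 200) ** 14 * (8 / 9) ** 2
        assert density_bound_F(100, 1) == pytest.approx(expected, abs=1e-15)
        assert round(density_bound_F(100, 1), 2) == 0.64

    def test_worked_value_c10000(self):
        assert density_bound_F(10000, 0) >= 0.96

    def test_default_parameters(self):
        expected = (68 / 72) ** 4 * (3 / 4) ** 2
        assert density_bound_F(36, 2) == pytest.approx(expected, abs=1e-15)

    def test_non_square_C_uses_real_sqrt(self):
        # C=50, tau=1: sizes with (i+2)^2 < 50 are i=1..5 -> k=5
        s = math.sqrt(50)
        expected = (97 / 100) ** 10 * ((s - 2) / (s - 1)) ** 2
        assert density_bound_F(50, 1) == pytest.approx(expected, abs=1e-15)

    def test_precondition_enforced(self):
        with pytest.raises(ValueError):
            density_bound_F(16, 2)  # C must exceed (tau+2)^2


class TestBCMMine:
    def test_single_edge_graph(self, default_params):
        g = WeightedBipartiteGraph.from_edges(["a"], ["b"], [("a", "b", 0.8)])
        result = bcm_mine(g, default_params)
        assert len(result.binets) == 1
        binet = result.binets[0]
        assert binet.x_members == ["a"] and binet.y_members == ["b"]
        assert binet.density == pytest.approx(0.8)
        assert binet.growth_trace == []

    def test_empty_graph(self, default_params):
        g = WeightedBipartiteGraph(["a"], ["b"], np.zeros((1, 1)))
        result = bcm_mine(g, default_params)
        assert result.binets == [] and result.w_max == 0.0

    def test_hand_trace_oracle(self, toy_graph, default_params):
        """Full run must equal the manual simulation of the seed-and-grow loop.

        Manual trace: seed (x1,y1,1.0); x2 admitted (contribution 0.95 vs
        alpha(1)=8/9 of density 1.0), then y2 (0.9 vs 8/9 of 0.975); both
        remaining candidates contribute 0.1 < alpha threshold, stop.  The
        next unselected seed is (x3,y3,0.85), which cannot grow.  The 0.1
        edges fall below beta * w_max = 0.7 and are never seeds.
        """
        result = bcm_mine(toy_graph, default_params)
        assert len(result.binets) == 2
        b0, b1 = result.binets
        assert b0.x_members == ["x1", "x2"] and b0.y_members == ["y1", "y2"]
        assert b0.seed_edge == ("x1", "y1", 1.0)
        assert b0.density == pytest.approx(0.9375, abs=1e-12)
        assert len(b0.growth_trace) == 2
        v, side, contrib, a_used, d_after = b0.growth_trace[0]
        assert (v, side) == ("x2", "x")
        assert contrib == pytest.approx(0.95)
        assert a_used == pytest.approx(8 / 9)
        assert d_after == pytest.approx(0.975)
        v, side, contrib, a_used, d_after = b0.growth_trace[1]
        assert (v, side) == ("y2", "y")
        assert contrib == pytest.approx(0.9)
        assert a_used == pytest.approx(8 / 9)
        assert d_after == pytest.approx(0.9375)
        assert b1.x_members == ["x3"] and b1.y_members == ["y3"]
        assert b1.density == pytest.approx(0.85)
        assert result.w_max == 1.0
        assert result.selected_edge_count == 5

    def test_seed_pruning_rules(self, toy_graph, default_params):
        result = bcm_mine(toy_graph, default_params)
        for b in result.binets:
            assert b.seed_edge[2] >= default_params.beta * result.w_max

    def test_growth_steps_respect_alpha(self, default_params):
        """Replaying every trace re-verifies contribution >= alpha * density."""
        for seed in range(10):
            g = random_graph(seed, n_x=12, n_y=12, p=0.6)
            for binet in bcm_mine(g, default_params).binets:
                xs = [binet.x_members[0]]
                ys = [binet.y_members[0]]
                d = binet.seed_edge[2]
                for v, side, contrib, a_used, d_after in binet.growth_trace:
                    size = len(xs) if side == "x" else len(ys)
                    assert a_used == pytest.approx(
                        alpha(size, default_params.C, default_params.tau)
                    )
                    assert contrib >= a_used * d - 1e-12
                    (xs if side == "x" else ys).append(v)
                    d = density(xs, ys, g)
                    assert d == pytest.approx(d_after, abs=1e-9)
                assert xs == binet.x_members and ys == binet.y_members
                assert d == pytest.approx(binet.density, abs=1e-9)

    def test_determinism(self, default_params):
        g = random_graph(3, n_x=15, n_y=15, p=0.5)
        r1 = bcm_mine(g, default_params)
        r2 = bcm_mine(g, default_params)
        assert [b.x_members for b in r1.binets] == [b.x_members for b in r2.binets]
        assert [b.growth_trace for b in r1.binets] == [
            b.growth_trace for b in r2.binets
        ]

    def test_vertices_may_be_shared_across_binets(self, default_params):
        # 0.85 fails the alpha test from the first seed (needs >= 8/9),
        # so it seeds its own BiNet sharing x1
        g = WeightedBipartiteGraph.from_edges(
            ["x1"], ["y1", "y2"], [("x1", "y1", 1.0), ("x1", "y2", 0.85)]
        )
        result = bcm_mine(g, BCMParams(C=36, tau=2, beta=0.8))
        assert len(result.binets) == 2
        assert all(b.x_members == ["x1"] for b in result.binets)


class TestGuarantee:
    def test_random_sweep_zero_violations(self, default_params):
        from bcmnet import generate_random_bipartite

        bound = density_bound_F(36, 2)
        for seed in range(20):
            g = generate_random_bipartite(20, 20, 0.5, 0.5, 1.0, seed)
            result = bcm_mine(g, default_params)
            report = verify_density_guarantee(result, g)
            assert report.bound == pytest.approx(bound)
            assert report.all_pass

    def test_single_edge_ratio_one(self, default_params):
        g = WeightedBipartiteGraph.from_edges(["a"], ["b"], [("a", "b", 0.7)])
        report = verify_density_guarantee(bcm_mine(g, default_params), g)
        assert report.ratios == [pytest.approx(1.0)]

    def test_mismatched_graph_rejected(self, toy_graph, default_params):
        result = bcm_mine(toy_graph, default_params)
        other = WeightedBipartiteGraph(
            toy_graph.x_ids, toy_graph.y_ids, toy_graph.weights * 0.5
        )
        with pytest.raises(ValueError):
            verify_density_guarantee(result, other)


class TestFilterMinDistinctGenes:
    def test_shared_symbols_count_once(self, default_params):
        from bcmnet import BiNet, MiningResult

        shared = BiNet(
            x_members=[f"g{i}" for i in range(5)],
            y_members=[f"g{i}" for i in range(5)],
            seed_edge=("g0", "g0", 1.0),
            density=1.0,
        )
        disjoint = BiNet(
            x_members=[f"t{i}" for i in range(6)],
            y_members=[f"s{i}" for i in range(5)],
            seed_edge=("t0", "s0", 1.0),
            density=1.0,
        )
        result = MiningResult([shared, disjoint], 0, default_params, 1.0)
        kept = filter_min_distinct_genes(result, min_genes=10)
        assert kept.binets == [disjoint]

    def test_census_matches_set_union(self, default_params):
        for seed in range(5):
            g = random_graph(seed, n_x=10, n_y=10, p=0.6)
            result = bcm_mine(g, default_params)
            for m in (1, 3, 5):
                kept = filter_min_distinct_genes(result, m)
                expected = [
                    b
                    for b in result.binets
                    if len(set(b.x_members) | set(b.y_members)) >= m
                ]
                assert kept.binets == expected


class TestBCMMinerEstimator:
    def test_sklearn_protocol(self):
        assert clone(BCMMiner(C=100, tau=1)).get_params()["C"] == 100
        # with the defaults the dense 2x2 matrix is absorbed into one BiNet
        W = np.array([[1.0, 0.9], [0.95, 0.9]])
        miner = BCMMiner().fit(W)
        assert miner.rows_.shape == (1, 2) and miner.columns_.shape == (1, 2)
        assert miner.rows_.all() and miner.columns_.all()
        assert miner.w_max_ == 1.0

    def test_matches_functional_interface(self, toy_graph):
        miner = BCMMiner().fit(toy_graph)
        direct = bcm_mine(toy_graph, BCMParams())
        assert [b.x_members for b in miner.binets_] == [
            b.x_members for b in direct.binets
        ]

    def test_invalid_params_raise_on_fit(self):
        with pytest.raises(ValueError):
            BCMMiner(C=9, tau=2).fit(np.eye(3))
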