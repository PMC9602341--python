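"""Signed-network summaries and cross-condition statistics."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import micronet as m

SIGNS = st.sampled_from([-1, 0, 1])


def toy_net(edges, n=4, condition=""):
    nodes = [f"n{i}" for i in range(n)]
    return m.build_network(edges, nodes=nodes, condition=condition)


class TestBuildNetwork:
    def test_empty_edges(self):
        net = toy_net([])
        assert net.n_edges == 0 and net.n_nodes == 4

    def test_duplicate_ordered_pair_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            toy_net([("n0", "n1", 1), ("n0", "n1", -1)])

    def test_self_edge_rejected(self):
        with pytest.raises(ValueError, match="self"):
            toy_net([("n0", "n0", 1)])

    def test_adjacency_matches_hand_drawing(self):
        net = toy_net([("n0", "n1", 1), ("n1", "n0", -1),
                       ("n2", "n3", 1, 0.4), ("n0", "n3", -1)])
        assert net.sign("n0", "n1") == 1
        assert net.sign("n1", "n0") == -1
        assert net.sign("n2", "n3") == 1
        assert net.sign("n3", "n2") == 0
        assert net.edges[("n2", "n3")][1] == pytest.approx(0.4)


class TestConnectance:
    def test_complete_digraph(self):
        edges = [(f"n{i}", f"n{j}", 1) for i in range(4) for j in range(4)
                 if i != j]
        assert m.connectance(toy_net(edges)) == 1.0

    def test_edgeless(self):
        assert m.connectance(toy_net([])) == 0.0

    def test_removing_an_edge_never_increases_it(self):
        edges = [("n0", "n1", 1), ("n1", "n2", -1), ("n2", "n0", 1)]
        full = m.connectance(toy_net(edges))
        fewer = m.connectance(toy_net(edges[:-1]))
        assert fewer <= full


class TestSignedDegree:
    def test_isolated_node_all_zero(self):
        net = toy_net([("n0", "n1", 1)])
        for sign in (1, -1):
            for direction in ("in", "out", "total"):
                assert m.signed_degree(net, "n3", sign, direction) == 0

    def test_hand_counted_degrees(self):
        net = toy_net([("n1", "n0", 1),   # +in for n0
                       ("n0", "n2", 1),   # +out for n0
                       ("n3", "n0", -1)])  # -in for n0
        assert m.signed_degree(net, "n0", 1, "total") == 2
        assert m.signed_degree(net, "n0", -1, "in") == 1
        assert m.signed_degree(net, "n0", -1, "out") == 0

    def test_handshake_identity_per_sign(self):
        rng = np.random.default_rng(3)
        pairs = [(f"n{i}", f"n{j}") for i in range(6) for j in range(6)
                 if i != j]
        chosen = [pairs[k] for k in rng.choice(len(pairs), 12, replace=False)]
        edges = [(u, v, int(rng.choice([-1, 1]))) for u, v in chosen]
        net = m.build_network(edges, nodes=[f"n{i}" for i in range(6)])
        for sign in (1, -1):
            n_edges = sum(1 for (s, _) in net.edges.values() if s == sign)
            tot_in = sum(m.signed_degree(net, n, sign, "in")
                         for n in net.nodes)
            tot_out = sum(m.signed_degree(net, n, sign, "out")
                          for n in net.nodes)
            assert tot_in == tot_out == n_edges


class TestClassifyPair:
    @pytest.mark.parametrize("signs, state", [
        ((1, 1), "mutualism"),
        ((1, 0), "commensalism"),
        ((1, -1), "antagonism"),
        ((-1, 0), "amensalism"),
        ((-1, -1), "competition"),
        ((0, 0), "none"),
    ])
    def test_table(self, signs, state):
        assert m.classify_pair(*signs) == state

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(SIGNS, SIGNS)
    def test_total_and_symmetric(self, a, b):
        assert m.classify_pair(a, b) == m.classify_pair(b, a)
        assert m.classify_pair(a, b) in {"mutualism", "commensalism",
                                         "antagonism", "amensalism",
                                         "competition", "none"}


class TestPairStateTable:
    def test_single_mutualism_pair(self):
        net = toy_net([("n0", "n1", 1), ("n1", "n0", 1)])
        table = m.pair_state_table(net)
        assert table["mutualism"] == {"count": 1, "percent": 100.0}

    def test_percentages_sum_to_100(self, net_30c):
        table = m.pair_state_table(net_30c)
        assert sum(v["percent"] for v in table.values()) == pytest.approx(100)
        rounded = sum(round(v["percent"], 2) for v in table.values())
        assert abs(rounded - 100) <= 0.05

    def test_invariant_under_node_relabeling(self):
        edges = [("n0", "n1", 1), ("n2", "n1", -1), ("n2", "n3", 1),
                 ("n3", "n2", 1)]
        t1 = m.pair_state_table(toy_net(edges))
        perm = {"n0": "n3", "n1": "n2", "n2": "n1", "n3": "n0"}
        t2 = m.pair_state_table(
            toy_net([(perm[u], perm[v], s) for u, v, s in edges]))
        assert t1 == t2


class TestPositiveLinkProportion:
    def test_all_negative_is_zero(self):
        assert m.positive_link_proportion(
            toy_net([("n0", "n1", -1), ("n2", "n0", -1)])) == 0.0

    def test_edgeless_undefined(self):
        with pytest.raises(ValueError):
            m.positive_link_proportion(toy_net([]))


class TestPartitionNodes:
    def test_identical_networks_have_no_specifics(self):
        net = toy_net([("n0", "n1", 1)])
        part = m.partition_nodes(net, net)
        assert part.specific_a == part.specific_b == ()
        assert set(part.common) == set(net.nodes)

    def test_disjoint_networks_have_no_common(self):
        a = m.build_network([], nodes=["x0", "x1"])
        b = m.build_network([], nodes=["y0", "y1"])
        part = m.partition_nodes(a, b)
        assert part.common == ()
        assert len(part.specific_a) == len(part.specific_b) == 2

    def test_partition_is_a_partition(self, net_30c, net_37c):
        part = m.partition_nodes(net_30c, net_37c)
        union = set(part.common) | set(part.specific_a) | set(part.specific_b)
        assert union == set(net_30c.nodes) | set(net_37c.nodes)
        assert len(part.common) + len(part.specific_a) == net_30c.n_nodes


class TestInducedSubnetwork:
    def test_full_subset_is_identity(self):
        net = toy_net([("n0", "n1", 1), ("n2", "n3", -1)])
        sub = m.induced_subnetwork(net, net.nodes)
        assert sub.edges == net.edges

    def test_two_node_subset(self):
        net = toy_net([("n0", "n1", 1), ("n1", "n2", -1)])
        sub = m.induced_subnetwork(net, ["n0", "n1"])
        assert set(sub.edges) == {("n0", "n1")}

    def test_matches_brute_force_filter(self):
        rng = np.random.default_rng(8)
        pairs = [(f"n{i}", f"n{j}") for i in range(6) for j in range(6)
                 if i != j]
        chosen = [pairs[k] for k in rng.choice(len(pairs), 14, replace=False)]
        edges = [(u, v, int(rng.choice([-1, 1]))) for u, v in chosen]
        net = m.build_network(edges, nodes=[f"n{i}" for i in range(6)])
        subset = {"n0", "n2", "n4", "n5"}
        sub = m.induced_subnetwork(net, subset)
        assert set(sub.edges) == {(u, v) for u, v, _ in edges
                                  if u in subset and v in subset}


def rank_sum_exact_p(x, y):
    """Enumeration oracle: two-sided rank-sum p for tie-free samples."""
    pooled = sorted(x + y)
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    w_obs = sum(ranks[v] for v in x)
    n = len(pooled)
    mean_w = len(x) * (n + 1) / 2
    count = total = 0
    for combo in itertools.combinations(range(1, n + 1), len(x)):
        w = sum(combo)
        total += 1
        if abs(w - mean_w) >= abs(w_obs - mean_w) - 1e-12:
            count += 1
    return count / total


class TestWilcoxonDegreeTest:
    def test_identical_groups_p_one(self):
        _, p = m.wilcoxon_degree_test([1, 2, 3], [1, 2, 3])
        assert p == pytest.approx(1.0)

    def test_separated_triples_exact_p(self):
        _, p = m.wilcoxon_degree_test([1, 2, 3], [10, 11, 12])
        assert p == pytest.approx(0.1)

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            n1, n2 = rng.integers(3, 7, 2)
            pool = rng.permutation(100)[: n1 + n2].astype(float)
            x, y = list(pool[:n1]), list(pool[n1:])
            _, p = m.wilcoxon_degree_test(x, y)
            assert p == pytest.approx(rank_sum_exact_p(x, y))


class TestSpearman:
    def test_identical_vectors_rho_one(self):
        # degree sequence (3, 2, 1, 0): identical networks correlate fully
        net = toy_net([("n0", "n1", 1), ("n0", "n2", 1), ("n0", "n3", -1)])
        rho, _ = m.spearman_degree_correlation(net, net, list(net.nodes))
        assert rho == pytest.approx(1.0)

    def test_reversed_ranks_rho_minus_one(self):
        a = toy_net([("n0", "n1", 1), ("n0", "n2", 1)])   # degrees 2,1,1,0
        b = toy_net([("n3", "n1", 1), ("n3", "n2", 1)])   # degrees 0,1,1,2
        rho, _ = m.spearman_degree_correlation(a, b, list(a.nodes))
        assert rho == pytest.approx(-1.0)

    def test_hand_ranked_toy_case(self):
        from scipy import stats
        a = m.build_network([("n0", "n1", 1), ("n0", "n2", 1),
                             ("n0", "n3", 1), ("n1", "n2", 1)],
                            nodes=[f"n{i}" for i in range(5)])
        b = m.build_network([("n4", "n0", -1), ("n2", "n1", 1),
                             ("n2", "n3", 1), ("n2", "n0", 1)],
                            nodes=[f"n{i}" for i in range(5)])
        common = [f"n{i}" for i in range(5)]
        da = [3, 2, 2, 1, 0]
        db = [2, 1, 3, 1, 1]
        want_rho, want_p = stats.spearmanr(da, db)
        rho, p = m.spearman_degree_correlation(a, b, common)
        assert rho == pytest.approx(want_rho)
        assert p == pytest.approx(want_p)


class TestGraphCorrelation:
    def test_identical_subnetworks_r_one(self):
        net = toy_net([("n0", "n1", 1), ("n2", "n3", -1)])
        assert m.graph_correlation(net, net, net.nodes) == pytest.approx(1.0)

    def test_complementary_adjacency_r_minus_one(self):
        nodes = ["n0", "n1"]
        a = m.build_network([("n0", "n1", 1)], nodes=nodes)
        b = m.build_network([("n1", "n0", 1)], nodes=nodes)
        assert m.graph_correlation(a, b, nodes) == pytest.approx(-1.0)

    def test_toy_case_matches_direct_pearson(self):
        rng = np.random.default_rng(12)
        nodes = [f"n{i}" for i in range(4)]
        def rand_net(seed):
            r = np.random.default_rng(seed)
            pairs = [(u, v) for u in nodes for v in nodes if u != v]
            chosen = [pairs[k] for k in r.choice(12, 5, replace=False)]
            return m.build_network([(u, v, 1) for u, v in chosen],
                                   nodes=nodes)
        a, b = rand_net(1), rand_net(2)
        va, vb = [], []
        for u in nodes:
            for v in nodes:
                if u != v:
                    va.append(1.0 if (u, v) in a.edges else 0.0)
                    vb.append(1.0 if (u, v) in b.edges else 0.0)
        want = np.corrcoef(va, vb)[0, 1]
        assert m.graph_correlation(a, b, nodes) == pytest.approx(want)


class TestPercentChange:
    def test_no_change_is_zero(self):
        assert m.percent_change(5.0, 5.0) == 0.0

    def test_zero_baseline_rejected(self):
        with pytest.raises(ValueError):
            m.percent_change(0.0, 1.0)
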