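import networkx as nx
import numpy as np
import pandas as pd
import pytest

from oracles import (
    edge_betweenness_oracle,
    modularity_oracle,
    naive_girvan_newman,
    random_connected_graph,
    spearman_oracle,
)
from taxonet.network import (
    METADATA,
    TAXON,
    NodeTable,
    assemble_node_table,
    build_network,
    count_cooccurrence,
    edge_betweenness,
    edge_passes,
    girvan_newman_partition,
    modularity,
    node_degree,
    spearman_with_p,
)


def _random_pair(rng, tie_fraction=0.3):
    n = int(rng.integers(5, 31))
    x = rng.normal(size=n)
    y = rng.normal(size=n)
    for v in (x, y):
        ties = rng.random(n) < tie_fraction
        v[ties] = np.round(v[ties], 0)  # collide values to create ties
    return x, y


class TestSpearman:
    def test_perfect_monotone(self):
        rho, p, n = spearman_with_p([1, 2, 3, 4, 5], [2, 4, 6, 8, 10])
        assert (rho, p, n) == (1.0, 0.0, 5)
        rho, p, _ = spearman_with_p([1, 2, 3, 4, 5], [10, 8, 6, 4, 2])
        assert (rho, p) == (-1.0, 0.0)

    def test_tied_example_matches_midrank_oracle(self):
        x, y = [1, 2, 2, 4], [3, 1, 2, 4]
        rho, p, _ = spearman_with_p(x, y)
        orho, op = spearman_oracle(x, y)
        assert rho == pytest.approx(orho, abs=1e-12)
        assert p == pytest.approx(op, abs=1e-10)

    def test_matches_oracle_on_random_tied_pairs(self, rng):
        for _ in range(60):
            x, y = _random_pair(rng)
            rho, p, _ = spearman_with_p(x, y)
            orho, op = spearman_oracle(x, y)
            assert rho == pytest.approx(orho, abs=1e-12)
            assert p == pytest.approx(op, abs=1e-10)

    def test_zero_variance_returns_nan(self):
        rho, p, n = spearman_with_p([1, 1, 1, 1], [1, 2, 3, 4])
        assert np.isnan(rho) and np.isnan(p) and n == 4


class TestCooccurrenceCounting:
    def test_joint_support_count(self):
        x = np.array([1, 0, 2, 3, 0, 1, 0, 2, 1, 1], dtype=float)
        y = np.array([0, 1, 1, 1, 0, 1, 1, 1, 0, 1], dtype=float)
        assert count_cooccurrence(x, y) == 5

    def test_disjoint_supports(self):
        assert count_cooccurrence([1.0, 0.0], [0.0, 1.0]) == 0

    def test_taxon_vs_complete_metadata(self):
        x = np.array([1, 0, 2, 0, 3], dtype=float)
        meta = np.array([0.0, 10.0, 50.0, 100.0, 25.0])
        assert count_cooccurrence(x, meta, TAXON, METADATA) == 3

    def test_missing_metadata_not_observed(self):
        meta = np.array([1.0, np.nan, 2.0])
        assert count_cooccurrence(np.ones(3), meta, TAXON, METADATA) == 2


class TestEdgeFilter:
    @pytest.mark.parametrize(
        "rho,p,expected",
        [
            (0.6, 0.001, False),   # rho exactly at threshold: excluded
            (-0.6, 0.001, False),
            (0.61, 0.05, False),   # p exactly at threshold: excluded
            (0.61, 0.01, True),
            (-0.70, 0.001, True),  # negative edges pass on |rho|
            (0.59, 0.001, False),
        ],
    )
    def test_strict_thresholds(self, rho, p, expected):
        assert edge_passes(rho, p) is expected

    def test_pair_below_min_obs_excluded_regardless_of_rho(self):
        # both taxa observed together in exactly 4 samples, perfectly correlated there
        x = np.array([1, 2, 3, 4, 0, 0, 0, 0, 0, 5], dtype=float)
        y = np.array([2, 4, 6, 8, 0, 0, 0, 0, 1, 0], dtype=float)
        values = pd.DataFrame([x, y], index=["a", "b"], columns=[f"s{i}" for i in range(10)])
        nodes = NodeTable(values=values, kinds=pd.Series({"a": TAXON, "b": TAXON}))
        assert count_cooccurrence(x, y) == 4
        net = build_network(nodes, min_obs=5)
        assert net.number_of_edges() == 0

    def test_edge_kept_with_signed_rho(self, rng):
        n = 12
        up = np.arange(1, n + 1, dtype=float)
        values = pd.DataFrame(
            [up, up[::-1], rng.permutation(up)],
            index=["inc", "dec", "noise"],
            columns=[f"s{i}" for i in range(n)],
        )
        kinds = pd.Series({k: TAXON for k in values.index})
        net = build_network(NodeTable(values=values, kinds=kinds))
        assert net.has_edge("dec", "inc")
        assert net.edges["dec", "inc"]["rho"] == pytest.approx(-1.0)
        assert net.edges["dec", "inc"]["n_obs"] == n

    def test_isolated_nodes_excluded(self):
        n = 10
        up = np.arange(1, n + 1, dtype=float)
        lone = np.array([5, 1, 9, 2, 8, 3, 10, 4, 6, 7], dtype=float)  # rho vs up ~ 0.28
        values = pd.DataFrame([up, up * 2, lone], index=["a", "b", "lone"],
                              columns=[f"s{i}" for i in range(n)])
        kinds = pd.Series({k: TAXON for k in values.index})
        net = build_network(NodeTable(values=values, kinds=kinds))
        assert "lone" not in net

    def test_edge_set_invariant_to_node_order(self, rng):
        values = pd.DataFrame(
            rng.dirichlet(np.ones(8), size=20).T,
            index=[f"t{i}" for i in range(8)],
            columns=[f"s{i}" for i in range(20)],
        )
        kinds = pd.Series({k: TAXON for k in values.index})
        net_a = build_network(NodeTable(values=values, kinds=kinds), rho_min=0.2)
        perm = list(rng.permutation(values.index))
        net_b = build_network(NodeTable(values=values.loc[perm], kinds=kinds.loc[perm]), rho_min=0.2)
        assert set(map(frozenset, net_a.edges)) == set(map(frozenset, net_b.edges))

    def test_filter_monotonicity(self, rng):
        values = pd.DataFrame(
            rng.dirichlet(np.ones(10), size=15).T,
            index=[f"t{i}" for i in range(10)],
            columns=[f"s{i}" for i in range(15)],
        )
        kinds = pd.Series({k: TAXON for k in values.index})
        nodes = NodeTable(values=values, kinds=kinds)
        loose = set(map(frozenset, build_network(nodes, rho_min=0.2, p_max=0.5, min_obs=3).edges))
        for kwargs in [dict(rho_min=0.5), dict(p_max=0.05), dict(min_obs=8)]:
            strict = build_network(nodes, **{"rho_min": 0.2, "p_max": 0.5, "min_obs": 3, **kwargs})
            assert set(map(frozenset, strict.edges)) <= loose


class TestAssembleNodeTable:
    def _rel(self, n_taxa=10, n_samples=8):
        rng = np.random.default_rng(7)
        return pd.DataFrame(
            rng.dirichlet(np.ones(n_taxa), size=n_samples).T,
            index=[f"t{i}" for i in range(n_taxa)],
            columns=[f"s{i}" for i in range(n_samples)],
        )

    def test_counts_and_kinds(self):
        rel = self._rel()
        meta = pd.DataFrame({"depth": np.arange(8.0), "cond": np.arange(8.0) ** 2},
                            index=rel.columns)
        nodes = assemble_node_table(rel, meta)
        assert nodes.values.shape[0] == 12
        assert (nodes.kinds == METADATA).sum() == 2

    def test_missing_metadata_preserved_not_imputed(self):
        rel = self._rel()
        meta = pd.DataFrame({"depth": [1.0, np.nan] * 4}, index=rel.columns)
        nodes = assemble_node_table(rel, meta)
        assert np.isnan(nodes.values.loc["depth"]).sum() == 4

    def test_taxa_only_network_permitted(self):
        nodes = assemble_node_table(self._rel(), None)
        assert (nodes.kinds == TAXON).all()

    def test_too_few_shared_samples_rejected(self):
        rel = self._rel(n_samples=8)
        meta = pd.DataFrame({"v": [1.0, 2.0]}, index=["s0", "s1"])
        with pytest.raises(ValueError, match="shared"):
            assemble_node_table(rel, meta)


class TestEdgeBetweenness:
    def test_path_graph(self):
        g = nx.Graph([("A", "B"), ("B", "C")])
        eb = edge_betweenness(g)
        assert eb[("A", "B")] == pytest.approx(2.0)
        assert eb[("B", "C")] == pytest.approx(2.0)

    def test_single_edge(self):
        assert edge_betweenness(nx.Graph([("A", "B")]))[("A", "B")] == pytest.approx(1.0)

    def test_bridge_between_triangles(self, two_triangles_bridge):
        assert edge_betweenness(two_triangles_bridge)[("C", "D")] == pytest.approx(9.0)

    def test_matches_enumeration_oracle_on_random_graphs(self, rng):
        for _ in range(30):
            edges = random_connected_graph(rng, max_nodes=10)
            ours = edge_betweenness(nx.Graph(edges))
            oracle = edge_betweenness_oracle(edges)
            assert set(ours) == set(oracle)
            for e in oracle:
                assert ours[e] == pytest.approx(oracle[e], abs=1e-9)

    def test_total_credit_equals_sum_of_path_lengths(self, rng):
        for _ in range(10):
            edges = random_connected_graph(rng, max_nodes=8)
            g = nx.Graph(edges)
            eb = edge_betweenness(g)
            lengths = dict(nx.all_pairs_shortest_path_length(g))
            expected = sum(
                lengths[u][v] for i, u in enumerate(g) for v in list(g)[i + 1:] if v in lengths[u]
            )
            assert sum(eb.values()) == pytest.approx(expected, abs=1e-9)


class TestGirvanNewman:
    def test_disconnected_triangles_stay_two_clusters(self):
        g = nx.Graph([("A", "B"), ("A", "C"), ("B", "C"), ("D", "E"), ("D", "F"), ("E", "F")])
        assign = girvan_newman_partition(g)
        assert assign.n_clusters == 2
        assert {assign.labels["A"], assign.labels["B"], assign.labels["C"]} == {1}

    def test_bridge_fixture_splits_exactly(self, two_triangles_bridge):
        assign = girvan_newman_partition(two_triangles_bridge)
        assert assign.members(1) == ["A", "B", "C"]
        assert assign.members(2) == ["D", "E", "F"]
        assert assign.removal_order[0] == ("C", "D")

    def test_complete_graph_is_one_cluster(self):
        assign = girvan_newman_partition(nx.complete_graph(["A", "B", "C", "D"]))
        assert assign.n_clusters == 1
        assert assign.modularity == pytest.approx(0.0)

    def test_modularity_matches_counting_oracle(self, rng):
        for _ in range(10):
            edges = random_connected_graph(rng, max_nodes=8)
            g = nx.Graph(edges)
            nodes = list(g)
            half = frozenset(nodes[: len(nodes) // 2])
            partition = [half, frozenset(nodes[len(nodes) // 2:])]
            assert modularity(g, partition) == pytest.approx(
                modularity_oracle([tuple(e) for e in g.edges], partition), abs=1e-12
            )

    def test_matches_naive_reimplementation_on_random_graphs(self, rng):
        for _ in range(30):
            edges = random_connected_graph(rng, max_nodes=8)
            assign = girvan_newman_partition(nx.Graph(edges))
            naive_q, naive_partition = naive_girvan_newman(edges)
            assert assign.modularity == pytest.approx(naive_q, abs=1e-9)
            recovered = frozenset(frozenset(assign.members(c)) for c in
                                  set(assign.labels.values()))
            assert recovered == naive_partition

    def test_labels_contiguous_from_one(self, rng):
        edges = random_connected_graph(rng, max_nodes=8)
        assign = girvan_newman_partition(nx.Graph(edges))
        labels = sorted(set(assign.labels.values()))
        assert labels == list(range(1, len(labels) + 1))
        assert -0.5 <= assign.modularity <= 1.0


class TestNodeDegree:
    def test_triangle_degrees(self):
        g = nx.Graph([("A", "B"), ("A", "C"), ("B", "C")])
        assert node_degree(g) == {"A": 2, "B": 2, "C": 2}
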