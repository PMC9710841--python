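import random

import networkx as nx
import numpy as np
import pytest

import oracles
from netstate import features as feat
from netstate.networks import extract_ego_network

from conftest import path3, star, triangle


def to_brute(net: nx.Graph) -> oracles.BruteGraph:
    return oracles.BruteGraph(list(net.nodes), [(u, v, d["weight"]) for u, v, d in net.edges(data=True)])


def nx_from(nodes, edges) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(nodes)
    for u, v, w in edges:
        g.add_edge(u, v, weight=w)
    return g


class TestShortestPaths:
    def test_hop_scheme_counts_edges(self):
        d = feat.shortest_paths(path3(), scheme="hop")
        assert d.loc["a", "c"] == 2

    def test_inverse_weight_length(self):
        g = nx.Graph()
        g.add_edge("a", "b", weight=4)
        d = feat.shortest_paths(g, scheme="inverse-weight")
        assert d.loc["a", "b"] == 0.25

    def test_matches_exhaustive_path_enumeration(self):
        rng = random.Random(5)
        for _ in range(20):
            nodes, edges = oracles.random_connected_graph(rng)
            net = nx_from(nodes, edges)
            bg = oracles.BruteGraph(nodes, edges)
            for scheme in ("inverse-weight", "hop"):
                mat = feat.shortest_paths(net, scheme)
                for s in nodes:
                    for t in nodes:
                        expected = oracles.sp_distance(bg, s, t, scheme)
                        assert mat.loc[s, t] == pytest.approx(float(expected), abs=1e-9)


class TestCommunities:
    def test_triangle_is_one_community(self):
        part = feat.detect_communities(triangle())
        assert part.n_communities == 1

    def test_two_cliques_with_a_bridge_split_in_two(self):
        g = nx.Graph()
        for offset, names in ((0, "abcd"), (1, "wxyz")):
            for i, u in enumerate(names):
                for v in names[i + 1 :]:
                    g.add_edge(u, v, weight=1)
        g.add_edge("a", "w", weight=1)
        part = feat.detect_communities(g)
        assert part.n_communities == 2
        # verified against exhaustive modularity search
        q_best, optima = oracles.optimal_partitions(to_brute(g))
        assert part.modularity == pytest.approx(q_best, abs=1e-9)
        key = frozenset(frozenset(n for n, c in part.membership.items() if c == i) for i in range(part.n_communities))
        assert key in optima

    def test_same_seed_gives_identical_partition(self):
        g = nx_from(*oracles.random_connected_graph(random.Random(3), n_min=12, n_max=12))
        p1 = feat.detect_communities(g, seed=11)
        p2 = feat.detect_communities(g, seed=11)
        assert p1.membership == p2.membership


class TestClosedForms:
    """Hand-derivable values on the star and triangle geometries."""

    def test_star_hub_ego_quantities(self):
        net = star(4)
        ego_net = extract_ego_network(net, "hub")
        assert feat.effective_size(ego_net, "hub") == pytest.approx(4.0)
        assert feat.ego_efficiency(ego_net, "hub") == pytest.approx(0.8)
        assert feat.burt_constraint(ego_net, "hub") == pytest.approx(1 / 4)
        assert feat.avg_dyadic_redundancy(ego_net, "hub") == 0.0
        assert feat.avg_similarity(net, "hub") == 0.0
        assert feat.reach_efficiency(net, "hub", ego_net) == pytest.approx(0.2)
        ego = feat.compute_ego_features(net, "hub", ego_net)
        assert ego["density_ego"] == pytest.approx(0.4)
        assert ego["betweenness_ego"] == pytest.approx(1.0)
        assert ego["transitivity_ego"] == 0.0
        assert ego["size_ego"] == 4.0

    def test_star_leaf_reach_efficiency(self):
        net = star(4)
        assert feat.reach_efficiency(net, "leaf1") == pytest.approx(0.5)

    def test_triangle_node_ego_quantities(self):
        net = triangle()
        ego_net = extract_ego_network(net, "a")
        assert feat.effective_size(ego_net, "a") == pytest.approx(1.0)
        assert feat.ego_efficiency(ego_net, "a") == pytest.approx(1 / 3)
        assert feat.burt_constraint(ego_net, "a") == pytest.approx(1.125)
        assert feat.avg_dyadic_redundancy(ego_net, "a") == pytest.approx(1.0)
        assert feat.avg_similarity(net, "a") == pytest.approx(1.0)
        ego = feat.compute_ego_features(net, "a", ego_net)
        assert ego["density_ego"] == pytest.approx(1.0)
        assert ego["betweenness_ego"] == pytest.approx(0.0)

    def test_single_edge_ego_degenerate_fallbacks(self):
        g = nx.Graph()
        g.add_edge("a", "b", weight=3)
        ego_net = extract_ego_network(g, "a")
        assert feat.effective_size(ego_net, "a") == pytest.approx(1.0)
        assert feat.ego_efficiency(ego_net, "a") == pytest.approx(0.5)
        assert feat.burt_constraint(ego_net, "a") == pytest.approx(1.0)
        assert feat.reach_efficiency(g, "a", ego_net) == pytest.approx(0.5)
        ego = feat.compute_ego_features(g, "a", ego_net)
        assert ego["transitivity_ego"] == 0.0
        assert ego["centralization_ego"] == 0.0

    def test_path_global_structure(self):
        gs = feat.compute_global_structural(path3())
        assert gs["density"] == pytest.approx(2 / 3)
        assert gs["transitivity"] == 0.0
        assert gs["centralization_degree"] == pytest.approx(1.0)

    def test_five_node_star_centralization(self):
        gs = feat.compute_global_structural(star(4))
        assert gs["centralization_degree"] == pytest.approx(3.0)

    def test_triangle_global_structure(self):
        part = feat.detect_communities(triangle())
        gs = feat.compute_global_structural(triangle(), part)
        assert gs["density"] == 1.0
        assert gs["transitivity"] == 1.0
        assert gs["centralization_degree"] == 0.0
        assert gs["diameter"] == 1.0
        assert gs["geodesic_distance"] == pytest.approx(1.0)

    def test_path_middle_node_centralities(self):
        net = path3()
        part = feat.detect_communities(net)
        nodal = feat.compute_global_nodal(net, "b", part)
        assert nodal["betweenness_centrality"] == pytest.approx(1.0)
        assert nodal["closeness_centrality"] == pytest.approx(1.0)
        assert nodal["degree_centrality"] == pytest.approx(1.0)


def oracle_feature_row(bg: oracles.BruteGraph, node, part_sizes, part_membership):
    """All 26 features recomputed with the brute-force oracles."""
    n = bg.n
    eg = oracles.ego_subgraph(bg, node)
    row = {
        "order": float(n),
        "size": float(sum(1 for _ in bg.edges())),
        "n_ordered_pairs": float(n * (n - 1)),
        "density": oracles.density(bg),
        "diameter": oracles.diameter_hops(bg),
        "geodesic_distance": oracles.geodesic_mean(bg),
        "transitivity": oracles.transitivity(bg),
        "centralization_degree": oracles.degree_centralization(bg),
        "degree_centrality": bg.degree(node) / (n - 1),
        "closeness_centrality": oracles.closeness(bg, node),
        "betweenness_centrality": oracles.betweenness(bg, node),
        "community_percent_size": part_sizes[part_membership[node]] / n,
        "avg_dyadic_redundancy": oracles.avg_dyadic_redundancy(bg, node),
        "avg_similarity": oracles.avg_similarity(bg, node),
        "betweenness_ego": oracles.betweenness(eg, node),
        "centralization_ego": oracles.degree_centralization(eg) if eg.n > 2 else 0.0,
        "constraint": oracles.constraint(bg, node),
        "density_ego": oracles.density(eg),
        "effective_size": oracles.effective_size(bg, node),
        "efficiency": oracles.efficiency(bg, node),
        "geodesic_distance_ego": oracles.geodesic_mean(eg),
        "n_ordered_pairs_ego": float(eg.n * (eg.n - 1)),
        "reach_efficiency": oracles.reach_efficiency(bg, node),
        "size_ego": float(sum(1 for _ in eg.edges())),
        "transitivity_ego": oracles.transitivity(eg),
    }
    return row


def assert_features_match_oracle(seed: int, n_graphs: int):
    rng = random.Random(seed)
    for _ in range(n_graphs):
        nodes, edges = oracles.random_connected_graph(rng)
        net = nx_from(nodes, edges)
        bg = oracles.BruteGraph(nodes, edges)
        rows = feat.weekly_feature_rows(net, week_index=1).set_index("participant_id")

        part = feat.detect_communities(net)
        q_best, optima = oracles.optimal_partitions(bg)
        assert part.modularity == pytest.approx(q_best, abs=1e-9)
        key = frozenset(
            frozenset(v for v, c in part.membership.items() if c == i) for i in range(part.n_communities)
        )
        assert key in optima
        assert rows["n_subcommunities"].iloc[0] == part.n_communities

        for node in nodes:
            expected = oracle_feature_row(bg, node, part.sizes, part.membership)
            got = rows.loc[node]
            for name, val in expected.items():
                assert got[name] == pytest.approx(val, abs=1e-9), (name, node, edges)


class TestOracleEquivalence:
    def test_all_features_match_bruteforce_on_random_graphs(self):
        assert_features_match_oracle(seed=5, n_graphs=30)


class TestInvariances:
    def test_weight_scaling_leaves_proportion_based_features_unchanged(self):
        rng = random.Random(9)
        scale_free = [
            "order", "size", "n_ordered_pairs", "density", "diameter", "transitivity",
            "centralization_degree", "degree_centrality", "betweenness_centrality",
            "avg_dyadic_redundancy", "avg_similarity", "betweenness_ego", "centralization_ego",
            "constraint", "density_ego", "effective_size", "efficiency",
            "n_ordered_pairs_ego", "reach_efficiency", "size_ego", "transitivity_ego",
        ]
        for _ in range(5):
            nodes, edges = oracles.random_connected_graph(rng)
            net = nx_from(nodes, edges)
            # power-of-two factor keeps inverse-weight lengths float-exact,
            # so shortest-path tie sets are preserved
            scaled = nx_from(nodes, [(u, v, w * 4) for u, v, w in edges])
            r1 = feat.weekly_feature_rows(net, 1).set_index("participant_id")
            r2 = feat.weekly_feature_rows(scaled, 1).set_index("participant_id")
            for name in scale_free:
                np.testing.assert_allclose(r1[name], r2[name], atol=1e-9, err_msg=name)
            # distance-based means scale inversely instead
            np.testing.assert_allclose(r1["geodesic_distance"], 4 * r2["geodesic_distance"], rtol=1e-9)

    def test_node_relabeling_permutes_rows_but_not_values(self):
        rng = random.Random(13)
        nodes, edges = oracles.random_connected_graph(rng)
        mapping = {v: f"p{v}" for v in nodes}
        net = nx_from(nodes, edges)
        relabeled = nx_from(
            [mapping[v] for v in nodes], [(mapping[u], mapping[v], w) for u, v, w in edges]
        )
        r1 = feat.weekly_feature_rows(net, 1).set_index("participant_id")
        r2 = feat.weekly_feature_rows(relabeled, 1).set_index("participant_id")
        for v in nodes:
            np.testing.assert_allclose(
                r1.loc[v, list(feat.FEATURE_COLUMNS)].astype(float),
                r2.loc[mapping[v], list(feat.FEATURE_COLUMNS)].astype(float),
                atol=1e-9,
            )


class TestFeatureMatrix:
    def test_shape_and_column_contract(self):
        nets = {1: triangle(), 2: star(4)}
        matrix = feat.assemble_feature_matrix(nets)
        assert list(matrix.columns) == ["participant_id", *feat.MATRIX_COLUMNS]
        assert len(matrix) == 3 + 5
        assert matrix.shape[1] == 28  # id + 26 features + week

    def test_global_columns_constant_within_week(self, tiny_tables):
        matrix, _ = tiny_tables
        for _, grp in matrix.groupby("week"):
            for col in feat.GLOBAL_STRUCTURAL_COLUMNS:
                assert grp[col].nunique() == 1

    def test_absent_participant_has_no_row(self):
        nets = {1: triangle(), 2: star(4)}
        matrix = feat.assemble_feature_matrix(nets)
        week2 = matrix[matrix["week"] == 2]
        assert "a" not in set(week2["participant_id"])

    def test_value_ranges(self, tiny_tables):
        matrix, _ = tiny_tables
        for col in ("density", "transitivity", "degree_centrality", "density_ego"):
            assert matrix[col].between(0, 1).all()
        assert (matrix["constraint"] > 0).all()
        assert (matrix["effective_size"] >= 1 - 1e-9).all()
        assert matrix["efficiency"].between(0, 1).all()
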