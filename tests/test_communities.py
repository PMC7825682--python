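"""Modularity, its maximization, the enumeration oracle, and the
force-directed layout diagnostics."""

import numpy as np
import networkx as nx
import pytest
from sklearn.metrics import adjusted_rand_score

from cpapnet import (
    ClassProfile,
    CommunityPartition,
    LayoutResult,
    build_network,
    detect_communities,
    exhaustive_modularity_oracle,
    force_layout,
    generate_clustered_cohort,
    layout_community_agreement,
    modularity,
)


def ari(partition, labels):
    nodes = sorted(labels)
    return adjusted_rand_score(
        [labels[v] for v in nodes], [partition.assignment[v] for v in nodes]
    )


class TestModularity:
    def test_two_disjoint_triangles_split_is_half(self, two_triangles):
        part = [{0, 1, 2}, {3, 4, 5}]
        assert modularity(two_triangles, part, weighted=False) == pytest.approx(0.5)

    def test_single_cluster_is_zero_weighted_and_not(self, two_triangles):
        part = [set(two_triangles.nodes)]
        for weighted in (True, False):
            assert modularity(two_triangles, part, weighted=weighted) == pytest.approx(
                0.0, abs=1e-15
            )

    def test_matches_networkx_on_random_weighted_graphs(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            G = nx.gnp_random_graph(12, 0.4, seed=int(rng.integers(1 << 30)))
            for u, v in G.edges():
                G[u][v]["weight"] = float(rng.integers(1, 6))
            labels = {v: int(rng.integers(0, 3)) for v in G}
            groups = {}
            for v, c in labels.items():
                groups.setdefault(c, set()).add(v)
            if G.number_of_edges() == 0:
                continue
            expected = nx.community.modularity(G, list(groups.values()))
            assert modularity(G, labels, weighted=True) == pytest.approx(expected)

    def test_empty_edge_set_is_degenerate_zero(self):
        G = nx.empty_graph(4)
        with pytest.warns(UserWarning):
            assert modularity(G, [{0}, {1}, {2}, {3}]) == 0.0

    def test_partition_must_cover_node_set(self, two_triangles):
        with pytest.raises(ValueError):
            modularity(two_triangles, [{0, 1, 2}])


class TestOracle:
    def test_two_node_path(self):
        G = nx.path_graph(2)
        res = exhaustive_modularity_oracle(G)
        assert res.m == 1  # the single-edge cluster beats the split
        assert res.modularity == pytest.approx(0.0)

    def test_two_triangles_optimum(self, two_triangles):
        res = exhaustive_modularity_oracle(two_triangles, weighted=False)
        assert res.modularity == pytest.approx(0.5)
        assert res.m == 2

    def test_refuses_large_graphs(self):
        with pytest.raises(ValueError):
            exhaustive_modularity_oracle(nx.path_graph(11))


class TestDetectCommunities:
    def test_two_triangles_recovered(self, two_triangles):
        part = detect_communities(two_triangles, seed=0, weighted=False)
        assert part.modularity == pytest.approx(0.5)
        assert sorted(map(sorted, part.communities())) == [[0, 1, 2], [3, 4, 5]]

    def test_complete_graph_single_community(self):
        part = detect_communities(nx.complete_graph(8), seed=0)
        assert part.m == 1
        assert part.modularity == pytest.approx(0.0, abs=1e-15)

    def test_never_below_trivial_partitions(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            G = nx.gnp_random_graph(12, 0.3, seed=int(rng.integers(1 << 30)))
            if G.number_of_edges() == 0:
                continue
            part = detect_communities(G, seed=0)
            assert part.modularity >= 0.0  # single cluster scores 0
            singletons = [{v} for v in G]
            assert part.modularity >= modularity(G, singletons)

    def test_deterministic_given_seed(self, two_triangles):
        a = detect_communities(two_triangles, seed=5)
        b = detect_communities(two_triangles, seed=5)
        assert a == b

    def test_invariant_to_input_construction_order(self):
        cohort = generate_clustered_cohort(seed=4)
        G = build_network(cohort.profiles, threshold=4)
        H = nx.Graph(threshold=4)
        H.add_nodes_from(reversed(list(G.nodes)))
        H.add_edges_from(
            (v, u, d) for u, v, d in reversed(list(G.edges(data=True)))
        )
        a = detect_communities(G, seed=0)
        b = detect_communities(H, seed=0)
        assert ari(a, b.assignment) == 1.0

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError):
            detect_communities(nx.Graph())

    def test_edgeless_graph_gives_singletons(self):
        part = detect_communities(nx.empty_graph(3), seed=0)
        assert part.m == 3

    def test_planted_recovery_with_well_separated_archetypes(self):
        """Archetypes differing pairwise in >= 3 of 6 classes are
        recoverable from the threshold-4 network."""
        archetypes = [
            ClassProfile("M", 2, True, True, True, True),
            ClassProfile("M", 0, False, False, True, False),
            ClassProfile("M", 1, True, False, False, False),
            ClassProfile("F", 3, False, True, False, True),
        ]
        hits = 0
        for seed in range(20):
            cohort = generate_clustered_cohort(
                archetypes, (40, 35, 35, 35), flip_prob=0.05, seed=seed
            )
            G = build_network(cohort.profiles, threshold=4)
            part = detect_communities(G, seed=seed)
            hits += ari(part, cohort.labels) >= 0.9
        assert hits >= 18

    def test_single_archetype_has_no_structure(self):
        cohort = generate_clustered_cohort(
            [ClassProfile("M", 2, True, True, True, True)], [60], 0.05, seed=0
        )
        G = build_network(cohort.profiles, threshold=4)
        part = detect_communities(G, seed=0)
        assert part.modularity < 0.05


class TestForceLayout:
    def test_energy_trace_monotone_nonincreasing(self, two_triangles):
        res = force_layout(two_triangles, iterations=150, seed=0)
        energies = np.array(res.energy)
        assert (np.diff(energies) <= 1e-9).all()
        assert energies[-1] <= energies[0]

    def test_two_cliques_separate_spatially(self):
        G = nx.disjoint_union(nx.complete_graph(5), nx.complete_graph(5))
        res = force_layout(G, iterations=300, seed=1)
        pos = np.array([res.coordinates[v] for v in sorted(G)])
        d = np.linalg.norm(pos[:, None] - pos[None, :], axis=-1)
        intra = np.mean([d[i, j] for i in range(5) for j in range(i + 1, 5)])
        inter = np.mean([d[i, j] for i in range(5) for j in range(5, 10)])
        assert intra < inter

    def test_single_node_has_no_forces(self):
        G = nx.empty_graph(1)
        res = force_layout(G, seed=0)
        assert len(res.coordinates) == 1

    def test_triangle_is_symmetric(self):
        res = force_layout(nx.complete_graph(3), iterations=500, seed=2)
        pos = np.array([res.coordinates[v] for v in range(3)])
        d = [np.linalg.norm(pos[i] - pos[j]) for i, j in [(0, 1), (0, 2), (1, 2)]]
        assert max(d) / min(d) < 1.05

    def test_exponent_domain(self, two_triangles):
        with pytest.raises(ValueError):
            force_layout(two_triangles, a=-0.5)
        with pytest.raises(ValueError):
            force_layout(two_triangles, r=0.5)


class TestLayoutAgreement:
    def test_planted_cohort_agreement_below_one(self):
        cohort = generate_clustered_cohort(seed=6)
        G = build_network(cohort.profiles, threshold=4)
        part = detect_communities(G, seed=0)
        layout = force_layout(G, iterations=200, seed=0)
        assert layout_community_agreement(layout, part) < 1.0

    def test_random_coordinates_give_ratio_near_one(self):
        rng = np.random.default_rng(0)
        coords = {i: tuple(rng.uniform(size=2)) for i in range(400)}
        layout = LayoutResult(coords, 1.0, -1.0, 0, 0)
        labels = {i: i % 4 for i in range(400)}
        assert layout_community_agreement(layout, labels) == pytest.approx(
            1.0, abs=0.05
        )

    def test_coincident_intra_points_drive_ratio_to_zero(self):
        coords = {0: (0.0, 0.0), 1: (0.0, 0.0), 2: (5.0, 5.0), 3: (5.0, 5.0)}
        layout = LayoutResult(coords, 1.0, -1.0, 0, 0)
        assert layout_community_agreement(layout, {0: 0, 1: 0, 2: 1, 3: 1}) == 0.0

    def test_single_community_undefined(self):
        layout = LayoutResult({0: (0, 0), 1: (1, 1)}, 1.0, -1.0, 0, 0)
        with pytest.raises(ValueError):
            layout_community_agreement(layout, {0: 0, 1: 0})
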