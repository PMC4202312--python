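import itertools

import networkx as nx
import numpy as np
import pytest

from mosaicnet.metrics import (
    attribute_assortativity,
    betweenness,
    community_supergraph,
    cycle_edges,
    group_betweenness_contrast,
    louvain_first_pass,
    per_class_assortativity,
)


def two_cliques(k=4):
    g = nx.Graph()
    for base in (0, k):
        for i, j in itertools.combinations(range(base, base + k), 2):
            g.add_edge(i, j)
    g.add_edge(0, k)  # single bridge between the cliques
    return g


class TestLouvain:
    def test_two_cliques_recovered_and_optimal(self):
        g = two_cliques(4)
        part = louvain_first_pass(g, seed=0)
        comms = sorted(map(sorted, part.communities().values()))
        assert comms == [[0, 1, 2, 3], [4, 5, 6, 7]]
        # exhaustive: no 2-partition has higher modularity
        from networkx.algorithms.community import modularity
        best = max(
            modularity(g, [set(s), set(g) - set(s)])
            for r in range(1, 5)
            for s in itertools.combinations(range(8), r)
            if set(s) != set(g)
        )
        assert part.modularity == pytest.approx(best)

    def test_empty_graph_is_error(self):
        with pytest.raises(ValueError, match="empty"):
            louvain_first_pass(nx.Graph())

    def test_edgeless_graph_all_singletons(self):
        g = nx.empty_graph(5)
        part = louvain_first_pass(g, seed=1)
        assert len(part.communities()) == 5
        assert part.modularity == 0.0

    def test_deterministic_given_seed(self):
        g = nx.gnp_random_graph(40, 0.15, seed=3)
        a = louvain_first_pass(g, seed=9)
        b = louvain_first_pass(g, seed=9)
        assert a.labels == b.labels and a.modularity == b.modularity

    def test_improves_on_singleton_partition(self):
        from networkx.algorithms.community import modularity
        for seed in range(5):
            g = nx.gnp_random_graph(30, 0.2, seed=seed)
            if g.number_of_edges() == 0:
                continue
            part = louvain_first_pass(g, seed=seed)
            singletons = modularity(g, [{n} for n in g])
            assert part.modularity >= singletons


class TestCycleEdges:
    def test_triangle_all_flagged(self):
        g = nx.cycle_graph(3)
        flags = cycle_edges(g)
        assert all(flags.values()) and len(flags) == 3

    def test_tree_none_flagged(self):
        g = nx.random_labeled_tree(12, seed=4)
        assert not any(cycle_edges(g).values())

    def test_matches_bridge_removal_oracle(self):
        rng = np.random.default_rng(6)
        for _ in range(25):
            n = int(rng.integers(3, 31))
            g = nx.gnp_random_graph(n, 0.15, seed=int(rng.integers(10 ** 6)))
            flags = cycle_edges(g)
            for u, v in g.edges:
                h = g.copy()
                h.remove_edge(u, v)
                # bridge iff removal disconnects u from v
                is_bridge = not nx.has_path(h, u, v)
                assert flags[(u, v)] == (not is_bridge)

    def test_supergraph_pools_communities(self):
        g = two_cliques(4)
        part = louvain_first_pass(g, seed=0)
        sg = community_supergraph(g, part)
        assert sg.number_of_nodes() == 2 and sg.number_of_edges() == 1
        (data,) = [d for _, _, d in sg.edges(data=True)]
        assert data["count"] == 1 and data["in_cycle"] is False
        assert all(d["size"] == 4 for _, d in sg.nodes(data=True))


class TestAssortativity:
    def test_two_same_label_cliques_r_one(self):
        g = two_cliques(4)
        g.remove_edge(0, 4)
        labels = {i: ("x" if i < 4 else "y") for i in g}
        assert attribute_assortativity(g, labels) == pytest.approx(1.0)

    def test_balanced_bipartite_r_minus_one(self):
        g = nx.complete_bipartite_graph(5, 5)
        labels = {i: ("left" if i < 5 else "right") for i in g}
        assert attribute_assortativity(g, labels) == pytest.approx(-1.0)

    def test_matches_networkx_on_random_graphs(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            g = nx.gnp_random_graph(30, 0.2, seed=int(rng.integers(10 ** 6)))
            labels = {n: str(rng.integers(3)) for n in g}
            nx.set_node_attributes(g, labels, "cls")
            expected = nx.attribute_assortativity_coefficient(g, "cls")
            assert attribute_assortativity(g, labels) == \
                pytest.approx(expected)

    def test_random_labels_near_zero(self):
        rng = np.random.default_rng(12)
        g = nx.gnp_random_graph(400, 0.05, seed=21)
        labels = {n: str(rng.integers(4)) for n in g}
        assert abs(attribute_assortativity(g, labels)) < 0.05

    def test_single_label_undefined(self):
        g = nx.path_graph(4)
        with pytest.raises(ValueError, match="not r=1"):
            attribute_assortativity(g, {n: "only" for n in g})

    def test_unlabeled_edges_dropped(self):
        g = nx.path_graph(4)
        labels = {0: "x", 1: "x", 2: "y"}  # node 3 unlabeled
        r = attribute_assortativity(g, labels, exclude_unlabeled=True)
        # remaining evaluated edges: (0,1) xx and (1,2) xy
        e = {("x", "x"): 0.5, ("x", "y"): 0.25, ("y", "x"): 0.25}
        ax, ay = 0.75, 0.25
        expected = (0.5 - (ax * ax + ay * ay)) / (1 - (ax * ax + ay * ay))
        assert r == pytest.approx(expected)

    def test_invariant_under_label_renaming(self):
        g = two_cliques(3)
        labels = {i: ("a" if i < 3 else "b") for i in g}
        renamed = {i: ("ZZZ" if v == "a" else "qq") for i, v in labels.items()}
        assert attribute_assortativity(g, labels) == \
            pytest.approx(attribute_assortativity(g, renamed))


class TestPerClassAssortativity:
    def test_isolated_block_scores_one(self):
        g = two_cliques(4)
        g.remove_edge(0, 4)
        labels = {i: ("x" if i < 4 else "y") for i in g}
        per = per_class_assortativity(g, labels)
        assert per["x"] == pytest.approx(1.0)
        assert per["y"] == pytest.approx(1.0)

    def test_disassortative_class_negative(self):
        g = nx.star_graph(5)  # hub 0, leaves 1..5
        labels = {0: "hub", **{i: "leaf" for i in range(1, 6)}}
        per = per_class_assortativity(g, labels)
        assert per["hub"] < 0

    def test_aggregating_classes_changes_coefficient(self):
        # merging two classes into one indicator changes r as recomputed
        g = two_cliques(4)
        labels = {i: ("x" if i < 4 else "y") for i in g}
        merged = {i: "xy" for i in g}
        merged[0] = "xy"
        per_split = per_class_assortativity(g, labels)
        # all nodes in one merged class: indicator degenerate, reported absent
        assert per_class_assortativity(g, merged) == {}
        assert set(per_split) == {"x", "y"}

    def test_hand_computed_small_graph(self):
        # path u-v-w labeled A A B: indicator for B over edges
        # (A,A) and (A,B); both orientations -> 4 endpoint pairs
        g = nx.path_graph(3)
        labels = {0: "A", 1: "A", 2: "B"}
        e_tt = 0.0
        e_tf = 0.25  # (B, not-B) each direction
        e_ff = 0.5   # the A-A edge in both orientations
        a_t = 0.25
        a_f = 0.75
        expected = ((e_tt + e_ff) - (a_t ** 2 + a_f ** 2)) / \
            (1 - (a_t ** 2 + a_f ** 2))
        per = per_class_assortativity(g, labels)
        assert per["B"] == pytest.approx(expected)


class TestBetweenness:
    def test_path_closed_form(self):
        g = nx.path_graph(3)
        bc = betweenness(g, mode="exact")
        assert bc[1] == pytest.approx(1.0)
        assert bc[0] == bc[2] == 0.0

    def test_star_closed_form(self):
        g = nx.star_graph(5)
        bc = betweenness(g, mode="exact")
        assert bc[0] == pytest.approx(1.0)
        assert all(bc[i] == 0.0 for i in range(1, 6))

    def test_pivots_equal_exact_when_k_is_n(self):
        rng = np.random.default_rng(31)
        for _ in range(5):
            g = nx.gnp_random_graph(int(rng.integers(20, 201)), 0.05,
                                    seed=int(rng.integers(10 ** 6)))
            exact = betweenness(g, mode="exact")
            approx = betweenness(g, mode="approximate",
                                 k_pivots=g.number_of_nodes(), seed=7)
            for node in g:
                assert approx[node] == pytest.approx(exact[node], abs=1e-12)

    def test_k_larger_than_n_clamped(self):
        g = nx.path_graph(5)
        bc = betweenness(g, mode="approximate", k_pivots=5000, seed=1)
        exact = betweenness(g, mode="exact")
        for node in g:
            assert bc[node] == pytest.approx(exact[node])

    def test_pivot_estimator_unbiased(self):
        g = nx.gnp_random_graph(40, 0.15, seed=44)
        exact = betweenness(g, mode="exact")
        sums = {n: 0.0 for n in g}
        n_seeds = 50
        for seed in range(n_seeds):
            est = betweenness(g, mode="approximate", k_pivots=25, seed=seed)
            for n in g:
                sums[n] += est[n]
        ref = max(exact.values())
        for n in g:
            assert sums[n] / n_seeds == pytest.approx(
                exact[n], abs=0.05 * ref)

    def test_invalid_mode_and_k(self):
        g = nx.path_graph(3)
        with pytest.raises(ValueError):
            betweenness(g, mode="quantum")
        with pytest.raises(ValueError):
            betweenness(g, mode="approximate", k_pivots=0)


class TestGroupContrast:
    def test_printed_means_round_to_17(self):
        contrast = group_betweenness_contrast(
            {"comp": 2.7e-5, "other": 1.6e-6}, {"comp"})
        assert contrast.ratio == pytest.approx(16.875)
        assert contrast.ratio_1dp == 16.9
        assert contrast.ratio_nearest_int == 17

    def test_identical_groups_ratio_one(self):
        bc = {"a": 0.3, "b": 0.3, "c": 0.3}
        contrast = group_betweenness_contrast(bc, {"a"})
        assert contrast.ratio == pytest.approx(1.0)

    def test_empty_group_is_error(self):
        with pytest.raises(ValueError):
            group_betweenness_contrast({"a": 0.1}, {"a"})
        with pytest.raises(ValueError):
            group_betweenness_contrast({"a": 0.1}, set())
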