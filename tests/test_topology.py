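from itertools import combinations

import numpy as np
import pytest

from enetkit import (
    EnhancerNetwork,
    betweenness,
    classify_pairs,
    detect_modules,
    is_modular,
    network_connectivity,
    pair_mutual_information,
    rank_hubs,
    tf_cosine_similarity,
)
import pandas as pd

from enetkit.topology import ModulePartition


def net_from_edges(edges, extra_nodes=(), gene="g"):
    nodes = {n for e in edges for n in e} | set(extra_nodes)
    return EnhancerNetwork(gene, nodes, {tuple(sorted(e)): 1.0 for e in edges})


# -- independent modularity oracle: exhaustive partition search --------------


def _partitions(items):
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in _partitions(rest):
        for i, block in enumerate(part):
            yield part[:i] + [block + [first]] + part[i + 1:]
        yield [[first]] + part


def _modularity(nodes, edges, part):
    m = len(edges)
    deg = {n: 0 for n in nodes}
    for a, b in edges:
        deg[a] += 1
        deg[b] += 1
    block_of = {n: i for i, block in enumerate(part) for n in block}
    q = 0.0
    for a, b in combinations(sorted(nodes), 2):
        if block_of[a] == block_of[b]:
            a_ij = 1.0 if tuple(sorted((a, b))) in edges else 0.0
            q += (a_ij - deg[a] * deg[b] / (2 * m)) / m
    # diagonal terms of the standard definition (every node shares its own block)
    q -= sum(deg[n] ** 2 for n in nodes) / (4 * m * m)
    return q


class TestModuleDetection:
    def test_two_cliques_joined_by_bridge(self):
        cliq1 = list(combinations(["a1", "a2", "a3", "a4"], 2))
        cliq2 = list(combinations(["b1", "b2", "b3", "b4"], 2))
        edges = set(map(tuple, map(sorted, cliq1 + cliq2 + [("a1", "b1")])))
        net = net_from_edges(edges)
        part = detect_modules(net, seed=7)
        groups = {}
        for n, mid in part.assignment.items():
            groups.setdefault(mid, set()).add(n)
        assert sorted(map(sorted, groups.values())) == [
            ["a1", "a2", "a3", "a4"],
            ["b1", "b2", "b3", "b4"],
        ]
        # exhaustive oracle: that split maximizes modularity over all
        # partitions of the 8 nodes
        nodes = sorted(net.nodes)
        best_q, best_part = max(
            ((_modularity(nodes, edges, p), p) for p in _partitions(nodes)),
            key=lambda t: t[0],
        )
        assert sorted(map(sorted, best_part)) == sorted(map(sorted, groups.values()))
        assert part.modularity == pytest.approx(best_q, abs=1e-9)

    def test_triangle_is_one_module(self):
        net = net_from_edges([("a", "b"), ("b", "c"), ("a", "c")])
        assert detect_modules(net).n_modules == 1

    def test_edgeless_nodes_become_singletons(self):
        net = EnhancerNetwork("g", {"a", "b", "c"}, {})
        part = detect_modules(net)
        assert part.n_modules == 3
        assert not is_modular(part)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(0)
        nodes = [f"n{i}" for i in range(12)]
        edges = {
            tuple(sorted(rng.choice(nodes, 2, replace=False))) for _ in range(20)
        }
        net = net_from_edges(edges)
        a = detect_modules(net, seed=7).assignment
        b = detect_modules(net, seed=7).assignment
        assert a == b


class TestPairClassification:
    def test_two_by_two_modules(self):
        part = ModulePartition("g", {"A1": 0, "A2": 0, "B1": 1, "B2": 1})
        pairs = classify_pairs(part)
        counts = {"Intra": 0, "Inter": 0}
        for v in pairs.values():
            counts[v] += 1
        assert counts == {"Intra": 2, "Inter": 4}

    def test_singleton_module_discarded(self):
        part = ModulePartition("g", {"A": 0, "B": 0, "C": 1})
        assert not is_modular(part)
        with pytest.raises(ValueError, match="modular"):
            classify_pairs(part)

    def test_blk_like_two_five_split(self):
        # 7 marked nodes split 2/5: 2*5 = 10 Inter, C(2,2)+C(5,2) = 11 Intra
        assignment = {"e1": 0, "e2": 0}
        assignment.update({f"f{i}": 1 for i in range(5)})
        pairs = classify_pairs(ModulePartition("g", assignment))
        inter = sum(v == "Inter" for v in pairs.values())
        intra = sum(v == "Intra" for v in pairs.values())
        assert (inter, intra) == (10, 11)

    def test_pair_count_identity(self):
        part = ModulePartition(
            "g", {"a": 0, "b": 0, "c": 1, "d": 1, "e": 1, "f": 2}
        )
        pairs = classify_pairs(part)
        n_assigned = 5  # f is in a singleton module
        assert len(pairs) == n_assigned * (n_assigned - 1) // 2


class TestConnectivity:
    def test_triangle(self):
        assert network_connectivity(
            net_from_edges([("a", "b"), ("b", "c"), ("a", "c")])
        ) == pytest.approx(2.0)

    def test_edgeless(self):
        assert network_connectivity(EnhancerNetwork("g", set("abcde"), {})) == 0.0

    def test_path_of_ten(self):
        edges = [(f"n{i}", f"n{i+1}") for i in range(9)]
        assert network_connectivity(net_from_edges(edges)) == pytest.approx(1.8)

    def test_empty_network_errors(self):
        with pytest.raises(ValueError):
            network_connectivity(EnhancerNetwork("g", set(), {}))


class TestHubs:
    def test_star_center_degree_one(self):
        edges = [("hub", leaf) for leaf in ["l1", "l2", "l3", "l4"]]
        table = rank_hubs([net_from_edges(edges)], K=1)
        assert table.scores["hub"] == pytest.approx(1.0)
        assert table.scores["l1"] == pytest.approx(0.25)
        assert table.hubs == {"hub"}

    def test_two_node_module_boundary(self):
        net = net_from_edges([("a", "b")])
        part = ModulePartition("g", {"a": 0, "b": 0})
        table = rank_hubs([net], scope="module", K=2, partitions={"g": part})
        assert table.scores["a"] == 1.0 and table.scores["b"] == 1.0

    def test_hub_group_partition_sums(self):
        rng = np.random.default_rng(1)
        nets = []
        parts = {}
        for g in range(4):
            nodes = [f"g{g}n{i}" for i in range(6)]
            edges = {
                tuple(sorted(rng.choice(nodes, 2, replace=False))) for _ in range(8)
            }
            net = net_from_edges(edges, extra_nodes=nodes, gene=f"g{g}")
            nets.append(net)
            parts[f"g{g}"] = detect_modules(net, seed=7)
        network_hubs = rank_hubs(nets, scope="network", K=0.25).hubs
        module_hubs = rank_hubs(nets, scope="module", K=0.25, partitions=parts).hubs
        everyone = {n for net in nets for n in net.nodes}
        ovlp = network_hubs & module_hubs
        only_m = module_hubs - network_hubs
        only_n = network_hubs - module_hubs
        non = everyone - network_hubs - module_hubs
        assert len(ovlp) + len(only_m) + len(only_n) + len(non) == len(everyone)

    def test_row_order_invariance(self):
        edges = [("a", "b"), ("b", "c"), ("c", "d")]
        t1 = rank_hubs([net_from_edges(edges)], K=2)
        t2 = rank_hubs([net_from_edges(list(reversed(edges)))], K=2)
        assert t1.hubs == t2.hubs and t1.scores == t2.scores

    def test_k_exceeding_enhancers_flags_all_with_warning(self):
        net = net_from_edges([("a", "b")])
        with pytest.warns(UserWarning, match="flagging all"):
            table = rank_hubs([net], K=10)
        assert table.hubs == {"a", "b"}


# -- independent betweenness oracle: explicit shortest-path enumeration ------


def _betweenness_oracle(nodes, edges):
    adj = {n: set() for n in nodes}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)

    def all_shortest_paths(s, t):
        # BFS layering, then DFS back-tracking through predecessor sets
        from collections import deque

        dist = {s: 0}
        preds = {s: []}
        dq = deque([s])
        while dq:
            u = dq.popleft()
            for v in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + 1
                    preds[v] = [u]
                    dq.append(v)
                elif dist[v] == dist[u] + 1:
                    preds[v].append(u)
        if t not in dist:
            return []
        paths = []

        def walk(v, acc):
            if v == s:
                paths.append([s] + acc)
                return
            for p in preds[v]:
                walk(p, [v] + acc)

        walk(t, [])
        return paths

    score = {n: 0.0 for n in nodes}
    for s, t in combinations(sorted(nodes), 2):
        paths = all_shortest_paths(s, t)
        if not paths:
            continue
        for n in nodes:
            if n in (s, t):
                continue
            frac = sum(n in p for p in paths) / len(paths)
            score[n] += frac
    n = len(nodes)
    norm = (n - 1) * (n - 2) / 2 if n > 2 else 1.0
    return {k: v / norm for k, v in score.items()}


class TestBetweenness:
    def test_path_center(self):
        bt = betweenness(net_from_edges([("a", "b"), ("b", "c")]))
        assert bt["b"] == pytest.approx(1.0)
        assert bt["a"] == 0.0 and bt["c"] == 0.0

    def test_clique_all_zero(self):
        bt = betweenness(net_from_edges(list(combinations("abcd", 2))))
        assert all(v == 0.0 for v in bt.values())

    def test_bridge_node_maximal(self):
        edges = [("a", "b"), ("b", "c"), ("a", "c"),
                 ("x", "a"), ("x", "d"),
                 ("d", "e"), ("e", "f"), ("d", "f")]
        bt = betweenness(net_from_edges(edges))
        assert max(bt, key=bt.get) == "x"

    def test_matches_enumeration_oracle_on_random_graphs(self):
        rng = np.random.default_rng(9)
        for _ in range(25):
            n = int(rng.integers(4, 8))
            nodes = [f"n{i}" for i in range(n)]
            edges = {
                tuple(sorted(rng.choice(nodes, 2, replace=False)))
                for _ in range(rng.integers(n - 1, n * 2))
            }
            net = net_from_edges(edges, extra_nodes=nodes)
            got = betweenness(net)
            expect = _betweenness_oracle(nodes, edges)
            for k in nodes:
                assert got[k] == pytest.approx(expect[k], abs=1e-9)


class TestPairSimilarity:
    def test_cosine_identical_vectors(self):
        tf = pd.DataFrame([[1, 1, 0], [1, 1, 0]], index=["a", "b"])
        assert tf_cosine_similarity(tf, [("a", "b")])[("a", "b")] == pytest.approx(1.0)

    def test_cosine_disjoint_supports(self):
        tf = pd.DataFrame([[1, 0], [0, 1]], index=["a", "b"])
        assert tf_cosine_similarity(tf, [("a", "b")])[("a", "b")] == 0.0

    def test_cosine_half_overlap(self):
        tf = pd.DataFrame([[1, 1, 0], [1, 0, 1]], index=["a", "b"])
        assert tf_cosine_similarity(tf, [("a", "b")])[("a", "b")] == pytest.approx(0.5)

    def test_all_zero_vector_scores_zero(self):
        tf = pd.DataFrame([[0, 0], [1, 1]], index=["a", "b"])
        assert tf_cosine_similarity(tf, [("a", "b")])[("a", "b")] == 0.0

    def test_missing_enhancer_errors(self):
        tf = pd.DataFrame([[1, 0]], index=["a"])
        with pytest.raises(KeyError, match="missing"):
            tf_cosine_similarity(tf, [("a", "zzz")])

    def test_nonbinary_matrix_rejected(self):
        tf = pd.DataFrame([[0.5, 1]], index=["a"])
        with pytest.raises(ValueError, match="binary"):
            tf_cosine_similarity(tf, [])


class TestMutualInformation:
    def test_identical_balanced_columns_one_bit(self, matrix_factory):
        x = np.array([0, 1] * 10, dtype=float)
        m = matrix_factory(np.column_stack([x, x]), features=["a", "b"])
        assert pair_mutual_information(m, [("a", "b")])[("a", "b")] == pytest.approx(1.0)

    def test_exactly_independent_table_zero(self, matrix_factory):
        # joint counts factorize: [[1,1],[1,1]] over 4 cells
        a = np.array([0, 0, 1, 1], dtype=float)
        b = np.array([0, 1, 0, 1], dtype=float)
        m = matrix_factory(np.column_stack([a, b]), features=["a", "b"])
        assert pair_mutual_information(m, [("a", "b")])[("a", "b")] == pytest.approx(0.0)

    def test_matches_plugin_formula(self, matrix_factory):
        # joint table [[40,10],[10,40]] over 100 cells
        a = np.array([0] * 50 + [1] * 50, dtype=float)
        b = np.array([0] * 40 + [1] * 10 + [0] * 10 + [1] * 40, dtype=float)
        m = matrix_factory(np.column_stack([a, b]), features=["a", "b"])
        expect = 0.0
        for pa, pb, pab in [(0.5, 0.5, 0.4), (0.5, 0.5, 0.1), (0.5, 0.5, 0.1), (0.5, 0.5, 0.4)]:
            expect += pab * np.log2(pab / (pa * pb))
        got = pair_mutual_information(m, [("a", "b")])[("a", "b")]
        assert got == pytest.approx(expect)

    def test_zero_variance_feature_gives_zero(self, matrix_factory):
        a = np.ones(10)
        b = np.array([0, 1] * 5, dtype=float)
        m = matrix_factory(np.column_stack([a, b]), features=["a", "b"])
        assert pair_mutual_information(m, [("a", "b")])[("a", "b")] == 0.0


def test_intra_pairs_dominate_inter_on_planted_networks(small_sim):
    """Within-module pairs: higher co-accessibility, smaller distance,
    higher TF-binding cosine than cross-module pairs."""
    from enetkit import build_network, coaccess_correlation, make_metacells
    from enetkit.network_construction import EnhancerGeneLink

    acc = small_sim.accessibility
    mm = make_metacells(acc, k=4, seed=0)
    cmap = coaccess_correlation(mm, small_sim.peaks)
    stats = {"Intra": {"co": [], "dist": [], "tf": []},
             "Inter": {"co": [], "dist": [], "tf": []}}
    for gid in small_sim.truth["modules"]:
        module_of = small_sim.truth["modules"][gid]
        links = [EnhancerGeneLink(gid, p, 0.5, 0.01) for p in module_of]
        net = build_network(links, cmap)
        part = detect_modules(net, seed=7)
        if not is_modular(part):
            continue
        pairs = classify_pairs(part)
        tfc = tf_cosine_similarity(small_sim.tf_matrix, pairs.keys())
        for (a, b), grp in pairs.items():
            stats[grp]["co"].append(cmap.get(a, b))
            stats[grp]["dist"].append(small_sim.peaks.distance(a, b))
            stats[grp]["tf"].append(tfc[(a, b)])
    assert np.mean(stats["Intra"]["co"]) > np.mean(stats["Inter"]["co"])
    assert np.mean(stats["Intra"]["dist"]) < np.mean(stats["Inter"]["dist"])
    assert np.mean(stats["Intra"]["tf"]) > np.mean(stats["Inter"]["tf"])
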