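import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from enetkit import (
    AlteredComponentDetector,
    AlteredComponentSet,
    EnhancerNetwork,
    adjacency_difference_multi,
    adjacency_difference_two,
    assign_stage_pattern,
    classify_gained_lost,
    cluster_altered,
    network_change_score,
    network_dynamic_score,
    tom_dissimilarity,
)
from enetkit.coaccessibility import CoaccessibilityMap


def sym(vals):
    C = np.array(vals, dtype=float)
    return 0.5 * (C + C.T)


def adj(n, pairs, rng=None):
    C = np.zeros((n, n))
    for (i, j), v in pairs.items():
        C[i, j] = C[j, i] = v
    return C


class TestAdjacencyDifference:
    def test_two_condition_formula(self):
        C1 = adj(2, {(0, 1): 0.3})
        C2 = adj(2, {(0, 1): 0.5})
        assert adjacency_difference_two(C1, C2)[0, 1] == pytest.approx(0.16)

    def test_equal_conditions_zero(self):
        C = adj(3, {(0, 1): 0.4, (1, 2): -0.2})
        assert np.all(adjacency_difference_two(C, C) == 0)

    def test_sign_flip_invisible(self):
        C1 = adj(2, {(0, 1): -0.4})
        C2 = adj(2, {(0, 1): 0.4})
        assert adjacency_difference_two(C1, C2)[0, 1] == 0.0

    def test_shape_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            adjacency_difference_two(np.zeros((2, 2)), np.zeros((3, 3)))

    def test_multi_condition_hand_value(self):
        # c over 3 stages = (0, 0, 0.9), mean 0.3:
        # sqrt((|0-0.09| + |0-0.09| + |0.81-0.09|)/3) = sqrt(0.30)
        Cs = [adj(2, {(0, 1): v}) for v in (0.0, 0.0, 0.9)]
        assert adjacency_difference_multi(Cs)[0, 1] == pytest.approx(
            np.sqrt(0.3), abs=1e-12
        )

    def test_condition_order_irrelevant(self):
        rng = np.random.default_rng(0)
        Cs = [sym(rng.uniform(-1, 1, (5, 5))) for _ in range(4)]
        for C in Cs:
            np.fill_diagonal(C, 0)
        D1 = adjacency_difference_multi(Cs)
        D2 = adjacency_difference_multi([Cs[2], Cs[0], Cs[3], Cs[1]])
        assert np.allclose(D1, D2)

    def test_fewer_than_three_conditions_redirected(self):
        with pytest.raises(ValueError, match="two"):
            adjacency_difference_multi([np.zeros((2, 2)), np.zeros((2, 2))])

    @given(
        st.lists(
            st.floats(min_value=-1.0, max_value=1.0), min_size=2, max_size=2
        )
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_difference_always_in_unit_interval(self, cs):
        C1 = adj(2, {(0, 1): cs[0]})
        C2 = adj(2, {(0, 1): cs[1]})
        d = adjacency_difference_two(C1, C2)[0, 1]
        assert 0.0 <= d <= 1.0


def tom_oracle(D):
    """Literal triple-loop evaluation of the dissimilarity formula."""
    p = D.shape[0]
    T = np.zeros((p, p))
    for i in range(p):
        for j in range(p):
            if i == j:
                continue
            num = sum(D[i, k] * D[k, j] for k in range(p) if k not in (i, j))
            num += D[i, j]
            row_i = sum(D[i, k] for k in range(p) if k != i)
            row_j = sum(D[j, k] for k in range(p) if k != j)
            T[i, j] = 1.0 - num / (min(row_i, row_j) + 1.0 - D[i, j])
    return T


class TestTomDissimilarity:
    def test_hand_evaluated_three_by_three(self):
        D = np.array([[0, 0.5, 0.2], [0.5, 0, 0.4], [0.2, 0.4, 0]])
        T = tom_dissimilarity(D)
        # t_12 = 1 - (0.2*0.4 + 0.5) / (min(0.7, 0.9) + 1 - 0.5)
        assert T[0, 1] == pytest.approx(1 - 0.58 / 1.2)
        assert np.allclose(np.diag(T), 0)

    def test_zero_difference_matrix_gives_all_ones(self):
        T = tom_dissimilarity(np.zeros((4, 4)))
        off = ~np.eye(4, dtype=bool)
        assert np.all(T[off] == 1.0)

    def test_matches_triple_loop_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            p = int(rng.integers(2, 9))
            D = sym(rng.uniform(0, 1, (p, p)))
            np.fill_diagonal(D, 0)
            assert np.allclose(tom_dissimilarity(D), tom_oracle(D), atol=1e-12)

    def test_invalid_entries_rejected(self):
        D = np.array([[0, 1.5], [1.5, 0]])
        with pytest.raises(ValueError):
            tom_dissimilarity(D)


class TestClusterAltered:
    def test_two_planted_blocks_recovered(self):
        ids = [f"e{i}" for i in range(6)]
        T = np.full((6, 6), 0.999)
        for blk in ([0, 1, 2], [3, 4, 5]):
            for i in blk:
                for j in blk:
                    T[i, j] = 0.1
        np.fill_diagonal(T, 0)
        result = cluster_altered(T, ids)
        assert sorted(map(sorted, result.clusters)) == [
            ["e0", "e1", "e2"],
            ["e3", "e4", "e5"],
        ]

    def test_no_change_yields_no_clusters(self):
        T = np.ones((5, 5))
        np.fill_diagonal(T, 0)
        result = cluster_altered(T, [f"e{i}" for i in range(5)])
        assert len(result) == 0
        assert len(result.unclustered) == 5

    def test_zero_cut_height_leaves_everything_unclustered(self):
        rng = np.random.default_rng(0)
        T = sym(rng.uniform(0.1, 1, (6, 6)))
        np.fill_diagonal(T, 0)
        result = cluster_altered(T, [f"e{i}" for i in range(6)], cut_height=0.0)
        assert len(result) == 0

    def test_single_enhancer_empty_result(self):
        result = cluster_altered(np.zeros((1, 1)), ["only"])
        assert len(result) == 0 and result.unclustered == {"only"}

    def test_clusters_must_be_disjoint(self):
        with pytest.raises(ValueError, match="disjoint"):
            AlteredComponentSet([{"a", "b"}, {"b", "c"}])


def _map(scores, condition=None):
    cmap = CoaccessibilityMap(condition=condition, max_dist=1e9)
    for (a, b), v in scores.items():
        cmap.set(a, b, v)
    return cmap


class TestChangeScore:
    def setup_method(self):
        self.net = EnhancerNetwork("g", {"a", "b", "c"}, {})
        self.altered = AlteredComponentSet([{"a", "b", "x"}])

    def test_single_altered_pair(self):
        h = _map({("a", "b"): 0.1})
        d = _map({("a", "b"): 0.6})
        assert network_change_score(self.net, h, d, self.altered) == pytest.approx(0.5)

    def test_no_altered_nodes_scores_zero(self):
        h = _map({("a", "b"): 0.1})
        d = _map({("a", "b"): 0.6})
        none = AlteredComponentSet([{"y", "z", "w"}])
        assert network_change_score(self.net, h, d, none) == 0.0

    def test_swapping_conditions_negates(self):
        h = _map({("a", "b"): 0.1})
        d = _map({("a", "b"): 0.6})
        fwd = network_change_score(self.net, h, d, self.altered)
        rev = network_change_score(self.net, d, h, self.altered)
        assert fwd == -rev


class TestGainedLost:
    def test_exact_decile_split(self):
        scores = {f"g{i}": float(i) for i in range(100)}
        labels = classify_gained_lost(scores, q=0.10)
        counts = {"Gained": 0, "Lost": 0, "Shared": 0}
        for v in labels.values():
            counts[v] += 1
        assert counts == {"Gained": 10, "Lost": 10, "Shared": 80}
        assert labels["g99"] == "Gained" and labels["g0"] == "Lost"

    def test_ties_resolved_deterministically(self):
        scores = {f"g{i}": 1.0 for i in range(10)}
        labels = classify_gained_lost(scores, q=0.10)
        assert sum(v == "Gained" for v in labels.values()) == 1
        assert labels == classify_gained_lost(dict(reversed(scores.items())), q=0.10)

    def test_half_quantile_leaves_no_shared(self):
        scores = {f"g{i}": float(i) for i in range(10)}
        labels = classify_gained_lost(scores, q=0.5)
        assert sum(v == "Shared" for v in labels.values()) == 0

    def test_few_genes_warns(self):
        with pytest.warns(UserWarning, match="coarse"):
            classify_gained_lost({"a": 1.0, "b": 2.0}, q=0.10)


class TestDynamicScore:
    def setup_method(self):
        self.net = EnhancerNetwork("g", {"a", "b"}, {})
        self.altered = AlteredComponentSet([{"a", "b", "x"}])

    def _maps(self, series):
        return [_map({("a", "b"): v}, condition=f"s{i}") for i, v in enumerate(series)]

    def test_equally_spaced_sums(self):
        # stage sums (0.1, 0.2, 0.3): sample sd is exactly 0.1
        assert network_dynamic_score(
            self.net, self._maps([0.1, 0.2, 0.3]), self.altered
        ) == pytest.approx(0.1)

    def test_constant_series_zero(self):
        assert network_dynamic_score(
            self.net, self._maps([0.4, 0.4, 0.4]), self.altered
        ) == pytest.approx(0.0, abs=1e-12)

    def test_hand_value(self):
        got = network_dynamic_score(self.net, self._maps([0, 0, 0.9]), self.altered)
        assert got == pytest.approx(0.5196, abs=1e-4)

    def test_too_few_stages(self):
        with pytest.raises(ValueError):
            network_dynamic_score(self.net, self._maps([1.0]), self.altered)


class TestStagePatterns:
    def setup_method(self):
        self.grouping = {"s1": "Early", "s2": "Middle", "s3": "Late"}

    def test_argmax_group(self):
        scores = {"g": {"s1": 5.0, "s2": 1.0, "s3": 1.0}}
        got = assign_stage_pattern(scores, self.grouping, {"g": True})
        assert got["g"] == "Early"
        scores = {"g": {"s1": 1.0, "s2": 1.0, "s3": 5.0}}
        assert assign_stage_pattern(scores, self.grouping, {"g": True})["g"] == "Late"

    def test_non_dynamic_network_unchanged(self):
        scores = {"g": {"s1": 9.0, "s2": 0.0, "s3": 0.0}}
        got = assign_stage_pattern(scores, self.grouping, {"g": False})
        assert got["g"] == "Unchanged"

    def test_tie_goes_to_earliest_group(self):
        scores = {"g": {"s1": 3.0, "s2": 3.0, "s3": 1.0}}
        assert assign_stage_pattern(scores, self.grouping, {"g": True})["g"] == "Early"

    def test_empty_grouping_errors(self):
        with pytest.raises(ValueError, match="empty"):
            assign_stage_pattern({}, {}, {})


class TestDetectorIntegration:
    def test_planted_block_detected_from_adjacencies(self):
        rng = np.random.default_rng(1)
        n = 10
        C1 = np.zeros((n, n))
        C2 = np.zeros((n, n))
        block = [0, 1, 2, 3]
        for i in block:
            for j in block:
                if i < j:
                    C2[i, j] = C2[j, i] = 0.7
        det = AlteredComponentDetector().fit([C1, C2], [f"e{i}" for i in range(n)])
        assert det.components_.members == {"e0", "e1", "e2", "e3"}
        assert list(det.labels_[:4]) == [0, 0, 0, 0]
        assert all(l == -1 for l in det.labels_[4:])

    def test_requires_two_conditions(self):
        with pytest.raises(ValueError):
            AlteredComponentDetector().fit([np.zeros((2, 2))], ["a", "b"])
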