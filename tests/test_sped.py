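"""Shortest Path Edit Distance: partition, lattice, graph, path, re-scorer."""

import random

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bioner.sped import (BoxLattice, SpedParams, box_score, build_graph,
                         build_lattice, common_prefix_length, partition,
                         prefix_rescore, shortest_path, sped_distance,
                         sped_path, tune_gap_cost)

L1 = SpedParams(piece_length=1)

words = st.text(alphabet=st.sampled_from("abcd -"), min_size=1, max_size=12)


def levenshtein(a: str, b: str) -> int:
    prev = list(range(len(a) + 1))
    for j, cb in enumerate(b, 1):
        cur = [j]
        for i, ca in enumerate(a, 1):
            cur.append(min(prev[i - 1] + (ca != cb), prev[i] + 1, cur[i - 1] + 1))
        prev = cur
    return prev[-1]


class TestPartition:
    @pytest.mark.parametrize("s,L,expected", [
        ("abcde", 2, ("ab", "cde")),
        ("abcd", 2, ("ab", "cd")),
        ("a", 2, ("a",)),
        ("", 3, ()),
        ("abcdefg", 3, ("abc", "defg")),
    ])
    def test_examples(self, s, L, expected):
        assert partition(s, L) == expected

    @given(words, st.integers(min_value=1, max_value=5))
    @settings(derandomize=True, max_examples=200)
    def test_concatenation_and_lengths(self, s, L):
        pieces = partition(s, L)
        assert "".join(pieces) == s
        if len(s) >= L:
            assert all(len(p) == L for p in pieces[:-1])
            assert L <= len(pieces[-1]) <= 2 * L - 1


class TestBoxScore:
    @pytest.mark.parametrize("u,v,expected", [
        ("a", "a", 0.0), ("a", "b", 1.0), ("ab", "ab", 0.5), ("aa", "aa", 0.0),
        ("ab", "cd", 1.0), ("abc", "ab", 4 / 6),
    ])
    def test_examples(self, u, v, expected):
        assert box_score(u, v) == pytest.approx(expected)

    def test_symmetric_and_bounded(self):
        rng = random.Random(0)
        for _ in range(100):
            u = "".join(rng.choice("abc") for _ in range(rng.randint(1, 4)))
            v = "".join(rng.choice("abc") for _ in range(rng.randint(1, 4)))
            assert box_score(u, v) == box_score(v, u)
            assert 0.0 <= box_score(u, v) <= 1.0

    def test_empty_piece_is_error(self):
        with pytest.raises(ValueError):
            box_score("", "a")


class TestLatticeAndGraph:
    def test_ab_ba_lattice(self):
        lat = build_lattice("ab", "ba", L1)
        assert lat.scores.tolist() == [[1.0, 0.0], [0.0, 1.0]]

    def test_identity_lattice_zero_diagonal(self):
        lat = build_lattice("abc", "abc", L1)
        assert np.allclose(np.diag(lat.scores), 0.0)

    def test_piece_count_shape(self):
        lat = build_lattice("abcd", "ab", SpedParams(piece_length=2))
        assert lat.scores.shape == (1, 2)

    def test_2x2_graph_shape(self):
        g = build_graph(build_lattice("ab", "ba", L1), 1.0)
        assert g.graph.number_of_nodes() == 5
        assert g.graph.number_of_edges() == 6

    def test_1x1_graph(self):
        g = build_graph(build_lattice("a", "b", L1), 1.0)
        assert g.graph.number_of_nodes() == 2
        assert g.graph.number_of_edges() == 1

    def test_acyclic(self):
        g = build_graph(build_lattice("abcd", "dcba", L1), 0.5)
        assert nx.is_directed_acyclic_graph(g.graph)


class TestShortestPath:
    def test_free_diagonal(self):
        lat = BoxLattice(("a", "b"), ("a", "b"),
                         np.array([[0.0, 1.0], [1.0, 0.0]]))
        r = shortest_path(build_graph(lat, 1.0))
        assert (r.weight, r.edge_count, r.normalized) == (0.0, 2, 0.0)

    def test_single_box(self):
        lat = BoxLattice(("x",), ("y",), np.array([[0.4]]))
        r = shortest_path(build_graph(lat, 1.0))
        assert (r.weight, r.edge_count, r.normalized) == (0.4, 1, 0.4)

    def test_forced_expensive_grid(self):
        lat = BoxLattice(("a", "b"), ("b", "a"),
                         np.array([[1.0, 0.0], [0.0, 1.0]]))
        r = shortest_path(build_graph(lat, 1.0))
        assert (r.weight, r.normalized) == (2.0, 1.0)

    def test_tie_break_maximizes_edges(self):
        # diagonal (1 edge, weight 1) ties two gap edges (2 edges, weight 1);
        # the longer path is preferred, minimizing the normalized score
        lat = BoxLattice(("a", "b"), ("a", "b"),
                         np.array([[0.0, 0.5], [0.5, 1.0]]))
        r = shortest_path(build_graph(lat, 0.5))
        assert r.weight == pytest.approx(1.0)
        assert r.edge_count == 3


class TestPrefixRescore:
    def test_hand_evaluation(self):
        assert prefix_rescore(0.5, 2) == pytest.approx(0.4)

    def test_zero_prefix_identity(self):
        assert prefix_rescore(0.37, 0) == 0.37

    def test_clamped_at_zero(self):
        assert prefix_rescore(0.0, 3) == 0.0

    def test_cap_limits_credit(self):
        capped = prefix_rescore(0.5, 10)
        assert capped == prefix_rescore(0.5, SpedParams().prefix_cap)

    @given(st.floats(0, 1), st.integers(0, 10))
    @settings(derandomize=True, max_examples=200)
    def test_never_increases(self, x, p):
        assert prefix_rescore(x, p) <= x + 1e-12


class TestCommonPrefix:
    @pytest.mark.parametrize("s,t,n", [
        ("abc", "abd", 2), ("x", "y", 0), ("dopamine", "dopamine", 8),
        ("", "abc", 0),
    ])
    def test_examples(self, s, t, n):
        assert common_prefix_length(s, t) == n


class TestSpedDistance:
    def test_identity(self):
        assert sped_distance("abc", "abc", L1) == 0.0

    def test_reversal_is_maximal(self):
        assert sped_distance("ab", "ba", L1) == 1.0

    def test_single_box_with_prefix_credit(self):
        assert sped_distance("ab", "ab", SpedParams(piece_length=2)) \
            == pytest.approx(0.4)

    def test_empty_conventions(self):
        assert sped_distance("", "", L1) == 0.0
        assert sped_distance("", "abc", L1) == 1.0
        assert sped_distance("abc", "", L1) == 1.0

    @given(words, words)
    @settings(derandomize=True, max_examples=150)
    def test_symmetric_and_in_range(self, s, t):
        d = sped_distance(s, t, L1)
        assert 0.0 <= d <= 1.0
        assert d == pytest.approx(sped_distance(t, s, L1))

    @given(words, words)
    @settings(derandomize=True, max_examples=150)
    def test_path_weight_bounds(self, s, t):
        r = sped_path(s, t, L1)
        assert r.weight >= levenshtein(s, t) - 1e-9
        if len(s) == len(t):
            hamming = sum(a != b for a, b in zip(s, t))
            assert r.weight <= hamming + 1e-9

    @given(words, words)
    @settings(derandomize=True, max_examples=100)
    def test_aligned_weight_fn_keeps_invariants(self, s, t):
        p = SpedParams(piece_length=1, weight_fn="aligned")
        d = sped_distance(s, t, p)
        assert 0.0 <= d <= 1.0
        assert d == pytest.approx(sped_distance(t, s, p))
        assert sped_distance(s, s, p) == 0.0


class TestTuneGapCost:
    def test_single_element_grid(self):
        assert tune_gap_cost([("ab", "ab", True)], [0.7]) == 0.7

    def test_all_tied_picks_smallest(self):
        pairs = [("aa", "aa", True), ("bb", "bb", True)]
        assert tune_gap_cost(pairs, [0.9, 0.2, 0.5]) == 0.2

    def test_separating_gap_wins(self):
        # matched pairs differ by an indel; unmatched pairs are full
        # mismatches. A large gap cost penalizes the indel-heavy match pairs
        # less than it raises the unmatched scores, widening the margin.
        pairs = [
            ("abcd", "abcd-", True), ("bcda", "bcda-", True),
            ("abcd", "dcba", False), ("acbd", "bdac", False),
        ]
        grid = [0.1, 1.0]
        best = tune_gap_cost(pairs, grid)
        # verify exhaustively against the stated objective
        from statistics import mean

        def objective(gap):
            p = SpedParams(piece_length=1, gap_cost=gap)
            m = mean(sped_distance(s, t, p) for s, t, f in pairs if f)
            n = mean(sped_distance(s, t, p) for s, t, f in pairs if not f)
            return n - m

        assert objective(best) == max(objective(g) for g in grid)

    def test_empty_grid_is_error(self):
        with pytest.raises(ValueError):
            tune_gap_cost([("a", "a", True)], [])
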