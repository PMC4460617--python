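"""Shortest Path Edit Distance (SPED) between two strings.

The two strings are cut into consecutive pieces of length L (the last piece
absorbs any remainder), every piece pair is scored by the mean character
mismatch over all character pairs of the two pieces, and the resulting score
lattice is turned into a weighted DAG: one vertex per lattice box plus a
source, diagonal edges carrying the box score, horizontal/vertical edges
carrying a gap cost. The distance is the weight of the shortest
source-to-bottom-right path divided by its edge count, then reduced by a
Jaro-Winkler-style common-prefix re-scorer and clamped to [0, 1].
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from statistics import mean
from typing import Callable, Sequence

import networkx as nx
import numpy as np

__all__ = [
    "SpedParams",
    "BoxLattice",
    "AlignmentGraph",
    "PathResult",
    "partition",
    "box_score",
    "aligned_score",
    "build_lattice",
    "build_graph",
    "shortest_path",
    "common_prefix_length",
    "prefix_rescore",
    "sped_distance",
    "tune_gap_cost",
    "WEIGHT_FNS",
]

_EPS = 1e-9


def box_score(u: str, v: str) -> float:
    """Mean character mismatch over all |u|·|v| character pairs.

    0 iff every character of u equals every character of v; 1 iff no
    character of u occurs in v. Symmetric, in [0, 1]. For pieces of unequal
    length the double sum runs over all pairs and is divided by |u|·|v|,
    which reduces to the equal-length formula when |u| = |v|.
    """
    if not u or not v:
        raise ValueError("box pieces must be non-empty")
    if len(u) == 1 and len(v) == 1:
        return 0.0 if u == v else 1.0
    mismatches = sum(1 for cu in u for cv in v if cu != cv)
    return mismatches / (len(u) * len(v))


def aligned_score(u: str, v: str) -> float:
    """Positionwise variant: mismatches at aligned positions, length excess
    counted as mismatch, divided by max(|u|, |v|)."""
    if not u or not v:
        raise ValueError("box pieces must be non-empty")
    n = min(len(u), len(v))
    mism = sum(1 for a, b in zip(u, v) if a != b) + abs(len(u) - len(v))
    return mism / max(len(u), len(v))


WEIGHT_FNS: dict[str, Callable[[str, str], float]] = {
    "eq1": box_score,
    "aligned": aligned_score,
}


@dataclass(frozen=True)
class SpedParams:
    """Tunable knobs of the distance.

    piece_length: L, the substring partition length (1 reduces the lattice
        to a per-character grid).
    gap_cost: weight of horizontal (deletion) and vertical (insertion)
        edges; selected in a learning phase via :func:`tune_gap_cost`.
    prefix_weight: strength of the common-prefix re-scorer.
    prefix_cap: maximum prefix length credited (Jaro-Winkler convention).
    weight_fn: name of the box weight function ("eq1" or "aligned").
    """

    piece_length: int = 1
    gap_cost: float = 1.0
    prefix_weight: float = 0.1
    prefix_cap: int = 4
    weight_fn: str = "eq1"

    def __post_init__(self) -> None:
        if self.piece_length < 1:
            raise ValueError("piece_length must be >= 1")
        if self.gap_cost < 0:
            raise ValueError("gap_cost must be >= 0")
        if not 0.0 <= self.prefix_weight <= 1.0:
            raise ValueError("prefix_weight must be in [0, 1]")
        if self.prefix_cap < 0:
            raise ValueError("prefix_cap must be >= 0")
        if self.weight_fn not in WEIGHT_FNS:
            raise ValueError(f"unknown weight_fn {self.weight_fn!r}")


@dataclass(frozen=True)
class BoxLattice:
    s_pieces: tuple[str, ...]
    t_pieces: tuple[str, ...]
    scores: np.ndarray  # rows = t pieces, columns = s pieces

    def __post_init__(self) -> None:
        if self.scores.shape != (len(self.t_pieces), len(self.s_pieces)):
            raise ValueError("score matrix shape does not match piece counts")


@dataclass(frozen=True)
class AlignmentGraph:
    graph: nx.DiGraph
    source: object
    target: object
    shape: tuple[int, int]  # (n_t, n_s)


@dataclass(frozen=True)
class PathResult:
    weight: float
    edge_count: int
    normalized: float


def partition(s: str, L: int) -> tuple[str, ...]:
    """Cut s into length-L pieces; the last piece absorbs the remainder.

    All pieces have length L except the last, whose length lies in
    [L, 2L-1]; a non-empty string shorter than L is its own single piece.
    """
    if L < 1:
        raise ValueError("L must be >= 1")
    n = len(s)
    if n == 0:
        return ()
    k = n // L
    if k <= 1:
        return (s,)
    return tuple(s[i * L:(i + 1) * L] for i in range(k - 1)) + (s[(k - 1) * L:],)


def build_lattice(s: str, t: str, params: SpedParams) -> BoxLattice:
    """Score every (t piece, s piece) pair; s runs along the columns."""
    if not s or not t:
        raise ValueError("lattice strings must be non-empty")
    wf = WEIGHT_FNS[params.weight_fn]
    sp = partition(s, params.piece_length)
    tp = partition(t, params.piece_length)
    scores = np.array([[wf(tpiece, spiece) for spiece in sp] for tpiece in tp],
                      dtype=float)
    return BoxLattice(sp, tp, scores)


def build_graph(lattice: BoxLattice, gap_cost: float) -> AlignmentGraph:
    """Lattice boxes become vertices (i, j), 1-based; a source vertex joins
    (1, 1) by a diagonal edge carrying that box's score. Horizontal and
    vertical edges carry the gap cost; diagonal edges the target box score.
    """
    nt, ns = lattice.scores.shape
    g = nx.DiGraph()
    src = "source"
    g.add_node(src)
    g.add_edge(src, (1, 1), weight=float(lattice.scores[0, 0]))
    for i in range(1, nt + 1):
        for j in range(1, ns + 1):
            if j > 1:
                g.add_edge((i, j - 1), (i, j), weight=gap_cost)
            if i > 1:
                g.add_edge((i - 1, j), (i, j), weight=gap_cost)
            if i > 1 and j > 1:
                g.add_edge((i - 1, j - 1), (i, j),
                           weight=float(lattice.scores[i - 1, j - 1]))
    return AlignmentGraph(g, src, (nt, ns), (nt, ns))


def shortest_path(graph: AlignmentGraph) -> PathResult:
    """Minimum-weight source→bottom-right path by topological relaxation.

    Among minimum-weight paths the one traversing the most edges is chosen
    (it minimizes the normalized score); normalized = weight / edge_count.
    """
    nt, ns = graph.shape
    best: dict[object, tuple[float, int]] = {graph.source: (0.0, 0)}
    order = [(i, j) for i in range(1, nt + 1) for j in range(1, ns + 1)]
    g = graph.graph
    for node in order:
        choice: tuple[float, int] | None = None
        for pred in g.predecessors(node):
            pw, pe = best[pred]
            cand = (pw + g.edges[pred, node]["weight"], pe + 1)
            if choice is None or cand[0] < choice[0] - _EPS or (
                    abs(cand[0] - choice[0]) <= _EPS and cand[1] > choice[1]):
                choice = cand
        best[node] = choice  # every node is reachable by construction
    weight, edges = best[graph.target]
    return PathResult(weight, edges, weight / edges)


def common_prefix_length(s: str, t: str) -> int:
    """Length of the longest common prefix of the exact strings given."""
    n = 0
    for a, b in zip(s, t):
        if a != b:
            break
        n += 1
    return n


def prefix_rescore(sped_norm: float, prefix_len: int,
                   params: SpedParams | None = None) -> float:
    """Reduce the normalized path weight for a shared prefix.

    score = SPED' − min(|prefix|, cap) · w · (1 − SPED'), clamped to [0, 1];
    never increases the score.
    """
    p = params or SpedParams()
    cred = min(prefix_len, p.prefix_cap)
    value = sped_norm - cred * p.prefix_weight * (1.0 - sped_norm)
    return max(0.0, min(1.0, value))


def sped_distance(s: str, t: str, params: SpedParams | None = None,
                  prefix_len: int | None = None) -> float:
    """Full SPED pipeline: partition → lattice → DAG → normalized shortest
    path → prefix re-score. 0 means identical, 1 maximally distant.

    ``prefix_len`` overrides the common-prefix length (used when scoring
    normalized forms but crediting the prefix of the raw forms). Empty-string
    conventions: both empty → 0, exactly one empty → 1.
    """
    p = params or SpedParams()
    if not s and not t:
        return 0.0
    if not s or not t:
        return 1.0
    lattice = build_lattice(s, t, p)
    result = shortest_path(build_graph(lattice, p.gap_cost))
    if prefix_len is None:
        prefix_len = common_prefix_length(s, t)
    return prefix_rescore(result.normalized, prefix_len, p)


def sped_path(s: str, t: str, params: SpedParams | None = None) -> PathResult:
    """Un-rescored shortest-path result (weight, edge count, normalized)."""
    p = params or SpedParams()
    if not s or not t:
        raise ValueError("sped_path requires non-empty strings")
    return shortest_path(build_graph(build_lattice(s, t, p), p.gap_cost))


def tune_gap_cost(pairs: Sequence[tuple[str, str, bool]],
                  grid: Sequence[float],
                  params: SpedParams | None = None) -> float:
    """Learning phase for the gap cost.

    Returns the grid value maximizing mean(distance over non-match pairs) −
    mean(distance over match pairs); ties (and all-tie degenerate inputs)
    resolve to the smallest grid value. A class with no pairs contributes 0.
    """
    if not grid:
        raise ValueError("gap-cost grid must be non-empty")
    p = params or SpedParams()
    best_gap: float | None = None
    best_obj = -math.inf
    for gap in grid:
        trial = replace(p, gap_cost=gap)
        match = [sped_distance(s, t, trial) for s, t, is_match in pairs if is_match]
        non = [sped_distance(s, t, trial) for s, t, is_match in pairs if not is_match]
        obj = (mean(non) if non else 0.0) - (mean(match) if match else 0.0)
        if (obj > best_obj + _EPS
                or (abs(obj - best_obj) <= _EPS
                    and best_gap is not None and gap < best_gap)):
            best_obj, best_gap = obj, gap
        elif best_gap is None:
            best_obj, best_gap = obj, gap
    return float(best_gap)
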