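"""Phase-one candidate generation: weighted approximate lookup over a trie.

The dictionary is indexed in a character trie; queries are matched under a
weighted edit distance in which case-only substitutions and swaps among the
separator characters {'-', ' ', '_'} are cheap, so the spelling-variant
families of biomedical names ("EGR-1" vs "egr 1") stay close while genuine
letter edits stay expensive. Trie traversal carries the dynamic-programming
row per prefix and prunes any branch whose best completion already exceeds
the cost threshold; its output is contractually identical to brute-force
filtering of the whole dictionary.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .dictionary import DictionaryEntry, EntityDictionary, normalize_term
from .merging import tokenize

__all__ = [
    "CostTable",
    "CandidateMatch",
    "TermIndex",
    "weighted_edit_distance",
    "approx_lookup",
    "scan_passage",
]

SEPARATORS = frozenset("- _")

_EPS = 1e-9  # absorbs float drift in threshold comparisons


@dataclass(frozen=True)
class CostTable:
    """Per-operation costs of the weighted edit distance.

    Case-only substitutions (same letter, different case) and
    separator-for-separator substitutions are far cheaper than real edits;
    inserting or deleting a separator is cheaper than a letter indel.
    """

    substitute_default: float = 1.0
    substitute_case_only: float = 0.1
    substitute_separator: float = 0.1
    indel_default: float = 1.0
    indel_separator: float = 0.2

    def __post_init__(self) -> None:
        for name in ("substitute_default", "substitute_case_only",
                     "substitute_separator", "indel_default", "indel_separator"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.substitute_case_only > self.substitute_default:
            raise ValueError("case-only substitution must not exceed default")
        if self.substitute_separator > self.substitute_default:
            raise ValueError("separator substitution must not exceed default")

    def sub(self, a: str, b: str) -> float:
        if a == b:
            return 0.0
        if a.lower() == b.lower():
            return self.substitute_case_only
        if a in SEPARATORS and b in SEPARATORS:
            return self.substitute_separator
        return self.substitute_default

    def indel(self, c: str) -> float:
        return self.indel_separator if c in SEPARATORS else self.indel_default


DEFAULT_COSTS = CostTable()

#: Unit costs reduce the distance to plain Levenshtein.
UNIT_COSTS = CostTable(1.0, 1.0, 1.0, 1.0, 1.0)


@dataclass(frozen=True)
class CandidateMatch:
    entry: DictionaryEntry
    cost: float

    def sort_key(self) -> tuple:
        return (self.cost, self.entry.surface, self.entry.entity_type,
                self.entry.source)


def weighted_edit_distance(a: str, b: str,
                           costs: CostTable = DEFAULT_COSTS) -> float:
    """Minimum total cost of an insert/delete/substitute script a → b."""
    prev = [0.0]
    for ch in a:
        prev.append(prev[-1] + costs.indel(ch))
    for cb in b:
        cur = [prev[0] + costs.indel(cb)]
        for i in range(1, len(a) + 1):
            ca = a[i - 1]
            cur.append(min(prev[i - 1] + costs.sub(ca, cb),
                           prev[i] + costs.indel(cb),
                           cur[i - 1] + costs.indel(ca)))
        prev = cur
    return prev[-1]


class _Node:
    __slots__ = ("children", "entries")

    def __init__(self) -> None:
        self.children: dict[str, _Node] = {}
        self.entries: list[DictionaryEntry] = []


class TermIndex:
    """Character trie over dictionary surfaces with per-key entry payloads.

    With ``normalized=True`` (the pipeline default) keys are the normalized
    surfaces, so whole variant families share one key; with
    ``normalized=False`` keys are the raw surfaces and the edit distance
    itself absorbs case/separator variation.
    """

    def __init__(self, dictionary: EntityDictionary, normalized: bool = True,
                 use_stemming: bool = False,
                 costs: CostTable = DEFAULT_COSTS):
        self.normalized = normalized
        self.use_stemming = use_stemming
        self.costs = costs
        self._root = _Node()
        self._n_keys = 0
        for entry in dictionary:
            key = self.key_for(entry)
            if key:
                self._insert(key, entry)

    def key_for(self, entry: DictionaryEntry) -> str:
        if self.normalized:
            return (normalize_term(entry.surface, True) if self.use_stemming
                    else entry.normalized)
        return entry.surface

    def _insert(self, key: str, entry: DictionaryEntry) -> None:
        node = self._root
        for ch in key:
            node = node.children.setdefault(ch, _Node())
        if not node.entries:
            self._n_keys += 1
        node.entries.append(entry)

    def __len__(self) -> int:
        return self._n_keys

    def lookup(self, query: str, max_cost: float) -> list[CandidateMatch]:
        """All entries within ``max_cost`` of ``query``, cheapest first.

        Cost-pruned depth-first traversal; exactly equivalent to filtering
        every key by :func:`weighted_edit_distance`.
        """
        if max_cost < 0:
            raise ValueError("max_cost must be >= 0")
        costs = self.costs
        limit = max_cost + _EPS
        first = [0.0]
        for ch in query:
            first.append(first[-1] + costs.indel(ch))
        out: list[CandidateMatch] = []
        stack: list[tuple[_Node, list[float]]] = [(self._root, first)]
        while stack:
            node, row = stack.pop()
            if node.entries and row[-1] <= limit:
                out.extend(CandidateMatch(e, row[-1]) for e in node.entries)
            for ch, child in node.children.items():
                cur = [row[0] + costs.indel(ch)]
                for i in range(1, len(query) + 1):
                    ca = query[i - 1]
                    cur.append(min(row[i - 1] + costs.sub(ca, ch),
                                   row[i] + costs.indel(ch),
                                   cur[i - 1] + costs.indel(ca)))
                if min(cur) <= limit:
                    stack.append((child, cur))
        out.sort(key=CandidateMatch.sort_key)
        return out


def approx_lookup(index: TermIndex, query: str,
                  max_cost: float) -> list[CandidateMatch]:
    """Dictionary entries within ``max_cost`` of ``query``, sorted by cost."""
    return index.lookup(query, max_cost)


def scan_passage(index: TermIndex, text: str, max_cost: float,
                 max_span_tokens: int,
                 use_stemming: Optional[bool] = None,
                 ) -> list[tuple[tuple[int, int], list[CandidateMatch]]]:
    """Approximate-match every token-aligned span of 1..max_span_tokens tokens.

    Span queries are normalized before lookup; spans whose normalized form is
    empty (pure punctuation) are skipped. Returns spans with at least one
    candidate, in ascending (start, end) order of 0-based half-open character
    offsets into the original text.
    """
    if max_span_tokens < 1:
        raise ValueError("max_span_tokens must be >= 1")
    stemming = index.use_stemming if use_stemming is None else use_stemming
    tokens = tokenize(text)
    cache: dict[str, list[CandidateMatch]] = {}
    out: list[tuple[tuple[int, int], list[CandidateMatch]]] = []
    for i in range(len(tokens)):
        for j in range(i, min(i + max_span_tokens, len(tokens))):
            start, end = tokens[i].start, tokens[j].end
            query = normalize_term(text[start:end], stemming)
            if not query:
                continue
            if query not in cache:
                cache[query] = index.lookup(query, max_cost)
            if cache[query]:
                out.append(((start, end), cache[query]))
    return out
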