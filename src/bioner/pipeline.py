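"""End-to-end extraction: approximate lookup → SPED re-ranking → merging.

For every token-aligned span of a passage, candidate dictionary entries are
generated by cost-bounded approximate lookup. A candidate whose normalized
surface equals the span's normalized text is a perfect match and is selected
immediately with score 0; otherwise surviving candidates are re-scored by
the shortest-path edit distance and must clear an acceptance threshold. The
best candidate per span wins by (score, source priority, longest surface,
lexicographic order); overlapping candidate mentions are then collapsed by
the POS/stem merging rule and a lowest-score-then-longest overlap policy.

Modes mirror the experimental arms: "all" (SPED + merging), "sped_only"
(no merging), "context_only" (no SPED re-scoring), plus "exact" — the
first-generation verbatim-lookup baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from .approx_match import CandidateMatch, TermIndex, scan_passage
from .dictionary import EntityDictionary, Passage, normalize_term
from .merging import Mention, merge_mentions, pos_tag, tokenize
from .sped import SpedParams, common_prefix_length, sped_distance

__all__ = [
    "MODES",
    "PipelineConfig",
    "SpanRecord",
    "ExtractionTrace",
    "Extractor",
    "extract_entities",
    "run_corpus",
]

MODES = ("all", "context_only", "sped_only", "exact")


@dataclass(frozen=True)
class PipelineConfig:
    mode: str = "all"
    max_cost: float = 0.6
    max_span_tokens: int = 4
    sped: SpedParams = field(default_factory=SpedParams)
    sped_accept_threshold: float = 0.3
    source_priority: Optional[tuple[str, ...]] = None
    use_stemming: bool = False
    merge_noun_only: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.max_cost < 0:
            raise ValueError("max_cost must be >= 0")
        if self.max_span_tokens < 1:
            raise ValueError("max_span_tokens must be >= 1")
        if not 0.0 <= self.sped_accept_threshold <= 1.0:
            raise ValueError("sped_accept_threshold must be in [0, 1]")

    @classmethod
    def from_toml(cls, path: str | Path) -> "PipelineConfig":
        """Load a config from a flat TOML file with an optional [sped] table."""
        import tomllib

        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        sped_kwargs = data.pop("sped", {})
        if "source_priority" in data and data["source_priority"] is not None:
            data["source_priority"] = tuple(data["source_priority"])
        return cls(sped=SpedParams(**sped_kwargs), **data)


@dataclass
class SpanRecord:
    start: int
    end: int
    n_candidates: int
    short_circuit: bool
    selected: bool
    score: Optional[float] = None
    entity_type: Optional[str] = None


@dataclass
class ExtractionTrace:
    """Observability record: one entry per candidate span, plus merge and
    overlap-suppression events."""

    spans: list[SpanRecord] = field(default_factory=list)
    merges: list[tuple[tuple[int, int], tuple[int, int]]] = field(default_factory=list)
    suppressed: list[tuple[int, int]] = field(default_factory=list)


class Extractor:
    """Reusable extractor holding the trie index for one dictionary."""

    def __init__(self, dictionary: EntityDictionary,
                 config: PipelineConfig | None = None):
        if len(dictionary) == 0:
            raise ValueError("cannot extract with an empty dictionary")
        self.dictionary = dictionary
        self.config = config or PipelineConfig()
        self.index = TermIndex(dictionary, normalized=True,
                               use_stemming=self.config.use_stemming)
        priority = self.config.source_priority or dictionary.source_priority
        self._rank = {s: i for i, s in enumerate(priority)}
        if self.config.mode == "exact":
            self._surface_map: dict[str, list] = {}
            for e in dictionary:
                self._surface_map.setdefault(e.surface, []).append(e)

    def _srcrank(self, entry) -> int:
        return self._rank.get(entry.source, len(self._rank))

    def _pick(self, scored: list[tuple[float, CandidateMatch]]
              ) -> tuple[float, CandidateMatch]:
        return min(scored, key=lambda sc: (
            sc[0], self._srcrank(sc[1].entry), -len(sc[1].entry.surface),
            sc[1].entry.surface, sc[1].entry.entity_type))

    def extract(self, text: str) -> tuple[list[Mention], ExtractionTrace]:
        trace = ExtractionTrace()
        if not text.strip():
            return [], trace
        cfg = self.config
        if cfg.mode == "exact":
            mentions = self._exact_scan(text, trace)
        else:
            mentions = self._approx_scan(text, trace)

        if cfg.mode in ("all", "context_only"):
            tokens = pos_tag(tokenize(text))
            mentions = merge_mentions(
                mentions, tokens, allow_adj_num=not cfg.merge_noun_only,
                on_merge=lambda rm, kp: trace.merges.append(
                    ((rm.start, rm.end), (kp.start, kp.end))))
        mentions = self._resolve_overlaps(mentions, trace)
        return sorted(mentions, key=lambda m: (m.start, m.end, m.entity_type)), trace

    def _exact_scan(self, text: str, trace: ExtractionTrace) -> list[Mention]:
        tokens = tokenize(text)
        out: list[Mention] = []
        for i in range(len(tokens)):
            for j in range(i, min(i + self.config.max_span_tokens, len(tokens))):
                start, end = tokens[i].start, tokens[j].end
                entries = self._surface_map.get(text[start:end])
                if not entries:
                    continue
                best = min(entries, key=lambda e: (
                    self._srcrank(e), -len(e.surface), e.surface, e.entity_type))
                out.append(Mention(start, end, text[start:end],
                                   best.entity_type, 0.0, best))
                trace.spans.append(SpanRecord(start, end, len(entries), True,
                                              True, 0.0, best.entity_type))
        return out

    def _approx_scan(self, text: str, trace: ExtractionTrace) -> list[Mention]:
        cfg = self.config
        out: list[Mention] = []
        for (start, end), candidates in scan_passage(
                self.index, text, cfg.max_cost, cfg.max_span_tokens):
            raw = text[start:end]
            norm = normalize_term(raw, cfg.use_stemming)
            perfect = [c for c in candidates if self.index.key_for(c.entry) == norm]
            if perfect:
                score, best = self._pick([(0.0, c) for c in perfect])
                out.append(Mention(start, end, raw, best.entry.entity_type,
                                   0.0, best.entry))
                trace.spans.append(SpanRecord(start, end, len(candidates), True,
                                              True, 0.0, best.entry.entity_type))
                continue
            if cfg.mode == "context_only":
                score, best = self._pick([(c.cost, c) for c in candidates])
                out.append(Mention(start, end, raw, best.entry.entity_type,
                                   score, best.entry))
                trace.spans.append(SpanRecord(start, end, len(candidates), False,
                                              True, score, best.entry.entity_type))
                continue
            scored = []
            for c in candidates:
                s = sped_distance(
                    norm, self.index.key_for(c.entry), cfg.sped,
                    prefix_len=common_prefix_length(raw, c.entry.surface))
                if s <= cfg.sped_accept_threshold + 1e-9:
                    scored.append((s, c))
            if not scored:
                trace.spans.append(SpanRecord(start, end, len(candidates),
                                              False, False))
                continue
            score, best = self._pick(scored)
            out.append(Mention(start, end, raw, best.entry.entity_type,
                               score, best.entry))
            trace.spans.append(SpanRecord(start, end, len(candidates), False,
                                          True, score, best.entry.entity_type))
        return out

    @staticmethod
    def _resolve_overlaps(mentions: Sequence[Mention],
                          trace: ExtractionTrace) -> list[Mention]:
        kept: list[Mention] = []
        order = sorted(mentions, key=lambda m: (
            m.score, -m.length, m.start, m.end, m.entity_type))
        for m in order:
            clash = any(k.entity_type == m.entity_type
                        and k.start < m.end and m.start < k.end for k in kept)
            if clash:
                trace.suppressed.append((m.start, m.end))
            else:
                kept.append(m)
        return kept


def extract_entities(text: str, dictionary: EntityDictionary,
                     config: PipelineConfig | None = None,
                     ) -> tuple[list[Mention], ExtractionTrace]:
    """One-shot extraction; builds a fresh :class:`Extractor` per call."""
    return Extractor(dictionary, config).extract(text)


def run_corpus(passages: Sequence[Passage], dictionary: EntityDictionary,
               config: PipelineConfig | None = None) -> list[list[Mention]]:
    """Extract mentions for every passage with a shared index."""
    ex = Extractor(dictionary, config)
    return [ex.extract(p.text)[0] for p in passages]
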