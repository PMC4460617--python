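"""Tokenization, lightweight POS tagging, stemming, and mention merging.

Overlapping candidate mentions produced by dictionary lookup are collapsed by
a four-condition rule: the shorter mention is merged into the longer one when
(1) both start at the same character, (2) they carry the same entity type,
(3) every token touching either mention is nominal (noun / adjective /
numeral), and (4) the shorter mention's stemmed token sequence is a prefix of
the longer's. Conditions (3) and (4) are the POS and lexical-similarity cues;
condition (2) is the contextual (top-category) cue.
"""

from __future__ import annotations

import re
import string
from dataclasses import dataclass, replace
from typing import Callable, Iterable, Optional, Sequence

from ._porter import stem_word

__all__ = [
    "Token",
    "Mention",
    "tokenize",
    "pos_tag",
    "stem",
    "merge_mentions",
]

_PUNCT = frozenset(string.punctuation)

POS_TAGS = ("NOUN", "ADJ", "VERB", "NUM", "OTHER")


@dataclass(frozen=True)
class Token:
    """A passage token: exact text, 0-based character offset, POS tag."""

    text: str
    start: int
    pos: str = "NOUN"

    @property
    def end(self) -> int:
        return self.start + len(self.text)


@dataclass(frozen=True)
class Mention:
    """A typed character span (0-based, half-open) in a passage."""

    start: int
    end: int
    surface: str
    entity_type: str
    score: float = 0.0
    matched_entry: Optional[object] = None  # DictionaryEntry when matched

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid mention span [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start

    def span_key(self) -> tuple[int, int, str]:
        return (self.start, self.end, self.entity_type)


def tokenize(text: str) -> list[Token]:
    """Split on whitespace, detaching edge punctuation as single-char tokens.

    Internal punctuation (hyphens in "EGR-1", periods in "E. coli") is kept
    inside the token. Offsets index the original text exactly.
    """
    tokens: list[Token] = []
    for m in re.finditer(r"\S+", text):
        chunk, base = m.group(), m.start()
        i, j = 0, len(chunk)
        while i < j - 1 and chunk[i] in _PUNCT:
            tokens.append(Token(chunk[i], base + i))
            i += 1
        trailing: list[Token] = []
        while j - 1 > i and chunk[j - 1] in _PUNCT:
            trailing.append(Token(chunk[j - 1], base + j - 1))
            j -= 1
        tokens.append(Token(chunk[i:j], base + i))
        tokens.extend(reversed(trailing))
    return tokens


# Small closed-class lists: enough to keep function words and copulas out of
# noun phrases without any model download.
_FUNCTION_WORDS = frozenset("""
    the a an of in on at by for with to from and or but as that this these
    those it its we they i you he she not no than then there here between
    into over under about after before during while if because so both each
    per via within without also however thus very more most less least such
    other same which when where who whom whose what how all any some few
    several most against through although since whether yet nor once
""".split())

_VERB_WORDS = frozenset("""
    is are was were be been being am has have had do does did can could may
    might must shall should will would show shows showed shown suggest
    suggests suggested indicate indicates indicated observe observes observed
    measure measures measured express expresses expressed induce induces
    induced inhibit inhibits inhibited activate activates activated bind
    binds bound regulate regulates regulated increase increases increased
    decrease decreases decreased found find reveal reveals revealed report
    reports reported perform performs performed use uses used
""".split())

# bases for the -ing/-ed morphological verb rule
_VERB_STEMS = frozenset("""
    show suggest indicat observ measur express induc inhibit activat bind
    regulat increas decreas reveal report perform us stain treat incubat
    analyz detect
""".split())

_ADJ_SUFFIXES = ("ous", "ive", "ible", "able", "ary", "ual", "ferous")


def _tag_one(text: str) -> str:
    low = text.lower()
    if all(c in _PUNCT for c in text):
        return "OTHER"
    if low in _FUNCTION_WORDS:
        return "OTHER"
    if low in _VERB_WORDS:
        return "VERB"
    if text[0].isdigit():
        return "NUM"
    if low.endswith("ly"):
        return "OTHER"
    if low.endswith("ing") and low[:-3] in _VERB_STEMS:
        return "VERB"
    if low.endswith("ed") and (low[:-2] in _VERB_STEMS or low[:-1] in _VERB_STEMS):
        return "VERB"
    if low.endswith(_ADJ_SUFFIXES):
        return "ADJ"
    return "NOUN"


def pos_tag(tokens: Sequence[Token],
            tagger: Callable[[str], str] | None = None) -> list[Token]:
    """Assign a POS tag to every token.

    The default tagger is deterministic and rule-based; any callable mapping
    token text to a tag in :data:`POS_TAGS` may be injected instead.
    """
    tag = tagger or _tag_one
    return [replace(t, pos=tag(t.text)) for t in tokens]


def stem(word: str) -> str:
    """Porter stem of a single word (lowercased)."""
    return stem_word(word)


def _overlapping_tokens(m: Mention, tokens: Sequence[Token]) -> list[Token]:
    return [t for t in tokens if t.start < m.end and t.end > m.start]


def _stems(m: Mention, tokens: Sequence[Token]) -> tuple[str, ...]:
    return tuple(stem(t.text) for t in _overlapping_tokens(m, tokens))


def merge_mentions(mentions: Iterable[Mention], tokens: Sequence[Token],
                   allow_adj_num: bool = True,
                   on_merge: Callable[[Mention, Mention], None] | None = None,
                   ) -> list[Mention]:
    """Merge shorter mentions into longer ones under the four-condition rule.

    Iterates to a fixed point; the result is a subset of the input, sorted by
    (start, descending length). ``allow_adj_num=False`` restricts condition
    (3) to pure-NOUN spans. ``on_merge(removed, kept)`` is called per event.
    """
    nominal = {"NOUN", "ADJ", "NUM"} if allow_adj_num else {"NOUN"}
    current: list[Mention] = sorted(
        mentions, key=lambda m: (m.start, -m.length, m.end, m.entity_type, m.score))

    # drop exact duplicates of (start, end, type), keeping the best score
    seen: dict[tuple[int, int, str], Mention] = {}
    for m in current:
        key = m.span_key()
        if key not in seen or m.score < seen[key].score:
            seen[key] = m
    current = sorted(
        seen.values(), key=lambda m: (m.start, -m.length, m.end, m.entity_type))

    def cond3(a: Mention, b: Mention) -> bool:
        toks = _overlapping_tokens(a, tokens) + _overlapping_tokens(b, tokens)
        return all(t.pos in nominal for t in toks)

    changed = True
    while changed:
        changed = False
        for shorter in current:
            for longer in current:
                if longer is shorter:
                    continue
                if (shorter.start == longer.start
                        and shorter.length < longer.length
                        and shorter.entity_type == longer.entity_type
                        and cond3(shorter, longer)):
                    s_stems = _stems(shorter, tokens)
                    l_stems = _stems(longer, tokens)
                    if s_stems == l_stems[: len(s_stems)]:
                        current.remove(shorter)
                        if on_merge is not None:
                            on_merge(shorter, longer)
                        changed = True
                        break
            if changed:
                break

    return sorted(current, key=lambda m: (m.start, -m.length, m.end, m.entity_type))
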