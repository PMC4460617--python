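"""Strict-match scoring, k-fold splitting, and IOB2 reading/writing.

A prediction is correct only when span boundaries and entity type both match
a gold mention (the JNLPBA convention); precision = TP/(TP+FP), recall =
TP/(TP+FN), and F1 is their harmonic mean, with 0/0 defined as 0.
"""

from __future__ import annotations

import random
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from .dictionary import Passage
from .merging import Mention

__all__ = [
    "EvalCounts",
    "Metrics",
    "FoldAssignment",
    "count_matches",
    "metrics",
    "f_measure",
    "kfold_split",
    "read_iob2",
    "write_iob2",
    "evaluate_corpus",
]


@dataclass(frozen=True)
class EvalCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("counts must be non-negative")

    def __add__(self, other: "EvalCounts") -> "EvalCounts":
        return EvalCounts(self.tp + other.tp, self.fp + other.fp,
                          self.fn + other.fn)


@dataclass(frozen=True)
class Metrics:
    precision: float
    recall: float
    f1: float

    def as_percent(self) -> tuple[float, float, float]:
        return (100 * self.precision, 100 * self.recall, 100 * self.f1)


@dataclass(frozen=True)
class FoldAssignment:
    folds: tuple[int, ...]  # fold index per item
    k: int
    seed: int

    def indices(self, fold: int) -> tuple[int, ...]:
        return tuple(i for i, f in enumerate(self.folds) if f == fold)


def count_matches(gold: Sequence[Mention], pred: Sequence[Mention]) -> EvalCounts:
    """One-to-one strict matching on (start, end, entity_type)."""
    g = Counter(m.span_key() for m in gold)
    p = Counter(m.span_key() for m in pred)
    tp = sum((g & p).values())
    return EvalCounts(tp, len(pred) - tp, len(gold) - tp)


def metrics(counts: EvalCounts) -> Metrics:
    tp, fp, fn = counts.tp, counts.fp, counts.fn
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    return Metrics(precision, recall, f_measure(precision, recall))


def f_measure(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall, on whatever scale both share."""
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def kfold_split(n_items: int, k: int, seed: int) -> FoldAssignment:
    """Seeded shuffle then round-robin assignment into k folds.

    Fold sizes differ by at most one; deterministic per seed.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if n_items < k:
        raise ValueError("need at least k items")
    order = list(range(n_items))
    random.Random(seed).shuffle(order)
    folds = [0] * n_items
    for pos, item in enumerate(order):
        folds[item] = pos % k
    return FoldAssignment(tuple(folds), k, seed)


def evaluate_corpus(gold: Sequence[Passage],
                    predictions: Sequence[Sequence[Mention]]) -> Metrics:
    """Aggregate strict-match metrics over aligned passage lists."""
    if len(gold) != len(predictions):
        raise ValueError("gold and prediction lists must align")
    total = EvalCounts()
    for g, p in zip(gold, predictions):
        total = total + count_matches(g.mentions, p)
    return metrics(total)


def _split_tag(tag: str, path: Path, lineno: int) -> tuple[str, str]:
    if tag == "O":
        return ("O", "")
    if len(tag) > 2 and tag[1] == "-" and tag[0] in "BI":
        return (tag[0], tag[2:])
    raise ValueError(f"{path}:{lineno}: malformed IOB2 tag {tag!r}")


def read_iob2(path: str | Path, strict: bool = True) -> list[Passage]:
    """Read token<TAB>tag sentences; B-/I- runs become mention spans over
    the single-space-joined sentence text.

    In strict mode an I- tag without a preceding B-/I- of the same type is
    an error naming the line; with ``strict=False`` it is repaired to B-.
    """
    path = Path(path)
    passages: list[Passage] = []
    sentence: list[tuple[str, str, str]] = []  # (token, marker, type)
    start_line = 1

    def flush(first_line: int) -> None:
        if not sentence:
            return
        offsets, pos = [], 0
        for tok, _, _ in sentence:
            offsets.append(pos)
            pos += len(tok) + 1
        text = " ".join(tok for tok, _, _ in sentence)
        mentions: list[Mention] = []
        open_span = None  # (start_index, type)
        for idx, (tok, marker, etype) in enumerate(sentence + [("", "O", "")]):
            if open_span is not None and (
                    marker != "I" or etype != open_span[1]):
                s = offsets[open_span[0]]
                e = offsets[idx - 1] + len(sentence[idx - 1][0])
                mentions.append(Mention(s, e, text[s:e], open_span[1]))
                open_span = None
            if marker == "B":
                open_span = (idx, etype)
            elif marker == "I" and open_span is None:
                open_span = (idx, etype)  # lenient repair; strict raised earlier
        passages.append(Passage(doc_id=str(len(passages)), text=text,
                                mentions=tuple(mentions)))
        sentence.clear()

    with path.open(encoding="utf-8") as fh:
        prev: tuple[str, str] = ("O", "")
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip():
                flush(start_line)
                start_line = lineno + 1
                prev = ("O", "")
                continue
            if "\t" not in line:
                raise ValueError(f"{path}:{lineno}: expected token<TAB>tag")
            token, tag = line.split("\t", 1)
            marker, etype = _split_tag(tag, path, lineno)
            if marker == "I" and strict and not (
                    prev[0] in "BI" and prev[1] == etype):
                raise ValueError(
                    f"{path}:{lineno}: I-{etype} without preceding B-/I-{etype}")
            sentence.append((token, marker, etype))
            prev = (marker, etype)
        flush(start_line)
    return passages


def write_iob2(passages: Sequence[Passage], path: str | Path) -> None:
    """Write passages as IOB2; inverse of :func:`read_iob2` on valid input.

    Mentions must align with whitespace token boundaries and must not
    overlap; each sentence block ends with a blank line.
    """
    path = Path(path)
    lines: list[str] = []
    for ps in passages:
        toks, offsets, pos = [], [], 0
        for tok in ps.text.split(" "):
            toks.append(tok)
            offsets.append(pos)
            pos += len(tok) + 1
        tags = ["O"] * len(toks)
        for m in sorted(ps.mentions, key=lambda m: (m.start, m.end)):
            covered = [i for i, (o, t) in enumerate(zip(offsets, toks))
                       if o >= m.start and o + len(t) <= m.end]
            if (not covered or offsets[covered[0]] != m.start
                    or offsets[covered[-1]] + len(toks[covered[-1]]) != m.end):
                raise ValueError(
                    f"mention [{m.start},{m.end}) in {ps.doc_id!r} is not "
                    f"token-aligned")
            if any(tags[i] != "O" for i in covered):
                raise ValueError(
                    f"overlapping mentions in {ps.doc_id!r} cannot be encoded")
            tags[covered[0]] = f"B-{m.entity_type}"
            for i in covered[1:]:
                tags[i] = f"I-{m.entity_type}"
        lines.extend(f"{tok}\t{tag}" for tok, tag in zip(toks, tags))
        lines.append("")
    path.write_text("\n".join(lines) + ("\n" if lines else ""), encoding="utf-8")
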