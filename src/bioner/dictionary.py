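"""Entity dictionaries: normalization, loading, merging, and synthesis.

A dictionary maps surface terms to entity-type labels with source provenance
(e.g. a GENIA-style corpus export, a MeSH-tree table, a UMLS-style TSV).
Terms from a tree-structured vocabulary are mapped to their top-level branch
label, so e.g. every descriptor under tree C becomes "Diseases".

The synthetic-corpus generator embeds dictionary terms in neutral filler
text, optionally rewriting a fraction of them into case/separator spelling
variants (the "EGR-1" / "Egr 1" / "egr-1" family), and records gold spans.
"""

from __future__ import annotations

import random
import re
import string
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from ._porter import stem_word
from .merging import Mention

__all__ = [
    "DictionaryEntry",
    "EntityDictionary",
    "Passage",
    "SyntheticCorpus",
    "MESH_CATEGORIES",
    "normalize_term",
    "load_tsv",
    "save_tsv",
    "load_tree_map",
    "merge_dictionaries",
    "generate_variants",
    "synth_dictionary",
    "synth_corpus",
]

#: The 16 top-level MeSH branch labels, keyed by tree-number letter.
MESH_CATEGORIES: dict[str, str] = {
    "A": "Anatomy",
    "B": "Organisms",
    "C": "Diseases",
    "D": "Chemicals and Drugs",
    "E": "Analytical, Diagnostic and Therapeutic Techniques and Equipment",
    "F": "Psychiatry and Psychology",
    "G": "Phenomena and Processes",
    "H": "Disciplines and Occupations",
    "I": "Anthropology, Education, Sociology and Social Phenomena",
    "J": "Technology, Industry, Agriculture",
    "K": "Humanities",
    "L": "Information Science",
    "M": "Named Groups",
    "N": "Health Care",
    "V": "Publication Characteristics",
    "Z": "Geographicals",
}

_EDGE_PUNCT = string.punctuation + string.whitespace


def normalize_term(term: str, use_stemming: bool = False) -> str:
    """Canonical form of a term: lowercase, separators to single spaces.

    Hyphens and underscores become spaces, whitespace runs collapse, and
    leading/trailing punctuation is stripped, so the whole spelling-variant
    family of e.g. "EGR-1" maps to "egr 1". With ``use_stemming`` each token
    is additionally replaced by its Porter stem. Idempotent.
    """
    s = term.lower().replace("-", " ").replace("_", " ")
    s = s.strip(_EDGE_PUNCT)
    s = " ".join(s.split())
    if use_stemming:
        s = " ".join(stem_word(tok) for tok in s.split())
    return s


@dataclass(frozen=True)
class DictionaryEntry:
    surface: str
    entity_type: str
    source: str
    normalized: str = ""
    concept_id: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.surface:
            raise ValueError("entry surface must be non-empty")
        if not self.entity_type:
            raise ValueError("entry entity_type must be non-empty")
        if not self.normalized:
            object.__setattr__(self, "normalized", normalize_term(self.surface))

    def key(self) -> tuple[str, str, str]:
        return (self.normalized, self.entity_type, self.source)


class EntityDictionary:
    """A deduplicated collection of entries plus an ordered source priority."""

    def __init__(self, entries: Iterable[DictionaryEntry],
                 source_priority: Sequence[str] | None = None):
        seen: dict[tuple[str, str, str], DictionaryEntry] = {}
        for e in entries:
            seen.setdefault(e.key(), e)
        self.entries: tuple[DictionaryEntry, ...] = tuple(seen.values())
        present = []
        for e in self.entries:
            if e.source not in present:
                present.append(e.source)
        if source_priority is None:
            source_priority = present
        missing = [s for s in present if s not in source_priority]
        if missing:
            raise ValueError(f"sources missing from priority list: {missing}")
        self.source_priority: tuple[str, ...] = tuple(source_priority)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def sources(self) -> tuple[str, ...]:
        return self.source_priority

    def source_rank(self, source: str) -> int:
        try:
            return self.source_priority.index(source)
        except ValueError:
            return len(self.source_priority)

    def subset(self, sources: Sequence[str]) -> "EntityDictionary":
        keep = set(sources)
        return EntityDictionary(
            [e for e in self.entries if e.source in keep],
            [s for s in self.source_priority if s in keep])

    def entry_keys(self) -> frozenset[tuple[str, str, str]]:
        return frozenset(e.key() for e in self.entries)


@dataclass(frozen=True)
class Passage:
    """A text passage with (gold) mentions."""

    doc_id: str
    text: str
    mentions: tuple[Mention, ...] = ()

    def __post_init__(self) -> None:
        for m in self.mentions:
            if not (0 <= m.start < m.end <= len(self.text)):
                raise ValueError(f"mention {m} outside passage {self.doc_id!r}")
            if self.text[m.start:m.end] != m.surface:
                raise ValueError(f"mention surface mismatch in {self.doc_id!r}")


@dataclass(frozen=True)
class SyntheticCorpus:
    passages: tuple[Passage, ...]
    dictionary: EntityDictionary
    seed: int
    variant_rate: float


def load_tsv(path: str | Path) -> EntityDictionary:
    """Read a dictionary TSV: surface<TAB>entity_type[<TAB>source[<TAB>concept_id]].

    Lines starting with '#' and blank lines are skipped; a missing source
    column defaults to the file stem. Duplicate (normalized, type, source)
    rows collapse to one entry.
    """
    path = Path(path)
    default_source = path.stem
    entries: list[DictionaryEntry] = []
    with path.open(encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2 or not fields[0].strip() or not fields[1].strip():
                raise ValueError(f"{path}:{lineno}: expected at least "
                                 f"surface<TAB>entity_type, got {line!r}")
            surface, entity_type = fields[0].strip(), fields[1].strip()
            source = fields[2].strip() if len(fields) > 2 and fields[2].strip() else default_source
            concept = fields[3].strip() if len(fields) > 3 and fields[3].strip() else None
            entries.append(DictionaryEntry(surface, entity_type, source,
                                           concept_id=concept))
    return EntityDictionary(entries)


def save_tsv(dictionary: EntityDictionary, path: str | Path) -> None:
    """Write a dictionary in the TSV dialect read by :func:`load_tsv`."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("# surface\tentity_type\tsource\tconcept_id\n")
        for e in sorted(dictionary.entries, key=lambda e: e.key()):
            fh.write(f"{e.surface}\t{e.entity_type}\t{e.source}\t{e.concept_id or ''}\n")


def load_tree_map(path: str | Path,
                  category_names: Mapping[str, str] | None = None,
                  source: str | None = None) -> EntityDictionary:
    """Read a two-column term<TAB>tree-number table, typing each term by the
    top-level branch label of its tree number's leading letter.

    A term listed under several tree numbers yields one entry per distinct
    resulting label. Unknown branch letters raise an error naming the letter.
    """
    path = Path(path)
    cats = dict(MESH_CATEGORIES if category_names is None else category_names)
    src = source or path.stem
    entries: list[DictionaryEntry] = []
    with path.open(encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2 or not fields[0].strip() or not fields[1].strip():
                raise ValueError(f"{path}:{lineno}: expected term<TAB>tree-number")
            term, tree = fields[0].strip(), fields[1].strip()
            letter = tree[0].upper()
            if letter not in cats:
                raise ValueError(
                    f"{path}:{lineno}: tree-number letter {letter!r} not in "
                    f"category mapping")
            entries.append(DictionaryEntry(term, cats[letter], src, concept_id=tree))
    return EntityDictionary(entries)


def merge_dictionaries(dicts: Sequence[EntityDictionary],
                       priority: Sequence[str] | None = None) -> EntityDictionary:
    """Union of dictionaries with provenance preserved.

    Conflicting entity types for the same normalized surface are all kept;
    disambiguation happens at extraction time through the source priority.
    """
    entries = [e for d in dicts for e in d.entries]
    if priority is None:
        priority = []
        for d in dicts:
            for s in d.source_priority:
                if s not in priority:
                    priority.append(s)
    return EntityDictionary(entries, priority)


_ALPHA_RUN = re.compile(r"[A-Za-z]+")


def _apply_case(term: str, pattern: str) -> str:
    def repl(m: re.Match) -> str:
        run = m.group()
        if pattern == "upper":
            return run.upper()
        if pattern == "lower":
            return run.lower()
        return run[0].upper() + run[1:].lower()

    return _ALPHA_RUN.sub(repl, term)


def generate_variants(term: str) -> set[str]:
    """Deterministic case/separator spelling variants of a term.

    Crosses case patterns {UPPER, Capitalized, lower} on alphabetic runs with
    separator substitutions {hyphen→space, space→hyphen, unchanged}; the
    original term is excluded. Every variant normalizes to the same key as
    the input ("EGR-1" → {"Egr-1", "Egr 1", "egr-1", "egr 1", "EGR 1", ...}).
    """
    if not term:
        raise ValueError("term must be non-empty")
    seps = {term, term.replace("-", " "), term.replace(" ", "-")}
    out: set[str] = set()
    for s in seps:
        for pattern in ("upper", "capitalized", "lower"):
            out.add(_apply_case(s, pattern))
    out.discard(term)
    return out


# Fixed neutral filler vocabulary for synthetic passages. Chosen to be common
# scientific-English function/context words unlikely to collide with entity
# surfaces; collisions with the supplied dictionary are filtered at run time.
FILLER_VOCABULARY: tuple[str, ...] = (
    "the", "a", "an", "of", "in", "on", "for", "with", "was", "were",
    "observed", "measured", "after", "before", "during", "treatment",
    "analysis", "results", "showed", "levels", "effect", "response",
    "study", "samples", "compared", "control", "group", "significant",
    "increase", "decrease", "expression", "activity", "role", "data",
    "method", "present", "findings", "approach", "evaluated", "under",
    "conditions", "reported", "further", "between", "within", "values",
    "obtained", "total", "relative", "changes",
)


def synth_dictionary(n_terms: int = 120,
                     sources: Sequence[str] = ("alpha", "beta"),
                     entity_types: Sequence[str] = (
                         "protein", "DNA", "cell_type", "chemical", "disease"),
                     seed: int = 0) -> EntityDictionary:
    """Generate a multi-source dictionary of invented, unambiguous terms.

    Surfaces are pronounceable nonsense words (optionally two-token or with a
    hyphenated numeral, so spelling-variant families exist); normalized
    surfaces are unique and no surface's token sequence prefixes another's,
    which keeps synthetic extraction experiments free of span ambiguity.
    """
    rng = random.Random(seed)
    cons, vows = "bdfgklmnprstvz", "aeiou"

    def word(n_syll: int) -> str:
        return "".join(rng.choice(cons) + rng.choice(vows) for _ in range(n_syll))

    bases: set[str] = set()
    while len(bases) < n_terms:
        bases.add(word(rng.randint(2, 3)))
    tails: set[str] = set()
    while len(tails) < max(8, n_terms // 4):
        w = word(2)
        if w not in bases:
            tails.add(w)
    tail_pool = sorted(tails)

    entries: list[DictionaryEntry] = []
    for i, base in enumerate(sorted(bases)):
        surface = base.capitalize() if rng.random() < 0.5 else base
        shape = rng.random()
        if shape < 0.3:
            surface = f"{surface}-{rng.randint(1, 9)}"
        elif shape < 0.55:
            surface = f"{surface} {rng.choice(tail_pool)}"
        entries.append(DictionaryEntry(
            surface=surface,
            entity_type=rng.choice(list(entity_types)),
            source=sources[i % len(sources)],
            concept_id=f"SYN{i:04d}"))
    return EntityDictionary(entries, list(sources))


def synth_corpus(dictionary: EntityDictionary, n_passages: int,
                 variant_rate: float, seed: int) -> SyntheticCorpus:
    """Generate passages embedding 1-5 dictionary terms amid neutral filler.

    Each embedded term is independently rewritten into one of its
    case/separator variants with probability ``variant_rate``; gold mentions
    record the span actually written and the entry's entity type. Identical
    arguments produce identical corpora.
    """
    if n_passages < 0:
        raise ValueError("n_passages must be >= 0")
    if not 0.0 <= variant_rate <= 1.0:
        raise ValueError("variant_rate must be in [0, 1]")
    if n_passages > 0 and len(dictionary) == 0:
        raise ValueError("cannot generate passages from an empty dictionary")

    rng = random.Random(seed)
    dict_keys = {e.normalized for e in dictionary}
    filler = [w for w in FILLER_VOCABULARY if normalize_term(w) not in dict_keys]
    entries = list(dictionary.entries)

    passages: list[Passage] = []
    for p in range(n_passages):
        parts: list[str] = []
        mention_slots: list[tuple[int, DictionaryEntry, str]] = []
        n_terms = rng.randint(1, 5)
        for t in range(n_terms):
            parts.extend(rng.choice(filler) for _ in range(rng.randint(1, 3)))
            entry = rng.choice(entries)
            written = entry.surface
            if rng.random() < variant_rate:
                variants = sorted(generate_variants(entry.surface))
                if variants:
                    written = rng.choice(variants)
            mention_slots.append((len(parts), entry, written))
            parts.append(written)
        parts.extend(rng.choice(filler) for _ in range(rng.randint(0, 2)))

        offsets: list[int] = []
        pos = 0
        for k, part in enumerate(parts):
            offsets.append(pos)
            pos += len(part) + (1 if k < len(parts) - 1 else 0)
        text = " ".join(parts)
        mentions = tuple(
            Mention(start=offsets[idx], end=offsets[idx] + len(written),
                    surface=written, entity_type=entry.entity_type)
            for idx, entry, written in mention_slots)
        passages.append(Passage(doc_id=f"synth-{seed}-{p:04d}", text=text,
                                mentions=mentions))
    return SyntheticCorpus(tuple(passages), dictionary, seed, variant_rate)
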