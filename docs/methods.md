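# Methods

## Overview

`bioner` recognizes entities by two-level string matching against a
multi-source dictionary: a cheap, threshold-bounded approximate lookup
proposes candidate dictionary entries for every token-aligned span, and the
Shortest Path Edit Distance (SPED) re-ranks candidates that are not perfect
matches. A context/POS/stem-based merging stage then consolidates
overlapping candidate mentions. The pipeline assumes nothing about the input
beyond tokenizability; it needs no training corpus, only a dictionary.

## Normalization

All dictionary keys and span queries are normalized: lowercase, `-` and `_`
to spaces, whitespace collapsed, edge punctuation stripped. This is the
minimal map that unifies the observed spelling-variant families of
biomedical names (case flips and hyphen/space swaps, e.g. the EGR-1 family)
while leaving real lexical content untouched. The map is idempotent, and the
variant generator is sound with respect to it: every generated variant of a
term normalizes to the term's key. Porter stemming is available as an extra
normalization step but is off by default for dictionary keys; stemming's
default role is inside the merging rule, where it tests lexical similarity
of mention token sequences. The Porter stemmer is the classic 1980
algorithm, implemented in `bioner._porter`.

## Weighted approximate lookup

The candidate generator measures a weighted edit distance with per-operation
costs (defaults): substitution 1.0, case-only substitution 0.1,
separator-for-separator substitution 0.1, indel 1.0, separator indel 0.2;
the default acceptance threshold is 0.6. These weights make an entire
case/separator variant family cost ≲ 0.5 while a single genuine letter edit
costs 1.0; the exact values are this package's declared defaults (the
operating weights of comparable published systems are not stated), and all
are configurable. The character-level costs form a metric, so the distance
obeys the triangle inequality and is symmetric.

The dictionary is a character trie whose terminal nodes carry the entries
sharing a key. Lookup carries the DP row for the current trie prefix and
abandons a branch once the row minimum exceeds the threshold — row minima
are non-decreasing under non-negative costs, so pruning is exact, and the
traversal is contractually (and test-verified) identical to brute-force
filtering of every key. Keys are normalized surfaces by default, so variant
families collapse to one key and hit at cost 0; a raw-surface index
(`TermIndex(..., normalized=False)`) is available when the edit distance
itself should absorb the variation.

Candidate spans are token-boundary-aligned (1..`max_span_tokens` tokens,
default 4), not arbitrary character substrings: entity mentions in prose
respect token boundaries, and free offsets would flood the matcher with
false positives from short names — the known weakness of dictionary methods.

## SPED

For strings S and T, both are partitioned into consecutive pieces of length
L; the last piece absorbs the remainder (length in [L, 2L−1]), and a string
shorter than L is its own piece. Each piece pair (u, v) is scored by the
mean character mismatch over all |u|·|v| character pairs — the printed
double-sum formula is implemented literally, divided by |u|·|v| so unequal
piece lengths stay in [0, 1] and the equal-length case reduces to l². Note
the double sum gives identical multi-character pieces a nonzero score
(e.g. "ab" vs "ab" → 0.5); a positionwise variant that scores aligned
characters only is provided as `weight_fn="aligned"`, but the literal
formula stays the default.

The score lattice becomes a DAG: one vertex per box plus a source joined to
box (1,1) by a diagonal edge carrying that box's score; diagonal edges carry
the target box score (substitution/match), horizontal and vertical edges a
gap cost (deletion/insertion). The distance is the minimum-weight
source→bottom-right path divided by its edge count; among equal-weight paths
the one with the most edges is chosen, which minimizes the normalized score
deterministically. Shortest paths are computed by single-pass relaxation in
topological (row-major) order; float ties are resolved with a 1e-9
tolerance.

A common prefix of the two strings (measured on the exact strings passed in,
before any normalization) earns a Jaro-Winkler-style credit:
SPED = SPED′ − min(|prefix|, 4) · 0.1 · (1 − SPED′), clamped to [0, 1]. The
cap of 4 follows the Jaro-Winkler convention; without it, long identical
prefixes drive the score negative. Empty-string conventions: two empty
strings score 0, exactly one empty scores 1.

Defaults are L = 1 and gap cost 1.0, which make SPED a normalized
per-character grid edit distance with these verified properties (checked
against independent brute-force oracles on random pairs): scores in [0, 1];
symmetry; identity at 0; the un-normalized path weight is bounded below by
Levenshtein distance and above by Hamming distance for equal lengths.
`tune_gap_cost` implements the learning phase: it grid-searches the gap cost
maximizing the separation between mean scores of non-matching and matching
labelled pairs, breaking ties toward the smallest value.

In the pipeline, SPED compares normalized forms but credits the common
prefix of the raw span and raw surface; candidates must clear
`sped_accept_threshold` (default 0.3 — with L = 1 and gap 1.0 this admits
near-variants and short real edits but rejects unrelated terms; no published
operating threshold exists to adopt).

## Merging and overlap resolution

The shorter of two candidate mentions is merged into the longer when all
four conditions hold: identical start offset; identical entity type (the
contextual top-category cue); every token overlapping either mention tagged
NOUN, ADJ or NUM (POS cue; a `merge_noun_only` flag restricts to pure
nouns — biomedical names like "EGR 1" contain numerals, so ADJ/NUM are
admitted by default); and the shorter mention's stemmed token sequence is a
prefix of the longer's. Prefix containment operationalizes "similar lexical
properties": it is the weakest relation under which merging shorter into
longer is well-defined. The rule iterates to a fixed point; the output is a
subset of the input and idempotent (property-tested on randomized mention
sets).

The built-in POS tagger is deterministic and rule-based (closed-class word
lists, digit-initial → NUM, a few suffix rules, default NOUN) so that no
model download is needed; any callable honoring the tag contract can be
injected. Cross-start overlaps, which the merging rule does not cover, are
resolved per entity type keeping the lowest score, then the longest span.

## Pipeline modes

`all` (SPED re-ranking + merging), `sped_only` (no merging), `context_only`
(approximate lookup + merging, no SPED gate), mirroring the three
experimental arms of hybrid dictionary NER; plus `exact`, the
first-generation baseline that accepts only verbatim raw-surface matches.
In every mode a candidate whose normalized surface equals the span's
normalized text is selected immediately at score 0 (the perfect-match
short-circuit, applied per span). Best-candidate ties break by source
priority, then longest surface, then lexicographic order; everything is
deterministic for a fixed (text, dictionary, config).

## Dictionaries

TSV sources (`surface / entity_type / source / concept_id`) and tree-map
sources (`term / tree-number`) can be merged with provenance preserved; a
tree term is typed by the top-level label of its tree number's leading
letter, defaulting to the 16 standard MeSH branch labels (A Anatomy,
B Organisms, C Diseases, D Chemicals and Drugs, …), injectable for other
taxonomies. When sources disagree on a surface's type, all entries are kept
and extraction resolves the conflict by source priority — terminology
mergers state no conflict policy, so the policy is explicit and
caller-controlled here. Native MeSH/UMLS/GENIA distribution formats are out
of scope; the TSV dialects stand in for them.

## Synthetic data

`synth_dictionary` generates multi-source dictionaries of pronounceable
nonsense terms (one to two tokens, optional hyphenated numeral, mixed
casing) whose normalized surfaces are unique and mutually non-prefixing —
deliberately ambiguity-free. `synth_corpus` embeds 1–5 dictionary terms per
passage among a fixed 50-word neutral filler vocabulary (filtered against
the dictionary at run time so no filler collides with a key), rewriting each
embedded term into a random member of its case/separator variant family
with probability `variant_rate`, and records gold spans. Everything is
seeded and byte-reproducible.

The default study conditions used by the acceptance script are 120 terms,
two sources, 200 passages, and variant rates 0 and 0.3. What the generator
emulates: multi-source coverage, span supervision, and the dominant
real-world failure mode of exact matching (spelling variants). What it does
not emulate: typos and morphological variants that survive normalization,
ambiguous or nested terms, genuinely noisy context, or the scale of a real
terminology — so perfect recovery on synthetic corpora demonstrates the
machinery end to end (candidate generation, short-circuiting, merging,
scoring) but does not predict benchmark-corpus accuracy, which depends on
dictionary coverage and ambiguity. Published benchmark reproduction is
additionally out of reach at desk scale because the JNLPBA corpus, MeSH
2010, GENIA and the license-restricted UMLS cannot ship with the package.

## Evaluation

Strict matching (exact span boundaries and entity type, one-to-one) is the
scoring criterion — the JNLPBA convention. Precision = TP/(TP+FP), recall =
TP/(TP+FN), F1 their harmonic mean, and every 0/0 is defined as 0. K-fold
splitting is a seeded shuffle with round-robin assignment over passages
(fold sizes differ by ≤ 1). IOB2 files are `token<TAB>tag` lines with blank
lines between sentences; sentence text is reconstructed with single spaces
(original inter-token spacing is not recoverable and not needed for strict
scoring in token space), making write∘read and read∘write exact inverses on
valid files. Orphan I- tags are an error naming the line in strict mode and
are repaired to B- in lenient mode.

## Known limitations

- No sentence splitting beyond the caller's passage boundaries; no
  abbreviation expansion, coordination handling ("A and B receptors"), or
  nested-entity output.
- The rule-based POS tagger is intentionally small; precision of the
  merging POS condition on real prose is bounded by it (inject a trained
  tagger for better behavior).
- Only the printed double-sum box weight and its aligned variant are
  implemented as lattice weight functions.
- Approximate candidate generation is span-by-span; no document-level
  disambiguation or coreference.
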