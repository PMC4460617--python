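# bioner — hybrid dictionary-based bio-entity recognition

Dictionary-based named-entity recognition locates biomedical entities
(proteins, genes, cell types, diseases, chemicals) in text by matching spans
against a precompiled term list. It needs no training data and yields concept
identities for free, but verbatim matching breaks on the rampant spelling
variation of biomedical names — "EGR-1", "Egr 1", "egr-1" and "EGR 1" are the
same protein — and merging terminologies of different provenance (a gene
corpus, the MeSH tree, a UMLS-style vocabulary) multiplies both coverage and
conflicts.

`bioner` implements a hybrid pipeline for this setting:

1. **Candidate generation** — dictionary surfaces are held in a character
   trie and every token-aligned span of a passage is looked up under a
   *weighted edit distance* in which case-only substitutions and swaps among
   `-`, `` ``, `_` are cheap (0.1) while real letter edits cost 1.0, so whole
   spelling-variant families fall inside a small cost threshold. Trie
   traversal carries the DP row per prefix and prunes on the threshold; its
   output is provably identical to brute-force filtering.
2. **Ranking by the Shortest Path Edit Distance (SPED)** — a span/candidate
   pair is scored by cutting both strings into length-*L* pieces, scoring
   every piece pair by its mean character mismatch
   (x_ij = Σ_a Σ_b [S[a] ≠ T[b]] / l²), turning the score lattice into a
   weighted DAG (diagonal edges carry box scores, horizontal/vertical edges a
   learnable gap cost), taking the shortest source→sink path normalized by
   its edge count, and crediting a shared prefix Jaro-Winkler-style:
   SPED = SPED′ − |prefix| · 0.1 · (1 − SPED′). A perfect normalized match
   short-circuits SPED entirely.
3. **Merging** — overlapping same-start candidates of the same type whose
   tokens are nominal (noun/adjective/numeral) and whose Porter-stemmed token
   sequences nest prefix-wise are collapsed into the longest mention;
   remaining same-type overlaps keep the lowest-score, then longest span.

Dictionaries are built from TSV term lists and/or MeSH-style tree tables
(each term typed by the top label of its tree number, e.g. `C17.300` →
"Diseases"), merged with per-source provenance and a source-priority rule for
type conflicts. Strict-span precision/recall/F1 scoring, IOB2 reading and
writing, seeded k-fold splitting, and a synthetic corpus generator complete
the toolchain.

## Worked example

```python
from bioner import DictionaryEntry, EntityDictionary, extract_entities

d = EntityDictionary([
    DictionaryEntry("EGR-1", "protein", "genia"),
    DictionaryEntry("B-Lymphocytes", "Anatomy", "mesh"),
    DictionaryEntry("Escherichia coli Proteins", "protein", "umls"),
])
text = "Expression of egr 1 in B lymphocytes was measured"
mentions, trace = extract_entities(text, d)
for m in mentions:
    print(f"[{m.start},{m.end}) {m.surface!r} -> {m.entity_type} "
          f"(score {m.score:.3f}, source {m.matched_entry.source})")
```

prints

```
[14,19) 'egr 1' -> protein (score 0.000, source genia)
[23,36) 'B lymphocytes' -> Anatomy (score 0.000, source mesh)
```

Both spans are spelling variants, not verbatim dictionary surfaces; they are
recovered at score 0 because normalization unifies their variant families
(the trace records the perfect-match short-circuit per span). The SPED scorer
is also available directly — raw strings, no normalization:

```sh
$ bioner sped --s "EGR-1" --t "Egr 1"
0.560000
$ bioner sped --s "dopamine receptor" --t "dopamine DC2 receptor"
0.000000
```

The second pair differs by an inserted token yet scores 0: the shared
8-character prefix (capped at 4) earns full credit against the small
normalized path weight.

The CLI covers the whole pipeline: `bioner build-dict` (merge TSV and
tree-map sources), `bioner synth` (seeded synthetic corpora with a
configurable spelling-variant rate), `bioner extract` (modes `all`,
`context_only`, `sped_only`, `exact`), `bioner eval` (strict P/R/F1, optional
k-fold means), and `bioner sped`.

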