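"""Dictionary construction, normalization, variants, and corpus synthesis."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bioner.dictionary import (MESH_CATEGORIES, DictionaryEntry,
                               EntityDictionary, generate_variants, load_tsv,
                               load_tree_map, merge_dictionaries,
                               normalize_term, save_tsv, synth_corpus,
                               synth_dictionary)

terms = st.text(
    alphabet=st.sampled_from("abcdefgXYZ0189 -_.,()"), min_size=0, max_size=24)


class TestNormalizeTerm:
    @pytest.mark.parametrize("raw,expected", [
        ("EGR-1", "egr 1"),
        ("Egr 1", "egr 1"),
        ("egr_1", "egr 1"),
        ("  Dopamine   Receptor ", "dopamine receptor"),
        ("(EGR-1)", "egr 1"),
        ("", ""),
    ])
    def test_examples(self, raw, expected):
        assert normalize_term(raw) == expected

    def test_variant_family_unified(self):
        family = ["EGR-1", "Egr-1", "Egr 1", "egr-1", "egr 1", "EGR 1"]
        assert {normalize_term(v) for v in family} == {"egr 1"}

    def test_stemming_uses_porter(self):
        assert normalize_term("Lymphocytes", use_stemming=True) == "lymphocyt"
        assert normalize_term("dopamine receptors", use_stemming=True) \
            == "dopamin receptor"

    @given(terms)
    @settings(derandomize=True, max_examples=200)
    def test_idempotent(self, t):
        once = normalize_term(t)
        assert normalize_term(once) == once


class TestGenerateVariants:
    def test_egr_family(self):
        out = generate_variants("EGR-1")
        assert {"Egr-1", "Egr 1", "egr-1", "egr 1", "EGR 1"} <= out
        assert "EGR-1" not in out

    def test_no_separator_word(self):
        assert generate_variants("abc") == {"Abc", "ABC"}

    @pytest.mark.parametrize("term", ["EGR-1", "E coli", "dopamine receptor",
                                      "abc", "B-Lymphocytes"])
    def test_variants_normalize_to_same_key(self, term):
        key = normalize_term(term)
        assert all(normalize_term(v) == key for v in generate_variants(term))


class TestLoadTsv:
    def test_basic_and_default_source(self, tmp_path):
        f = tmp_path / "mydict.tsv"
        f.write_text("# comment\nEGR-1\tProtein\nE coli\tOrganism\n")
        d = load_tsv(f)
        assert len(d) == 2
        assert {e.source for e in d} == {"mydict"}

    def test_normalization_collapse(self, tmp_path):
        f = tmp_path / "d.tsv"
        f.write_text("EGR-1\tProtein\nEgr 1\tProtein\n")
        assert len(load_tsv(f)) == 1

    def test_malformed_line_names_lineno(self, tmp_path):
        f = tmp_path / "d.tsv"
        f.write_text("EGR-1\tProtein\nonlyonefield\n")
        with pytest.raises(ValueError, match=":2"):
            load_tsv(f)

    def test_empty_file_is_empty_dictionary(self, tmp_path):
        f = tmp_path / "d.tsv"
        f.write_text("")
        assert len(load_tsv(f)) == 0

    def test_round_trip_is_fixed_point(self, tmp_path, synthetic_dictionary):
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        save_tsv(synthetic_dictionary, p1)
        d1 = load_tsv(p1)
        save_tsv(d1, p2)
        d2 = load_tsv(p2)
        assert d1.entry_keys() == d2.entry_keys()
        assert p1.read_text().splitlines()[1:] == p2.read_text().splitlines()[1:]


class TestLoadTreeMap:
    def test_top_category_mapping(self, tmp_path):
        f = tmp_path / "tree.tsv"
        f.write_text("Rheumatic Diseases\tC17.300\nB-Lymphocytes\tA11.118\n")
        d = load_tree_map(f)
        types = {e.surface: e.entity_type for e in d}
        assert types["Rheumatic Diseases"] == "Diseases"
        assert types["B-Lymphocytes"] == "Anatomy"

    def test_multiple_tree_numbers_one_entry_per_type(self, tmp_path):
        f = tmp_path / "tree.tsv"
        f.write_text("Histamine\tD03.383\nHistamine\tD02.092\n")
        assert len(load_tree_map(f)) == 1  # same resulting label

    def test_unknown_letter_is_error(self, tmp_path):
        f = tmp_path / "tree.tsv"
        f.write_text("Thing\tQ01.100\n")
        with pytest.raises(ValueError, match="'Q'"):
            load_tree_map(f)

    def test_sixteen_default_branches(self):
        assert len(MESH_CATEGORIES) == 16
        assert MESH_CATEGORIES["D"] == "Chemicals and Drugs"

    def test_empty_file(self, tmp_path):
        f = tmp_path / "tree.tsv"
        f.write_text("")
        assert len(load_tree_map(f)) == 0


class TestMergeDictionaries:
    def test_disjoint_union(self):
        a = EntityDictionary([DictionaryEntry(f"worda{i}", "t", "A")
                              for i in range(10)])
        b = EntityDictionary([DictionaryEntry(f"wordb{i}", "t", "B")
                              for i in range(10)])
        assert len(merge_dictionaries([a, b])) == 20

    def test_type_conflicts_retained(self):
        a = EntityDictionary([DictionaryEntry("EGR-1", "Protein", "A")])
        b = EntityDictionary([DictionaryEntry("Egr 1", "Chemicals and Drugs", "B")])
        m = merge_dictionaries([a, b], priority=["A", "B"])
        assert len(m) == 2
        assert m.source_rank("A") < m.source_rank("B")

    def test_merge_of_nothing(self):
        assert len(merge_dictionaries([])) == 0

    def test_associative_on_entry_sets(self):
        ds = [EntityDictionary([DictionaryEntry(f"w{i}{j}", "t", f"S{i}")
                                for j in range(4)]) for i in range(3)]
        left = merge_dictionaries([merge_dictionaries(ds[:2]), ds[2]])
        right = merge_dictionaries([ds[0], merge_dictionaries(ds[1:])])
        assert left.entry_keys() == right.entry_keys()

    def test_priority_must_cover_sources(self):
        a = EntityDictionary([DictionaryEntry("x", "t", "A")])
        with pytest.raises(ValueError, match="A"):
            merge_dictionaries([a], priority=["B"])


class TestSynthCorpus:
    def test_zero_passages(self, synthetic_dictionary):
        assert synth_corpus(synthetic_dictionary, 0, 0.3, 7).passages == ()

    def test_variant_rate_zero_surfaces_verbatim(self, synthetic_dictionary):
        corpus = synth_corpus(synthetic_dictionary, 50, 0.0, 7)
        surfaces = {e.surface for e in synthetic_dictionary}
        for p in corpus.passages:
            for m in p.mentions:
                assert m.surface in surfaces
                assert p.text[m.start:m.end] == m.surface

    def test_seeded_determinism(self, synthetic_dictionary):
        a = synth_corpus(synthetic_dictionary, 20, 0.5, 13)
        b = synth_corpus(synthetic_dictionary, 20, 0.5, 13)
        assert a == b

    def test_variants_stay_in_family(self, synthetic_dictionary):
        corpus = synth_corpus(synthetic_dictionary, 50, 1.0, 3)
        keys = {e.normalized: e.entity_type for e in synthetic_dictionary}
        for p in corpus.passages:
            for m in p.mentions:
                assert normalize_term(m.surface) in keys

    def test_empty_dictionary_is_error(self):
        with pytest.raises(ValueError):
            synth_corpus(EntityDictionary([]), 5, 0.0, 7)

    def test_synth_dictionary_unambiguous(self):
        d = synth_dictionary(n_terms=100, seed=5)
        keys = [e.normalized for e in d]
        assert len(keys) == len(set(keys)) == 100
        assert set(d.sources()) == {e.source for e in d}
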