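import pytest

from bioner.dictionary import (DictionaryEntry, EntityDictionary,
                               synth_dictionary)


@pytest.fixture
def egr_dictionary() -> EntityDictionary:
    return EntityDictionary([
        DictionaryEntry("EGR-1", "protein", "genia"),
        DictionaryEntry("dopamine receptor", "chemical", "mesh"),
        DictionaryEntry("B-Lymphocytes", "anatomy", "mesh"),
    ])


@pytest.fixture(scope="session")
def synthetic_dictionary() -> EntityDictionary:
    return synth_dictionary(n_terms=80, seed=11)
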