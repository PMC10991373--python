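import pytest

from iduqa import (
    NoteRecipe,
    clean_notes,
    enrich_filter,
    generate_corpus,
    load_lexicon,
    load_question_bank,
    load_rules,
)


@pytest.fixture(scope="session")
def lexicon():
    return load_lexicon()


@pytest.fixture(scope="session")
def bank():
    return load_question_bank()


@pytest.fixture(scope="session")
def rules():
    return load_rules()


@pytest.fixture(scope="session")
def small_corpus(lexicon):
    """A 100-patient corpus with gold facts: (raw notes, cleaned kept notes, gold)."""
    recipe = NoteRecipe(n_patients=100, seed=1234)
    notes, gold = generate_corpus(recipe, lexicon)
    cleaned = clean_notes(notes)
    kept, dropped = enrich_filter(cleaned, lexicon)
    return notes, cleaned, kept, dropped, gold
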