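"""Build a gold-standard QA dataset from notes with the rule-based pipeline.

Cleans and enriches a synthetic corpus, runs the three-step answer extraction
(sentence split -> keyword sentences -> parsing-rule reduction), maps answers
to query-group questions, and writes a SQuAD-style JSON with a patient-level
70-10-20 split.
"""

from collections import Counter

from iduqa import (
    NoteRecipe, build_gold_dataset, clean_notes, enrich_filter, generate_corpus,
    load_lexicon, load_question_bank, load_rules, remove_length_outliers,
    write_squad,
)

lexicon, bank, rules = load_lexicon(), load_question_bank(), load_rules()
notes, _ = generate_corpus(NoteRecipe(n_patients=60, seed=7), lexicon)

cleaned = clean_notes(notes)
kept, dropped = enrich_filter(cleaned, lexicon)
kept = remove_length_outliers(kept)
print(f"{len(kept)} notes kept (contain an IDU keyword), {len(dropped)} dropped")

samples = build_gold_dataset(kept, bank, rules, lexicon, seed=7)
print(f"{len(samples)} QA samples")
print("split sizes:", dict(Counter(s.split for s in samples)))
print("query groups:", dict(Counter(s.group.value for s in samples)))

s = samples[0]
print("\nexample sample:")
print(" question:", s.question)
print(" answer:  ", s.answers[0].text, "| rules:", s.answers[0].rule_trace)

write_squad(samples, "gold_dataset.json")
print("\nwrote gold_dataset.json")
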