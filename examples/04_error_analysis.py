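"""Error-analysis suite: length bins, recall intervals, null-note detection.

Uses a deliberately imperfect extractor (it returns the whole keyword
sentence instead of the reduced span) so the analyses have errors to bin.
"""

from iduqa import (
    NoiseSpec, NoteRecipe, build_gold_dataset, build_null_samples, clean_notes,
    emit_null_cohort, enrich_filter, evaluate, generate_corpus, load_lexicon,
    load_question_bank, load_rules, null_note_detection, predict_dataset,
    quartile_bin_analysis, recall_interval_table, rule_based_extractor,
)
from iduqa.annotate import ParsingRule, RuleSet

lexicon, bank = load_lexicon(), load_question_bank()
rules = load_rules()
notes, _ = generate_corpus(NoteRecipe(n_patients=80, seed=3), lexicon)
kept, _ = enrich_filter(clean_notes(notes), lexicon)
samples = build_gold_dataset(kept, bank, rules, lexicon, seed=3)

# fallback-only extractor: full keyword sentences, no span reduction
blunt = rule_based_extractor(bank, lexicon, RuleSet([ParsingRule("fallback")]))
preds = predict_dataset(samples, blunt)
report, scores = evaluate(preds, samples, compute_ci=False)
print(f"blunt extractor: strict {report.macro_strict_f1:.1f} | "
      f"relaxed {report.macro_relaxed_f1:.1f} | recall {report.macro_recall:.1f}")

print("\nrecall intervals of non-strict matches (should lean to (99-100]):")
print(recall_interval_table(scores).to_string(index=False))

print("\nmacro scores by gold-answer-length quartile:")
print(quartile_bin_analysis(scores, "gold_answer_len").to_string(index=False))

nulls = clean_notes(emit_null_cohort(40, seed=5, lexicon=lexicon))
null_preds = predict_dataset(build_null_samples(nulls, bank),
                             rule_based_extractor(bank, lexicon, rules))
rate, tally = null_note_detection(null_preds)
print(f"\nnull-note detection rate: {100 * rate:.1f}% "
      f"({len(nulls)} keyword-free notes); mispredictions: {dict(tally)}")
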