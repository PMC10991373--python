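# iduqa

Extractive question answering for **injection drug use (IDU)** information in
clinical notes.

IDU is a major driver of morbidity (endocarditis, HIV, Hepatitis C, overdose)
but has no ICD code: when it is documented at all, it is documented in
free-text notes. `iduqa` implements a complete desk-scale QA framework for
surfacing that information: given a clinician's question (e.g. *"Has the
patient ever shared needles?"*) and a note, the system returns a verbatim
contiguous span of the note as the answer, or the empty string when the note
contains no IDU information.

The package is aimed at clinical-NLP researchers and health-system data
scientists who need (a) a reproducible rule-based pipeline for generating
gold-standard span annotations from raw notes, (b) a sliding-window QA engine
that any span extractor (rule-based or transformer) can plug into, and (c) a
faithful strict/relaxed span-evaluation and error-analysis suite. Because
real clinical notes cannot be redistributed, a synthetic note generator with
planted, gold-annotated IDU facts makes every component testable end to end.

## What it implements

**Gold-standard generation.** Questions are organized in nine *query groups*
(drug names, visible signs, risky needle use, active/historical use,
frequency, last use, skin popping, harm reduction, existence of IDU), each
with variants produced by abbreviation/synonym/syntax rewrites
(patient↔pt, intravenous↔iv, IDU↔IVDU, ...). Notes are cleaned by four
ordered rules (delete newlines around within-sentence punctuation, rejoin
broken sentences, collapse whitespace/punctuation runs), screened against a
six-group IDU keyword lexicon (`ivdu`, `inject(s/ed) heroin/meth/...`,
`sharing/shared/dirty needle(s)`, ...), and filtered for word-count outliers
by the interquartile range. Answer extraction is three steps — sentence
tokenization on periods, keyword-sentence selection, and parsing-rule span
reduction (negation, temporal, track-marks, OUD-specific cue families) — and
each answer is mapped to every query group whose trigger words it contains.
The dataset is split 70-10-20 **by patient** to prevent leakage.

**QA engine.** BERT-style span QA caps input at 512 tokens; with a 20-token
question the per-chunk context budget is 492 tokens, and longer notes are
chunked by a document stride of 128 tokens. Extractors are pluggable: the
bundled reference extractor reuses the annotation rules and scores candidate
spans by trigger-word overlap; a Hugging Face adapter
(`iduqa.transformer`, optional extra) serves fine-tuned checkpoints. The
engine pools candidates across windows, enforces a 100-token answer cap,
deduplicates overlap spans, and supports null (empty-string) answers.

**Evaluation.** Per-sample strict F1 ∈ {0, 1} is exact character equality.
Relaxed scores count whitespace tokens: TP = |pred ∩ gold| (multiset),
FP = |pred \ gold|, FN = |gold \ pred|, P = TP/(TP+FP), R = TP/(TP+FN),
F1 = 2PR/(P+R); all macro-averaged as percentages. The error-analysis suite
adds seeded bootstrap 95% CIs, quartile bins over note/question/answer
length, a 12-interval recall table for non-strict matches, answer/context
length-ratio distributions, and empty-answer detection on keyword-free notes.

## Worked example

```python
from iduqa import (clean_text, load_lexicon, load_question_bank, load_rules,
                   rule_based_extractor, predict)
from iduqa.annotate import QASample

lexicon, bank, rules = load_lexicon(), load_question_bank(), load_rules()
note = ("pt X, 200 yrs old. he has a history of smoking with 50 pack years, "
        "quit 10 years ago. social ethanol user. no history of idu. "
        "remote history of marijuana use.")
clean, _ = clean_text(note)
sample = QASample("s1", "pX", "n1", clean,
                  "Does the patient have any history of IDU?", answers=[])
print(predict(sample, rule_based_extractor(bank, lexicon, rules)).text)
```

prints

```
no history of idu
```

— the negation parsing rule anchors on the generic IDU keyword `idu`, walks
back to the cue `no`, and returns the span verbatim from the note. Running
`examples/03_predict_and_evaluate.py` (synthetic corpus, rules extractor)
prints macro strict F1 100.00 and macro relaxed F1/P/R 100.00 — perfect by
construction, since the extractor and the gold annotations share one rule
set; the numbers measure the engine's span bookkeeping, not clinical
accuracy. `examples/04_error_analysis.py` degrades the extractor to
whole-sentence answers and prints strict 97.7 vs relaxed 99.7, with all
non-strict matches landing in the (99–100] recall interval.

Each script in `examples/` is a narrative walk-through of one capability
(corpus generation, gold-dataset building, prediction + scoring, error
analysis). A thin CLI mirrors the stages:

```bash
iduqa synth --out notes.jsonl --gold gold.jsonl --seed 1
iduqa annotate --notes notes.jsonl --out dataset.json
iduqa predict --dataset dataset.json --extractor rules --out preds.jsonl
iduqa evaluate --pred preds.jsonl --gold dataset.json --report report.json
```

## Limitations

The parsing rules and trigger-word sets are reconstructions of a
summarized design and are deliberately configuration-driven so richer rule
tables can be dropped in. Synthetic notes exercise the pipeline's contracts,
not the linguistic messiness of real clinical text; see `docs/methods.md`
for what passing tests do and do not establish.
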