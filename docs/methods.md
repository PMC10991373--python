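# Methods

This note documents the models, procedures, defaults, and numerical choices
behind `iduqa`, and what its synthetic-data tests do and do not establish.

## Task and assumptions

The task is extractive QA: given a question about a patient's injection drug
use and a cleaned clinical note, return a verbatim contiguous span of the
note (or the empty string when the note carries no IDU information). The
gold-annotation pipeline rests on three working assumptions: (1) a question
is answered from a single place in the note at a time; (2) the inquired
information fits within a single sentence; (3) multiple IDU mentions in one
note are separate answer strings, generally answering different questions.
These assumptions fail on questionnaire-style or bulleted notes — such cases
are exactly what a human review pass would correct, and this package
implements only the automated pre-annotation stage.

## Note cleaning

Four ordered rules: (i) delete a newline following a comma/semicolon/colon;
(ii) delete a newline preceding a period/comma/semicolon; (iii) replace a
newline flanked by word characters with a space; (iv) collapse runs of
whitespace, or of an identical punctuation character, to single instances.
One ordered pass is not idempotent on its own (rule iv can merge a mixed
whitespace run into a newline that now sits between word characters), so the
pass is iterated to a fixpoint (≤5 rounds suffice; typically 2). Cleaning is
total, never touches alphanumeric characters, and returns a composed
monotone offset map so spans can be projected raw↔clean in both directions.
"Within the same sentence" in rule (iii) is operationalized as: both
neighbors of the newline are word characters — the cheapest reading
consistent with the documented examples.

## Lexicon and matching

The keyword lexicon has six groups (IV drug names, visible signs, risky
needle use, skin popping, harm reduction, generic IDU terms). Patterns are
written in a compact grammar — top-level `/` for alternatives,
`stem(s/ed)` for optional suffixes — and expand to case-insensitive,
word-boundary-anchored regular expressions (so `idu` never fires inside
`individual`). Two deliberate choices: "skin popping" is owned by the
skin-popping group only, so every expanded surface form is matched by
exactly one entry (the visible-signs *trigger* set still contains the
phrase); and bare `injecting` is included among generic terms because the
documented reduction examples anchor on it. Overlapping hits resolve
earliest-start, then longest, then lexicon order. Notes without any hit are
discarded as presumptively IDU-free; kept notes drop word-count outliers
outside `[Q1 − 1.5·IQR, Q3 + 1.5·IQR]` (two-sided, multiplier 1.5 — the
conventional fence, since no specific fence is documented).

## Parsing rules

Rules are data, loaded from the same JSON config as the lexicon, with
priority negation > temporal > track-marks-status > OUD-specific > fallback
(negation changes meaning most, so it wins). Before any rule fires, the
candidate sentence is narrowed to its period-free segment containing the
anchor (first) keyword — stray mid-span periods act as clause terminators —
and a leading section label (`social history:`) is stripped when it sits
more than 40 characters before the first keyword with an intervening comma.
Reductions: **negation** captures from the nearest cue before the keyword
(`denies`, `no history of`, `never`, ...) through the keyword to the next
comma or segment end; **temporal** extends from the segment start through
the clause containing the last temporal cue (`last`, `ago`, `since`,
`recent`, `prior`, `quit`); **track-marks** keeps the comma-delimited clause
around the phrase; **OUD-specific** joins the OUD mention and keyword
clauses when adjacent; **fallback** returns the whole segment. Spans are
trimmed of trailing punctuation and must still contain a keyword, else the
next rule is tried. A produced answer records its rule trace.

## Question bank, variants, and mapping

Nine query groups each carry a base question, stored variants, and a
trigger-word set. `expand_question_variants` applies substitution pairs
(patient↔pt, intravenous↔iv, history↔hx, IDU↔IVDU, injection↔intravenous)
one at a time in both directions plus an all-substitutions pass, for two
rounds, and anchored syntax templates; expansion is deduplicated,
deterministic, and closed under re-expansion. An answer maps to every group
whose triggers it contains (boundary-anchored, case-insensitive); generic
IDU keywords additionally assign the existence group, and an answer matching
nothing falls back to existence alone. Default trigger sets are limited to
words attested in the documented examples; users extend them in config. One
QA sample is emitted per (note, question variant); several answers of one
group on a note become several answer entries of that sample.

## Split

Patients (not notes) are shuffled with a seeded RNG after sorting by id,
then cut floor(0.70·n) / floor(0.10·n) / remainder. All samples of a patient
share a split; 200 patients give exactly 140/20/40.

## QA engine

The engine tokenizer is word/punctuation (`\w+` runs or single punctuation
marks) rather than pure whitespace, so an answer that excludes a trailing
period still aligns to token boundaries — the analogue of BERT basic
tokenization. Window capacity is `max_seq_len − question_len − overhead`
with overhead a tokenizer property defaulting to 0, realizing the 512−20=492
budget; windows advance by the 128-token stride until the last window
reaches the context end. Candidates from all windows are pooled;
spans beyond the 100-token answer cap or with end<start are discarded;
duplicate spans from window overlaps keep their best score; ties break
earlier-start then shorter-span (undocumented in the source design; chosen
for determinism). Aggregation across windows is max-score (vs. summing
logits — also undocumented; max is the conventional SQuAD choice). Each
window contributes a scored null candidate (SQuAD-v2 style, default score
0.5); the empty string is returned only when the null outscores every span.
Per-sample extractor failures are logged and marked, not fatal.

The reference extractor is rule-based: it reruns Steps 1–3 on the window
text, keeps answers mapped to the question's group (exact variant lookup,
else trigger-based inference), and scores them by trigger-overlap count
(plus generic-keyword hits for existence). A transformer adapter behind the
same contract serves Hugging Face span-QA checkpoints; fine-tuning at the
published scale (batch 32, lr 3e−5, 5 epochs, GPU) is out of scope here.

## Evaluation

Strict match is raw character equality — no lowercasing or whitespace
normalization by default, with an optional normalizer for callers who want
one. Relaxed metrics count whitespace-token *multisets* (the per-token
TP/FP/FN definitions imply counts, not sets). Multi-answer samples score
against the gold answer maximizing relaxed F1 (the SQuAD convention). Macro
scores are sample-level means × 100. Confidence intervals use the seeded
percentile bootstrap (10,000 resamples; normal approximation available);
constant data yields a zero-width interval. Quartile bins split at empirical
25/50/75 percentiles of context/question/gold-answer token length; the
recall table uses the fixed 12 intervals (99–100], (90–99], ..., (0–10],
{0} over samples with strict F1 = 0; the ratio analysis restricts to
full-recall non-strict matches, where a whole-context prediction would hide.

## Synthetic data

The generator emulates the kind of corpus the pipeline targets: notes of
boilerplate sections (chief complaint, demographics, family history, exam,
plan) with IDU snippets planted in a social-history section. Snippet
templates instantiate documented exemplar sentences (sample answers per
query group, free-text drug-name forms, negated and temporal mentions) with
slot-filled drug names and durations; each template's reduced answer is
known by construction, so planted facts carry exact gold offsets into the
clean rendering. Defaults: 50 patients; 1–3 notes per patient
(0.50/0.35/0.15); positive rate 0.80; 1–3 facts per positive note
(0.65/0.25/0.10); group mix dominated by active/historical use (0.28), then
existence (0.20) and drug names (0.16), with skin popping and harm reduction
rarest (0.03 each) — matching the qualitative distribution of the source
corpus; negation and temporal template rates 0.35 each. Formatting noise
(newline after comma 0.30, mid-word newline 0.08, punctuation runs 0.10) is
constrained to be exactly invertible by the cleaning rules, making the
cleaning contract testable as a round trip. Negative notes and the null
cohort are verified keyword-free against the lexicon at generation time.

**What passing tests show — and don't.** Perfect recovery and 100% strict F1
on synthetic corpora are self-consistency results: the extractor and the
gold annotations share one rule set, and the planted snippets are drawn from
the implemented rule families. They validate span bookkeeping (offsets,
chunking, deduplication, scoring) and the contracts between modules, not
performance on real clinical language, where rule misses, unusual layouts,
and vocabulary drift (e.g. fentanyl, xylazine are absent from the default
lexicon) all degrade results.

## Problem sizes

The test suite and the acceptance script run on corpora of roughly 500–1000
notes (250–500 patients), ~4000 QA samples, and 100-note null cohorts, with
the group-mix convergence check at ~5000 planted facts — sizes chosen so the
whole suite completes in seconds on one CPU while every property is
exercised at non-trivial scale.

## Known limitations

Sentence splitting on periods mis-segments decimal numbers and
abbreviations; the default rule and trigger tables are intentionally
minimal reconstructions; the OUD-specific rule is conservative (adjacent
clauses only); the transformer back-end is inference-only and untested
without weights; and no de-identification, section segmentation, or spell
correction is attempted.
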