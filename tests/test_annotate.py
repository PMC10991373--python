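"""Sentence splitting, span reduction, question mapping, and dataset assembly."""

import pytest

from iduqa import (
    QueryGroup,
    SentenceSpan,
    annotate_note,
    assign_groups,
    build_gold_dataset,
    candidate_sentences,
    clean_note,
    clean_text,
    map_to_questions,
    match_keywords,
    read_squad,
    reduce_answer,
    split_patients,
    split_sentences,
    write_squad,
)
from iduqa.annotate import GoldAnswer
from iduqa.notes import ClinicalNote


# ---------------------------------------------------------------------------
# Step 1: sentences
# ---------------------------------------------------------------------------

def test_two_sentences():
    assert len(split_sentences("a b. c d.")) == 2


def test_sentence_spans_reconstruct_text():
    text = "hx ivdu, last use 2 yrs ago. denies etoh. follow up"
    spans = split_sentences(text)
    for s in spans:
        assert text[s.start : s.end] == s.text
    # spans cover all non-whitespace characters, in order
    covered = sorted(i for s in spans for i in range(s.start, s.end))
    expected = [i for i, ch in enumerate(text) if not ch.isspace() or
                any(s.start <= i < s.end for s in spans)]
    assert set(covered) <= set(range(len(text)))
    rebuilt = "".join(text[i] for i in covered)
    assert rebuilt.replace(" ", "") == text.replace(" ", "")


def test_keyword_and_temporal_cue_in_first_sentence(lexicon):
    spans = split_sentences("hx ivdu, last use 2 yrs ago. denies etoh.")
    assert len(spans) == 2
    assert "ivdu" in spans[0].text and "last" in spans[0].text


# ---------------------------------------------------------------------------
# Step 2: candidates
# ---------------------------------------------------------------------------

def test_candidate_selection(lexicon):
    text = "pt seen today. has h/o ivdu. plan reviewed."
    sents = split_sentences(text)
    matches = match_keywords(text, lexicon)
    cands = candidate_sentences(sents, matches)
    assert [c.text for c in cands] == ["has h/o ivdu."]
    assert candidate_sentences(sents, []) == []


def test_two_keyword_sentences_both_retained(lexicon):
    text = "has h/o ivdu. last used iv meth 2 years ago."
    cands = candidate_sentences(split_sentences(text), match_keywords(text, lexicon))
    assert len(cands) == 2


# ---------------------------------------------------------------------------
# Step 3: reduction
# ---------------------------------------------------------------------------

def _reduce(text, lexicon, rules):
    matches = match_keywords(text, lexicon)
    return reduce_answer(SentenceSpan(0, len(text), text), matches, rules)


def test_reduction_strips_nonessential_prefix(lexicon, rules):
    raw = (
        "social history: pt lives with family in [location], quit smoking 10 y ago, "
        "occ etoh, . hx methamphetamine use, has been using daily via injecting "
        "since a relapse in December."
    )
    clean, _ = clean_text(raw)
    ans = _reduce(clean, lexicon, rules)
    assert ans.text == (
        "hx methamphetamine use, has been using daily via injecting "
        "since a relapse in December"
    )


def test_negation_rule_captures_cue_through_keyword(lexicon, rules):
    ans = _reduce("pt lives with family, denies any tobacco, etoh or ivdu", lexicon, rules)
    assert ans.text == "denies any tobacco, etoh or ivdu"
    assert ans.rule_trace == ["negation"]


def test_fallback_returns_whole_sentence(lexicon, rules):
    ans = _reduce("h/o active iv drug use.", lexicon, rules)
    assert ans.text == "h/o active iv drug use"
    assert ans.rule_trace == ["fallback"]


def test_reduced_span_is_verbatim_and_contains_keyword(lexicon, rules):
    text = "notes reviewed. pt reports using iv meth, follow up scheduled."
    sents = split_sentences(text)
    matches = match_keywords(text, lexicon)
    sent = candidate_sentences(sents, matches)[0]
    in_sent = [m for m in matches if m.start >= sent.start and m.end <= sent.end]
    ans = reduce_answer(sent, in_sent, rules)
    assert text[ans.start : ans.end] == ans.text
    assert any(m.start >= ans.start and m.end <= ans.end for m in in_sent)


def test_reduce_requires_keyword(rules):
    with pytest.raises(ValueError):
        reduce_answer(SentenceSpan(0, 4, "etoh"), [], rules)


# ---------------------------------------------------------------------------
# question-to-answer mapping
# ---------------------------------------------------------------------------

def test_multi_group_mapping(bank, lexicon):
    groups = assign_groups("recent ivdu with meth and heroin", bank, lexicon)
    assert QueryGroup.active_historical in groups
    assert QueryGroup.drug_names in groups


def test_track_marks_maps_to_visible_signs(bank, lexicon):
    groups = assign_groups(
        "track marks noted over bilateral upper extremities", bank, lexicon
    )
    assert QueryGroup.visible_signs in groups


def test_generic_keyword_maps_existence_only(bank, lexicon):
    assert assign_groups("no ivdu", bank, lexicon) == {QueryGroup.existence}


def test_map_to_questions_emits_every_variant(bank, lexicon):
    ans = GoldAnswer("n1", 0, 7, "no ivdu")
    pairs = map_to_questions(ans, bank, lexicon)
    existence = next(e for e in bank if e.group is QueryGroup.existence)
    assert [q for q, _ in pairs] == existence.variants


def test_mapping_agrees_with_brute_force_trigger_oracle(bank, lexicon):
    """Trigger-intersection oracle over template answers (token/phrase scan)."""
    import re as _re

    from iduqa.synthetic import TEMPLATES

    for tpl in TEMPLATES:
        answer = tpl.answer.format(drug="heroin", n=3)
        groups = assign_groups(answer, bank, lexicon)
        for entry in bank:
            hit = any(
                _re.search(
                    r"(?<!\w)" + r"\s+".join(map(_re.escape, t.split())) + r"(?!\w)",
                    answer,
                    _re.IGNORECASE,
                )
                for t in entry.trigger_words
            )
            if hit:
                assert entry.group in groups
            elif entry.group is not QueryGroup.existence:
                assert entry.group not in groups


# ---------------------------------------------------------------------------
# dataset assembly and split
# ---------------------------------------------------------------------------

def test_patient_split_proportions_and_disjointness():
    pids = [f"P{i:04d}" for i in range(200)]
    assign = split_patients(pids, seed=5)
    counts = {s: sum(1 for v in assign.values() if v == s) for s in
              ("train", "validation", "test")}
    assert counts == {"train": 140, "validation": 20, "test": 40}


def test_split_deterministic_and_order_invariant():
    pids = [f"P{i}" for i in range(57)]
    a = split_patients(pids, seed=9)
    b = split_patients(list(reversed(pids)), seed=9)
    assert a == b
    assert split_patients(pids, seed=10) != a


def test_bad_split_proportions_rejected():
    with pytest.raises(ValueError):
        split_patients(["a", "b"], proportions=(0.5, 0.2, 0.2))


def test_build_gold_dataset_invariants(small_corpus, bank, rules, lexicon):
    _, _, kept, _, _ = small_corpus
    samples = build_gold_dataset(kept, bank, rules, lexicon, seed=3)
    again = build_gold_dataset(kept, bank, rules, lexicon, seed=3)
    assert [s.sample_id for s in samples] == [s.sample_id for s in again]

    split_by_patient: dict[str, set[str]] = {}
    for s in samples:
        assert s.answers, "enriched notes must yield answers"
        for a in s.answers:
            assert s.context[a.start : a.end] == a.text
            # answer lies within a single sentence
            sent = next(
                sp for sp in split_sentences(s.context)
                if sp.start <= a.start and a.end <= sp.end
            )
            assert sent is not None
        split_by_patient.setdefault(s.patient_id, set()).add(s.split)
    assert all(len(v) == 1 for v in split_by_patient.values()), "patient leakage"


def test_annotate_note_dedupes_spans(lexicon, bank, rules):
    note = clean_note(
        ClinicalNote("n", "p", "2022-01-01", "note", "has h/o ivdu. has h/o ivdu.")
    )
    answers = annotate_note(note, lexicon, bank, rules)
    assert len(answers) == 2  # same text, distinct offsets
    assert len({(a.start, a.end) for a in answers}) == 2


def test_squad_round_trip(tmp_path, small_corpus, bank, rules, lexicon):
    _, _, kept, _, _ = small_corpus
    samples = build_gold_dataset(kept[:10], bank, rules, lexicon, seed=1)
    path = tmp_path / "gold.json"
    write_squad(samples, str(path))
    back = read_squad(str(path))
    assert len(back) == len(samples)
    for orig, rt in zip(samples, back):
        assert (orig.sample_id, orig.question, orig.context) == (
            rt.sample_id, rt.question, rt.context)
        assert [a.text for a in orig.answers] == [a.text for a in rt.answers]
        assert [a.start for a in orig.answers] == [a.start for a in rt.answers]
        assert orig.split == rt.split and orig.group == rt.group
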