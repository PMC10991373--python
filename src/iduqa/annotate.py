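"""Rule-based gold-standard answer extraction and QA dataset assembly.

The pre-annotation strategy rests on three working assumptions: a question is
answered from a single place in the note at a time; the inquired information
fits in a single sentence; and multiple IDU mentions in one note are separate
answer strings. The pipeline is:

1. split the cleaned note into sentences (periods end sentences);
2. keep sentences containing at least one lexicon keyword;
3. reduce each candidate sentence to a concise answer span with parsing rules
   (negation, temporal, track-marks status, OUD-specific families; whole
   sentence as fallback);
4. map each answer to every query group whose trigger words it contains, and
   emit one QA sample per (note, question variant) with a patient-level
   70-10-20 train/validation/test split.

The default parsing-rule set is a reconstruction driven by the cue families
the published pipeline describes; all cues are configuration, so a richer
rule table can be supplied without touching code.
"""

from __future__ import annotations

import json
import math
import random
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .lexicon import (
    KeywordLexicon,
    QueryGroup,
    QuestionBankEntry,
    count_trigger_hits,
    load_config,
)
from .notes import ClinicalNote, KeywordMatch, match_keywords

__all__ = [
    "SentenceSpan",
    "ParsingRule",
    "RuleSet",
    "GoldAnswer",
    "QASample",
    "load_rules",
    "split_sentences",
    "candidate_sentences",
    "reduce_answer",
    "assign_groups",
    "map_to_questions",
    "annotate_note",
    "build_gold_dataset",
    "build_null_samples",
    "write_squad",
    "read_squad",
    "write_samples_jsonl",
]


@dataclass(frozen=True)
class SentenceSpan:
    """A sentence as a character span into cleaned text (period included)."""

    start: int
    end: int
    text: str


@dataclass(frozen=True)
class ParsingRule:
    """A keyword-anchored span-reduction rule: a cue family plus its cue list."""

    family: str  # negation | temporal | track_marks_status | oud_specific | fallback
    cues: tuple[str, ...] = ()

    def cue_pattern(self) -> re.Pattern[str] | None:
        if not self.cues:
            return None
        alts = sorted(self.cues, key=len, reverse=True)
        joined = "|".join(r"\s+".join(re.escape(w) for w in c.split()) for c in alts)
        return re.compile(rf"(?<!\w)(?:{joined})(?!\w)", re.IGNORECASE)


@dataclass
class RuleSet:
    """Ordered parsing rules plus shared reduction parameters."""

    rules: list[ParsingRule]
    label_strip_distance: int = 40

    def __post_init__(self) -> None:
        if not self.rules or self.rules[-1].family != "fallback":
            self.rules = [*self.rules, ParsingRule("fallback")]


@dataclass
class GoldAnswer:
    """A contiguous answer span in cleaned note text with rule provenance."""

    note_id: str
    start: int
    end: int
    text: str
    groups: set[QueryGroup] = field(default_factory=set)
    rule_trace: list[str] = field(default_factory=list)


@dataclass
class QASample:
    """A (context, question, answers) triple with patient linkage and split tag."""

    sample_id: str
    patient_id: str
    note_id: str
    context: str
    question: str
    answers: list[GoldAnswer]
    split: str = ""
    group: QueryGroup | None = None


def load_rules(config_path: str | None = None) -> RuleSet:
    """Load the parsing-rule set (priority order and cue lists) from config."""
    cfg = load_config(config_path)["rules"]
    rules = []
    for family in cfg["priority"]:
        if family == "fallback":
            rules.append(ParsingRule("fallback"))
        else:
            rules.append(ParsingRule(family, tuple(cfg[family]["cues"])))
    return RuleSet(rules, label_strip_distance=int(cfg.get("label_strip_distance", 40)))


# ---------------------------------------------------------------------------
# Step 1: sentence splitting
# ---------------------------------------------------------------------------

def split_sentences(clean: str) -> list[SentenceSpan]:
    """Split cleaned text into sentence spans; periods end sentences.

    Spans partition the non-whitespace text; each span ends at a period or at
    end of text.
    """
    spans: list[SentenceSpan] = []
    cursor = 0
    n = len(clean)
    while cursor < n:
        dot = clean.find(".", cursor)
        end = n if dot == -1 else dot + 1
        seg = clean[cursor:end]
        stripped = seg.strip()
        if stripped:
            start = cursor + len(seg) - len(seg.lstrip())
            stop = cursor + len(seg.rstrip())
            spans.append(SentenceSpan(start, stop, clean[start:stop]))
        cursor = end
    return spans


# ---------------------------------------------------------------------------
# Step 2: candidate sentences
# ---------------------------------------------------------------------------

def candidate_sentences(
    sentences: Sequence[SentenceSpan], matches: Sequence[KeywordMatch]
) -> list[SentenceSpan]:
    """Sentences containing at least one keyword match, in order."""
    return [
        s
        for s in sentences
        if any(m.start >= s.start and m.end <= s.end for m in matches)
    ]


# ---------------------------------------------------------------------------
# Step 3: span reduction
# ---------------------------------------------------------------------------

def _clause_bounds(text: str, pos: int, lo: int, hi: int) -> tuple[int, int]:
    """Comma-delimited clause of ``text`` containing position ``pos``."""
    start = text.rfind(",", lo, pos)
    start = lo if start == -1 else start + 1
    end = text.find(",", pos, hi)
    end = hi if end == -1 else end
    return start, end

_LABEL_RE = re.compile(r"^([A-Za-z][\w /-]{0,30}):\s*")


def _trim(text: str, start: int, end: int) -> tuple[int, int]:
    while start < end and text[start] in " \t\n":
        start += 1
    while end > start and text[end - 1] in " \t\n.,;:":
        end -= 1
    return start, end


def reduce_answer(
    sentence: SentenceSpan,
    matches_in_sentence: Sequence[KeywordMatch],
    rules: RuleSet,
) -> GoldAnswer:
    """Reduce a keyword-bearing sentence to a concise answer span.

    The first rule (in configured priority) whose cue pattern applies and
    whose resulting span still contains a keyword wins; otherwise the whole
    sentence (minus stray leading section labels and trailing punctuation) is
    the answer. Offsets in the returned answer are absolute, matching the
    coordinates of ``sentence`` and the keyword matches.
    """
    if not matches_in_sentence:
        raise ValueError("reduce_answer requires at least one keyword match")
    base = sentence.start
    text = sentence.text
    local = sorted(
        (m.start - base, m.end - base) for m in matches_in_sentence
    )
    anchor_start, anchor_end = local[0]

    # narrow to the period-free segment containing the anchor keyword: stray
    # periods inside a span act as clause terminators
    lo = text.rfind(".", 0, anchor_start) + 1
    dot = text.find(".", anchor_end)
    hi = len(text) if dot == -1 else dot
    while lo < hi and text[lo] in " \t\n":
        lo += 1

    # strip a leading section label ("social history:") when it sits far from
    # the first keyword with an intervening comma
    m = _LABEL_RE.match(text[lo:hi])
    if m is not None:
        label_end = lo + m.end()
        if (
            anchor_start - label_end > rules.label_strip_distance
            and "," in text[label_end:anchor_start]
        ):
            lo = label_end

    in_region = [(s, e) for s, e in local if s >= lo and e <= hi]
    if in_region:
        anchor_start, anchor_end = in_region[0]

    def contains_keyword(s: int, e: int) -> bool:
        return any(ks >= s and ke <= e for ks, ke in local)

    for rule in rules.rules:
        span = _apply_rule(rule, text, lo, hi, anchor_start, anchor_end)
        if span is None:
            continue
        s, e = _trim(text, *span)
        if e > s and contains_keyword(s, e):
            return GoldAnswer(
                note_id="",
                start=base + s,
                end=base + e,
                text=text[s:e],
                rule_trace=[rule.family],
            )
    s, e = _trim(text, lo, hi)  # unreachable with a fallback rule present
    return GoldAnswer(note_id="", start=base + s, end=base + e, text=text[s:e],
                      rule_trace=["fallback"])


def _apply_rule(
    rule: ParsingRule, text: str, lo: int, hi: int, kw_start: int, kw_end: int
) -> tuple[int, int] | None:
    if rule.family == "fallback":
        return lo, hi
    pat = rule.cue_pattern()
    if pat is None:
        return None
    cues = [m for m in pat.finditer(text, lo, hi)]
    if not cues:
        return None

    if rule.family == "negation":
        before = [m for m in cues if m.start() < kw_start]
        if not before:
            return None
        cue = before[-1]
        nxt = text.find(",", kw_end, hi)
        end = hi if nxt == -1 else nxt
        return cue.start(), end

    if rule.family == "temporal":
        last_pos = max(max(m.end() for m in cues), kw_end)
        nxt = text.find(",", last_pos, hi)
        end = hi if nxt == -1 else nxt
        return lo, end

    if rule.family == "track_marks_status":
        cue = cues[0]
        return _clause_bounds(text, cue.start(), lo, hi)

    if rule.family == "oud_specific":
        cue = cues[0]
        cs, ce = _clause_bounds(text, cue.start(), lo, hi)
        ks, ke = _clause_bounds(text, kw_start, lo, hi)
        # adjacent-or-same clause requirement
        if cs > ke + 1 and ks > ce + 1:
            return None
        return min(cs, ks), max(ce, ke)

    return None


# ---------------------------------------------------------------------------
# question-to-answer mapping
# ---------------------------------------------------------------------------

def assign_groups(
    answer_text: str,
    bank: Sequence[QuestionBankEntry],
    lexicon: KeywordLexicon | None = None,
) -> set[QueryGroup]:
    """Query groups whose trigger words occur in the answer.

    Generic IDU keywords always assign the existence group; an answer matching
    no trigger set at all falls back to existence alone (it contains an IDU
    keyword by construction).
    """
    groups: set[QueryGroup] = set()
    for entry in bank:
        if count_trigger_hits(answer_text, entry.trigger_words) > 0:
            groups.add(entry.group)
    if lexicon is not None:
        for entry in lexicon.by_group("generic_idu"):
            if entry.pattern.search(answer_text):
                groups.add(QueryGroup.existence)
                break
    if not groups:
        groups.add(QueryGroup.existence)
    return groups


def map_to_questions(
    answer: GoldAnswer,
    bank: Sequence[QuestionBankEntry],
    lexicon: KeywordLexicon | None = None,
) -> list[tuple[str, GoldAnswer]]:
    """Emit (question, answer) pairs for every variant of every assigned group."""
    answer.groups = assign_groups(answer.text, bank, lexicon)
    pairs = []
    for entry in bank:
        if entry.group in answer.groups:
            for variant in entry.variants:
                pairs.append((variant, answer))
    return pairs


# ---------------------------------------------------------------------------
# dataset assembly
# ---------------------------------------------------------------------------

def annotate_note(
    note: ClinicalNote,
    lexicon: KeywordLexicon,
    bank: Sequence[QuestionBankEntry],
    rules: RuleSet,
) -> list[GoldAnswer]:
    """Run Steps 1-3 plus group assignment on one cleaned note."""
    if note.clean_text is None:
        raise ValueError(f"note {note.note_id}: clean before annotation")
    clean = note.clean_text
    matches = match_keywords(clean, lexicon)
    answers: list[GoldAnswer] = []
    seen: set[tuple[int, int]] = set()
    for sent in candidate_sentences(split_sentences(clean), matches):
        in_sent = [m for m in matches if m.start >= sent.start and m.end <= sent.end]
        ans = reduce_answer(sent, in_sent, rules)
        ans.note_id = note.note_id
        ans.groups = assign_groups(ans.text, bank, lexicon)
        if (ans.start, ans.end) not in seen:
            seen.add((ans.start, ans.end))
            answers.append(ans)
    return answers


def split_patients(
    patient_ids: Iterable[str],
    proportions: tuple[float, float, float] = (0.70, 0.10, 0.20),
    seed: int = 0,
) -> dict[str, str]:
    """Assign each patient to train/validation/test by seeded shuffle + cut.

    Train and validation take ``floor(p * n)`` patients each; the remainder is
    the test set. Patient ids are sorted before the seeded shuffle so the
    assignment is reproducible regardless of input order.
    """
    if not math.isclose(sum(proportions), 1.0, abs_tol=1e-9):
        raise ValueError(f"split proportions must sum to 1, got {proportions}")
    ids = sorted(set(patient_ids))
    rng = random.Random(seed)
    rng.shuffle(ids)
    n = len(ids)
    n_train = math.floor(proportions[0] * n)
    n_val = math.floor(proportions[1] * n)
    assign: dict[str, str] = {}
    for i, pid in enumerate(ids):
        if i < n_train:
            assign[pid] = "train"
        elif i < n_train + n_val:
            assign[pid] = "validation"
        else:
            assign[pid] = "test"
    return assign


def build_gold_dataset(
    notes: Sequence[ClinicalNote],
    bank: Sequence[QuestionBankEntry],
    rules: RuleSet,
    lexicon: KeywordLexicon,
    split: tuple[float, float, float] = (0.70, 0.10, 0.20),
    seed: int = 0,
) -> list[QASample]:
    """Assemble the gold QA dataset from cleaned, enriched notes.

    One sample per (note, question variant) of each assigned query group;
    multiple answers of one group on a note become multiple answer entries of
    that sample. The split is at the patient level so no patient leaks across
    train/validation/test.
    """
    assignment = split_patients((n.patient_id for n in notes), split, seed)
    samples: list[QASample] = []
    for note in notes:
        answers = annotate_note(note, lexicon, bank, rules)
        for entry in bank:
            group_answers = [a for a in answers if entry.group in a.groups]
            if not group_answers:
                continue
            for vi, question in enumerate(entry.variants):
                samples.append(
                    QASample(
                        sample_id=f"{note.note_id}:{entry.group.value}:{vi}",
                        patient_id=note.patient_id,
                        note_id=note.note_id,
                        context=note.clean_text,  # type: ignore[arg-type]
                        question=question,
                        answers=group_answers,
                        split=assignment[note.patient_id],
                        group=entry.group,
                    )
                )
    return samples


def build_null_samples(
    notes: Sequence[ClinicalNote],
    bank: Sequence[QuestionBankEntry],
    question: str | None = None,
) -> list[QASample]:
    """Existence-group samples with empty answers for keyword-free notes."""
    entry = next(e for e in bank if e.group is QueryGroup.existence)
    q = question if question is not None else entry.base_question
    return [
        QASample(
            sample_id=f"{n.note_id}:null",
            patient_id=n.patient_id,
            note_id=n.note_id,
            context=n.clean_text if n.clean_text is not None else n.raw_text,
            question=q,
            answers=[],
            split="test",
            group=QueryGroup.existence,
        )
        for n in notes
    ]


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def write_squad(samples: Sequence[QASample], path: str) -> None:
    """Write samples as SQuAD-style JSON (data -> paragraphs -> qas)."""
    by_note: dict[str, list[QASample]] = {}
    for s in samples:
        by_note.setdefault(s.note_id, []).append(s)
    data = []
    for note_id, group in by_note.items():
        qas = [
            {
                "id": s.sample_id,
                "question": s.question,
                "answers": [
                    {"text": a.text, "answer_start": a.start} for a in s.answers
                ],
                "is_impossible": not s.answers,
                "split": s.split,
                "query_group": s.group.value if s.group else None,
            }
            for s in group
        ]
        data.append(
            {
                "title": group[0].patient_id,
                "paragraphs": [
                    {"context": group[0].context, "note_id": note_id, "qas": qas}
                ],
            }
        )
    with open(path, "w", encoding="utf-8") as fh:
        json.dump({"version": "iduqa-1.0", "data": data}, fh, indent=1)


def read_squad(path: str) -> list[QASample]:
    with open(path, "r", encoding="utf-8") as fh:
        payload = json.load(fh)
    samples: list[QASample] = []
    for article in payload["data"]:
        for para in article["paragraphs"]:
            context = para["context"]
            note_id = para.get("note_id", "")
            for qa in para["qas"]:
                answers = [
                    GoldAnswer(
                        note_id=note_id,
                        start=a["answer_start"],
                        end=a["answer_start"] + len(a["text"]),
                        text=a["text"],
                    )
                    for a in qa.get("answers", [])
                ]
                grp = qa.get("query_group")
                samples.append(
                    QASample(
                        sample_id=qa["id"],
                        patient_id=article.get("title", ""),
                        note_id=note_id,
                        context=context,
                        question=qa["question"],
                        answers=answers,
                        split=qa.get("split", ""),
                        group=QueryGroup(grp) if grp else None,
                    )
                )
    return samples


def write_samples_jsonl(samples: Sequence[QASample], path: str) -> None:
    """Flat JSONL export: one sample per line."""
    with open(path, "w", encoding="utf-8") as fh:
        for s in samples:
            fh.write(
                json.dumps(
                    {
                        "sample_id": s.sample_id,
                        "patient_id": s.patient_id,
                        "note_id": s.note_id,
                        "context": s.context,
                        "question": s.question,
                        "answers": [
                            {"text": a.text, "start": a.start, "end": a.end,
                             "groups": sorted(g.value for g in a.groups),
                             "rule_trace": a.rule_trace}
                            for a in s.answers
                        ],
                        "split": s.split,
                        "query_group": s.group.value if s.group else None,
                    }
                )
                + "\n"
            )
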