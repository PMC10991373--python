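"""Sliding-window QA engine with a pluggable answer extractor.

BERT-style span-QA models cap the input at ``max_seq_len`` tokens (512 by
default); with a 20-token question the per-chunk context budget is 492 tokens.
Longer notes are split into overlapping windows advanced by a document stride
(128 tokens). An *extractor* — any callable from a :class:`Chunk` to scored
span candidates plus a null candidate — scores each window; the engine gathers
candidates across windows, enforces the answer-length cap, deduplicates spans
found in window overlaps, and returns the best-scoring span (or the empty
string when the null candidate wins).

The reference extractor is rule-based: it reuses the pre-annotation pipeline
on the window text and scores answers by trigger-word overlap with the
question's query group, so the engine is fully testable without trained
weights. A transformer back-end can be plugged in behind the same contract.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Protocol, Sequence

from .annotate import (
    QASample,
    RuleSet,
    assign_groups,
    candidate_sentences,
    reduce_answer,
    split_sentences,
)
from .lexicon import (
    KeywordLexicon,
    QueryGroup,
    QuestionBankEntry,
    count_trigger_hits,
)
from .notes import match_keywords
from .tokens import Token, wordpunct_tokens

logger = logging.getLogger(__name__)

__all__ = [
    "Chunk",
    "Candidate",
    "SpanPrediction",
    "Extractor",
    "make_chunks",
    "predict",
    "predict_dataset",
    "rule_based_extractor",
]

MAX_SEQ_LEN = 512
QUERY_LENGTH = 20
ANSWER_LENGTH = 100
DOC_STRIDE = 128


@dataclass(frozen=True)
class Chunk:
    """One context window paired with the question tokens."""

    sample_id: str
    question_text: str
    question_tokens: tuple[str, ...]
    context_text: str  # the FULL context; window tokens carry offsets into it
    window_tokens: tuple[Token, ...]
    window_start_token: int


@dataclass(frozen=True)
class Candidate:
    """A scored window-relative token span; ``start/end is None`` marks null."""

    start_token: int | None
    end_token: int | None
    score: float


@dataclass(frozen=True)
class SpanPrediction:
    """A predicted answer span (or the empty string) with its score."""

    sample_id: str
    start_char: int | None
    end_char: int | None
    text: str
    score: float
    failed: bool = False


class Extractor(Protocol):
    def __call__(self, chunk: Chunk) -> list[Candidate]: ...


def make_chunks(
    question_tokens: Sequence[str],
    context_tokens: Sequence[Token],
    max_seq_len: int = MAX_SEQ_LEN,
    stride: int = DOC_STRIDE,
    query_length: int = QUERY_LENGTH,
    special_token_overhead: int = 0,
    sample_id: str = "",
    question_text: str = "",
    context_text: str = "",
) -> list[Chunk]:
    """Split the context into sliding windows of the remaining token budget.

    Window capacity is ``max_seq_len - len(question) - special_token_overhead``;
    window starts advance by ``stride`` until the final window reaches the end
    of the context, so every context token appears in at least one window.
    Questions longer than ``query_length`` tokens are truncated with a warning.
    """
    q = list(question_tokens)
    if len(q) > query_length:
        warnings.warn(
            f"question has {len(q)} tokens; truncating to query length {query_length}"
        )
        q = q[:query_length]
    capacity = max_seq_len - len(q) - special_token_overhead
    if capacity <= 0:
        raise ValueError("no token budget left for the context window")
    if stride <= 0 or stride >= capacity:
        raise ValueError(f"stride must be in (0, capacity={capacity}), got {stride}")
    starts = [0]
    while starts[-1] + capacity < len(context_tokens):
        starts.append(starts[-1] + stride)
    return [
        Chunk(
            sample_id=sample_id,
            question_text=question_text,
            question_tokens=tuple(q),
            context_text=context_text,
            window_tokens=tuple(context_tokens[s : s + capacity]),
            window_start_token=s,
        )
        for s in starts
    ]


def predict(
    sample: QASample,
    extractor: Extractor,
    max_seq_len: int = MAX_SEQ_LEN,
    stride: int = DOC_STRIDE,
    query_length: int = QUERY_LENGTH,
    answer_length: int = ANSWER_LENGTH,
    special_token_overhead: int = 0,
) -> SpanPrediction:
    """Predict one answer span for a sample by pooling candidates over chunks.

    Span candidates longer than ``answer_length`` tokens or with end before
    start are discarded; duplicates from window overlaps collapse to their
    best score; ties break toward the earlier, then shorter span. The null
    candidate wins only if it outscores every span candidate.
    """
    ctx_tokens = wordpunct_tokens(sample.context)
    q_tokens = [t.text for t in wordpunct_tokens(sample.question)]
    chunks = make_chunks(
        q_tokens,
        ctx_tokens,
        max_seq_len=max_seq_len,
        stride=stride,
        query_length=query_length,
        special_token_overhead=special_token_overhead,
        sample_id=sample.sample_id,
        question_text=sample.question,
        context_text=sample.context,
    )
    best_null = -math.inf
    spans: dict[tuple[int, int], float] = {}
    for chunk in chunks:
        for cand in extractor(chunk):
            if cand.start_token is None or cand.end_token is None:
                best_null = max(best_null, cand.score)
                continue
            if cand.end_token < cand.start_token:
                continue
            if cand.end_token - cand.start_token + 1 > answer_length:
                continue
            if not (0 <= cand.start_token < len(chunk.window_tokens)):
                continue
            if not (0 <= cand.end_token < len(chunk.window_tokens)):
                continue
            start_char = chunk.window_tokens[cand.start_token].start
            end_char = chunk.window_tokens[cand.end_token].end
            key = (start_char, end_char)
            if key not in spans or cand.score > spans[key]:
                spans[key] = cand.score
    if spans:
        (start_char, end_char), score = min(
            spans.items(), key=lambda kv: (-kv[1], kv[0][0], kv[0][1] - kv[0][0])
        )
        if best_null <= score:
            return SpanPrediction(
                sample_id=sample.sample_id,
                start_char=start_char,
                end_char=end_char,
                text=sample.context[start_char:end_char],
                score=score,
            )
    null_score = best_null if best_null > -math.inf else 0.0
    return SpanPrediction(sample.sample_id, None, None, "", null_score)


def predict_dataset(
    samples: Sequence[QASample], extractor: Extractor, **kwargs
) -> list[SpanPrediction]:
    """Predict over a dataset; extractor failures mark the sample failed and
    the pipeline continues."""
    out: list[SpanPrediction] = []
    for sample in samples:
        try:
            out.append(predict(sample, extractor, **kwargs))
        except Exception:  # noqa: BLE001 - isolate per-sample failures
            logger.exception("extractor failed on sample %s", sample.sample_id)
            out.append(
                SpanPrediction(sample.sample_id, None, None, "", math.nan, failed=True)
            )
    return out


# ---------------------------------------------------------------------------
# rule-based reference extractor
# ---------------------------------------------------------------------------

def _normalize_question(q: str) -> str:
    return " ".join(q.split()).lower()


def rule_based_extractor(
    bank: Sequence[QuestionBankEntry],
    lexicon: KeywordLexicon,
    rules: RuleSet,
    null_score: float = 0.5,
) -> Callable[[Chunk], list[Candidate]]:
    """Reference extractor: pre-annotation rules scored by trigger overlap.

    For a question of query group ``g``, the window text is run through the
    Step 1-3 reduction; answers mapped to ``g`` become span candidates scored
    by the count of ``g``'s trigger words they contain (plus generic IDU
    keyword hits for the existence group). Every chunk also yields a null
    candidate with a fixed score, so keyword-free windows predict the empty
    string. Deterministic: repeated calls give identical candidates.
    """
    variant_to_group: dict[str, QueryGroup] = {}
    for entry in bank:
        for v in entry.variants:
            variant_to_group[_normalize_question(v)] = entry.group
    triggers = {entry.group: entry.trigger_words for entry in bank}

    def group_for_question(question: str) -> QueryGroup | None:
        g = variant_to_group.get(_normalize_question(question))
        if g is not None:
            return g
        best: QueryGroup | None = None
        best_hits = 0
        for entry in bank:
            hits = count_trigger_hits(question, entry.trigger_words)
            if hits > best_hits:
                best, best_hits = entry.group, hits
        return best

    def score_answer(text: str, group: QueryGroup) -> float:
        score = float(count_trigger_hits(text, triggers[group]))
        if group is QueryGroup.existence:
            for entry in lexicon.by_group("generic_idu"):
                score += sum(1 for _ in entry.pattern.finditer(text))
        return score

    def extractor(chunk: Chunk) -> list[Candidate]:
        null = Candidate(None, None, null_score)
        if not chunk.window_tokens:
            return [null]
        group = group_for_question(chunk.question_text or " ".join(chunk.question_tokens))
        if group is None:
            return [null]
        base = chunk.window_tokens[0].start
        window_text = chunk.context_text[base : chunk.window_tokens[-1].end]
        matches = match_keywords(window_text, lexicon)
        if not matches:
            return [null]
        candidates = [null]
        sentences = split_sentences(window_text)
        for sent in candidate_sentences(sentences, matches):
            in_sent = [m for m in matches if m.start >= sent.start and m.end <= sent.end]
            ans = reduce_answer(sent, in_sent, rules)
            groups = assign_groups(ans.text, bank, lexicon)
            if group not in groups:
                continue
            abs_start, abs_end = base + ans.start, base + ans.end
            start_tok = end_tok = None
            for i, tok in enumerate(chunk.window_tokens):
                if start_tok is None and tok.start >= abs_start:
                    start_tok = i
                if tok.end <= abs_end:
                    end_tok = i
            if start_tok is None or end_tok is None or end_tok < start_tok:
                continue
            candidates.append(Candidate(start_tok, end_tok, score_answer(ans.text, group)))
        return candidates

    return extractor
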