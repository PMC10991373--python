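"""Clinical note records, text cleaning, keyword screening, and length filtering.

Cleaning applies four rules, in order, to undo common formatting damage in
free-text notes:

(i)   delete a newline that follows a within-sentence punctuation mark
      (comma, semicolon, colon);
(ii)  delete a newline that precedes a period, comma, or semicolon;
(iii) replace a newline flanked by word characters (a line break inside a
      sentence) with a single space;
(iv)  collapse runs of whitespace or of an identical punctuation character to
      a single instance.

One ordered application of (i)-(iv) can itself leave a newline directly
between word characters (rule (iv) may merge a mixed whitespace run into one
newline), so the ordered pass is iterated to a fixpoint; cleaning is therefore
idempotent by construction. An offset map (raw -> clean, monotone) is composed
across passes so spans can be projected in either direction.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Sequence

import numpy as np

from .lexicon import KeywordLexicon
from .tokens import whitespace_tokens

__all__ = [
    "ClinicalNote",
    "KeywordMatch",
    "OffsetMap",
    "clean_text",
    "clean_note",
    "clean_notes",
    "match_keywords",
    "enrich_filter",
    "remove_length_outliers",
    "read_notes_jsonl",
    "write_notes_jsonl",
    "read_notes_csv",
    "write_notes_csv",
]

_PUNCT_AFTER = ",;:"  # rule (i): newline after these is deleted
_PUNCT_BEFORE = ".,;"  # rule (ii): newline before these is deleted


@dataclass
class OffsetMap:
    """Monotone character-position mapping between raw and cleaned text."""

    raw_to_clean: np.ndarray  # length len(raw)+1
    clean_to_raw: np.ndarray  # length len(clean)+1

    def to_clean(self, pos: int) -> int:
        return int(self.raw_to_clean[pos])

    def to_raw(self, pos: int) -> int:
        return int(self.clean_to_raw[pos])

    def span_to_raw(self, start: int, end: int) -> tuple[int, int]:
        """Project a clean-text span back onto the raw text."""
        return int(self.clean_to_raw[start]), int(self.clean_to_raw[end])


@dataclass
class ClinicalNote:
    """One note record: identifiers, date, type, raw and (optionally) clean text."""

    note_id: str
    patient_id: str
    date: str
    note_type: str
    raw_text: str
    clean_text: str | None = None
    offset_map: OffsetMap | None = field(default=None, repr=False, compare=False)

    @property
    def length_words(self) -> int:
        """Whitespace-delimited word count of the cleaned text."""
        if self.clean_text is None:
            raise ValueError(f"note {self.note_id}: not cleaned yet")
        return len(whitespace_tokens(self.clean_text))


@dataclass(frozen=True)
class KeywordMatch:
    """A lexicon hit in cleaned text: ``clean[start:end] == matched_text``."""

    keyword_group: str
    matched_text: str
    start: int
    end: int


# ---------------------------------------------------------------------------
# cleaning
# ---------------------------------------------------------------------------

def _char_pass(
    text: str, decide: Callable[[str, int], str | None]
) -> tuple[str, np.ndarray]:
    """Apply a per-character edit; returns new text and src->dst offset map.

    ``decide`` returns None to keep the character, "" to delete it, or a
    replacement string of length one.
    """
    out: list[str] = []
    mapping = np.empty(len(text) + 1, dtype=np.int64)
    for i, ch in enumerate(text):
        mapping[i] = len(out)
        action = decide(text, i)
        if action is None:
            out.append(ch)
        elif action:
            out.append(action)
    mapping[len(text)] = len(out)
    return "".join(out), mapping


def _rule_i(text: str, i: int) -> str | None:
    if text[i] == "\n" and i > 0 and text[i - 1] in _PUNCT_AFTER:
        return ""
    return None


def _rule_ii(text: str, i: int) -> str | None:
    if text[i] == "\n" and i + 1 < len(text) and text[i + 1] in _PUNCT_BEFORE:
        return ""
    return None


def _is_word(ch: str) -> bool:
    return ch.isalnum() or ch == "_"


def _rule_iii(text: str, i: int) -> str | None:
    if (
        text[i] == "\n"
        and 0 < i < len(text) - 1
        and _is_word(text[i - 1])
        and _is_word(text[i + 1])
    ):
        return " "
    return None


def _collapse_runs(text: str) -> tuple[str, np.ndarray]:
    """Rule (iv): collapse whitespace runs and identical-punctuation runs."""
    out: list[str] = []
    mapping = np.empty(len(text) + 1, dtype=np.int64)
    i = 0
    n = len(text)
    while i < n:
        ch = text[i]
        j = i + 1
        if ch.isspace():
            while j < n and text[j].isspace():
                j += 1
            run = text[i:j]
            kept = "\n" if "\n" in run else run[0]
            mapping[i:j] = len(out)
            out.append(kept)
        elif not _is_word(ch):
            while j < n and text[j] == ch:
                j += 1
            mapping[i:j] = len(out)
            out.append(ch)
        else:
            mapping[i] = len(out)
            out.append(ch)
        i = j
    mapping[n] = len(out)
    return "".join(out), mapping


def _one_round(text: str) -> tuple[str, np.ndarray]:
    total = np.arange(len(text) + 1, dtype=np.int64)
    for rule in (_rule_i, _rule_ii, _rule_iii):
        text, m = _char_pass(text, rule)
        total = m[total]
    text, m = _collapse_runs(text)
    total = m[total]
    return text, total


def clean_text(raw: str) -> tuple[str, OffsetMap]:
    """Clean note text; returns the cleaned text and a raw<->clean offset map.

    Total and idempotent: ``clean_text(clean)[0] == clean``.
    """
    text = raw
    total = np.arange(len(raw) + 1, dtype=np.int64)
    for _ in range(5):
        new_text, m = _one_round(text)
        total = m[total]
        if new_text == text:
            break
        text = new_text
    clean_to_raw = np.searchsorted(total, np.arange(len(text) + 1), side="left")
    return text, OffsetMap(raw_to_clean=total, clean_to_raw=clean_to_raw.astype(np.int64))


def clean_note(note: ClinicalNote) -> ClinicalNote:
    """Return a copy of ``note`` with ``clean_text`` and ``offset_map`` set."""
    clean, omap = clean_text(note.raw_text)
    return replace(note, clean_text=clean, offset_map=omap)


def clean_notes(notes: Iterable[ClinicalNote]) -> list[ClinicalNote]:
    return [clean_note(n) for n in notes]


# ---------------------------------------------------------------------------
# keyword screening
# ---------------------------------------------------------------------------

def match_keywords(clean: str, lexicon: KeywordLexicon) -> list[KeywordMatch]:
    """All non-overlapping lexicon matches in cleaned text, sorted by start.

    Patterns are case-insensitive and word-boundary anchored (so ``idu`` never
    fires inside ``individual``). Where entries overlap, the earliest match
    wins; ties prefer the longest match, then lexicon order.
    """
    raw: list[tuple[int, int, int, KeywordMatch]] = []
    for idx, entry in enumerate(lexicon.entries):
        for m in entry.pattern.finditer(clean):
            raw.append(
                (
                    m.start(),
                    -(m.end() - m.start()),
                    idx,
                    KeywordMatch(entry.keyword_group, m.group(), m.start(), m.end()),
                )
            )
    raw.sort(key=lambda t: t[:3])
    out: list[KeywordMatch] = []
    last_end = -1
    for _, _, _, km in raw:
        if km.start >= last_end:
            out.append(km)
            last_end = km.end
    return out


def enrich_filter(
    notes: Sequence[ClinicalNote], lexicon: KeywordLexicon
) -> tuple[list[ClinicalNote], list[ClinicalNote]]:
    """Split notes into (kept, dropped): kept notes contain >=1 IDU keyword."""
    kept: list[ClinicalNote] = []
    dropped: list[ClinicalNote] = []
    for note in notes:
        if note.clean_text is None:
            raise ValueError(f"note {note.note_id}: clean before enrichment")
        (kept if match_keywords(note.clean_text, lexicon) else dropped).append(note)
    return kept, dropped


def remove_length_outliers(
    notes: Sequence[ClinicalNote], iqr_multiplier: float = 1.5
) -> list[ClinicalNote]:
    """Drop notes whose word count lies outside ``[Q1 - k*IQR, Q3 + k*IQR]``.

    Quartiles are computed on the input word counts; order is preserved. With
    fewer than 4 notes the quartiles are meaningless, so the input is returned
    unchanged with a warning.
    """
    if iqr_multiplier <= 0:
        raise ValueError("iqr_multiplier must be positive")
    notes = list(notes)
    if len(notes) < 4:
        warnings.warn("fewer than 4 notes; skipping IQR outlier removal")
        return notes
    lengths = np.array([n.length_words for n in notes], dtype=float)
    q1, q3 = np.percentile(lengths, [25, 75])
    iqr = q3 - q1
    lo, hi = q1 - iqr_multiplier * iqr, q3 + iqr_multiplier * iqr
    return [n for n, w in zip(notes, lengths) if lo <= w <= hi]


# ---------------------------------------------------------------------------
# I/O: JSONL and CSV corpora
# ---------------------------------------------------------------------------

_FIELDS = ("note_id", "patient_id", "date", "note_type", "text")


def _note_from_record(rec: dict) -> ClinicalNote:
    return ClinicalNote(
        note_id=str(rec["note_id"]),
        patient_id=str(rec["patient_id"]),
        date=str(rec["date"]),
        note_type=str(rec.get("note_type", "")),
        raw_text=str(rec["text"]),
    )


def read_notes_jsonl(path: str) -> list[ClinicalNote]:
    """Read notes from JSONL (one record per line with the standard header)."""
    notes = []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if line.strip():
                notes.append(_note_from_record(json.loads(line)))
    return notes


def write_notes_jsonl(notes: Iterable[ClinicalNote], path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for n in notes:
            rec = {
                "note_id": n.note_id,
                "patient_id": n.patient_id,
                "date": n.date,
                "note_type": n.note_type,
                "text": n.clean_text if n.clean_text is not None else n.raw_text,
            }
            fh.write(json.dumps(rec) + "\n")


def read_notes_csv(path: str) -> list[ClinicalNote]:
    with open(path, "r", encoding="utf-8", newline="") as fh:
        return [_note_from_record(rec) for rec in csv.DictReader(fh)]


def write_notes_csv(notes: Iterable[ClinicalNote], path: str) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=_FIELDS)
        writer.writeheader()
        for n in notes:
            writer.writerow(
                {
                    "note_id": n.note_id,
                    "patient_id": n.patient_id,
                    "date": n.date,
                    "note_type": n.note_type,
                    "text": n.clean_text if n.clean_text is not None else n.raw_text,
                }
            )
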