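"""Keyword lexicon, query groups, question bank, and trigger words.

The information targets are organized in nine *query groups* — the categories
of injection-drug-use (IDU) information a clinician may ask about. Notes are
screened with a keyword lexicon organized in six *keyword groups*; answers are
routed to query groups through per-group *trigger word* sets.

The bundled default configuration reproduces the published keyword table and
question inventory; every section can be overridden from a user JSON file with
sections ``keywords``, ``questions``, ``triggers``, ``substitutions``,
``syntax_templates`` and ``rules``.
"""

from __future__ import annotations

import copy
import json
import re
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from typing import Iterable, Iterator

__all__ = [
    "QueryGroup",
    "KEYWORD_GROUPS",
    "ConfigError",
    "LexiconEntry",
    "KeywordLexicon",
    "QuestionBankEntry",
    "load_config",
    "load_lexicon",
    "load_question_bank",
    "expand_question_variants",
    "triggers_for_group",
    "count_trigger_hits",
    "expand_compact_pattern",
]


class QueryGroup(str, Enum):
    """The nine categories of IDU information clinicians ask about."""

    drug_names = "drug_names"
    visible_signs = "visible_signs"
    risky_needle = "risky_needle"
    active_historical = "active_historical"
    frequency = "frequency"
    last_use = "last_use"
    skin_popping = "skin_popping"
    harm_reduction = "harm_reduction"
    existence = "existence"


#: The six keyword groups of the screening lexicon.
KEYWORD_GROUPS = (
    "iv_drug_names",
    "visible_signs",
    "risky_needle",
    "skin_popping",
    "harm_reduction",
    "generic_idu",
)


class ConfigError(ValueError):
    """Raised when a lexicon/question-bank configuration entry is invalid."""


# ---------------------------------------------------------------------------
# compact pattern grammar
# ---------------------------------------------------------------------------

def _split_top_level(text: str, sep: str) -> list[str]:
    """Split on ``sep`` outside parentheses."""
    parts, depth, buf = [], 0, []
    for ch in text:
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise ConfigError(f"unbalanced ')' in pattern {text!r}")
        if ch == sep and depth == 0:
            parts.append("".join(buf))
            buf = []
        else:
            buf.append(ch)
    if depth != 0:
        raise ConfigError(f"unbalanced '(' in pattern {text!r}")
    parts.append("".join(buf))
    return parts


_SUFFIX_RE = re.compile(r"^(?P<stem>[^()]*)\((?P<sufs>[^()]+)\)$")


def _expand_part(part: str, source: str) -> list[str]:
    """Expand one slash-alternative, honoring ``stem(s/ed)`` suffix markers."""
    part = part.strip()
    if not part:
        raise ConfigError(f"empty alternative in pattern {source!r}")
    m = _SUFFIX_RE.match(part)
    if m is None:
        if "(" in part or ")" in part:
            raise ConfigError(f"malformed inflection marker in pattern {source!r}")
        return [part]
    stem = m.group("stem")
    sufs = [s for s in m.group("sufs").split("/")]
    if any(not s for s in sufs):
        raise ConfigError(f"empty suffix alternative in pattern {source!r}")
    # the bare stem is a valid surface form too: "safe(r)" -> safe, safer
    return [stem] + [stem + s for s in sufs]


def expand_compact_pattern(compact: str) -> list[list[str]]:
    """Expand a compact keyword pattern into per-token alternative lists.

    The compact grammar is the one used in the published keyword table:
    whitespace separates tokens, top-level ``/`` separates alternatives of a
    token, and a trailing ``(a/b)`` marks optional suffixes of the stem, e.g.
    ``"sharing/shared/dirty needle(s)"`` expands to
    ``[[sharing, shared, dirty], [needle, needles]]``.
    """
    if not compact or not compact.strip():
        raise ConfigError("empty keyword pattern")
    token_alts: list[list[str]] = []
    for token in compact.split():
        alts: list[str] = []
        for part in _split_top_level(token, "/"):
            alts.extend(_expand_part(part, compact))
        # dedupe, preserve order
        seen: dict[str, None] = {}
        for a in alts:
            seen.setdefault(a)
        token_alts.append(list(seen))
    return token_alts


def _compile_compact(compact: str) -> tuple[re.Pattern[str], str]:
    token_alts = expand_compact_pattern(compact)
    token_res = [
        "(?:" + "|".join(re.escape(a) for a in alts) + ")" for alts in token_alts
    ]
    pattern = re.compile(r"\b" + r"\s+".join(token_res) + r"\b", re.IGNORECASE)
    canonical = " ".join(alts[0] for alts in token_alts)
    if pattern.fullmatch(canonical) is None:  # pragma: no cover - defensive
        raise ConfigError(f"pattern {compact!r} does not match its canonical form")
    return pattern, canonical


# ---------------------------------------------------------------------------
# lexicon
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LexiconEntry:
    """One lexicon pattern: a keyword group, a compiled pattern, its canonical form."""

    keyword_group: str
    source: str
    pattern: re.Pattern[str]
    canonical_form: str

    def surface_forms(self) -> list[str]:
        """All literal surface forms the pattern accepts (cross product of tokens)."""
        from itertools import product

        return [" ".join(p) for p in product(*expand_compact_pattern(self.source))]


@dataclass
class KeywordLexicon:
    """The IDU screening lexicon: compiled keyword patterns in six groups."""

    entries: list[LexiconEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        groups = {e.keyword_group for e in self.entries}
        unknown = groups - set(KEYWORD_GROUPS)
        if unknown:
            raise ConfigError(f"unknown keyword group(s): {sorted(unknown)}")

    def by_group(self, group: str) -> list[LexiconEntry]:
        return [e for e in self.entries if e.keyword_group == group]

    def iter_matches(self, text: str) -> Iterator[tuple[LexiconEntry, re.Match[str]]]:
        """All raw (entry, match) pairs; overlap resolution is the caller's job."""
        for entry in self.entries:
            for m in entry.pattern.finditer(text):
                yield entry, m


@dataclass
class QuestionBankEntry:
    """A query group with its question variants and trigger-word set."""

    group: QueryGroup
    base_question: str
    variants: list[str]
    trigger_words: set[str]

    def __post_init__(self) -> None:
        if not self.variants:
            raise ConfigError(f"{self.group.value}: empty question variant list")
        if len(set(self.variants)) != len(self.variants):
            raise ConfigError(f"{self.group.value}: duplicate question variants")
        if self.base_question not in self.variants:
            raise ConfigError(f"{self.group.value}: base question not among variants")


# ---------------------------------------------------------------------------
# configuration loading
# ---------------------------------------------------------------------------

def _default_config() -> dict:
    with resources.files("iduqa.data").joinpath("default_config.json").open(
        "r", encoding="utf-8"
    ) as fh:
        return json.load(fh)


def load_config(config_path: str | None = None) -> dict:
    """Load the merged configuration (defaults overlaid with the user file).

    Merging is per section and, inside ``keywords``/``questions``/``triggers``,
    per group: a group present in the user file replaces the default entry for
    that group; omitted groups keep their defaults. An empty user section is a
    no-op, so merging is idempotent.
    """
    cfg = _default_config()
    if config_path is None:
        return cfg
    with open(config_path, "r", encoding="utf-8") as fh:
        user = json.load(fh)
    for section, value in user.items():
        if isinstance(value, dict) and isinstance(cfg.get(section), dict):
            merged = copy.deepcopy(cfg[section])
            merged.update(value)
            cfg[section] = merged
        else:
            cfg[section] = value
    return cfg


def load_lexicon(config_path: str | None = None) -> KeywordLexicon:
    """Build the keyword lexicon from the default + user configuration.

    Compact slash-alternations are expanded into explicit alternatives and
    compiled as case-insensitive, word-boundary-anchored patterns. A malformed
    pattern raises :class:`ConfigError` naming the offending entry.
    """
    cfg = load_config(config_path)
    entries: list[LexiconEntry] = []
    for group in KEYWORD_GROUPS:
        for compact in cfg["keywords"].get(group, []):
            try:
                pattern, canonical = _compile_compact(compact)
            except ConfigError as err:
                raise ConfigError(
                    f"keyword group {group!r}, entry {compact!r}: {err}"
                ) from err
            entries.append(LexiconEntry(group, compact, pattern, canonical))
    return KeywordLexicon(entries)


def load_question_bank(config_path: str | None = None) -> list[QuestionBankEntry]:
    """Load the nine query groups with their question variants and triggers."""
    cfg = load_config(config_path)
    bank: list[QuestionBankEntry] = []
    for group in QueryGroup:
        try:
            q = cfg["questions"][group.value]
        except KeyError:
            raise ConfigError(f"missing question entry for query group {group.value!r}")
        triggers = set(cfg["triggers"].get(group.value, []))
        bank.append(
            QuestionBankEntry(
                group=group,
                base_question=q["base"],
                variants=list(q["variants"]),
                trigger_words=triggers,
            )
        )
    return bank


def triggers_for_group(
    group: QueryGroup | str, config_path: str | None = None
) -> set[str]:
    """Trigger words/phrases whose presence routes an answer to ``group``."""
    group = QueryGroup(group)
    cfg = load_config(config_path)
    return set(cfg["triggers"].get(group.value, []))


# ---------------------------------------------------------------------------
# trigger matching
# ---------------------------------------------------------------------------

def _trigger_regex(trigger: str) -> re.Pattern[str]:
    words = [re.escape(w) for w in trigger.split()]
    return re.compile(r"(?<!\w)" + r"\s+".join(words) + r"(?!\w)", re.IGNORECASE)


def count_trigger_hits(text: str, triggers: Iterable[str]) -> int:
    """Number of boundary-anchored, case-insensitive trigger occurrences in ``text``."""
    total = 0
    for trig in triggers:
        total += sum(1 for _ in _trigger_regex(trig).finditer(text))
    return total


# ---------------------------------------------------------------------------
# question variant expansion
# ---------------------------------------------------------------------------

_TRANSFORMS = ("abbreviation", "synonym", "syntax")


def _word_sub(question: str, a: str, b: str) -> str:
    return re.sub(rf"\b{re.escape(a)}\b", b, question)


def expand_question_variants(
    base_question: str,
    group: QueryGroup | str,
    transforms: set[str],
    config_path: str | None = None,
) -> list[str]:
    """Generate question variants by abbreviation, synonym, and syntax rewrites.

    Substitution pairs (patient<->pt, intravenous<->iv, history<->hx,
    IDU<->IVDU, injection<->intravenous) are applied one at a time in both
    directions, plus an all-substitutions pass, for two rounds; syntactic
    templates are anchored rewrite rules. The result is deduplicated and
    deterministic, and expansion is closed (re-expanding adds nothing).
    """
    if not base_question:
        raise ValueError("base_question must be non-empty")
    QueryGroup(group)  # validate
    unknown = set(transforms) - set(_TRANSFORMS)
    if unknown:
        raise ValueError(f"unknown transform label(s): {sorted(unknown)}")
    cfg = load_config(config_path)

    pairs: list[tuple[str, str]] = []
    for kind in ("abbreviation", "synonym"):
        if kind in transforms:
            pairs.extend((a, b) for a, b in cfg["substitutions"][kind])
    templates: list[tuple[re.Pattern[str], str]] = []
    if "syntax" in transforms:
        templates = [
            (re.compile(pat), repl) for pat, repl in cfg["syntax_templates"]
        ]

    out: dict[str, None] = {base_question: None}
    for _ in range(2):
        for q in list(out):
            for a, b in pairs:
                out.setdefault(_word_sub(q, a, b))
                out.setdefault(_word_sub(q, b, a))
            if pairs:
                all_fwd = q
                all_bwd = q
                for a, b in pairs:
                    all_fwd = _word_sub(all_fwd, a, b)
                    all_bwd = _word_sub(all_bwd, b, a)
                out.setdefault(all_fwd)
                out.setdefault(all_bwd)
            for pat, repl in templates:
                rewritten = pat.sub(repl, q)
                if rewritten != q and pat.match(q):
                    out.setdefault(rewritten)
    return list(out)
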