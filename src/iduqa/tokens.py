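"""Offset-preserving tokenizers.

Two tokenizations coexist in the pipeline: whitespace tokens are the unit of
the relaxed evaluation metrics and of word counts (words are whitespace
delimited), while the QA engine's reference tokenizer splits punctuation into
its own tokens so answer spans that exclude a trailing period still align to
token boundaries.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

__all__ = ["Token", "whitespace_tokens", "wordpunct_tokens"]

_WS = re.compile(r"\S+")
_WP = re.compile(r"\w+|[^\w\s]")


@dataclass(frozen=True)
class Token:
    text: str
    start: int
    end: int  # half-open


def _tokenize(text: str, pattern: re.Pattern[str]) -> list[Token]:
    return [Token(m.group(), m.start(), m.end()) for m in pattern.finditer(text)]


def whitespace_tokens(text: str) -> list[Token]:
    """Whitespace-delimited tokens with character offsets."""
    return _tokenize(text, _WS)


def wordpunct_tokens(text: str) -> list[Token]:
    """Word/punctuation tokens (``\\w+`` runs or single punctuation marks)."""
    return _tokenize(text, _WP)
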