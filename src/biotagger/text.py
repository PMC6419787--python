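"""Canonicalization and tokenization shared by the lexicon and the engine.

Flexible matching is defined as equality of *canonical keys*: text is
full-case-folded, and every maximal run of separator-class characters
(whitespace plus a configurable hyphen class covering ASCII hyphen,
Unicode hyphens, en/em dashes, underscore and slash) collapses to a
single space.  This captures the case / hyphen / spacing variation that
dictionary names exhibit while staying deterministic and cheap.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

__all__ = ["Token", "HYPHEN_CLASS", "canonicalize", "tokenize", "separator_pattern"]

#: Characters treated like a hyphen: they separate tokens and collapse
#: to a single space under canonicalization.
HYPHEN_CLASS = "-‐‑‒–—_/"


def separator_pattern(hyphen_class: str = HYPHEN_CLASS) -> tuple[re.Pattern, re.Pattern]:
    """Compile (separator-run, token-run) regexes for a hyphen class."""
    cls = re.escape(hyphen_class)
    return (
        re.compile(rf"[\s{cls}]+"),
        re.compile(rf"[^\s{cls}]+"),
    )


_SEP_RE, _TOKEN_RE = separator_pattern()


@dataclass(frozen=True)
class Token:
    """A maximal run of non-separator characters, with half-open offsets."""

    start: int
    end: int
    text: str


def canonicalize(surface: str, sep_re: re.Pattern = _SEP_RE) -> str:
    """Case-fold and collapse separator runs to single spaces.

    Pure; the empty string canonicalizes to the empty string.  Leading
    and trailing separators are stripped.  All non-separator characters
    are preserved (punctuation such as ``.`` or ``'`` stays put).
    """
    return sep_re.sub(" ", surface.casefold()).strip()


def tokenize(text: str, token_re: re.Pattern = _TOKEN_RE) -> list[Token]:
    """Split on separator-class characters, keeping exact offsets.

    Punctuation adjacent to alphanumerics stays attached to its token,
    so ``"E. coli"`` yields tokens ``"E."`` and ``"coli"``.  The tokens
    plus the gaps between them reconstruct the input exactly.
    """
    return [Token(m.start(), m.end(), m.group(0)) for m in token_re.finditer(text)]
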