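"""Dictionary-based named entity recognition by hash lookups.

The engine considers, for each document section, every window of
1..max_key_tokens consecutive tokens, forms the window's canonical key,
and looks it up in the preloaded dictionary index.  Because matching is
a pure function of (document, dictionary, requested types) and the
dictionary is read-only, a single dictionary instance safely serves any
number of concurrent calls, and tagging time depends on document length
and the longest name's token count — not on dictionary size.

Matches must start and end on token boundaries.  Overlapping candidates
are resolved leftmost-longest per section; candidates sharing an
identical span but mapping to different entity types are all reported,
one annotation per type, each carrying every matching identifier
(ambiguity is preserved, never resolved by the engine).

:func:`oracle_tag` is a deliberately naive reference implementation
(per-name sliding scan) used as ground truth in tests; it shares no
lookup machinery with :func:`tag`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .dictionary import Dictionary, EntityType, map_type
from .documents import Document, SECTIONS
from .text import Token, canonicalize, tokenize

__all__ = ["Annotation", "MatchConfig", "tag", "tag_sections", "oracle_tag"]

ALL_TYPES = frozenset(EntityType)


@dataclass(frozen=True)
class Annotation:
    """A matched span in a document section, normalized to identifiers.

    Offsets are 0-based, half-open, within the section's text.
    ``identifiers`` lists (type_code, database identifier) for every
    entity of ``entity_type`` sharing the matched canonical key.
    """

    document_id: str
    section: str  # "T" or "A"
    start: int
    end: int
    matched_text: str
    entity_type: EntityType
    identifiers: tuple[tuple[int, str], ...]


@dataclass(frozen=True)
class MatchConfig:
    """Engine knobs.

    min_key_length: canonical keys shorter than this only match when the
    source span equals one of the dictionary's exact surface forms for
    the key — a guard against false positives from aggressive folding of
    one-letter symbols.
    """

    min_key_length: int = 2


DEFAULT_CONFIG = MatchConfig()

# sort rank: title before abstract, i.e. document order
_SECTION_RANK = {"T": 0, "A": 1}


def _resolve_leftmost_longest(
    candidates: list[tuple[int, int, str]],
) -> list[tuple[int, int, str]]:
    """Greedy leftmost-longest sweep over (start, end, key) candidates."""
    kept: list[tuple[int, int, str]] = []
    last_end = -1
    for cand in sorted(candidates, key=lambda c: (c[0], -c[1])):
        if cand[0] >= last_end:
            kept.append(cand)
            last_end = cand[1]
    return kept


def _emit(
    document_id: str,
    section: str,
    text: str,
    spans: Iterable[tuple[int, int, str]],
    dictionary: Dictionary,
    types: frozenset[EntityType],
) -> list[Annotation]:
    """Turn resolved (start, end, key) spans into per-type annotations."""
    out: list[Annotation] = []
    for start, end, key in spans:
        by_type: dict[EntityType, list[tuple[int, str]]] = {}
        for serial in dictionary.index[key]:
            ent = dictionary.entities[serial]
            by_type.setdefault(ent.entity_type, []).append((ent.type_code, ent.identifier))
        for etype in sorted(by_type, key=lambda t: t.value):
            if etype not in types:
                continue
            out.append(
                Annotation(
                    document_id=document_id,
                    section=section,
                    start=start,
                    end=end,
                    matched_text=text[start:end],
                    entity_type=etype,
                    identifiers=tuple(by_type[etype]),
                )
            )
    return out


def _candidate_ok(
    key: str,
    span_text: str,
    dictionary: Dictionary,
    types: frozenset[EntityType],
    config: MatchConfig,
) -> bool:
    if key in dictionary.blocked:
        return False
    if len(key) < config.min_key_length and span_text not in dictionary.surfaces.get(key, ()):
        return False
    return any(
        map_type(dictionary.entities[s].type_code) in types for s in dictionary.index[key]
    )


def tag_sections(
    document_id: str,
    sections: Sequence[tuple[str, str]],
    dictionary: Dictionary,
    types: Iterable[EntityType] = ALL_TYPES,
    config: MatchConfig = DEFAULT_CONFIG,
) -> list[Annotation]:
    """Tag (section_label, text) pairs; the engine's inner entry point."""
    types = frozenset(types)
    annotations: list[Annotation] = []
    max_tokens = dictionary.max_key_tokens
    if max_tokens == 0:
        return annotations
    for label, text in sections:
        tokens = tokenize(text)
        # token text contains no separator characters, so the canonical
        # key of any token window is its case-folded tokens joined by
        # single spaces — no per-window re-canonicalization needed
        folded = [t.text.casefold() for t in tokens]
        n = len(tokens)
        index = dictionary.index
        candidates: list[tuple[int, int, str]] = []
        for i in range(n):
            key = folded[i]
            for j in range(i, min(i + max_tokens, n)):
                if j > i:
                    key = f"{key} {folded[j]}"
                if key in index:
                    start, end = tokens[i].start, tokens[j].end
                    if _candidate_ok(key, text[start:end], dictionary, types, config):
                        candidates.append((start, end, key))
        resolved = _resolve_leftmost_longest(candidates)
        annotations.extend(_emit(document_id, label, text, resolved, dictionary, types))
    annotations.sort(key=lambda a: (_SECTION_RANK[a.section], a.start, a.entity_type.value))
    return annotations


def tag(
    doc: Document,
    dictionary: Dictionary,
    types: Iterable[EntityType] = ALL_TYPES,
    config: MatchConfig = DEFAULT_CONFIG,
) -> list[Annotation]:
    """Find all dictionary matches in a document's title and abstract."""
    return tag_sections(
        doc.document_id,
        [("T", doc.title), ("A", doc.abstract)],
        dictionary,
        types,
        config,
    )


def oracle_tag(
    doc: Document,
    dictionary: Dictionary,
    types: Iterable[EntityType] = ALL_TYPES,
    config: MatchConfig = DEFAULT_CONFIG,
) -> list[Annotation]:
    """Naive O(names x text) reference tagger for small inputs.

    For every dictionary key, slide a window of the key's token count
    over each section and compare the canonicalized source span against
    the key.  Applies the same candidate filters and the same
    leftmost-longest resolution as :func:`tag`, but through an
    independent code path (no hash lookups on window keys).
    """
    types = frozenset(types)
    annotations: list[Annotation] = []
    for label in SECTIONS:
        text = doc.section(label)
        tokens = tokenize(text)
        n = len(tokens)
        candidates: list[tuple[int, int, str]] = []
        for key in dictionary.index:
            width = key.count(" ") + 1
            for i in range(n - width + 1):
                start, end = tokens[i].start, tokens[i + width - 1].end
                span_text = text[start:end]
                if canonicalize(span_text) != key:
                    continue
                if _candidate_ok(key, span_text, dictionary, types, config):
                    candidates.append((start, end, key))
        # independent leftmost-longest resolution
        chosen: list[tuple[int, int, str]] = []
        remaining = sorted(set(candidates), key=lambda c: (c[0], c[0] - c[1]))
        while remaining:
            best = remaining[0]
            chosen.append(best)
            remaining = [c for c in remaining if c[0] >= best[1]]
        annotations.extend(_emit(doc.document_id, label, text, chosen, dictionary, types))
    annotations.sort(key=lambda a: (_SECTION_RANK[a.section], a.start, a.entity_type.value))
    return annotations
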