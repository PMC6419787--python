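"""Flat-file annotation table: the CLI's output format.

Columns: ``document_id  section  start  end  matched_text  type
identifiers`` (tab-separated; identifiers ``;``-joined database ids).
Rows are sorted by (document_id, section with title first, start).
"""

from __future__ import annotations

from typing import IO, Iterable

from .ner import Annotation

__all__ = ["annotation_row", "write_annotations", "sort_key"]

_SECTION_RANK = {"T": 0, "A": 1}


def sort_key(a: Annotation) -> tuple:
    return (a.document_id, _SECTION_RANK[a.section], a.start, a.entity_type.value)


def annotation_row(a: Annotation) -> str:
    ids = ";".join(identifier for _code, identifier in a.identifiers)
    return (
        f"{a.document_id}\t{a.section}\t{a.start}\t{a.end}\t"
        f"{a.matched_text}\t{a.entity_type.value}\t{ids}"
    )


def write_annotations(annotations: Iterable[Annotation], fh: IO[str]) -> None:
    for a in sorted(annotations, key=sort_key):
        fh.write(annotation_row(a) + "\n")
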