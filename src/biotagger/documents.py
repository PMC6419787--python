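"""Documents: a title/abstract pair addressed by an identifier.

Corpus files are headerless TSV rows ``document_id<TAB>title<TAB>abstract``;
section texts therefore must not contain tabs or newlines (the synthetic
corpus generator guarantees this).
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

__all__ = ["Document", "read_corpus", "write_corpus"]

#: Section labels: T = title, A = abstract/body.
SECTIONS = ("T", "A")


@dataclass(frozen=True)
class Document:
    """One document; missing sections are empty strings, never absent."""

    document_id: str
    title: str = ""
    abstract: str = ""
    source: str = ""

    def __post_init__(self):
        if not self.document_id:
            raise ValueError("document_id must be non-empty")

    def section(self, label: str) -> str:
        if label == "T":
            return self.title
        if label == "A":
            return self.abstract
        raise KeyError(label)


def read_corpus(path: str | os.PathLike) -> list[Document]:
    """Read a ``document_id<TAB>title<TAB>abstract`` TSV."""
    docs = []
    for line_no, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        if not line:
            continue
        fields = line.split("\t")
        if len(fields) != 3:
            raise ValueError(f"{path}:{line_no}: expected 3 fields, got {len(fields)}")
        docs.append(Document(document_id=fields[0], title=fields[1], abstract=fields[2]))
    return docs


def write_corpus(docs: Iterable[Document], path: str | os.PathLike) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for doc in docs:
            for text in (doc.title, doc.abstract):
                if "\t" in text or "\n" in text:
                    raise ValueError(f"document {doc.document_id}: section text contains TAB/newline")
            fh.write(f"{doc.document_id}\t{doc.title}\t{doc.abstract}\n")
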