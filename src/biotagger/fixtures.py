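"""Deterministic synthetic lexicons and corpora with planted entities.

Everything here is driven by one explicit seed through a single
``random.Random`` instance per call — identical specs yield byte-identical
files on any platform, so tests and benchmarks never need downloads.

In *strict* mode the decoy vocabulary is drawn from a character alphabet
disjoint from the one dictionary names use, so no decoy n-gram can ever
canonicalize to a dictionary key: the engine's output on a strict corpus
is provably exactly the planted ground truth.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from pathlib import Path
from .dictionary import (
    Dictionary,
    EntityType,
    RESERVED_TYPE_CODES,
    load_dictionary,
)
from .documents import Document
from .ner import Annotation
from .text import canonicalize

__all__ = ["FixtureSpec", "make_dictionary", "make_corpus", "write_fixture"]

# dictionary names draw on the left alphabet, decoys on the right one
_NAME_ALPHABET = "abcdefghijklm"
_DECOY_ALPHABET = "nopqrstuvwxyz"

_TYPE_ORDER = tuple(EntityType)
_CODE_FOR_TYPE = {v: k for k, v in RESERVED_TYPE_CODES.items()}
_GENE_TAXA = (9606, 10090, 7227, 4932, 511145)


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic dataset; identical specs → identical bytes."""

    seed: int = 7
    entities_per_type: int = 10
    names_per_entity: tuple[int, int] = (1, 3)
    n_documents: int = 20
    planted_per_document: tuple[int, int] = (3, 5)
    decoy_vocabulary_size: int = 200
    ambiguous_fraction: float = 0.15
    strict: bool = True


def _identifier(rng: random.Random, etype: EntityType, type_code: int, serial: int) -> str:
    if etype is EntityType.GENE:
        return f"{type_code}.ENSP{serial:011d}"
    if etype is EntityType.CHEMICAL:
        return f"CID{serial:09d}"
    if etype is EntityType.ORGANISM:
        return str(10000 + serial)
    if etype is EntityType.SUBCELLULAR_STRUCTURE:
        return f"GO:{serial:07d}"
    if etype is EntityType.TISSUE_AND_ORGAN:
        return f"BTO:{serial:07d}"
    return f"DOID:{serial}"


def _base_name(rng: random.Random, used: set[str]) -> str:
    """A fresh multi-token lowercase base name with an unused canonical key."""
    while True:
        n_tokens = rng.randint(1, 3)
        toks = [
            "".join(rng.choice(_NAME_ALPHABET) for _ in range(rng.randint(3, 7)))
            for _ in range(n_tokens)
        ]
        name = " ".join(toks)
        if name not in used:
            used.add(name)
            return name


def _variants(rng: random.Random, base: str, k: int) -> list[str]:
    """Up to k spelling variants sharing base's canonical key."""
    pool = [
        base,
        base.upper(),
        base.title(),
        base.replace(" ", "-"),
        base.upper().replace(" ", "-"),
        base.replace(" ", "_"),
        base.capitalize(),
    ]
    # single-token names: some variants coincide; dedupe preserving order
    seen: list[str] = []
    for v in pool:
        if v not in seen:
            seen.append(v)
    rng.shuffle(seen)
    picked = seen[: max(1, k)]
    if base not in picked:
        picked[0] = base
    return picked


def make_dictionary(spec: FixtureSpec) -> Dictionary:
    """Generate a lexicon spread across all six entity types.

    Names include deliberate case / hyphen / underscore variants of a
    lowercase base form to exercise canonicalization, and (for
    ``ambiguous_fraction`` of entities) a name shared with another
    entity of the same type to exercise ambiguity preservation.
    """
    rng = random.Random(spec.seed)
    used_bases: set[str] = set()
    entity_rows: list[str] = []
    name_rows: list[str] = []
    serial = 0
    lo, hi = spec.names_per_entity
    bases_by_type: dict[EntityType, list[str]] = {t: [] for t in _TYPE_ORDER}
    for etype in _TYPE_ORDER:
        for _ in range(spec.entities_per_type):
            serial += 1
            if etype is EntityType.GENE:
                type_code = rng.choice(_GENE_TAXA)
            else:
                type_code = _CODE_FOR_TYPE[etype]
            entity_rows.append(f"{serial}\t{type_code}\t{_identifier(rng, etype, type_code, serial)}")
            share_pool = bases_by_type[etype]
            if share_pool and rng.random() < spec.ambiguous_fraction:
                base = rng.choice(share_pool)
            else:
                base = _base_name(rng, used_bases)
            bases_by_type[etype].append(base)
            for surface in _variants(rng, base, rng.randint(lo, hi)):
                name_rows.append(f"{serial}\t{surface}")
    return load_dictionary(entity_rows, name_rows)


def _decoy_vocabulary(rng: random.Random, spec: FixtureSpec, dictionary: Dictionary) -> list[str]:
    alphabet = _DECOY_ALPHABET if spec.strict else _NAME_ALPHABET + _DECOY_ALPHABET
    vocab: list[str] = []
    seen: set[str] = set()
    while len(vocab) < spec.decoy_vocabulary_size:
        tok = "".join(rng.choice(alphabet) for _ in range(rng.randint(4, 8)))
        if tok in seen or canonicalize(tok) in dictionary.index:
            continue
        seen.add(tok)
        vocab.append(tok)
    return vocab


def make_corpus(
    spec: FixtureSpec, dictionary: Dictionary
) -> tuple[list[Document], list[Annotation]]:
    """Documents of decoy tokens with dictionary names planted at known offsets.

    Returns the documents and the ground truth: one annotation per
    planted span *per entity type sharing its canonical key*, with the
    identifiers the engine is expected to report, at exact offsets.
    """
    rng = random.Random(spec.seed * 2 + 1)
    vocab = _decoy_vocabulary(rng, spec, dictionary)
    all_surfaces = sorted({rec.surface for rec in dictionary.names})
    docs: list[Document] = []
    truth: list[Annotation] = []
    for d in range(spec.n_documents):
        doc_id = f"SYN{spec.seed}-{d:04d}"
        n_plants = rng.randint(*spec.planted_per_document)
        in_title = min(rng.randint(0, 1), n_plants)
        plan = [("T", in_title), ("A", n_plants - in_title)]
        sections: dict[str, str] = {}
        doc_truth: list[Annotation] = []
        for label, k in plan:
            words: list[str] = [rng.choice(vocab) for _ in range(rng.randint(2, 6))]
            plant_info: list[tuple[int, str]] = []  # (word slot, surface)
            for _ in range(k):
                surface = rng.choice(all_surfaces)
                plant_info.append((len(words), surface))
                words.append(surface)
                for _ in range(rng.randint(1, 4)):
                    words.append(rng.choice(vocab))
            text = " ".join(words)
            sections[label] = text
            # recover exact character offsets of the planted surfaces
            offsets: list[int] = []
            pos = 0
            for w in words:
                offsets.append(pos)
                pos += len(w) + 1
            for slot, surface in plant_info:
                start = offsets[slot]
                end = start + len(surface)
                key = canonicalize(surface)
                by_type: dict[EntityType, list[tuple[int, str]]] = {}
                for s in dictionary.index[key]:
                    ent = dictionary.entities[s]
                    by_type.setdefault(ent.entity_type, []).append(
                        (ent.type_code, ent.identifier)
                    )
                for etype in sorted(by_type, key=lambda t: t.value):
                    doc_truth.append(
                        Annotation(
                            document_id=doc_id,
                            section=label,
                            start=start,
                            end=end,
                            matched_text=surface,
                            entity_type=etype,
                            identifiers=tuple(by_type[etype]),
                        )
                    )
        docs.append(
            Document(document_id=doc_id, title=sections["T"], abstract=sections["A"])
        )
        doc_truth.sort(key=lambda a: ({"T": 0, "A": 1}[a.section], a.start, a.entity_type.value))
        truth.extend(doc_truth)
    return docs, truth


def write_fixture(spec: FixtureSpec, out_dir: str | Path) -> dict[str, Path]:
    """Emit dictionary TSVs, corpus TSV, and ground-truth TSV under out_dir."""
    from .dictionary import write_dictionary
    from .documents import write_corpus
    from .tabular import write_annotations

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dictionary = make_dictionary(spec)
    docs, truth = make_corpus(spec, dictionary)
    paths = write_dictionary(dictionary, out)
    corpus_path = out / "corpus.tsv"
    truth_path = out / "ground_truth.tsv"
    write_corpus(docs, corpus_path)
    with open(truth_path, "w", encoding="utf-8", newline="\n") as fh:
        write_annotations(truth, fh)
    paths.update(corpus=corpus_path, ground_truth=truth_path)
    return paths
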