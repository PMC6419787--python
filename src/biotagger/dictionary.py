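"""Multi-type biomedical NER lexicon: loading, validation, indexing.

A dictionary ties surface names to entities, where an entity is a
(serial, type_code, database identifier) triple.  Type codes follow the
convention of publicly distributed tagger dictionaries: a positive code
is an NCBI taxonomy identifier naming the organism whose gene namespace
the entity belongs to (annotated as GENE), and a fixed set of small
negative codes name the non-gene entity classes.

The on-disk dialect is headerless UTF-8 TSV:

* entities file: ``serial<TAB>type_code<TAB>identifier``
* names file:    ``serial<TAB>surface``
* blocked file:  one surface per line (optional)

which is shape-compatible with the deposited production dictionaries.
"""

from __future__ import annotations

import enum
import io
import os
from dataclasses import dataclass
from pathlib import Path
from types import MappingProxyType
from typing import IO, Iterable, Iterator, Mapping, Union

from .text import canonicalize

__all__ = [
    "EntityType",
    "Entity",
    "NameRecord",
    "Dictionary",
    "DictionaryLoadError",
    "UnknownTypeCodeError",
    "RESERVED_TYPE_CODES",
    "map_type",
    "load_dictionary",
    "write_dictionary",
]


class EntityType(enum.Enum):
    """The six entity classes the annotation protocol accepts.

    PROTEIN is deliberately absent: the gene dictionary is locus-based
    (it does not distinguish splice isoforms) and also covers ncRNAs,
    so every gene/protein mention is annotated as GENE and PROTEIN
    requests are rejected rather than silently remapped.
    """

    GENE = "GENE"
    CHEMICAL = "CHEMICAL"
    ORGANISM = "ORGANISM"
    SUBCELLULAR_STRUCTURE = "SUBCELLULAR_STRUCTURE"
    TISSUE_AND_ORGAN = "TISSUE_AND_ORGAN"
    DISEASE = "DISEASE"


#: Reserved negative type codes, one per non-gene entity class.
#: Any positive code is an organism-specific gene namespace (-> GENE).
RESERVED_TYPE_CODES: Mapping[int, EntityType] = MappingProxyType(
    {
        -1: EntityType.CHEMICAL,
        -2: EntityType.ORGANISM,
        -22: EntityType.SUBCELLULAR_STRUCTURE,
        -25: EntityType.TISSUE_AND_ORGAN,
        -26: EntityType.DISEASE,
    }
)


class UnknownTypeCodeError(ValueError):
    """Raised for a type code that is neither positive nor reserved."""


def map_type(type_code: int) -> EntityType:
    """Map an internal type code to its protocol entity type.

    Positive codes are organism taxon identifiers and map to GENE;
    the reserved negative codes map to their fixed class.  Zero and
    unreserved negative codes are invalid.
    """
    if type_code > 0:
        return EntityType.GENE
    try:
        return RESERVED_TYPE_CODES[type_code]
    except KeyError:
        raise UnknownTypeCodeError(
            f"type code {type_code} is neither a positive organism code "
            f"nor one of the reserved codes {sorted(RESERVED_TYPE_CODES)}"
        ) from None


@dataclass(frozen=True)
class Entity:
    """One normalizable thing: internal serial, type code, database id."""

    serial: int
    type_code: int
    identifier: str

    @property
    def entity_type(self) -> EntityType:
        return map_type(self.type_code)


@dataclass(frozen=True)
class NameRecord:
    """A surface name attached to an entity serial."""

    serial: int
    surface: str


@dataclass(frozen=True)
class Dictionary:
    """Preloaded, read-only lexicon index.

    ``index`` maps canonical keys to the sorted serials sharing that key
    (ambiguity is preserved, never resolved at load time).  ``surfaces``
    keeps the original surface forms per key, which the engine's
    short-name guard uses to require exact spelling for very short keys,
    and which makes the dictionary round-trippable to disk.
    """

    index: Mapping[str, tuple[int, ...]]
    entities: Mapping[int, Entity]
    surfaces: Mapping[str, tuple[str, ...]]
    names: tuple[NameRecord, ...]
    blocked: frozenset[str]
    max_key_tokens: int

    def __len__(self) -> int:
        return len(self.entities)


class DictionaryLoadError(ValueError):
    """A malformed or inconsistent dictionary file; names file and line."""

    def __init__(self, filename: str, line_no: int, message: str):
        super().__init__(f"{filename}:{line_no}: {message}")
        self.filename = filename
        self.line_no = line_no


Source = Union[str, os.PathLike, IO[str], Iterable[str]]


def _iter_lines(source: Source, default_label: str) -> tuple[str, Iterator[str]]:
    """Resolve a path / file-like / iterable-of-lines into (label, lines)."""
    if isinstance(source, (str, os.PathLike)):
        path = Path(source)
        return str(path), iter(path.read_text(encoding="utf-8").splitlines())
    label = getattr(source, "name", default_label)
    if isinstance(source, io.IOBase) or hasattr(source, "read"):
        return str(label), iter(source.read().splitlines())
    return default_label, iter(line.rstrip("\n") for line in source)


def load_dictionary(
    entities_source: Source,
    names_source: Source,
    blocked_source: Source | None = None,
) -> Dictionary:
    """Load and index the lexicon in a single pass per file.

    Raises :class:`DictionaryLoadError` for a row with the wrong field
    count, a non-integer serial, a duplicate serial in the entities
    file, or a name referencing an unknown serial.
    """
    ent_label, ent_lines = _iter_lines(entities_source, "<entities>")
    entities: dict[int, Entity] = {}
    for line_no, line in enumerate(ent_lines, start=1):
        if not line:
            continue
        fields = line.split("\t")
        if len(fields) != 3:
            raise DictionaryLoadError(
                ent_label, line_no, f"expected 3 tab-separated fields, got {len(fields)}"
            )
        try:
            serial = int(fields[0])
            type_code = int(fields[1])
        except ValueError:
            raise DictionaryLoadError(
                ent_label, line_no, f"non-integer serial or type code: {fields[:2]}"
            ) from None
        if serial <= 0:
            raise DictionaryLoadError(ent_label, line_no, f"serial must be positive: {serial}")
        if serial in entities:
            raise DictionaryLoadError(ent_label, line_no, f"duplicate serial {serial}")
        identifier = fields[2]
        if not identifier:
            raise DictionaryLoadError(ent_label, line_no, "empty identifier")
        try:
            map_type(type_code)
        except UnknownTypeCodeError as exc:
            raise DictionaryLoadError(ent_label, line_no, str(exc)) from None
        entities[serial] = Entity(serial, type_code, identifier)

    names_label, name_lines = _iter_lines(names_source, "<names>")
    index: dict[str, set[int]] = {}
    surfaces: dict[str, set[str]] = {}
    records: list[NameRecord] = []
    max_key_tokens = 0
    for line_no, line in enumerate(name_lines, start=1):
        if not line:
            continue
        fields = line.split("\t")
        if len(fields) != 2:
            raise DictionaryLoadError(
                names_label, line_no, f"expected 2 tab-separated fields, got {len(fields)}"
            )
        try:
            serial = int(fields[0])
        except ValueError:
            raise DictionaryLoadError(
                names_label, line_no, f"non-integer serial: {fields[0]!r}"
            ) from None
        if serial not in entities:
            raise DictionaryLoadError(
                names_label, line_no, f"name references unknown serial {serial}"
            )
        surface = fields[1]
        if not surface:
            raise DictionaryLoadError(names_label, line_no, "empty surface name")
        key = canonicalize(surface)
        if not key:
            raise DictionaryLoadError(
                names_label, line_no, f"surface {surface!r} canonicalizes to nothing"
            )
        index.setdefault(key, set()).add(serial)
        surfaces.setdefault(key, set()).add(surface)
        records.append(NameRecord(serial, surface))
        max_key_tokens = max(max_key_tokens, key.count(" ") + 1)

    blocked: set[str] = set()
    if blocked_source is not None:
        blk_label, blk_lines = _iter_lines(blocked_source, "<blocked>")
        for line_no, line in enumerate(blk_lines, start=1):
            if not line:
                continue
            if "\t" in line:
                raise DictionaryLoadError(
                    blk_label, line_no, "expected a single field per blocked-name row"
                )
            blocked.add(canonicalize(line))

    return Dictionary(
        index=MappingProxyType({k: tuple(sorted(v)) for k, v in index.items()}),
        entities=MappingProxyType(dict(entities)),
        surfaces=MappingProxyType({k: tuple(sorted(v)) for k, v in surfaces.items()}),
        names=tuple(sorted(records, key=lambda r: (r.serial, r.surface))),
        blocked=frozenset(blocked),
        max_key_tokens=max_key_tokens,
    )


def write_dictionary(dictionary: Dictionary, target: str | os.PathLike) -> dict[str, Path]:
    """Write ``entities.tsv``, ``names.tsv`` and ``blocked.tsv`` under ``target``.

    Rows are emitted in a canonical sort order so identical dictionaries
    produce byte-identical files; reloading the emitted files yields an
    index-identical dictionary.
    """
    target_dir = Path(target)
    target_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "entities": target_dir / "entities.tsv",
        "names": target_dir / "names.tsv",
        "blocked": target_dir / "blocked.tsv",
    }
    with open(paths["entities"], "w", encoding="utf-8", newline="\n") as fh:
        for serial in sorted(dictionary.entities):
            ent = dictionary.entities[serial]
            fh.write(f"{ent.serial}\t{ent.type_code}\t{ent.identifier}\n")
    with open(paths["names"], "w", encoding="utf-8", newline="\n") as fh:
        for rec in sorted(dictionary.names, key=lambda r: (r.serial, r.surface)):
            fh.write(f"{rec.serial}\t{rec.surface}\n")
    with open(paths["blocked"], "w", encoding="utf-8", newline="\n") as fh:
        for key in sorted(dictionary.blocked):
            fh.write(f"{key}\n")
    return paths
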