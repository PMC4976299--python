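"""PubTator corpus I/O and MEDIC-style vocabulary loading.

Offset convention: annotation offsets are 0-based, end-exclusive character
positions over ``title + "\\n" + abstract`` (a single separator character).
This convention is validated at load time: every annotation's quoted surface
text must equal the document substring at its span, or loading fails.

MeSH concept IDs are handled bare (``D007674``); a leading ``MESH:``
namespace prefix is stripped on load and never re-emitted. OMIM concepts are
excluded from normalization dictionaries.
"""

from __future__ import annotations

import gzip
import io
import logging
import re
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator, Union

logger = logging.getLogger(__name__)

CONCEPT_ID_RE = re.compile(r"^(?:D\d+|C\d+|-1)$")

#: Provenance tags for dictionary entries, in decreasing lookup priority.
PROVENANCES = ("primary", "synonym", "external_synonym", "abbrev_expanded")


class PubTatorParseError(ValueError):
    """Raised on a malformed PubTator line; carries the line number."""


class SpanValidationError(ValueError):
    """Raised when an annotation's text does not match its span."""


@dataclass(frozen=True)
class Mention:
    """A disease mention span with an optional normalized concept ID.

    Offsets index into ``title + "\\n" + abstract``; ``end`` is exclusive.
    ``concept_id`` is a bare MeSH ID (``D...``/``C...``) or ``"-1"`` for
    "no concept".
    """

    start: int
    end: int
    text: str
    entity_type: str = "Disease"
    concept_id: str = "-1"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid span ({self.start}, {self.end})")
        if self.concept_id and not CONCEPT_ID_RE.match(self.concept_id):
            raise ValueError(f"malformed concept_id {self.concept_id!r}")


@dataclass
class Document:
    """A title + abstract with its disease mention annotations."""

    doc_id: str
    title: str
    abstract: str
    mentions: list[Mention] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.doc_id:
            raise ValueError("doc_id must be non-empty")
        self.mentions = sorted(self.mentions, key=lambda m: (m.start, m.end))
        self.validate()

    @property
    def text(self) -> str:
        """Title and abstract joined by the single-character separator."""
        return self.title + "\n" + self.abstract

    def validate(self) -> None:
        text = self.text
        for m in self.mentions:
            if m.end > len(text):
                raise SpanValidationError(
                    f"doc {self.doc_id}: span ({m.start},{m.end}) exceeds text"
                )
            actual = text[m.start : m.end]
            if actual != m.text:
                raise SpanValidationError(
                    f"doc {self.doc_id}: span ({m.start},{m.end}) reads "
                    f"{actual!r}, annotation says {m.text!r}"
                )


@dataclass(frozen=True)
class DictionaryEntry:
    """One name string attached to a concept.

    ``provenance`` records where the name came from (primary name, MEDIC
    synonym, externally sourced synonym, or abbreviation-expanded variant);
    ``rank`` is the load order, used as the final "first entry" tie-break.
    """

    concept_id: str
    name: str
    provenance: str
    rank: int

    def __post_init__(self) -> None:
        if self.provenance not in PROVENANCES:
            raise ValueError(f"unknown provenance {self.provenance!r}")


class Dictionary:
    """An ordered collection of DictionaryEntry with unique ranks."""

    def __init__(self, entries: Iterable[DictionaryEntry] = ()) -> None:
        self.entries: list[DictionaryEntry] = list(entries)
        ranks = [e.rank for e in self.entries]
        if len(set(ranks)) != len(ranks):
            raise ValueError("entry ranks must be unique")

    def add(self, concept_id: str, name: str, provenance: str) -> DictionaryEntry:
        entry = DictionaryEntry(concept_id, name, provenance, self.next_rank())
        self.entries.append(entry)
        return entry

    def next_rank(self) -> int:
        return max((e.rank for e in self.entries), default=-1) + 1

    def __iter__(self) -> Iterator[DictionaryEntry]:
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def names(self) -> list[str]:
        return [e.name for e in self.entries]

    def copy(self) -> "Dictionary":
        return Dictionary(self.entries)


Stream = Union[str, IO[str], IO[bytes]]


def _open_text(stream: Stream, mode: str = "rt"):
    """Accept a path (plain or .gz) or an open text/binary handle."""
    if isinstance(stream, str):
        if stream.endswith(".gz"):
            return gzip.open(stream, mode, encoding="utf-8"), True
        return open(stream, mode, encoding="utf-8"), True
    if isinstance(stream, io.TextIOBase) or hasattr(stream, "encoding"):
        return stream, False
    # binary handle: wrap (may be gzip)
    data_stream = stream
    head = data_stream.peek(2) if hasattr(data_stream, "peek") else b""
    if head[:2] == b"\x1f\x8b":
        return io.TextIOWrapper(gzip.GzipFile(fileobj=data_stream)), False
    return io.TextIOWrapper(data_stream, encoding="utf-8"), False


def read_pubtator(stream: Stream) -> list[Document]:
    """Parse a PubTator-format collection into Documents.

    Blocks of ``PMID|t|title``, ``PMID|a|abstract`` and tab-separated
    annotation lines (doc_id, start, end, text, type, concept_id), separated
    by blank lines. Non-Disease annotations are skipped with a warning;
    extra trailing columns are ignored with a warning.
    """
    handle, owned = _open_text(stream)
    try:
        docs: list[Document] = []
        title: str | None = None
        abstract: str | None = None
        doc_id: str | None = None
        anns: list[Mention] = []

        def flush() -> None:
            nonlocal title, abstract, doc_id, anns
            if doc_id is None:
                return
            docs.append(
                Document(doc_id, title or "", abstract or "", mentions=anns)
            )
            title = abstract = doc_id = None
            anns = []

        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                flush()
                continue
            m = re.match(r"^([^|\t]+)\|([ta])\|(.*)$", line)
            if m:
                pid, kind, payload = m.groups()
                if doc_id is not None and pid != doc_id:
                    flush()
                doc_id = pid
                if kind == "t":
                    title = payload
                else:
                    abstract = payload
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise PubTatorParseError(
                    f"line {lineno}: expected PMID|t|, PMID|a| or >=6 "
                    f"tab-separated annotation fields, got {line!r}"
                )
            if len(fields) > 6:
                logger.warning(
                    "line %d: ignoring %d extra annotation column(s)",
                    lineno,
                    len(fields) - 6,
                )
            pid, start_s, end_s, text, ent_type, concept = fields[:6]
            if doc_id is not None and pid != doc_id:
                raise PubTatorParseError(
                    f"line {lineno}: annotation doc id {pid!r} does not match "
                    f"block {doc_id!r}"
                )
            if ent_type != "Disease":
                logger.warning(
                    "line %d: skipping non-Disease annotation (%s)",
                    lineno,
                    ent_type,
                )
                continue
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise PubTatorParseError(
                    f"line {lineno}: non-integer offsets {start_s!r},{end_s!r}"
                ) from exc
            concept = concept.strip()
            if concept.startswith("MESH:"):
                concept = concept[5:]
            if not concept:
                concept = "-1"
            anns.append(Mention(start, end, text, ent_type, concept))
        flush()
        return docs
    finally:
        if owned:
            handle.close()


def write_pubtator(docs: Iterable[Document], stream: Stream) -> None:
    """Write Documents in PubTator format (round-trip stable)."""
    handle, owned = _open_text(stream, "wt")
    try:
        for doc in docs:
            handle.write(f"{doc.doc_id}|t|{doc.title}\n")
            handle.write(f"{doc.doc_id}|a|{doc.abstract}\n")
            for m in doc.mentions:
                handle.write(
                    f"{doc.doc_id}\t{m.start}\t{m.end}\t{m.text}"
                    f"\t{m.entity_type}\t{m.concept_id}\n"
                )
            handle.write("\n")
    finally:
        if owned:
            handle.close()


MEDIC_COLUMNS = [
    "DiseaseName",
    "DiseaseID",
    "AltDiseaseIDs",
    "Definition",
    "ParentIDs",
    "TreeNumbers",
    "ParentTreeNumbers",
    "Synonyms",
    "SlimMappings",
]


class SchemaError(ValueError):
    pass


def read_medic_tsv(stream: Stream, include_synonyms: bool = True) -> Dictionary:
    """Load a MEDIC-style disease vocabulary (CTD column order).

    Emits one entry per primary name (provenance ``primary``) and, when
    ``include_synonyms`` is set, one per pipe-separated synonym (provenance
    ``synonym``). Rows whose DiseaseID is an OMIM concept are dropped; a
    ``MESH:`` prefix is stripped from IDs. Comment lines start with ``#``.
    """
    handle, owned = _open_text(stream)
    try:
        dictionary = Dictionary()
        n_omim = 0
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 8:
                raise SchemaError(
                    f"line {lineno}: expected >= 8 MEDIC columns "
                    f"({', '.join(MEDIC_COLUMNS[:8])}), got {len(fields)}"
                )
            name, disease_id = fields[0], fields[1]
            synonyms = fields[7]
            if disease_id.startswith("OMIM:"):
                n_omim += 1
                continue
            if disease_id.startswith("MESH:"):
                disease_id = disease_id[5:]
            dictionary.add(disease_id, name, "primary")
            if include_synonyms and synonyms:
                for syn in synonyms.split("|"):
                    syn = syn.strip()
                    if syn:
                        dictionary.add(disease_id, syn, "synonym")
        if n_omim:
            logger.info("dropped %d OMIM rows", n_omim)
        return dictionary
    finally:
        if owned:
            handle.close()


def read_dictionary_tsv(stream: Stream) -> Dictionary:
    """Load an enhanced dictionary persisted by :func:`write_dictionary_tsv`."""
    handle, owned = _open_text(stream)
    try:
        entries = []
        for line in handle:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            concept_id, name, provenance, rank = line.split("\t")
            entries.append(DictionaryEntry(concept_id, name, provenance, int(rank)))
        return Dictionary(entries)
    finally:
        if owned:
            handle.close()


def write_dictionary_tsv(dictionary: Dictionary, stream: Stream) -> None:
    handle, owned = _open_text(stream, "wt")
    try:
        for e in dictionary:
            handle.write(f"{e.concept_id}\t{e.name}\t{e.provenance}\t{e.rank}\n")
    finally:
        if owned:
            handle.close()


def read_synonym_tsv(stream: Stream) -> dict[str, list[str]]:
    """Load a generic phrase -> synonyms map (phrase TAB pipe-separated)."""
    handle, owned = _open_text(stream)
    try:
        source: dict[str, list[str]] = {}
        for line in handle:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            phrase, syns = line.split("\t")
            source[phrase] = [s for s in syns.split("|") if s]
        return source
    finally:
        if owned:
            handle.close()


def write_synonym_tsv(source: dict[str, list[str]], stream: Stream) -> None:
    handle, owned = _open_text(stream, "wt")
    try:
        for phrase, syns in source.items():
            handle.write(f"{phrase}\t{'|'.join(syns)}\n")
    finally:
        if owned:
            handle.close()
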