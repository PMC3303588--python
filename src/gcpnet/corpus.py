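"""Document-concept occurrence corpora and thesaurus handling.

The raw material for concept profiling is a binary document x concept
occurrence record: a concept either appears in a document or it does not.
Term frequencies are deliberately ignored; the association weights downstream
are defined on document-level 2x2 co-occurrence tables.

A thesaurus assigns each concept id a canonical name, a semantic class
(``disease``, ``gene`` or ``other``) and a list of synonyms.  The gene-class
entries define the vocabulary over which genetic concept profiles are built.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import sparse

logger = logging.getLogger(__name__)

SEMANTIC_CLASSES = ("disease", "gene", "other")


class CorpusParseError(ValueError):
    """Raised when an occurrence or thesaurus file is malformed."""


@dataclass
class OccurrenceCorpus:
    """Sparse binary document x concept occurrence record.

    Parameters
    ----------
    occurrences
        Iterable of ``(doc_id, concept_id)`` pairs; duplicates are collapsed.
    documents
        Optional explicit document universe.  Documents mentioned in
        ``occurrences`` are always included; extra ids enlarge the corpus
        total ``T`` without adding occurrences.
    """

    occurrences: set[tuple[str, str]]
    documents: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.occurrences = set(self.occurrences)
        self.documents = set(self.documents) | {d for d, _ in self.occurrences}
        if not self.documents:
            raise ValueError("corpus must contain at least one document")
        self._index: dict[str, set[str]] = {}
        for doc, concept in self.occurrences:
            self._index.setdefault(concept, set()).add(doc)

    @property
    def n_documents(self) -> int:
        """Total document count T."""
        return len(self.documents)

    @property
    def concepts(self) -> set[str]:
        return set(self._index)

    def documents_with(self, concept: str) -> set[str]:
        """Documents containing *concept* (empty set if never observed)."""
        return set(self._index.get(concept, set()))

    def to_matrix(
        self, concept_order: Sequence[str] | None = None
    ) -> tuple[sparse.csr_matrix, list[str], list[str]]:
        """Return a CSR document x concept indicator matrix.

        Returns ``(X, doc_ids, concept_ids)`` with rows/columns in the given
        (or sorted) order.  The matrix is the basis for the vectorised
        co-occurrence computations in :mod:`gcpnet.profiles`.
        """
        docs = sorted(self.documents)
        concepts = list(concept_order) if concept_order is not None else sorted(self._index)
        doc_pos = {d: i for i, d in enumerate(docs)}
        con_pos = {c: j for j, c in enumerate(concepts)}
        rows, cols = [], []
        for doc, concept in self.occurrences:
            j = con_pos.get(concept)
            if j is not None:
                rows.append(doc_pos[doc])
                cols.append(j)
        X = sparse.csr_matrix(
            (np.ones(len(rows), dtype=np.int64), (rows, cols)),
            shape=(len(docs), len(concepts)),
        )
        return X, docs, concepts

    def write(self, path: str | Path) -> None:
        """Write the corpus as a two-column TSV (sorted, reproducible)."""
        path = Path(path)
        with path.open("w", encoding="utf-8") as fh:
            fh.write("doc_id\tconcept_id\n")
            for doc, concept in sorted(self.occurrences):
                fh.write(f"{doc}\t{concept}\n")


def read_occurrences(path: str | Path) -> OccurrenceCorpus:
    """Read a ``doc_id<TAB>concept_id`` TSV into an :class:`OccurrenceCorpus`.

    Duplicate pairs are collapsed.  Malformed lines raise
    :class:`CorpusParseError` with the offending line number.
    """
    path = Path(path)
    pairs: set[tuple[str, str]] = set()
    with path.open("r", encoding="utf-8") as fh:
        header = fh.readline()
        if not header:
            raise CorpusParseError(f"{path}: empty occurrence file")
        cols = header.rstrip("\n").split("\t")
        if cols[:2] != ["doc_id", "concept_id"]:
            raise CorpusParseError(
                f"{path}:1: expected header 'doc_id<TAB>concept_id', got {header.rstrip()!r}"
            )
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2 or not parts[0] or not parts[1]:
                raise CorpusParseError(f"{path}:{lineno}: malformed line {line!r}")
            pairs.add((parts[0], parts[1]))
    if not pairs:
        raise CorpusParseError(f"{path}: no occurrence records")
    corpus = OccurrenceCorpus(pairs)
    logger.info(
        "read %d occurrence pairs over %d documents and %d concepts from %s",
        len(pairs), corpus.n_documents, len(corpus.concepts), path,
    )
    return corpus


@dataclass
class ThesaurusEntry:
    concept_id: str
    name: str
    semantic_class: str
    synonyms: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.semantic_class not in SEMANTIC_CLASSES:
            raise ValueError(
                f"unknown semantic class {self.semantic_class!r} for {self.concept_id}"
            )


class Thesaurus:
    """Concept id -> (canonical name, semantic class, synonyms) mapping.

    Gene-class entries define the gene vocabulary for profile building.
    """

    def __init__(self, entries: Iterable[ThesaurusEntry]):
        self.entries: dict[str, ThesaurusEntry] = {}
        for entry in entries:
            if entry.concept_id in self.entries:
                raise ValueError(f"duplicate concept id {entry.concept_id!r}")
            self.entries[entry.concept_id] = entry

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, concept_id: str) -> bool:
        return concept_id in self.entries

    def __getitem__(self, concept_id: str) -> ThesaurusEntry:
        return self.entries[concept_id]

    @property
    def gene_vocabulary(self) -> list[str]:
        """Sorted concept ids of all gene-class entries."""
        return sorted(c for c, e in self.entries.items() if e.semantic_class == "gene")

    def concepts_of_class(self, semantic_class: str) -> list[str]:
        return sorted(
            c for c, e in self.entries.items() if e.semantic_class == semantic_class
        )

    def write(self, path: str | Path) -> None:
        path = Path(path)
        with path.open("w", encoding="utf-8") as fh:
            fh.write("concept_id\tname\tclass\tsynonyms\n")
            for cid in sorted(self.entries):
                e = self.entries[cid]
                fh.write(f"{cid}\t{e.name}\t{e.semantic_class}\t{';'.join(e.synonyms)}\n")


def read_thesaurus(path: str | Path) -> Thesaurus:
    """Read a ``concept_id<TAB>name<TAB>class<TAB>synonyms`` TSV."""
    path = Path(path)
    entries = []
    with path.open("r", encoding="utf-8") as fh:
        header = fh.readline()
        if not header:
            raise CorpusParseError(f"{path}: empty thesaurus file")
        cols = header.rstrip("\n").split("\t")
        if cols[:4] != ["concept_id", "name", "class", "synonyms"]:
            raise CorpusParseError(
                f"{path}:1: expected header 'concept_id<TAB>name<TAB>class<TAB>synonyms'"
            )
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3 or not parts[0] or not parts[1]:
                raise CorpusParseError(f"{path}:{lineno}: malformed line {line!r}")
            synonyms = tuple(s for s in (parts[3].split(";") if len(parts) > 3 else []) if s)
            try:
                entries.append(ThesaurusEntry(parts[0], parts[1], parts[2], synonyms))
            except ValueError as exc:
                raise CorpusParseError(f"{path}:{lineno}: {exc}") from exc
    thesaurus = Thesaurus(entries)
    logger.info(
        "read thesaurus with %d entries (%d gene-class) from %s",
        len(thesaurus), len(thesaurus.gene_vocabulary), path,
    )
    return thesaurus


@dataclass
class ConceptMappingReport:
    """Outcome of mapping free-text input names onto thesaurus concepts.

    The three groups partition the input names.  Ambiguous names (matching
    more than one thesaurus entry) are excluded from downstream profile
    building; this mirrors dropping a disease term that could not be mapped
    uniquely.
    """

    resolved: dict[str, str]
    ambiguous: dict[str, list[str]]
    unmapped: list[str]

    @property
    def resolved_ids(self) -> list[str]:
        return [self.resolved[name] for name in self.resolved]


def map_concepts(names: Sequence[str], thesaurus: Thesaurus) -> ConceptMappingReport:
    """Map input names to concept ids by case-insensitive exact match.

    A name matching exactly one entry (by canonical name or synonym) is
    resolved; matching several entries is ambiguous; matching none is
    unmapped.  No fuzzy matching is attempted.
    """
    if not names:
        raise ValueError("names must be non-empty")
    lookup: dict[str, set[str]] = {}
    for cid, entry in thesaurus.entries.items():
        for label in (entry.name, *entry.synonyms):
            lookup.setdefault(label.casefold(), set()).add(cid)

    resolved: dict[str, str] = {}
    ambiguous: dict[str, list[str]] = {}
    unmapped: list[str] = []
    for name in names:
        hits = sorted(lookup.get(name.casefold(), set()))
        if len(hits) == 1:
            resolved[name] = hits[0]
        elif len(hits) > 1:
            ambiguous[name] = hits
            logger.warning("concept %r is ambiguous (candidates: %s); excluded", name, hits)
        else:
            unmapped.append(name)
            logger.warning("concept %r not found in thesaurus", name)
    return ConceptMappingReport(resolved=resolved, ambiguous=ambiguous, unmapped=unmapped)
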