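"""Document collections, disease-synonym lexicons and search-query construction.

Documents are year-stamped title+abstract records.  Two on-disk dialects are
supported: MEDLINE flat files (PMID/TI/AB/DP tags, parsed with Bio.Medline)
and a JSON-lines dialect ``{"id", "year", "title", "abstract"}``.  A synonym
lexicon is a JSON map from canonical disease name to its term list (canonical
name first).
"""

from __future__ import annotations

import json
import logging
import unicodedata
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterator

from Bio import Medline

logger = logging.getLogger(__name__)

__all__ = [
    "Document",
    "DocumentCollection",
    "SynonymLexicon",
    "read_medline",
    "read_jsonl",
    "write_jsonl",
    "read_lexicon",
    "default_lexicon",
    "default_stopwords",
    "build_query",
    "stratify_by_year",
]


@dataclass(frozen=True)
class Document:
    """A single year-stamped bibliographic record."""

    id: str
    year: int
    title: str = ""
    abstract: str = ""

    def __post_init__(self) -> None:
        if not (self.title or self.abstract):
            raise ValueError(f"document {self.id!r}: title and abstract both empty")

    @property
    def text(self) -> str:
        """Title and abstract joined for downstream tokenization."""
        return f"{self.title} {self.abstract}".strip()


@dataclass
class DocumentCollection:
    """Ordered list of documents with unique ids."""

    documents: list[Document] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [d.id for d in self.documents]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate document ids in collection")

    @property
    def M(self) -> int:
        return len(self.documents)

    def __len__(self) -> int:
        return len(self.documents)

    def __iter__(self) -> Iterator[Document]:
        return iter(self.documents)

    def __getitem__(self, i: int) -> Document:
        return self.documents[i]


class SynonymLexicon:
    """Canonical disease name -> term list (canonical name included, first).

    Synonym lists are deduplicated case-insensitively (simple lowercase fold
    after NFC normalization), preserving first-seen order.
    """

    def __init__(self, entries: dict[str, list[str]]):
        self.entries: dict[str, list[str]] = {}
        for name, terms in entries.items():
            if not terms:
                raise ValueError(f"lexicon entry {name!r} is empty")
            seen: set[str] = set()
            clean: list[str] = []
            for t in terms:
                key = unicodedata.normalize("NFC", t).lower()
                if key not in seen:
                    seen.add(key)
                    clean.append(t)
            self.entries[name] = clean

    def terms(self, name: str) -> list[str]:
        """All terms for a disease, canonical name first."""
        return list(self.entries[name])

    def n_synonyms(self, name: str) -> int:
        """Number of synonyms, not counting the canonical name itself."""
        return len(self.entries[name]) - 1

    def diseases(self) -> list[str]:
        return list(self.entries)

    def __contains__(self, name: str) -> bool:
        return name in self.entries

    def __len__(self) -> int:
        return len(self.entries)


def _parse_year(dp: str) -> int | None:
    # MEDLINE DP fields are heterogeneous ("2008 Jan-Feb", "2011 May 3");
    # take the first 4-digit token.
    for tok in dp.replace("-", " ").replace("/", " ").split():
        if len(tok) == 4 and tok.isdigit():
            return int(tok)
    return None


def read_medline(path: str | Path) -> DocumentCollection:
    """Read a MEDLINE flat file (PMID/TI/AB/DP records) into a collection.

    Records missing both title and abstract, or with an unparseable
    publication year, are dropped with a logged warning; they never enter
    the collection silently.
    """
    path = Path(path)
    docs: list[Document] = []
    n_dropped = 0
    with path.open(encoding="utf-8") as fh:
        for rec in Medline.parse(fh):
            pmid = rec.get("PMID", "")
            title = rec.get("TI", "") or ""
            abstract = rec.get("AB", "") or ""
            year = _parse_year(rec.get("DP", "") or "")
            if not (title or abstract) or year is None or not pmid:
                n_dropped += 1
                logger.warning("dropping record PMID=%r (missing TI+AB, DP or PMID)", pmid)
                continue
            docs.append(Document(id=pmid, year=year, title=title, abstract=abstract))
    if n_dropped:
        logger.info("read_medline: %d records dropped from %s", n_dropped, path)
    return DocumentCollection(docs)


def read_jsonl(path: str | Path) -> DocumentCollection:
    """Read the JSON-lines dialect {id, year, title, abstract}."""
    docs = []
    with Path(path).open(encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            rec = json.loads(line)
            docs.append(
                Document(
                    id=str(rec["id"]),
                    year=int(rec["year"]),
                    title=rec.get("title", "") or "",
                    abstract=rec.get("abstract", "") or "",
                )
            )
    return DocumentCollection(docs)


def write_jsonl(collection: DocumentCollection, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for d in collection:
            fh.write(
                json.dumps(
                    {"id": d.id, "year": d.year, "title": d.title, "abstract": d.abstract}
                )
                + "\n"
            )


def read_lexicon(path: str | Path) -> SynonymLexicon:
    with Path(path).open(encoding="utf-8") as fh:
        return SynonymLexicon(json.load(fh))


def default_lexicon() -> SynonymLexicon:
    """The packaged diabetes/obesity synonym lexicon."""
    text = resources.files("rlda.data").joinpath("disease_lexicon.json").read_text("utf-8")
    return SynonymLexicon(json.loads(text))


def default_stopwords() -> list[str]:
    """The packaged English stop-word list (one token per line, lowercase)."""
    text = resources.files("rlda.data").joinpath("stopwords.txt").read_text("utf-8")
    return [w for w in (line.strip() for line in text.splitlines()) if w]


def build_query(
    synonyms: list[str], field: str = "Title/Abstract", connective: str = "OR"
) -> str:
    """Build a boolean bibliographic search query from a synonym list.

    Each synonym is suffixed with the search-field qualifier and
    parenthesized; terms are joined by the connective in lexicon order:
    ``(diabetes[Title/Abstract]) OR (MODY[Title/Abstract])``.
    """
    if not synonyms:
        raise ValueError("synonym list is empty")
    terms = [f"({s}[{field}])" for s in synonyms]
    if len(terms) == 1:
        return terms[0]
    return f" {connective} ".join(terms)


def stratify_by_year(collection: DocumentCollection) -> dict[int, DocumentCollection]:
    """Partition a collection by publication year, preserving input order."""
    parts: dict[int, list[Document]] = {}
    for doc in collection:
        parts.setdefault(doc.year, []).append(doc)
    return {year: DocumentCollection(docs) for year, docs in sorted(parts.items())}
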