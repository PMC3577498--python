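"""Document corpora: titled abstracts with PMID-like identifiers.

Two interchangeable on-disk dialects are supported:

* JSONL — one object per line with keys ``pmid``, ``title``, ``abstract``
  and optional ``year``;
* a Medline-XML subset — ``PubmedArticle/MedlineCitation`` with ``PMID``,
  ``ArticleTitle`` and ``Abstract/AbstractText`` elements (everything else
  is ignored).

A corpus encoded both ways loads to field-identical documents.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Literal

from lxml import etree

from .errors import ParseError, ValidationError


@dataclass(frozen=True)
class Document:
    """One titled abstract. Title and abstract may not both be empty."""

    doc_id: str
    title: str
    abstract: str = ""
    year: int | None = None

    def __post_init__(self) -> None:
        if not self.doc_id:
            raise ValidationError("doc_id must be non-empty")
        if not self.title and not self.abstract:
            raise ValidationError(f"{self.doc_id}: title and abstract both empty")


class Corpus:
    """An ordered, duplicate-free collection of documents."""

    def __init__(self, documents: Iterable[Document]) -> None:
        self.documents: list[Document] = list(documents)
        seen: set[str] = set()
        for doc in self.documents:
            if doc.doc_id in seen:
                raise ValidationError(f"duplicate doc_id {doc.doc_id!r}")
            seen.add(doc.doc_id)

    @property
    def N(self) -> int:
        return len(self.documents)

    def __len__(self) -> int:
        return len(self.documents)

    def __iter__(self) -> Iterator[Document]:
        return iter(self.documents)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Corpus):
            return NotImplemented
        return self.documents == other.documents

    def content_hash(self) -> str:
        """Order-independent SHA-256 over document fields (hex, 12 chars)."""
        h = hashlib.sha256()
        for doc in sorted(self.documents, key=lambda d: d.doc_id):
            h.update(
                json.dumps(
                    [doc.doc_id, doc.title, doc.abstract, doc.year],
                    ensure_ascii=False,
                ).encode("utf-8")
            )
        return h.hexdigest()[:12]

    def save_jsonl(self, path: str | Path) -> None:
        with Path(path).open("w", encoding="utf-8") as fh:
            for doc in self.documents:
                record = {"pmid": doc.doc_id, "title": doc.title, "abstract": doc.abstract}
                if doc.year is not None:
                    record["year"] = doc.year
                fh.write(json.dumps(record, ensure_ascii=False) + "\n")

    def save_medline_xml(self, path: str | Path) -> None:
        root = etree.Element("PubmedArticleSet")
        for doc in self.documents:
            article = etree.SubElement(root, "PubmedArticle")
            citation = etree.SubElement(article, "MedlineCitation")
            etree.SubElement(citation, "PMID").text = doc.doc_id
            art = etree.SubElement(citation, "Article")
            etree.SubElement(art, "ArticleTitle").text = doc.title
            if doc.abstract:
                abstract = etree.SubElement(art, "Abstract")
                etree.SubElement(abstract, "AbstractText").text = doc.abstract
            if doc.year is not None:
                journal = etree.SubElement(art, "Journal")
                issue = etree.SubElement(journal, "JournalIssue")
                pubdate = etree.SubElement(issue, "PubDate")
                etree.SubElement(pubdate, "Year").text = str(doc.year)
        tree = etree.ElementTree(root)
        tree.write(str(path), xml_declaration=True, encoding="utf-8", pretty_print=True)


def _load_jsonl(path: Path) -> list[Document]:
    documents = []
    with path.open("r", encoding="utf-8") as fh:
        for index, line in enumerate(fh):
            line = line.strip()
            if not line:
                continue
            try:
                record = json.loads(line)
                documents.append(
                    Document(
                        doc_id=str(record["pmid"]),
                        title=record.get("title", ""),
                        abstract=record.get("abstract", ""),
                        year=record.get("year"),
                    )
                )
            except (json.JSONDecodeError, KeyError, ValidationError) as exc:
                raise ParseError(f"{path}: record {index}: {exc}") from exc
    return documents


def _load_medline_xml(path: Path) -> list[Document]:
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    documents = []
    for index, citation in enumerate(tree.iter("MedlineCitation")):
        pmid = citation.findtext("PMID")
        if pmid is None:
            raise ParseError(f"{path}: record {index}: missing PMID")
        title = citation.findtext("Article/ArticleTitle") or ""
        abstract = " ".join(
            (node.text or "").strip()
            for node in citation.findall("Article/Abstract/AbstractText")
        ).strip()
        year_text = citation.findtext("Article/Journal/JournalIssue/PubDate/Year")
        year = int(year_text) if year_text else None
        try:
            documents.append(
                Document(doc_id=pmid, title=title, abstract=abstract, year=year)
            )
        except ValidationError as exc:
            raise ParseError(f"{path}: record {index}: {exc}") from exc
    return documents


def load_corpus(
    path: str | Path, format: Literal["jsonl", "medline_xml"] | None = None
) -> Corpus:
    """Load a corpus from JSONL or a Medline-XML subset.

    ``format=None`` infers the dialect from the file suffix (``.xml`` →
    medline_xml, anything else → jsonl).  Duplicate doc ids raise
    :class:`ValidationError`; unparseable records raise :class:`ParseError`
    with the record index.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "medline_xml" if path.suffix.lower() == ".xml" else "jsonl"
    if format == "jsonl":
        return Corpus(_load_jsonl(path))
    if format == "medline_xml":
        return Corpus(_load_medline_xml(path))
    raise ValueError(f"unknown corpus format {format!r}")
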