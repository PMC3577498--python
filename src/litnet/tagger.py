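"""Dictionary tagging: scan titles+abstracts for thesaurus concepts.

The tagger links a document to a concept when any synonym occurs in the
title or abstract as a token-boundary, case-insensitive match.  Titles and
abstracts are scanned jointly (the counting unit is the whole record, not
the sentence), and a concept is linked at most once per document —
presence, not frequency, is what co-occurrence counting rests on.

Overlapping candidate matches are resolved longest-match-first: the scanner
tries synonyms in decreasing length at each position and consumes the
matched span, so "insulin receptor" in "insulin receptor substrate"
suppresses a separate "insulin" hit on the same span.  A match must be
flanked by non-alphanumeric characters or the string ends; hyphens inside
synonyms match literally.
"""

from __future__ import annotations

import re
from pathlib import Path

from .corpus import Corpus
from .errors import ParseError, ValidationError
from .thesaurus import Thesaurus, normalize


class MentionIndex:
    """Bidirectional document ↔ concept map plus the corpus size N.

    ``by_concept`` and ``by_doc`` are exact inverses; ``by_doc`` has one
    entry per corpus document (possibly empty), so ``N == len(by_doc)``.
    ``categories`` carries each tagged concept's thesaurus category so
    category-restricted counting needs no thesaurus round trip.
    """

    def __init__(
        self,
        by_doc: dict[str, set[str]],
        categories: dict[str, str],
    ) -> None:
        self.by_doc = by_doc
        self.categories = categories
        self.by_concept: dict[str, set[str]] = {}
        for doc_id, concept_ids in by_doc.items():
            for cid in concept_ids:
                self.by_concept.setdefault(cid, set()).add(doc_id)

    @property
    def N(self) -> int:
        return len(self.by_doc)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MentionIndex):
            return NotImplemented
        return (
            self.by_doc == other.by_doc
            and self.categories == other.categories
        )

    def doc_count(self, concept_id: str) -> int:
        """Number of documents mentioning the concept."""
        return len(self.by_concept.get(concept_id, ()))

    def concepts_in_category(self, category: str) -> list[str]:
        """Tagged concepts (≥ 1 document) of a category, sorted."""
        return sorted(
            cid
            for cid in self.by_concept
            if self.categories.get(cid) == category
        )

    def save(self, concept_path: str | Path, doc_path: str | Path) -> None:
        """Serialize to two TSVs (concept→docs with category, doc→concepts)."""
        with Path(concept_path).open("w", encoding="utf-8") as fh:
            fh.write("concept_id\tcategory\tdoc_ids\n")
            for cid in sorted(self.by_concept):
                docs = ",".join(sorted(self.by_concept[cid]))
                fh.write(f"{cid}\t{self.categories.get(cid, '')}\t{docs}\n")
        with Path(doc_path).open("w", encoding="utf-8") as fh:
            fh.write("doc_id\tconcept_ids\n")
            for doc_id in sorted(self.by_doc):
                cids = ",".join(sorted(self.by_doc[doc_id]))
                fh.write(f"{doc_id}\t{cids}\n")

    @classmethod
    def load(
        cls, concept_path: str | Path, doc_path: str | Path
    ) -> "MentionIndex":
        categories: dict[str, str] = {}
        by_concept: dict[str, set[str]] = {}
        with Path(concept_path).open("r", encoding="utf-8") as fh:
            if fh.readline().rstrip("\n") != "concept_id\tcategory\tdoc_ids":
                raise ParseError(f"{concept_path}: bad header")
            for lineno, line in enumerate(fh, start=2):
                line = line.rstrip("\n")
                if not line:
                    continue
                try:
                    cid, category, docs = line.split("\t")
                except ValueError as exc:
                    raise ParseError(f"{concept_path}: line {lineno}") from exc
                categories[cid] = category
                by_concept[cid] = set(d for d in docs.split(",") if d)
        by_doc: dict[str, set[str]] = {}
        with Path(doc_path).open("r", encoding="utf-8") as fh:
            if fh.readline().rstrip("\n") != "doc_id\tconcept_ids":
                raise ParseError(f"{doc_path}: bad header")
            for lineno, line in enumerate(fh, start=2):
                line = line.rstrip("\n")
                if not line:
                    continue
                try:
                    doc_id, cids = line.split("\t")
                except ValueError as exc:
                    raise ParseError(f"{doc_path}: line {lineno}") from exc
                by_doc[doc_id] = set(c for c in cids.split(",") if c)
        index = cls(by_doc, categories)
        if index.by_concept != by_concept:
            raise ValidationError(
                "concept→doc and doc→concept tables are not inverses"
            )
        return index


def _synonym_pattern(thesaurus: Thesaurus) -> re.Pattern[str] | None:
    """One alternation over all synonyms, longest first, token-bounded.

    Internal whitespace in a synonym matches any whitespace run; everything
    else is literal.  Longest-first alternation gives longest-match
    semantics at each scan position, and ``finditer`` consumes matched
    spans so shorter synonyms cannot re-match inside them.
    """
    normalized = sorted(thesaurus.name_index, key=lambda s: (-len(s), s))
    if not normalized:
        return None
    alternatives = [re.escape(s).replace(r"\ ", r"\s+") for s in normalized]
    return re.compile(
        r"(?<![A-Za-z0-9])(?:" + "|".join(alternatives) + r")(?![A-Za-z0-9])",
        re.IGNORECASE,
    )


def tag_corpus(corpus: Corpus, thesaurus: Thesaurus) -> MentionIndex:
    """Build the document↔concept index for a corpus.

    Deterministic and order-independent: permuting the corpus yields an
    identical index.  An empty corpus yields an empty index with N=0.
    """
    pattern = _synonym_pattern(thesaurus)
    categories = {cid: c.category for cid, c in thesaurus.concepts.items()}
    by_doc: dict[str, set[str]] = {}
    for doc in corpus:
        text = doc.title + "\n" + doc.abstract
        hits: set[str] = set()
        if pattern is not None:
            for match in pattern.finditer(text):
                hits.update(thesaurus.name_index[normalize(match.group(0))])
        by_doc[doc.doc_id] = hits
    tagged = set().union(*by_doc.values()) if by_doc else set()
    return MentionIndex(by_doc, {cid: categories[cid] for cid in tagged})


def get_references(
    index: MentionIndex, concept_ids: set[str]
) -> dict[str, set[str]]:
    """Documents in which each queried concept occurs.

    Exactly ``by_concept`` restricted to the query; unknown ids map to the
    empty set.
    """
    return {cid: set(index.by_concept.get(cid, set())) for cid in concept_ids}
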