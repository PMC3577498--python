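"""Controlled vocabularies of biomedical concepts.

A thesaurus maps opaque concept identifiers to synonym sets within a fixed
category system (gene, disease, drug, pathway).  All downstream counting is
done on concept identifiers, never on surface strings, so the thesaurus is
the single place where free text meets the vocabulary.

Matching is exact-after-normalization: lowercase, trimmed, internal
whitespace collapsed.  No stemming is applied — dictionary matching on
curated synonyms keeps false hits low, at the price of missing inflected
variants.  A synonym shared by several concepts stays ambiguous: resolution
returns every matching concept and the tagger counts all of them.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

from .errors import ParseError, ValidationError

#: The closed category system. Extensible by passing ``categories=`` to
#: :class:`Thesaurus`, but closed by default.
CATEGORIES: frozenset[str] = frozenset({"gene", "disease", "drug", "pathway"})

_WS = re.compile(r"\s+")


def normalize(term: str) -> str:
    """Normalize a surface string for synonym matching.

    Lowercase, strip leading/trailing whitespace and collapse internal
    whitespace runs to single spaces.  Hyphens and other punctuation are
    kept literal.
    """
    return _WS.sub(" ", term.strip()).lower()


@dataclass(frozen=True)
class Concept:
    """One vocabulary entry: an identifier, a category and its synonyms."""

    concept_id: str
    category: str
    preferred_name: str
    synonyms: frozenset[str]

    def __post_init__(self) -> None:
        if not self.concept_id:
            raise ValidationError("concept_id must be non-empty")
        if not self.synonyms:
            raise ValidationError(f"{self.concept_id}: synonym set is empty")
        if any(not s for s in self.synonyms):
            raise ValidationError(f"{self.concept_id}: empty synonym")
        if self.preferred_name not in self.synonyms:
            raise ValidationError(
                f"{self.concept_id}: preferred name {self.preferred_name!r} "
                "is not among its synonyms"
            )


class Thesaurus:
    """A validated collection of :class:`Concept` with a synonym index.

    Parameters
    ----------
    concepts:
        The vocabulary entries.  Concept ids must be unique.
    categories:
        Allowed categories; defaults to the closed four-category system.
    """

    def __init__(
        self,
        concepts: Iterable[Concept],
        categories: frozenset[str] = CATEGORIES,
    ) -> None:
        self.categories = frozenset(categories)
        self.concepts: dict[str, Concept] = {}
        self.name_index: dict[str, set[str]] = {}
        for concept in concepts:
            if concept.category not in self.categories:
                raise ValidationError(
                    f"{concept.concept_id}: unknown category "
                    f"{concept.category!r}; allowed: {sorted(self.categories)}"
                )
            if concept.concept_id in self.concepts:
                raise ValidationError(f"duplicate concept_id {concept.concept_id!r}")
            self.concepts[concept.concept_id] = concept
            for synonym in concept.synonyms:
                self.name_index.setdefault(normalize(synonym), set()).add(
                    concept.concept_id
                )

    def __len__(self) -> int:
        return len(self.concepts)

    def __contains__(self, concept_id: str) -> bool:
        return concept_id in self.concepts

    def __getitem__(self, concept_id: str) -> Concept:
        return self.concepts[concept_id]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Thesaurus):
            return NotImplemented
        return self.concepts == other.concepts and self.categories == other.categories

    def category_of(self, concept_id: str) -> str:
        return self.concepts[concept_id].category

    def ids_in_category(self, category: str) -> list[str]:
        """All concept ids of a category, sorted."""
        return sorted(
            cid for cid, c in self.concepts.items() if c.category == category
        )

    def resolve(self, query: str) -> set[str]:
        """Concept ids whose synonym set contains the normalized query."""
        return set(self.name_index.get(normalize(query), set()))

    def save(self, path: str | Path) -> None:
        """Write the thesaurus as TSV (synonyms pipe-separated, UTF-8)."""
        path = Path(path)
        with path.open("w", encoding="utf-8") as fh:
            fh.write("concept_id\tcategory\tpreferred_name\tsynonyms\n")
            for cid in sorted(self.concepts):
                c = self.concepts[cid]
                other = sorted(c.synonyms - {c.preferred_name})
                syns = "|".join([c.preferred_name, *other])
                fh.write(f"{c.concept_id}\t{c.category}\t{c.preferred_name}\t{syns}\n")


def load_thesaurus(path: str | Path) -> Thesaurus:
    """Load a thesaurus from its TSV representation.

    Expected header: ``concept_id  category  preferred_name  synonyms`` with
    synonyms pipe-separated.  Malformed rows raise :class:`ParseError`
    naming the line; duplicate ids and unknown categories raise
    :class:`ValidationError`.
    """
    path = Path(path)
    concepts: list[Concept] = []
    with path.open("r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n")
        expected = "concept_id\tcategory\tpreferred_name\tsynonyms"
        if header != expected:
            raise ParseError(f"{path}: line 1: expected header {expected!r}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise ParseError(
                    f"{path}: line {lineno}: expected 4 tab-separated fields, "
                    f"got {len(fields)}"
                )
            cid, category, preferred, synonyms_field = fields
            synonyms = frozenset(s for s in synonyms_field.split("|"))
            try:
                concepts.append(
                    Concept(
                        concept_id=cid,
                        category=category,
                        preferred_name=preferred,
                        synonyms=synonyms,
                    )
                )
            except ValidationError as exc:
                raise ValidationError(f"{path}: line {lineno}: {exc}") from exc
    return Thesaurus(concepts)


def resolve_terms(
    thesaurus: Thesaurus, queries: Iterable[str]
) -> Mapping[str, set[str]]:
    """Resolve free-text queries to concept ids, case-insensitively.

    Unknown queries map to the empty set; ambiguity (one synonym, several
    concepts) is preserved, not resolved.
    """
    return {q: thesaurus.resolve(q) for q in queries}
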