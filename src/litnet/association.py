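"""Pairwise co-occurrence scoring: lift and the 0–100 R-scaled score.

For a concept pair (a, b) with per-concept document counts c_a, c_b, joint
count lc and corpus size N, the lift is

    lift = lc * N / (c_a * c_b)

— the ratio of the observed joint count to its expectation under
independence.  The R-scaled score rescales log-lift onto [0, 100]:

    rs = 100 * ln(lift) / scale_ref        (clipped to [0, 100])

with rs = 0 whenever lc = 0 or lift <= 1, and scale_ref the maximum
ln(lift) over the scoring run's pairs with lc >= lc_min.  rs values are
therefore comparable within one scoring run only; writers persist
scale_ref in the output header.  This rescaled log-lift is a
reimplementation choice — the historical 0–100 score this mirrors was
never published in formula form (see docs/methods.md).

Thresholds are strict: a pair passes when rs > rs_min and lc > lc_min.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import ValidationError
from .tagger import MentionIndex


@dataclass(frozen=True)
class PairStats:
    """Raw counts for one unordered concept pair (a < b canonically)."""

    concept_a: str
    concept_b: str
    c_a: int
    c_b: int
    lc: int
    N: int

    def __post_init__(self) -> None:
        if self.concept_a == self.concept_b:
            raise ValidationError("self-pairs are undefined")
        if self.lc > min(self.c_a, self.c_b) or max(self.c_a, self.c_b) > self.N:
            raise ValidationError(
                f"inconsistent counts for ({self.concept_a}, {self.concept_b})"
            )

    @property
    def lift(self) -> float:
        if self.c_a == 0 or self.c_b == 0:
            return 0.0
        return self.lc * self.N / (self.c_a * self.c_b)


@dataclass(frozen=True)
class AssociationScore:
    pair: PairStats
    lift: float
    rs: float


@dataclass(frozen=True)
class AssociationThresholds:
    """Strict cut-offs: pairs pass when rs > rs_min and lc > lc_min."""

    rs_min: float = 30.0
    lc_min: int = 5

    def __post_init__(self) -> None:
        if not 0.0 <= self.rs_min <= 100.0:
            raise ValidationError("rs_min must lie in [0, 100]")
        if self.lc_min < 0:
            raise ValidationError("lc_min must be >= 0")


#: Default gene–gene / gene–drug thresholds.
DEFAULT_THRESHOLDS = AssociationThresholds(rs_min=30.0, lc_min=5)
#: Stricter default for gene–disease extraction.
DISEASE_THRESHOLDS = AssociationThresholds(rs_min=35.0, lc_min=5)


def pair_stats(index: MentionIndex, a: str, b: str) -> PairStats:
    """Counts for one pair, from set sizes and intersection size."""
    if a == b:
        raise ValidationError(f"self-pair {a!r}")
    a, b = sorted((a, b))
    docs_a = index.by_concept.get(a, set())
    docs_b = index.by_concept.get(b, set())
    return PairStats(
        concept_a=a,
        concept_b=b,
        c_a=len(docs_a),
        c_b=len(docs_b),
        lc=len(docs_a & docs_b),
        N=index.N,
    )


def score_pair(stats: PairStats, scale_ref: float | None) -> AssociationScore:
    """Attach lift and rs to raw pair counts.

    ``scale_ref`` is the run's maximum log-lift; ``None`` (no pair in the
    run exceeded independence) forces rs = 0.
    """
    lift = stats.lift
    if lift > 1.0 and stats.lc >= 1 and scale_ref is not None and scale_ref > 0:
        rs = min(100.0, max(0.0, 100.0 * math.log(lift) / scale_ref))
    else:
        rs = 0.0
    return AssociationScore(pair=stats, lift=lift, rs=rs)


def compute_scale_ref(
    stats: Iterable[PairStats], lc_min: int
) -> float | None:
    """Maximum ln(lift) over pairs with lc >= lc_min and lift > 1."""
    best = None
    for s in stats:
        if s.lc >= lc_min and s.lift > 1.0:
            value = math.log(s.lift)
            if best is None or value > best:
                best = value
    return best


def _joint_counts(
    index: MentionIndex, ids_a: Sequence[str], ids_b: Sequence[str]
) -> dict[tuple[str, str], int]:
    """Joint document counts for all cross pairs with lc >= 1.

    Iterates documents rather than pairs: abstracts mention few concepts,
    so per-document cross products are cheap even for large vocabularies.
    """
    set_a, set_b = set(ids_a), set(ids_b)
    same = set_a == set_b
    counts: dict[tuple[str, str], int] = {}
    for concepts in index.by_doc.values():
        in_a = concepts & set_a
        if not in_a:
            continue
        if same:
            for x, y in combinations(sorted(in_a), 2):
                counts[(x, y)] = counts.get((x, y), 0) + 1
        else:
            in_b = concepts & set_b
            for x in in_a:
                for y in in_b:
                    if x != y:
                        key = tuple(sorted((x, y)))
                        counts[key] = counts.get(key, 0) + 1
    return counts


def score_pairs(
    index: MentionIndex,
    ids_a: Sequence[str],
    ids_b: Sequence[str],
    thresholds: AssociationThresholds,
) -> list[AssociationScore]:
    """Score all cross pairs between two id sets and apply thresholds.

    scale_ref is taken over this run's pairs with lc >= lc_min; only pairs
    with rs > rs_min and lc > lc_min are returned, sorted by rs descending,
    ties by lc descending then pair ids.
    """
    joint = _joint_counts(index, ids_a, ids_b)
    stats = [
        PairStats(
            concept_a=a,
            concept_b=b,
            c_a=index.doc_count(a),
            c_b=index.doc_count(b),
            lc=lc,
            N=index.N,
        )
        for (a, b), lc in joint.items()
    ]
    scale_ref = compute_scale_ref(stats, thresholds.lc_min)
    scored = [score_pair(s, scale_ref) for s in stats]
    passing = [
        s
        for s in scored
        if s.rs > thresholds.rs_min and s.pair.lc > thresholds.lc_min
    ]
    passing.sort(
        key=lambda s: (-s.rs, -s.pair.lc, s.pair.concept_a, s.pair.concept_b)
    )
    return passing


def score_category_pairs(
    index: MentionIndex,
    cat_a: str,
    cat_b: str,
    thresholds: AssociationThresholds = DEFAULT_THRESHOLDS,
) -> list[AssociationScore]:
    """Score all tagged cross-category pairs and apply thresholds."""
    return score_pairs(
        index,
        index.concepts_in_category(cat_a),
        index.concepts_in_category(cat_b),
        thresholds,
    )


def literature_neighbours(
    index: MentionIndex,
    concept_id: str,
    category_filter: str,
    thresholds: AssociationThresholds = DEFAULT_THRESHOLDS,
) -> list[AssociationScore]:
    """All passing partners of one concept, restricted to a category.

    The result is exactly the concept's slice of the corresponding
    category-pair run (same scale_ref), ranked by rs, then lc, then id.
    """
    if concept_id not in index.by_concept:
        raise ValidationError(f"unknown concept {concept_id!r}")
    cat_a = index.categories[concept_id]
    scores = score_category_pairs(index, cat_a, category_filter, thresholds)
    return [
        s
        for s in scores
        if concept_id in (s.pair.concept_a, s.pair.concept_b)
    ]


class ProfileMatrix:
    """Dense gene × disease matrix of rs values (0 where a pair failed).

    Columns are disease profiles over a common gene universe; they feed the
    correlation-distance clustering.
    """

    def __init__(self, frame: pd.DataFrame) -> None:
        self.frame = frame

    @property
    def row_ids(self) -> list[str]:
        return list(self.frame.index)

    @property
    def col_ids(self) -> list[str]:
        return list(self.frame.columns)

    def top_k_columns(self, k: int) -> "ProfileMatrix":
        """Keep the k columns with the most nonzero entries (ties by id)."""
        nonzero = (self.frame > 0).sum(axis=0)
        order = sorted(self.frame.columns, key=lambda c: (-nonzero[c], c))
        return ProfileMatrix(self.frame[order[:k]])

    def save(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t", index_label="gene")

    @classmethod
    def load(cls, path: str | Path) -> "ProfileMatrix":
        return cls(pd.read_csv(path, sep="\t", index_col="gene"))


def build_profile_matrix(
    scores: Iterable[AssociationScore],
    genes: Sequence[str],
    diseases: Sequence[str],
) -> ProfileMatrix:
    """Arrange passing gene–disease scores into a dense profile matrix."""
    genes = list(genes)
    diseases = list(diseases)
    if not genes or not diseases:
        raise ValidationError("gene and disease lists must be non-empty")
    frame = pd.DataFrame(0.0, index=genes, columns=diseases)
    gene_set, disease_set = set(genes), set(diseases)
    for s in scores:
        a, b = s.pair.concept_a, s.pair.concept_b
        if a in gene_set and b in disease_set:
            frame.loc[a, b] = s.rs
        elif b in gene_set and a in disease_set:
            frame.loc[b, a] = s.rs
    return ProfileMatrix(frame)


def save_scores(
    scores: Iterable[AssociationScore],
    path: str | Path,
    thresholds: AssociationThresholds | None = None,
    scale_ref: float | None = None,
    corpus_hash: str | None = None,
) -> None:
    """Write scores as TSV with a reproducibility header (# key=value)."""
    with Path(path).open("w", encoding="utf-8") as fh:
        if scale_ref is not None:
            fh.write(f"# scale_ref={scale_ref!r}\n")
        if thresholds is not None:
            fh.write(f"# rs_min={thresholds.rs_min} lc_min={thresholds.lc_min}\n")
        if corpus_hash is not None:
            fh.write(f"# corpus_hash={corpus_hash}\n")
        fh.write("concept_a\tconcept_b\tc_a\tc_b\tlc\tN\tlift\trs\n")
        for s in scores:
            p = s.pair
            fh.write(
                f"{p.concept_a}\t{p.concept_b}\t{p.c_a}\t{p.c_b}\t{p.lc}\t{p.N}"
                f"\t{s.lift:.6g}\t{s.rs:.6g}\n"
            )
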