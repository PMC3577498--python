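"""Keyword over-representation for a gene set (hypergeometric test).

A drug or disease keyword is "linked" to a gene when their pair passes the
association thresholds.  Given a query gene set of size n drawn from a
background of N_bg corpus-tagged genes, of which K are linked to the
keyword and k fall in the query, the enrichment p-value is the one-sided
hypergeometric tail P(X >= k).  The background is restricted to thesaurus
genes with at least one mention: genes absent from the corpus cannot be
drawn.  Results are filtered on the raw p-value, but Benjamini–Hochberg
q-values are always reported alongside so FDR control is one column away.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .association import (
    AssociationThresholds,
    DEFAULT_THRESHOLDS,
    score_pairs,
)
from .errors import ValidationError
from .tagger import MentionIndex


@dataclass(frozen=True)
class EnrichmentResult:
    keyword_id: str
    category: str
    k: int      # query genes linked to the keyword
    K: int      # background genes linked to the keyword
    n: int      # query size
    N_bg: int   # background size
    p_value: float
    q_value: float


def enrich(
    gene_set: Iterable[str],
    index: MentionIndex,
    category: str,
    thresholds: AssociationThresholds = DEFAULT_THRESHOLDS,
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """Over-represented keywords of a category in a gene set.

    Returns keywords with p < alpha, sorted by p ascending (ties by id).
    q-values are BH-adjusted over every keyword with at least one linked
    background gene, before the alpha filter.
    """
    if category not in {"drug", "disease"}:
        raise ValidationError("enrichment category must be 'drug' or 'disease'")
    query = set(gene_set)
    if not query:
        raise ValidationError("gene_set is empty")
    background = set(index.concepts_in_category("gene"))
    if not query <= background:
        missing = sorted(query - background)[:5]
        raise ValidationError(
            f"query genes not in tagged background: {missing} ..."
        )
    n, N_bg = len(query), len(background)

    # Gene–keyword links under the thresholds, over the full background.
    links: dict[str, set[str]] = {}
    for score in score_pairs(
        index, sorted(background), index.concepts_in_category(category), thresholds
    ):
        a, b = score.pair.concept_a, score.pair.concept_b
        gene, keyword = (a, b) if index.categories[a] == "gene" else (b, a)
        links.setdefault(keyword, set()).add(gene)

    rows = []
    for keyword in sorted(links):
        linked = links[keyword]
        K = len(linked)
        k = len(linked & query)
        p = float(hypergeom.sf(k - 1, N_bg, K, n))
        rows.append((keyword, k, K, p))
    if not rows:
        return []
    q_values = multipletests([r[3] for r in rows], method="fdr_bh")[1]
    results = [
        EnrichmentResult(
            keyword_id=keyword,
            category=category,
            k=k,
            K=K,
            n=n,
            N_bg=N_bg,
            p_value=p,
            q_value=float(q),
        )
        for (keyword, k, K, p), q in zip(rows, q_values)
    ]
    results = [r for r in results if r.p_value < alpha]
    results.sort(key=lambda r: (r.p_value, r.keyword_id))
    return results


def save_enrichment(results: Iterable[EnrichmentResult], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("keyword\tcategory\tk\tK\tn\tN_bg\tp_value\tq_value\n")
        for r in results:
            fh.write(
                f"{r.keyword_id}\t{r.category}\t{r.k}\t{r.K}\t{r.n}\t{r.N_bg}"
                f"\t{r.p_value:.6g}\t{r.q_value:.6g}\n"
            )
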