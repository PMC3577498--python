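"""Neighbor-weighted literature scores and candidate-gene selection.

The literature score of gene g with term d (a drug or disease keyword)
averages the gene's own rs with the term against the evidence carried by
its network neighborhood:

    literature_score(g) = (g1 + Ns) / 2
    Ns = (rg2*g2 + rg3*g3 + ... + rgn*gn) / (rg2 + rg3 + ... + rgn)

where g1 is the rs of g with d, g2..gn are the neighbors' rs values with
d, and rg2..rgn are the rs weights of the edges joining g to those
neighbors.  Ns is a weighted mean, so the score stays within the convex
hull of the inputs and in [0, 100].  A gene with no direct link can still
acquire a score through well-connected neighbors — and conversely a
directly-selected candidate can be ruled out once its neighborhood is
taken into account.

A gene without neighbors keeps its direct score unchanged: halving a lone
direct score would penalize isolated genes for missing data, against the
score's intent of adding neighborhood evidence.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
import pandas as pd

from .errors import ValidationError
from .network import LiteratureNetwork


@dataclass(frozen=True)
class NeighborScoreInput:
    """One gene's direct rs with a term plus its weighted neighborhood.

    ``neighbors`` holds (g_i, rg_i) pairs: the neighbor's rs with the term
    and the rs of the edge joining it to the gene.
    """

    g1: float
    neighbors: tuple[tuple[float, float], ...] = ()

    def __post_init__(self) -> None:
        if not 0.0 <= self.g1 <= 100.0:
            raise ValidationError("g1 must lie in [0, 100]")
        for g_i, rg_i in self.neighbors:
            if not 0.0 <= g_i <= 100.0:
                raise ValidationError("neighbor term scores must lie in [0, 100]")
            if not 0.0 < rg_i <= 100.0:
                raise ValidationError("edge weights must lie in (0, 100]")


def neighbor_component(inputs: NeighborScoreInput) -> float:
    """Ns: the rs-weighted mean of the neighbors' term scores."""
    if not inputs.neighbors:
        raise ValidationError("neighbor list is empty; Ns is undefined")
    total = sum(rg for _, rg in inputs.neighbors)
    return sum(g * rg for g, rg in inputs.neighbors) / total


def literature_score(inputs: NeighborScoreInput) -> float:
    """(g1 + Ns) / 2 with neighbors; g1 alone without."""
    if not inputs.neighbors:
        return inputs.g1
    return (inputs.g1 + neighbor_component(inputs)) / 2.0


@dataclass(frozen=True)
class GeneTermScores:
    """Per-gene direct rs, Ns and literature score for one term."""

    term: str
    frame: pd.DataFrame  # index: gene; columns: direct, ns, literature_score

    @property
    def genes(self) -> set[str]:
        return set(self.frame.index)

    def save(self, path: str | Path) -> None:
        out = self.frame.copy()
        out.insert(0, "term", self.term)
        out.to_csv(path, sep="\t", index_label="gene")


def score_genes_for_term(
    network: LiteratureNetwork, term_attribute: str
) -> GeneTermScores:
    """Literature scores for every gene in an annotated network.

    ``term_attribute`` names the node attribute holding each gene's direct
    rs with the term (set by :func:`litnet.network.annotate_nodes`).
    """
    graph = network.graph
    missing = [n for n, d in graph.nodes(data=True) if term_attribute not in d]
    if missing:
        raise ValidationError(
            f"nodes missing attribute {term_attribute!r}: {sorted(missing)[:5]}"
        )
    rows = {}
    for node in graph.nodes:
        g1 = float(graph.nodes[node][term_attribute])
        neighbors = tuple(
            (float(graph.nodes[nb][term_attribute]), float(graph.edges[node, nb]["rs"]))
            for nb in graph.neighbors(node)
        )
        inputs = NeighborScoreInput(g1=g1, neighbors=neighbors)
        ns = neighbor_component(inputs) if neighbors else float("nan")
        rows[node] = (g1, ns, literature_score(inputs))
    frame = pd.DataFrame.from_dict(
        rows, orient="index", columns=["direct", "ns", "literature_score"]
    ).sort_index()
    return GeneTermScores(term=term_attribute, frame=frame)


def select_candidates(
    scores_hi: GeneTermScores,
    scores_lo: GeneTermScores,
    hi: float = 25.0,
    lo: float = 25.0,
    use: str = "literature_score",
) -> list[str]:
    """Genes scoring above ``hi`` on one term and below ``lo`` on another.

    The canonical use ranks genes high on a drug of interest (e.g. a
    glucocorticoid) and low on a confounding process (e.g. inflammation).
    ``use`` selects the score column: "literature_score" (neighborhood
    included) or "direct".
    """
    if use not in {"literature_score", "direct"}:
        raise ValidationError("use must be 'literature_score' or 'direct'")
    if scores_hi.genes != scores_lo.genes:
        raise ValidationError("score sets cover different gene universes")
    hi_col = scores_hi.frame[use]
    lo_col = scores_lo.frame[use]
    return sorted(g for g in scores_hi.genes if hi_col[g] > hi and lo_col[g] < lo)
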