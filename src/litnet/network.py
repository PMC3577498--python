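"""rs-weighted literature gene networks and their topology statistics.

Nodes are genes; an edge joins two genes whose co-occurrence passes the
association thresholds, weighted by the pair's rs (lc kept as a secondary
attribute for filtering).  Isolated genes stay in the network and are
reported — the connected-count is part of the contract.  Node attributes
hold rs values with annotation keywords (a drug, a disease) for downstream
neighbor scoring.

Topology statistics mirror what is usually reported for literature
networks: hub sets (degree above a cut-off), a power-law fit to the degree
distribution, and shortest-path betweenness centrality.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

import networkx as nx
import numpy as np
from scipy import stats

from .association import (
    AssociationThresholds,
    DEFAULT_THRESHOLDS,
    score_pairs,
)
from .errors import ValidationError
from .tagger import MentionIndex


class LiteratureNetwork:
    """Undirected rs-weighted gene graph with per-node keyword annotations.

    Thin wrapper over :class:`networkx.Graph`; the graph is exposed as
    ``.graph`` for any analysis litnet does not wrap.
    """

    def __init__(self, graph: nx.Graph) -> None:
        for u, v in graph.edges():
            if u == v:
                raise ValidationError("self-loops are not allowed")
        self.graph = graph

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def connected_count(self) -> int:
        """Number of genes with at least one edge (the "k of n connected" report)."""
        return sum(1 for _, d in self.graph.degree() if d > 0)

    def isolated_nodes(self) -> set[str]:
        return {n for n, d in self.graph.degree() if d == 0}

    def node_attribute(self, name: str) -> dict[str, float]:
        return {n: data.get(name, 0.0) for n, data in self.graph.nodes(data=True)}


def build_network(
    gene_set: Iterable[str],
    index: MentionIndex,
    thresholds: AssociationThresholds = DEFAULT_THRESHOLDS,
) -> LiteratureNetwork:
    """Connect genes whose co-occurrence passes the thresholds.

    All input genes become nodes (isolates retained); edges carry ``rs``
    and ``lc``.  Output is invariant to gene_set ordering.
    """
    genes = sorted(set(gene_set))
    if not genes:
        raise ValidationError("gene_set is empty")
    graph = nx.Graph()
    graph.add_nodes_from(genes)
    for score in score_pairs(index, genes, genes, thresholds):
        graph.add_edge(
            score.pair.concept_a,
            score.pair.concept_b,
            rs=score.rs,
            lc=score.pair.lc,
        )
    return LiteratureNetwork(graph)


def annotate_nodes(
    network: LiteratureNetwork,
    index: MentionIndex,
    keyword_id: str,
    attribute_name: str,
    thresholds: AssociationThresholds = DEFAULT_THRESHOLDS,
) -> LiteratureNetwork:
    """Attach each gene's rs with a keyword as a node attribute (in place).

    Genes whose pair with the keyword fails the thresholds get 0.  The rs
    scale is the gene × keyword-category scoring run restricted to the
    network's genes, so annotations are comparable across nodes.  Topology
    is unchanged; annotating twice with the same keyword is idempotent.
    """
    if keyword_id not in index.by_concept:
        raise ValidationError(f"unknown keyword {keyword_id!r}")
    genes = sorted(network.nodes)
    keyword_cat = index.categories[keyword_id]
    values = {g: 0.0 for g in genes}
    for score in score_pairs(
        index, genes, index.concepts_in_category(keyword_cat), thresholds
    ):
        a, b = score.pair.concept_a, score.pair.concept_b
        if a == keyword_id and b in values:
            values[b] = score.rs
        elif b == keyword_id and a in values:
            values[a] = score.rs
    nx.set_node_attributes(network.graph, values, attribute_name)
    return network


@dataclass(frozen=True)
class PowerLawFit:
    """Least-squares line on log-degree vs log-CCDF (degrees >= 1)."""

    slope: float
    intercept: float
    p_value: float
    r_squared: float
    #: maximum-likelihood exponent alpha of p(d) ~ d^-alpha (alternative)
    mle_exponent: float


@dataclass(frozen=True)
class DegreeAnalysis:
    degrees: dict[str, int]
    hubs: set[str]
    fit: PowerLawFit | None


def fit_power_law(degrees: Sequence[int]) -> PowerLawFit | None:
    """Fit the degree CCDF on log-log scale.

    Uses degrees >= 1 only.  The CCDF P(D >= d) at each observed degree is
    regressed on log d; the p-value is the two-sided t-test on the slope.
    If p(d) ~ d^-alpha then the CCDF slope estimates -(alpha - 1).  The MLE
    exponent (continuous approximation with dmin = min degree) is reported
    as an alternative estimate.
    """
    values = np.asarray([d for d in degrees if d >= 1], dtype=float)
    if values.size < 3 or np.unique(values).size < 3:
        return None
    unique = np.unique(values)
    ccdf = np.array([(values >= d).mean() for d in unique])
    reg = stats.linregress(np.log(unique), np.log(ccdf))
    dmin = unique.min()
    mle = 1.0 + values.size / np.sum(np.log(values / (dmin - 0.5)))
    return PowerLawFit(
        slope=float(reg.slope),
        intercept=float(reg.intercept),
        p_value=float(reg.pvalue),
        r_squared=float(reg.rvalue**2),
        mle_exponent=float(mle),
    )


def degree_analysis(
    network: LiteratureNetwork, hub_min_degree: int = 100
) -> DegreeAnalysis:
    """Degrees, hub set (degree > hub_min_degree) and power-law fit.

    With all nodes isolated the fit is undefined and reported as ``None``.
    """
    if not network.nodes:
        raise ValidationError("network is empty")
    degrees = {n: int(d) for n, d in network.graph.degree()}
    hubs = {n for n, d in degrees.items() if d > hub_min_degree}
    return DegreeAnalysis(
        degrees=degrees, hubs=hubs, fit=fit_power_law(list(degrees.values()))
    )


def betweenness(network: LiteratureNetwork) -> dict[str, float]:
    """Shortest-path betweenness centrality, normalized by pair count.

    Unweighted shortest paths (hop counts): edge rs measures literature
    support, not traversal cost.  Deterministic.
    """
    return {
        n: float(v)
        for n, v in nx.betweenness_centrality(network.graph, normalized=True).items()
    }


def neighborhood_subnetwork(
    network: LiteratureNetwork, seed_nodes: Iterable[str]
) -> LiteratureNetwork:
    """Induced subgraph on the seeds and their direct neighbors."""
    seeds = set(seed_nodes)
    unknown = seeds - network.nodes
    if unknown:
        raise ValidationError(f"unknown seed nodes: {sorted(unknown)}")
    keep = set(seeds)
    for s in seeds:
        keep.update(network.graph.neighbors(s))
    return LiteratureNetwork(network.graph.subgraph(keep).copy())


def export_network(
    network: LiteratureNetwork,
    path: str | Path,
    format: Literal["graphml", "sif", "edge_tsv"] = "graphml",
) -> None:
    """Write the network for downstream tools (e.g. Cytoscape).

    graphml round-trips nodes, edges, weights and node attributes;
    sif is the minimal "g1 cooccurs g2" interaction format; edge_tsv is
    ``source  target  rs  lc``.
    """
    path = Path(path)
    if format == "graphml":
        nx.write_graphml(network.graph, str(path))
    elif format == "sif":
        with path.open("w", encoding="utf-8") as fh:
            for u, v in sorted(map(sorted, network.graph.edges())):
                fh.write(f"{u} cooccurs {v}\n")
            for n in sorted(network.isolated_nodes()):
                fh.write(f"{n}\n")
    elif format == "edge_tsv":
        with path.open("w", encoding="utf-8") as fh:
            fh.write("source\ttarget\trs\tlc\n")
            for u, v in sorted(map(sorted, network.graph.edges())):
                data = network.graph.edges[u, v]
                fh.write(f"{u}\t{v}\t{data['rs']:.6g}\t{data['lc']}\n")
    else:
        raise ValueError(f"unknown network format {format!r}")


def load_graphml(path: str | Path) -> LiteratureNetwork:
    graph = nx.read_graphml(str(path))
    # GraphML stores numbers as typed attributes already; relabel to str ids.
    return LiteratureNetwork(nx.relabel_nodes(graph, {n: str(n) for n in graph.nodes}))
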