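"""Gene network construction, annotation, topology and export."""

from collections import deque
from itertools import combinations

import networkx as nx
import numpy as np
import pytest

from litnet.association import AssociationThresholds
from litnet.errors import ValidationError
from litnet.network import (
    LiteratureNetwork,
    annotate_nodes,
    betweenness,
    build_network,
    degree_analysis,
    export_network,
    fit_power_law,
    load_graphml,
    neighborhood_subnetwork,
)
from litnet.simulate import GeneratorConfig, PlantedPair, generate
from litnet.tagger import tag_corpus

OPEN = AssociationThresholds(rs_min=0.0, lc_min=0)


def make_net(edges, isolated=()):
    g = nx.Graph()
    for u, v in edges:
        g.add_edge(u, v, rs=50.0, lc=10)
    g.add_nodes_from(isolated)
    return LiteratureNetwork(g)


@pytest.fixture
def planted_clique_index():
    genes = ["G000", "G001", "G002", "G003"]
    pairs = tuple(
        PlantedPair(a, b, 0.02) for a, b in combinations(genes, 2)
    )
    config = GeneratorConfig(
        seed=9, n_genes=10, n_diseases=2, n_drugs=2, n_docs=1500,
        background_rate=0.01, planted_pairs=pairs,
    )
    thesaurus, corpus, _ = generate(config)
    return tag_corpus(corpus, thesaurus)


def test_build_network_recovers_planted_clique(planted_clique_index):
    genes = [f"G{i:03d}" for i in range(10)]
    network = build_network(genes, planted_clique_index, AssociationThresholds(30.0, 5))
    clique = {"G000", "G001", "G002", "G003"}
    for a, b in combinations(sorted(clique), 2):
        assert network.graph.has_edge(a, b)
    assert network.nodes == set(genes)  # isolates retained
    assert network.connected_count() >= 4
    assert network.isolated_nodes() <= set(genes) - clique


def test_build_network_invariant_to_gene_order(planted_clique_index):
    genes = [f"G{i:03d}" for i in range(10)]
    a = build_network(genes, planted_clique_index, OPEN)
    b = build_network(genes[::-1], planted_clique_index, OPEN)
    assert set(a.graph.edges) == set(b.graph.edges)


def test_no_thresholds_yields_edge_per_comentioned_pair(planted_clique_index):
    genes = [f"G{i:03d}" for i in range(10)]
    network = build_network(genes, planted_clique_index, OPEN)
    index = planted_clique_index
    for a, b in combinations(genes, 2):
        docs_a = index.by_concept.get(a, set())
        docs_b = index.by_concept.get(b, set())
        joint = docs_a & docs_b
        if joint:
            stats_lift = len(joint) * index.N / (len(docs_a) * len(docs_b))
            assert network.graph.has_edge(a, b) == (stats_lift > 1.0)


def test_annotate_nodes_sets_rs_and_is_idempotent(planted_clique_index):
    index = planted_clique_index
    network = build_network([f"G{i:03d}" for i in range(10)], index, OPEN)
    annotate_nodes(network, index, "D000", "seed_disease", OPEN)
    first = network.node_attribute("seed_disease")
    annotate_nodes(network, index, "D000", "seed_disease", OPEN)
    assert network.node_attribute("seed_disease") == first
    assert all(0.0 <= v <= 100.0 for v in first.values())
    with pytest.raises(ValidationError):
        annotate_nodes(network, index, "NOSUCH", "x", OPEN)


def test_star_graph_hub_detection():
    network = make_net([("hub", f"n{i}") for i in range(10)])
    analysis = degree_analysis(network, hub_min_degree=5)
    assert analysis.hubs == {"hub"}
    assert analysis.degrees["hub"] == 10


def test_hub_set_shrinks_as_cutoff_rises():
    network = make_net(
        [("a", f"x{i}") for i in range(6)] + [("b", f"x{i}") for i in range(3)]
    )
    previous = None
    for cutoff in range(0, 8):
        hubs = degree_analysis(network, cutoff).hubs
        if previous is not None:
            assert hubs <= previous
        previous = hubs


def test_power_law_fit_on_zipf_sample():
    rng = np.random.default_rng(123)
    degrees = rng.zipf(2.5, size=300)
    fit = fit_power_law(list(degrees))
    # CCDF slope estimates -(alpha - 1) = -1.5
    assert fit.slope == pytest.approx(-1.5, abs=0.5)
    assert fit.p_value < 1e-3
    assert fit.mle_exponent == pytest.approx(2.5, abs=0.5)


def test_power_law_fit_beats_poisson_degrees_on_r_squared():
    wins = 0
    for seed in range(20):
        rng = np.random.default_rng(seed)
        power = fit_power_law(list(rng.zipf(2.5, size=300)))
        poisson = fit_power_law(list(1 + rng.poisson(8.0, size=300)))
        wins += power.r_squared > poisson.r_squared
    assert wins > 10


def test_degree_fit_undefined_for_isolated_nodes():
    network = make_net([], isolated=["a", "b", "c"])
    assert degree_analysis(network, 1).fit is None


def brute_force_betweenness(graph):
    """Enumerate every shortest path explicitly (BFS levels + DFS walk)."""
    nodes = sorted(graph.nodes)
    score = {n: 0.0 for n in nodes}
    for s, t in combinations(nodes, 2):
        # BFS distances from s
        dist = {s: 0}
        queue = deque([s])
        while queue:
            u = queue.popleft()
            for w in graph.neighbors(u):
                if w not in dist:
                    dist[w] = dist[u] + 1
                    queue.append(w)
        if t not in dist:
            continue
        paths = []
        stack = [[t]]
        while stack:
            path = stack.pop()
            head = path[-1]
            if head == s:
                paths.append(path)
                continue
            for w in graph.neighbors(head):
                if dist.get(w) == dist[head] - 1:
                    stack.append(path + [w])
        for path in paths:
            for v in path[1:-1]:
                score[v] += 1.0 / len(paths)
    n = len(nodes)
    norm = (n - 1) * (n - 2) / 2 if n > 2 else 1
    return {v: s / norm for v, s in score.items()}


def test_path_graph_betweenness():
    network = make_net([("a", "b"), ("b", "c")])
    result = betweenness(network)
    assert result == {"a": 0.0, "b": 1.0, "c": 0.0}


def test_complete_graph_betweenness_all_zero():
    network = make_net(list(combinations("abcde", 2)))
    assert all(v == 0.0 for v in betweenness(network).values())


def test_barbell_bridge_node_is_maximal():
    # two triangles joined through "m": a-b-c + c-m + m-d + d-e-f
    network = make_net(
        [("a", "b"), ("b", "c"), ("a", "c"), ("c", "m"), ("m", "d"),
         ("d", "e"), ("e", "f"), ("d", "f")]
    )
    result = betweenness(network)
    assert result["m"] == max(result.values())
    assert result == pytest.approx(brute_force_betweenness(network.graph))


@pytest.mark.parametrize("seed", range(6))
def test_betweenness_matches_brute_force_on_random_graphs(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(5, 31))
    graph = nx.gnp_random_graph(n, 0.25, seed=seed)
    graph = nx.relabel_nodes(graph, {i: f"n{i}" for i in graph.nodes})
    nx.set_edge_attributes(graph, 50.0, "rs")
    nx.set_edge_attributes(graph, 10, "lc")
    network = LiteratureNetwork(graph)
    expected = brute_force_betweenness(graph)
    assert betweenness(network) == pytest.approx(expected, abs=1e-12)


def test_neighborhood_subnetwork_is_induced():
    network = make_net(
        [("s", "a"), ("s", "b"), ("a", "b"), ("b", "c"), ("c", "d")],
        isolated=["z"],
    )
    sub = neighborhood_subnetwork(network, {"s"})
    assert sub.nodes == {"s", "a", "b"}
    assert set(map(frozenset, sub.graph.edges)) == {
        frozenset(e) for e in [("s", "a"), ("s", "b"), ("a", "b")]
    }
    identity = neighborhood_subnetwork(network, network.nodes)
    assert identity.nodes == network.nodes
    with pytest.raises(ValidationError):
        neighborhood_subnetwork(network, {"nope"})


def test_export_formats_and_graphml_round_trip(tmp_path):
    network = make_net([("g1", "g2")], isolated=["g3"])
    network.graph.nodes["g1"]["dex"] = 40.0

    export_network(network, tmp_path / "n.sif", "sif")
    assert "g1 cooccurs g2" in (tmp_path / "n.sif").read_text()

    export_network(network, tmp_path / "n.tsv", "edge_tsv")
    lines = (tmp_path / "n.tsv").read_text().splitlines()
    assert len(lines) - 1 == network.n_edges

    export_network(network, tmp_path / "n.graphml", "graphml")
    reloaded = load_graphml(tmp_path / "n.graphml")
    assert reloaded.nodes == network.nodes
    assert set(map(frozenset, reloaded.graph.edges)) == {frozenset(("g1", "g2"))}
    assert reloaded.graph.edges["g1", "g2"]["rs"] == 50.0
    assert reloaded.graph.nodes["g1"]["dex"] == 40.0

    with pytest.raises(ValueError):
        export_network(network, tmp_path / "n.x", "dot")
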