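"""End-to-end diagnostic: the full pipeline on a bundled synthetic fixture.

Runs simulate → tag → associations → network → enrich → cluster → score in
a working directory, checking each stage against the generator's planted
truth.  Checks are deliberately tolerant (the corpus is stochastic); the
candidate-selection stage is additionally re-run to confirm byte-identical
outputs under the fixed seed.
"""

from __future__ import annotations

from pathlib import Path

from .association import (
    AssociationThresholds,
    DISEASE_THRESHOLDS,
    build_profile_matrix,
    save_scores,
    score_category_pairs,
)
from .clustering import bootstrap_support
from .corpus import load_corpus
from .enrichment import enrich
from .network import annotate_nodes, build_network, degree_analysis, export_network
from .neighbor_score import score_genes_for_term, select_candidates
from .simulate import default_scenario, generate, planted_cross_pairs
from .tagger import MentionIndex, tag_corpus
from .thesaurus import load_thesaurus

StageReport = tuple[str, bool, str]


def run_selftest(seed: int, workdir: Path) -> list[StageReport]:
    report: list[StageReport] = []
    config = default_scenario(seed)
    thresholds = AssociationThresholds(rs_min=30.0, lc_min=5)

    # simulate -------------------------------------------------------------
    thesaurus, corpus, truth = generate(config)
    thesaurus.save(workdir / "thesaurus.tsv")
    corpus.save_jsonl(workdir / "corpus.jsonl")
    truth.to_json(workdir / "truth.json")
    ok = corpus.N == config.n_docs and len(thesaurus) == 200
    report.append(("simulate", ok, f"{corpus.N} docs, {len(thesaurus)} concepts"))

    # tag ------------------------------------------------------------------
    thesaurus = load_thesaurus(workdir / "thesaurus.tsv")
    corpus = load_corpus(workdir / "corpus.jsonl")
    index = tag_corpus(corpus, thesaurus)
    index.save(workdir / "index.concepts.tsv", workdir / "index.docs.tsv")
    index = MentionIndex.load(
        workdir / "index.concepts.tsv", workdir / "index.docs.tsv"
    )
    ok = index.N == corpus.N and truth.hub in index.by_concept
    report.append(
        ("tag", ok, f"{len(index.by_concept)} concepts with >=1 mention")
    )

    # associations ---------------------------------------------------------
    gd = score_category_pairs(index, "gene", "disease", thresholds)
    gr = score_category_pairs(index, "gene", "drug", thresholds)
    save_scores(gd + gr, workdir / "scores.tsv", thresholds=thresholds)
    recovered = {
        (s.pair.concept_a, s.pair.concept_b) for s in gd + gr
    }
    planted = planted_cross_pairs(config)
    frac = len(recovered & planted) / len(planted)
    ok = frac >= 0.8
    report.append(
        ("associations", ok, f"recovered {frac:.0%} of planted cross pairs")
    )

    # network --------------------------------------------------------------
    network = build_network(thesaurus.ids_in_category("gene"), index, thresholds)
    analysis = degree_analysis(network, hub_min_degree=8)
    max_degree = max(analysis.degrees.values())
    ok = analysis.degrees.get(truth.hub, 0) == max_degree and max_degree > 0
    annotate_nodes(network, index, "R000", "drug_of_interest", thresholds)
    annotate_nodes(network, index, "D001", "confounder", thresholds)
    export_network(network, workdir / "network.graphml", format="graphml")
    report.append(
        ("network", ok, f"{network.connected_count()} connected, hub degree {max_degree}")
    )

    # enrich ---------------------------------------------------------------
    seed_genes = sorted(
        {g for s in gd for g in (s.pair.concept_a, s.pair.concept_b)
         if index.categories[g] == "gene"
         and "D000" in (s.pair.concept_a, s.pair.concept_b)}
    )
    results = enrich(seed_genes, index, "drug", thresholds, alpha=0.05)
    ok = any(r.keyword_id == "R000" for r in results)
    report.append(
        ("enrich", ok,
         f"top drug {results[0].keyword_id if results else 'none'} "
         f"(p={results[0].p_value:.2e})" if results else "no enrichment")
    )

    # cluster --------------------------------------------------------------
    scores_disease = score_category_pairs(index, "gene", "disease", DISEASE_THRESHOLDS)
    diseases = sorted(
        {c for s in scores_disease for c in (s.pair.concept_a, s.pair.concept_b)
         if index.categories[c] == "disease"}
    )
    matrix = build_profile_matrix(
        scores_disease, index.concepts_in_category("gene"), diseases
    ).top_k_columns(80)
    frame = matrix.frame.loc[matrix.frame.sum(axis=1) > 0]
    matrix.frame = frame.loc[:, frame.std(axis=0, ddof=0) > 0]
    dendrogram, support = bootstrap_support(matrix, B=100, seed=seed)
    (workdir / "dendrogram.nwk").write_text(dendrogram.to_newick(support) + "\n")
    block_au = []
    for block in truth.blocks:
        members = frozenset(b for b in block if b in matrix.col_ids)
        record = support.records.get(members)
        block_au.append(record.au if record is not None else 0.0)
    ok = all(au >= 70.0 for au in block_au)
    report.append(
        ("cluster", ok, "block AU " + "/".join(f"{au:.0f}" for au in block_au))
    )

    # score ----------------------------------------------------------------
    def write_candidates(path: Path) -> None:
        hi_scores = score_genes_for_term(network, "drug_of_interest")
        lo_scores = score_genes_for_term(network, "confounder")
        direct = set(select_candidates(hi_scores, lo_scores, 25, 25, use="direct"))
        weighted = set(
            select_candidates(hi_scores, lo_scores, 25, 25, use="literature_score")
        )
        with path.open("w") as fh:
            fh.write("gene\tdirect_selected\tliterature_selected\n")
            for gene in sorted(direct | weighted):
                fh.write(f"{gene}\t{int(gene in direct)}\t{int(gene in weighted)}\n")

    write_candidates(workdir / "candidates.tsv")
    write_candidates(workdir / "candidates.rerun.tsv")
    first = (workdir / "candidates.tsv").read_bytes()
    ok = (
        first == (workdir / "candidates.rerun.tsv").read_bytes()
        and len(first.splitlines()) > 1
    )
    report.append(
        ("score", ok, f"{len(first.splitlines()) - 1} candidate genes, rerun identical")
    )
    return report
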