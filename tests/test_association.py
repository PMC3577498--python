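"""Pair counting, lift/rs scoring, thresholds and profile matrices."""

import math
from itertools import combinations

import pytest

from litnet.association import (
    AssociationThresholds,
    PairStats,
    build_profile_matrix,
    compute_scale_ref,
    literature_neighbours,
    pair_stats,
    save_scores,
    score_category_pairs,
    score_pair,
)
from litnet.errors import ValidationError
from litnet.simulate import GeneratorConfig, PlantedPair, generate
from litnet.tagger import MentionIndex, tag_corpus


def make_index(by_doc, categories=None):
    cats = categories or {}
    inferred = {c: cats.get(c, "gene") for cs in by_doc.values() for c in cs}
    return MentionIndex({d: set(cs) for d, cs in by_doc.items()}, inferred)


@pytest.fixture
def toy_index():
    """A in {d1,d2,d3}; B in {d1,d2,d4}; N=5."""
    return make_index(
        {"d1": {"A", "B"}, "d2": {"A", "B"}, "d3": {"A"}, "d4": {"B"}, "d5": set()}
    )


def test_pair_stats_counts_from_set_intersection(toy_index):
    stats = pair_stats(toy_index, "A", "B")
    assert (stats.c_a, stats.c_b, stats.lc, stats.N) == (3, 3, 2, 5)


def test_pair_stats_symmetric_and_rejects_self_pairs(toy_index):
    assert pair_stats(toy_index, "A", "B") == pair_stats(toy_index, "B", "A")
    with pytest.raises(ValidationError):
        pair_stats(toy_index, "A", "A")


def test_disjoint_concepts_have_zero_joint_count():
    index = make_index({"d1": {"A"}, "d2": {"B"}})
    assert pair_stats(index, "A", "B").lc == 0


def test_score_pair_hand_arithmetic(toy_index):
    stats = pair_stats(toy_index, "A", "B")
    assert stats.lift == pytest.approx(10 / 9)
    # if this pair sets the run's maximal log-lift, it scores exactly 100
    score = score_pair(stats, scale_ref=math.log(10 / 9))
    assert score.rs == pytest.approx(100.0)


@pytest.mark.parametrize(
    "c_a, c_b, lc, N",
    [(3, 3, 0, 5), (4, 4, 2, 8)],
)
def test_score_pair_zero_cases(c_a, c_b, lc, N):
    stats = PairStats("A", "B", c_a, c_b, lc, N)
    score = score_pair(stats, scale_ref=1.0)
    if lc == 0:
        assert score.lift == 0.0
    else:
        assert score.lift == pytest.approx(1.0)  # independence boundary
    assert score.rs == 0.0


def test_rs_monotone_in_lift_at_fixed_scale_ref():
    scale_ref = math.log(50.0)
    rs_values = [
        score_pair(PairStats("A", "B", 10, 10, lc, 1000), scale_ref).rs
        for lc in range(0, 11)
    ]
    assert rs_values == sorted(rs_values)
    assert rs_values[-1] == pytest.approx(100.0)  # clipped at the top


def test_rs_invariant_under_doc_relabeling(toy_index):
    relabeled = make_index(
        {f"x{d}": set(cs) for d, cs in toy_index.by_doc.items()}
    )
    a = pair_stats(toy_index, "A", "B")
    b = pair_stats(relabeled, "A", "B")
    assert (a.lift, a.lc) == (b.lift, b.lc)


def naive_pair_scan(index):
    """Independent double loop over concepts x documents."""
    concepts = sorted(index.by_concept)
    out = {}
    for a, b in combinations(concepts, 2):
        c_a = c_b = lc = 0
        for docs in [index.by_doc]:
            for _, cs in docs.items():
                c_a += a in cs
                c_b += b in cs
                lc += a in cs and b in cs
        out[(a, b)] = (c_a, c_b, lc, index.N)
    return out


def test_counts_match_naive_double_loop_scan():
    config = GeneratorConfig(
        seed=3, n_genes=12, n_diseases=6, n_drugs=4, n_docs=250,
        background_rate=0.03,
        planted_pairs=(PlantedPair("G000", "D000", 0.05),),
    )
    thesaurus, corpus, _ = generate(config)
    index = tag_corpus(corpus, thesaurus)
    expected = naive_pair_scan(index)
    for (a, b), (c_a, c_b, lc, N) in expected.items():
        stats = pair_stats(index, a, b)
        assert (stats.c_a, stats.c_b, stats.lc, stats.N) == (c_a, c_b, lc, N)


def test_score_category_pairs_recovers_planted_pair_only():
    config = GeneratorConfig(
        seed=5, n_genes=10, n_diseases=5, n_drugs=0, n_docs=1500,
        background_rate=0.01,
        planted_pairs=(PlantedPair("G000", "D000", 0.02),),
    )
    thesaurus, corpus, _ = generate(config)
    index = tag_corpus(corpus, thesaurus)
    scores = score_category_pairs(
        index, "gene", "disease", AssociationThresholds(30.0, 5)
    )
    assert {(s.pair.concept_a, s.pair.concept_b) for s in scores} == {("D000", "G000")}


def test_raising_lc_min_never_enlarges_result(toy_index):
    def result(lc_min):
        return {
            (s.pair.concept_a, s.pair.concept_b)
            for s in score_category_pairs(
                toy_index, "gene", "gene", AssociationThresholds(0.0, lc_min)
            )
        }

    previous = result(0)
    for lc_min in range(1, 5):
        current = result(lc_min)
        assert current <= previous
        previous = current


def test_extreme_rs_threshold_returns_only_saturated_pairs(toy_index):
    scores = score_category_pairs(
        toy_index, "gene", "gene", AssociationThresholds(100.0, 0)
    )
    assert scores == []  # rs > 100 is unsatisfiable after clipping


def test_literature_neighbours_subset_ranking_and_errors(toy_index):
    thresholds = AssociationThresholds(0.0, 0)
    neighbours = literature_neighbours(toy_index, "A", "gene", thresholds)
    all_pairs = score_category_pairs(toy_index, "gene", "gene", thresholds)
    assert set(neighbours) <= set(all_pairs)
    rs_list = [s.rs for s in neighbours]
    assert rs_list == sorted(rs_list, reverse=True)
    with pytest.raises(ValidationError):
        literature_neighbours(toy_index, "ZZZ", "gene", thresholds)


def test_concept_without_comentions_has_no_neighbours():
    index = make_index({"d1": {"A"}, "d2": {"B"}})
    assert literature_neighbours(index, "A", "gene", AssociationThresholds(0.0, 0)) == []


def test_profile_matrix_placement_and_top_k(toy_index):
    from litnet.association import AssociationScore

    score = AssociationScore(
        pair=PairStats("D9", "G1", 3, 3, 2, 5), lift=2.0, rs=60.0
    )
    matrix = build_profile_matrix([score], ["G1", "G2"], ["D9", "D8"])
    assert matrix.frame.loc["G1", "D9"] == 60.0
    assert matrix.frame.to_numpy().sum() == 60.0
    top = matrix.top_k_columns(1)
    assert top.col_ids == ["D9"]
    with pytest.raises(ValidationError):
        build_profile_matrix([score], [], ["D9"])


def test_scores_tsv_written_with_reproducibility_header(tmp_path, toy_index):
    thresholds = AssociationThresholds(0.0, 0)
    scores = score_category_pairs(toy_index, "gene", "gene", thresholds)
    stats = [s.pair for s in scores]
    out = tmp_path / "scores.tsv"
    save_scores(scores, out, thresholds=thresholds,
                scale_ref=compute_scale_ref(stats, 0), corpus_hash="abc123")
    text = out.read_text()
    assert text.startswith("# scale_ref=")
    assert "corpus_hash=abc123" in text
    assert text.count("\n") == 4 + len(scores)  # 3 comment lines + header
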