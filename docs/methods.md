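# Methods

## Scope and model

`litnet` computes co-occurrence statistics over a corpus of titled
abstracts tagged with a controlled vocabulary. The underlying model is
deliberately plain: a document either mentions a concept or it does not
(presence, not frequency), and association between two concepts is measured
by how far their joint document count exceeds the independence expectation.
Everything downstream — networks, enrichment, clustering, neighbor scores —
is built from these per-pair counts. No direction, causality or
sentence-level structure is inferred.

## Tagging

A document is linked to a concept when any synonym occurs in the title or
abstract as a token-boundary, case-insensitive match. Titles and abstracts
are scanned jointly; the counting unit is the record. Matching is
exact-after-normalization (lowercase, trimmed, internal whitespace
collapsed; no stemming), and overlapping candidate matches are resolved
longest-match-first, so a two-word synonym consumes its span before any
nested one-word synonym can fire. Token boundaries are "not flanked by
[A-Za-z0-9]"; hyphens inside synonyms match literally. These rules trade
biological cleverness for full reproducibility: the same corpus and
thesaurus always produce the same mention index, and a naive per-document
scan reproduces it exactly (tested).

Ambiguous synonyms (one string claimed by several concepts) stay ambiguous:
all claiming concepts are linked. No disambiguation model is attempted.

## The R-scaled association score

For a pair with document counts `c_a`, `c_b`, joint count `lc` and corpus
size `N`:

    lift = lc·N / (c_a·c_b)
    rs   = 100 · ln(lift) / scale_ref,  clipped to [0, 100]
           (rs = 0 when lc = 0 or lift ≤ 1)

`scale_ref` is the maximum `ln(lift)` over the scoring run's pairs with
`lc ≥ lc_min`. **The rs formula is this package's construction.** The 0–100
score it mirrors descends from earlier co-publication mining systems whose
exact formula was never published; rescaled log-lift reproduces the
documented range, is monotone in association strength, and is fully
deterministic given a corpus — but it makes rs values comparable only
within a single scoring run, and numeric rs values here will not match any
historical system's output. Writers persist `scale_ref` (plus thresholds
and a corpus hash) in the TSV header so a run can be audited.

Thresholds are strict inequalities. Defaults: `rs > 30, lc > 5` for
gene–gene and gene–drug scoring, `rs > 35, lc > 5` for gene–disease
extraction. Units: rs is dimensionless on a 0–100 scale; lc is a document
count.

## Networks

The gene network has an edge wherever a gene pair passes the thresholds,
weighted by rs with lc kept as a secondary attribute. Isolated genes remain
nodes — the "k of n genes connected" report is part of the contract. Node
annotations store each gene's rs with a chosen keyword (a drug, a disease)
on the same 0–100 scale, computed within the gene × keyword-category run
restricted to the network's genes.

Topology statistics: hubs are nodes with degree above a cut-off (default
100, following the convention for large literature networks; synthetic
tests use smaller cut-offs scaled to their graphs). The power-law check
regresses log CCDF on log degree over degrees ≥ 1 and reports the slope,
its two-sided t-test p-value and R²; for a degree density ~ d^-α the CCDF
slope estimates −(α − 1). A maximum-likelihood α (continuous approximation,
`1 + n / Σ ln(d/(d_min − ½))`) is reported alongside as an alternative; the
regression form is the default because it matches how such fits are usually
presented for these networks. Betweenness is unweighted shortest-path
betweenness, normalized by pair count — edge rs measures literature
support, not traversal cost, so hop counts are the right metric.

## Enrichment

A keyword is "linked" to a gene when the pair passes the thresholds. The
background is the set of thesaurus genes with at least one mention (a gene
absent from the corpus cannot be drawn into any query). The p-value is the
one-sided hypergeometric tail P(X ≥ k). Results are filtered on the raw
p-value at `alpha` (default 0.05) because that is the convention the
pipeline's outputs follow, but Benjamini–Hochberg q-values over all tested
keywords are always emitted so FDR control costs nothing.

## Disease clustering and bootstrap support

Disease profiles are the columns of the gene × disease rs matrix
(thresholded entries; zero where a pair failed). Distance is `1 − Pearson`
between columns; a constant column has no defined correlation and is
rejected by name. Agglomeration is complete linkage with deterministic
tie-breaking (smallest member id lexicographically), implemented directly
— about forty lines — because standard library implementations leave
tie-breaking unspecified and replicate-counting needs bit-reproducible
trees; scipy's complete linkage serves as a cross-check on tie-free inputs
in the tests.

Support values resample the **genes** (rows) with replacement — the
profiles being compared are profiles over genes. For each scale
r ∈ {0.5, 0.6, …, 1.4} and B replicates (default 100), BP_r(cluster) is the
fraction of replicate trees containing the cluster as an exact leaf set.
The AU value extrapolates across scales through the probit fit

    Φ⁻¹(1 − BP_r) ≈ v·√r + c/√r      (weighted least squares,
                                      weights B·φ(z)²/(BP(1−BP)))
    AU = 100 · (1 − Φ(v − c));  BP is reported at r = 1.

Degenerate scales — BP_r of exactly 0 or 1 — carry no information about
(v, c) and are dropped before the fit; if fewer than three informative
scales remain, AU saturates to 100 when the mean BP is ≥ 0.5 and to 0
otherwise. This is the standard treatment in multiscale-bootstrap software
and is what makes a cluster present in every replicate at every scale come
out at AU = 100 rather than at the ≈58 a naive fit of the clipped constant
would give. Remaining proportions are clipped to [1/(2B), 1 − 1/(2B)] as a
numerical guard. A cluster never observed at any scale is reported AU = 0
with a flag. One caveat worth knowing: when BP is flat across scales the
fit has no multiscale signal and AU lands between 50 and BP (on BP's side
of 50) — exactly 50 when BP = 0.5 — rather than at BP itself.

Within bootstrap replicates a resampled column can become constant; its
correlations are then set to 0 (distance 1), expressing that a degenerate
profile supports no particular grouping. Trees are exported as Newick with
branch lengths equal to merge-height differences and internal labels
"AU/BP".

## Neighbor-weighted literature score

    literature_score(g) = (g1 + Ns)/2,   Ns = Σ rgᵢ·gᵢ / Σ rgᵢ

with g1 the gene's direct rs with the term and (gᵢ, rgᵢ) the neighbors'
term scores and edge weights. Ns is a weighted mean, so the score is
bounded by the convex hull of its inputs and stays in [0, 100]; scaling all
edge weights by a constant leaves it unchanged. Two resolved ambiguities:
(1) the displayed form of the source equation is typeset ambiguously and is
read as (g1 + Ns)/2, the only reading that keeps scores in range; (2) a
gene with no neighbors keeps its direct score unchanged — halving a lone
direct score would penalize isolated genes for missing data, contradicting
the score's purpose of *adding* neighborhood evidence. Only direct
neighbors contribute; there is no recursion or diffusion.

Candidate selection takes two annotated terms and returns genes above `hi`
on one and below `lo` on the other (defaults 25/25), in either "direct" or
"literature_score" mode. Both modes are exposed because the interesting
phenomenon is their disagreement: genes selected on direct scores but
excluded once neighbors are blended in, and vice versa.

## Synthetic corpus generator

Real abstract corpora and curated thesauri cannot ship with the package, so
the generator is first-class, tested code that emulates the substrate:
every document mentions each concept independently at a background rate;
each planted pair (gene, keyword, q) additionally co-mentions both members
with probability q; disease blocks share planted gene sets (correlated
profiles); a hub gene gets many planted gene partners. Mentions are
injected as literal synonym strings inside template sentences built from a
fixed filler word list disjoint from all synonyms — truth flows through
text, so the tagger is exercised, never bypassed. Generation is
deterministic given the seed, byte-identical across runs.

The model admits closed forms: with background b and planted events
touching a concept, P(miss x) = (1−b)·Π(1−qᵢ), and for a pair
P(both) = 1 − P(miss a) − P(miss b) + P(miss a)·P(miss b)·(shared-event
correction), giving `expected_pair_lift` and `expected_pair_joint_docs`,
verified against direct Monte-Carlo simulation of the mention model. A
consequence worth stating: a planted event inflates *both marginals*, so
expected lift is not monotone in q — it peaks near the background rate and
decays like 1/q beyond it, and concepts carrying many planted pairs have
deflated per-pair lifts. This shapes the default scenario.

**Default study conditions** (`default_scenario`): 200 concepts (100
genes, 60 diseases, 40 drugs), 2,000 documents, background rate 0.01 —
each concept in ~20 documents, each document mentioning ~2 concepts.
Planted structure separates roles so each component sits in its intended
regime:

* six high-lift keywords, each with 4 dedicated genes at excess 0.012
  (expected lift ≈ 10, expected joint count ≈ 25): the material for
  recovery statistics at the rs > 30, lc > 5 working point (sensitivity
  and specificity are measured over these pairs, per the detectability
  condition expected lift ≥ 8 and expected lc ≥ 15);
* a demo neighborhood (seed disease, drug of interest, confounder disease,
  a 4-gene clique and bridge edges) at expected lifts ≈ 2.3–6, enough to
  pass thresholds most of the time and to exhibit the neighbor-score
  migration effect, but deliberately entangled and hence not part of the
  recovery denominator;
* a hub with 12 dedicated partners;
* two 3-disease blocks each sharing 12 genes at excess 0.0075 — wide,
  low-excess blocks keep disease marginals (and per-pair lift ≈ 3.2, rs
  comfortably above the 35 profile cut) at the level of a 6-gene block
  while doubling the rows the profile bootstrap can resample, which is
  what makes block AU values stable.

What the generator does **not** emulate: natural language (no synonymy
beyond the thesaurus, no negation, no abbreviations), publication-date
structure, citation topology, realistic degree distributions (the planted
network is clique + star, not scale-free; the power-law machinery is
therefore validated on directly sampled zipf degrees), and realistic
marginal heterogeneity (all background concepts are exchangeable). Passing
tests show the pipeline recovers known structure through the full
text-to-score path under this model; they do not certify performance on
real Medline text.

Problem sizes in the test-bed (chosen as the smallest at which the
statistics of interest are stable): 20 generator seeds for recovery and
topology statistics, 100 seeds (40 genes, 800 documents) for the
enrichment rank statistic, 20 seeds of a 30-gene two-block profile matrix
(within-block correlation 0.9) with B = 100 bootstrap replicates for
clustering support, 1,000 random instances for the neighbor-score oracle,
and brute-force cross-checks on graphs up to 30 nodes.

## Known limitations

* rs is run-relative; scores from different runs (or different corpora)
  are not comparable without the persisted `scale_ref`.
* Ambiguous synonyms inflate counts for all claiming concepts; on real
  text this overcounts (the generator's vocabulary is collision-free by
  construction).
* The hypergeometric null treats gene–keyword links as exchangeable draws;
  highly co-mentioned gene families violate this independence.
* AU values inherit the usual multiscale-bootstrap caveats: with few
  informative scales the saturation rule is a step function, and flat BP
  profiles give AU pulled toward 50, not AU = BP.
* Single/average linkage and the MLE power-law exponent are exposed behind
  flags but are secondary, lightly exercised surfaces.
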