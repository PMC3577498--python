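# litnet

Literature co-occurrence mining for disease-related gene networks.

Abstract databases hold decades of evidence connecting genes to diseases and
drugs, but the evidence is scattered over millions of titled abstracts.
`litnet` turns a concept thesaurus (genes, diseases, drugs, pathways) and a
corpus of abstracts into quantitative association networks: it tags every
abstract with the concepts it mentions, scores concept pairs by how much
their co-mention exceeds chance, links genes into an rs-weighted literature
network, tests gene sets for drug/disease keyword over-representation,
clusters disease profiles with multiscale-bootstrap support, and ranks genes
by a neighbor-weighted literature score to nominate biomarker candidates —
for example, genes strongly tied to a glucocorticoid such as dexamethasone
but only weakly (directly *or through their network neighbors*) to
inflammation.

It is written for computational biologists who want the whole pipeline as a
library plus a thin CLI, with every stage testable against synthetic corpora
carrying planted ground truth.

## The statistics at the core

**Association score.** For concepts *a*, *b* mentioned in `c_a`, `c_b` of
*N* abstracts and jointly in `lc`, the lift is

```
lift = lc · N / (c_a · c_b)
```

and the R-scaled score rescales log-lift onto 0–100 within a scoring run:

```
rs = 100 · ln(lift) / max-run-log-lift      (clipped to [0, 100]; 0 if lift ≤ 1)
```

Pairs pass when `rs > rs_min` and `lc > lc_min` (defaults 30 and 5;
gene–disease extraction uses 35 and 5). The rescaled log-lift form of rs is
this package's own construction (see `docs/methods.md`): it reproduces the
documented 0–100 range and is monotone in association strength, but rs
values are comparable within one run only.

**Enrichment.** A keyword linked to *K* of *N_bg* background genes and *k*
of a query of *n* genes gets the one-sided hypergeometric tail
P(X ≥ k); Benjamini–Hochberg q-values are reported alongside the raw
p-values.

**Disease clustering.** Disease profiles (columns of the gene × disease rs
matrix) are clustered by complete linkage on correlation distance
`1 − r`. Cluster confidence comes from multiscale bootstrap over genes:
BP_r is the fraction of replicates (at resampling ratio r) containing the
cluster, and the approximately unbiased value is obtained from the probit
fit `Φ⁻¹(1 − BP_r) ≈ v√r + c/√r` as `AU = 1 − Φ(v − c)`.

**Neighbor-weighted literature score.** For gene *g* and term *d* with
direct score `g1`, neighbors scoring `g2..gn` with *d* and edge weights
`rg2..rgn`:

```
literature_score(g) = (g1 + Ns) / 2,   Ns = Σ rgᵢ·gᵢ / Σ rgᵢ
```

so a gene that looks clean on a confounder can be re-flagged through its
neighborhood, and vice versa.

## Worked example

Real corpora are not redistributable, so the example runs on the bundled
synthetic-corpus generator, whose planted structure plays the role of the
ground truth (`D000` = seed disease, `R000` = drug of interest, `D001` =
confounder disease):

```python
import litnet as ln

config = ln.default_scenario(seed=7)
thesaurus, corpus, truth = ln.generate(config)
index = ln.tag_corpus(corpus, thesaurus)

thresholds = ln.AssociationThresholds(rs_min=30.0, lc_min=5)
partners = ln.literature_neighbours(index, "D000", "gene", thresholds)
genes = sorted({s.pair.concept_a if s.pair.concept_a.startswith("G")
                else s.pair.concept_b for s in partners})
network = ln.build_network(genes, index, thresholds)
results = ln.enrich(genes, index, "drug", thresholds, alpha=0.05)

ln.annotate_nodes(network, index, "R000", "drug_of_interest", thresholds)
ln.annotate_nodes(network, index, "D001", "confounder", thresholds)
dex = ln.score_genes_for_term(network, "drug_of_interest")
infl = ln.score_genes_for_term(network, "confounder")
direct = ln.select_candidates(dex, infl, 25, 25, use="direct")
weighted = ln.select_candidates(dex, infl, 25, 25, use="literature_score")
```

Output:

```
corpus: 2000 abstracts, 200 tagged concepts
genes associated with disease D000: 7
  G007  rs=43.9  lc=31
  G005  rs=43.5  lc=34
  G006  rs=43.1  lc=33
network: 7 genes, 3 edges, 5 connected
enriched drug R000: k=2/7, K=5/100, p=3.82e-02, q=2.45e-01
candidates (direct scores): ['G004', 'G005']
candidates (neighbor-weighted): ['G003']
  G004: direct confounder rs=0.0 but neighbor-weighted 34.6 -> excluded
  G005: direct confounder rs=0.0 but neighbor-weighted 32.7 -> excluded
```

Reading the numbers: seven genes pass the rs > 30, lc > 5 cut with the seed
disease; the planted drug of interest R000 is the enriched drug keyword
(p = 0.038 < 0.05); G004 and G005 look like clean drug-specific candidates
on their *direct* scores (confounder rs = 0), but both sit next to
confounder-linked genes in the network, their neighbor-weighted confounder
scores rise above the 25 cut-off, and they are excluded — the migration
effect the neighbor score exists to expose.

The same pipeline is available as a CLI:

```
litnet simulate --seed 7 --out-dir run/
litnet tag --thesaurus run/thesaurus.tsv --corpus run/corpus.jsonl --out-dir run/
litnet associations --index-dir run/ --cat-a gene --cat-b disease --out run/scores.tsv
litnet selftest --seed 7
```

`litnet selftest` runs the whole chain (simulate → tag → associations →
network → enrich → cluster → score) against the planted truth and reports
PASS/FAIL per stage.

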