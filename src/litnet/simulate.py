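"""Synthetic thesauri and corpora with planted, known structure.

Real abstract corpora and curated thesauri are not redistributable, so
every pipeline stage is exercised against generated data with planted
ground truth instead: documents mention each concept independently at a
background rate, selected gene–keyword pairs receive an excess joint
mention probability, groups of diseases share planted gene partners
(inducing correlated disease profiles), and one gene can be planted as a
hub with many gene partners.

Mentions are injected as literal synonym strings embedded in template
sentences, so the truth flows through text and the *tagger* is exercised,
not bypassed.  Filler vocabulary is a fixed word list disjoint from all
generated synonyms; no natural-language realism is claimed.

The generative model per document: concept x is mentioned with background
probability b independently; each planted pair (a, b*, q) additionally
mentions both members with probability q, independently of everything
else.  Closed-form mention and co-mention probabilities (and hence the
expected lift of any pair) follow from independence; see
:func:`expected_pair_lift`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .association import ProfileMatrix
from .corpus import Corpus, Document
from .errors import ValidationError
from .thesaurus import Concept, Thesaurus

_FILLERS = (
    "patients cohort analysis treatment observed levels response clinical "
    "serum plasma baseline outcome measured elevated reduced signaling "
    "expression receptor activity metabolic chronic acute tissue muscle "
    "liver subjects randomized placebo therapy dose followup biomarker"
).split()


@dataclass(frozen=True)
class PlantedPair:
    """A gene–keyword pair with excess joint mention probability."""

    gene: str
    keyword: str
    excess: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.excess <= 1.0:
            raise ValidationError("excess must lie in [0, 1]")


@dataclass(frozen=True)
class DiseaseBlock:
    """Diseases sharing the same planted gene partners (correlated profiles)."""

    diseases: tuple[str, ...]
    genes: tuple[str, ...]
    excess: float


@dataclass(frozen=True)
class PlantedHub:
    """A gene planted with many gene partners (elevated degree)."""

    gene: str
    partners: tuple[str, ...]
    excess: float


@dataclass(frozen=True)
class GeneratorConfig:
    seed: int
    n_genes: int = 100
    n_diseases: int = 60
    n_drugs: int = 40
    n_docs: int = 2000
    background_rate: float = 0.01
    planted_pairs: tuple[PlantedPair, ...] = ()
    planted_blocks: tuple[DiseaseBlock, ...] = ()
    planted_hub: PlantedHub | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.background_rate <= 1.0:
            raise ValidationError("background_rate must lie in [0, 1]")
        known = set(self.all_ids())
        for pair in self.expanded_pairs():
            if pair.gene not in known or pair.keyword not in known:
                raise ValidationError(
                    f"planted pair ({pair.gene}, {pair.keyword}) outside vocabulary"
                )

    def gene_ids(self) -> list[str]:
        return [f"G{i:03d}" for i in range(self.n_genes)]

    def disease_ids(self) -> list[str]:
        return [f"D{i:03d}" for i in range(self.n_diseases)]

    def drug_ids(self) -> list[str]:
        return [f"R{i:03d}" for i in range(self.n_drugs)]

    def all_ids(self) -> list[str]:
        return self.gene_ids() + self.disease_ids() + self.drug_ids()

    def expanded_pairs(self) -> list[PlantedPair]:
        """All planted pairs: direct ones plus block and hub expansions."""
        pairs = list(self.planted_pairs)
        for block in self.planted_blocks:
            for disease in block.diseases:
                for gene in block.genes:
                    pairs.append(PlantedPair(gene, disease, block.excess))
        if self.planted_hub is not None:
            hub = self.planted_hub
            for partner in hub.partners:
                pairs.append(PlantedPair(hub.gene, partner, hub.excess))
        return pairs


@dataclass(frozen=True)
class PlantedTruth:
    """Ground truth emitted beside a generated corpus."""

    pairs: frozenset[tuple[str, str]]       # canonically ordered planted pairs
    blocks: tuple[tuple[str, ...], ...]     # disease ids per block
    hub: str | None
    hub_partners: tuple[str, ...]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "pairs": sorted(list(p) for p in self.pairs),
            "blocks": [list(b) for b in self.blocks],
            "hub": self.hub,
            "hub_partners": list(self.hub_partners),
        }
        Path(path).write_text(json.dumps(payload, indent=1), encoding="utf-8")

    @classmethod
    def from_json(cls, path: str | Path) -> "PlantedTruth":
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(
            pairs=frozenset(tuple(p) for p in payload["pairs"]),
            blocks=tuple(tuple(b) for b in payload["blocks"]),
            hub=payload["hub"],
            hub_partners=tuple(payload["hub_partners"]),
        )


def _build_thesaurus(config: GeneratorConfig) -> Thesaurus:
    """Collision-free synthetic vocabulary with multiword synonyms."""
    concepts = []
    for cid in config.gene_ids():
        token = cid.lower()
        concepts.append(
            Concept(cid, "gene", cid, frozenset({cid, f"gene product {token}"}))
        )
    for cid in config.disease_ids():
        token = cid.lower()
        concepts.append(
            Concept(cid, "disease", cid, frozenset({cid, f"{token} syndrome"}))
        )
    for cid in config.drug_ids():
        token = cid.lower()
        concepts.append(
            Concept(cid, "drug", cid, frozenset({cid, f"compound {token}"}))
        )
    return Thesaurus(concepts)


def generate(config: GeneratorConfig) -> tuple[Thesaurus, Corpus, PlantedTruth]:
    """Generate (thesaurus, corpus, truth); byte-identical for equal seeds."""
    rng = np.random.default_rng(config.seed)
    thesaurus = _build_thesaurus(config)
    ids = config.all_ids()
    col = {cid: i for i, cid in enumerate(ids)}

    mentions = rng.random((config.n_docs, len(ids))) < config.background_rate
    for pair in config.expanded_pairs():
        hit = rng.random(config.n_docs) < pair.excess
        mentions[hit, col[pair.gene]] = True
        mentions[hit, col[pair.keyword]] = True

    synonym_lists = {
        cid: sorted(thesaurus[cid].synonyms) for cid in ids
    }
    documents = []
    for j in range(config.n_docs):
        present = [ids[i] for i in np.flatnonzero(mentions[j])]
        order = rng.permutation(len(present))
        phrases = []
        for k in order:
            syns = synonym_lists[present[k]]
            phrases.append(syns[rng.integers(0, len(syns))])
        filler = [
            _FILLERS[rng.integers(0, len(_FILLERS))] for _ in range(6)
        ]
        if phrases:
            title = f"A study of {phrases[0]} in {filler[0]} {filler[1]}"
            sentences = [
                f"We measured {phrase} in {filler[2 + i % 4]} samples."
                for i, phrase in enumerate(phrases[1:])
            ]
            sentences.append(f"The {filler[2]} {filler[3]} remained {filler[4]}.")
        else:
            title = f"Observations on {filler[0]} {filler[1]} in a cohort"
            sentences = [f"No {filler[2]} change in {filler[3]} was {filler[4]}."]
        documents.append(
            Document(
                doc_id=f"{10_000_000 + j}",
                title=title,
                abstract=" ".join(sentences),
                year=2000 + int(rng.integers(0, 20)),
            )
        )

    truth = PlantedTruth(
        pairs=frozenset(
            tuple(sorted((p.gene, p.keyword))) for p in config.expanded_pairs()
        ),
        blocks=tuple(b.diseases for b in config.planted_blocks),
        hub=config.planted_hub.gene if config.planted_hub else None,
        hub_partners=(
            config.planted_hub.partners if config.planted_hub else ()
        ),
    )
    return thesaurus, Corpus(documents), truth


def mention_probability(config: GeneratorConfig, concept_id: str) -> float:
    """Marginal per-document mention probability under the model."""
    miss = 1.0 - config.background_rate
    for pair in config.expanded_pairs():
        if concept_id in (pair.gene, pair.keyword):
            miss *= 1.0 - pair.excess
    return 1.0 - miss


def _pair_probabilities(
    config: GeneratorConfig, a: str, b: str
) -> tuple[float, float, float]:
    """(P(a), P(b), P(a and b)) per document under the generative model."""
    b0 = config.background_rate
    miss_a = miss_b = 1.0 - b0
    miss_joint = (1.0 - b0) ** 2
    for pair in config.expanded_pairs():
        touches_a = a in (pair.gene, pair.keyword)
        touches_b = b in (pair.gene, pair.keyword)
        if touches_a:
            miss_a *= 1.0 - pair.excess
        if touches_b:
            miss_b *= 1.0 - pair.excess
        if touches_a or touches_b:
            miss_joint *= 1.0 - pair.excess
    return 1.0 - miss_a, 1.0 - miss_b, 1.0 - miss_a - miss_b + miss_joint


def expected_pair_joint_docs(config: GeneratorConfig, a: str, b: str) -> float:
    """Expected number of documents mentioning both members of a pair."""
    return config.n_docs * _pair_probabilities(config, a, b)[2]


def expected_pair_lift(config: GeneratorConfig, a: str, b: str) -> float:
    """Closed-form expected lift of a pair under the generative model.

    With background rate b0 and planted events touching a and/or b,

        P(not x)        = (1 - b0) * prod over pairs touching x of (1 - q)
        P(not a, not b) = (1 - b0)^2 * prod over pairs touching a or b (1 - q)
        P(a and b)      = 1 - P(not a) - P(not b) + P(not a, not b)

    and lift = P(a and b) / (P(a) * P(b)).  A pair with no planted event
    has lift exactly 1 (independence); lift is monotone in any planted
    excess on the pair.
    """
    if a == b:
        raise ValidationError("self-pairs are undefined")
    p_a, p_b, p_joint = _pair_probabilities(config, a, b)
    if p_a == 0.0 or p_b == 0.0:
        return 0.0
    return p_joint / (p_a * p_b)


def default_scenario(seed: int) -> GeneratorConfig:
    """The standard study conditions used throughout the test-bed.

    200 concepts (100 genes, 60 diseases, 40 drugs), 2,000 documents,
    background rate 0.01.  A planted event raises the marginal mention
    probability of both its members, so concepts carrying many planted
    pairs have deflated per-pair lifts; the scenario therefore separates
    roles:

    * a *demo* neighborhood for candidate selection: seed disease D000
      (genes G000-G007), drug of interest R000 (G000, G001, G004, G005),
      confounder disease D001 (G002, G003, G006, G007), a planted 4-gene
      clique G000-G003 and bridges G004-G002/G006, G005-G003/G007 so that
      directly-clean genes acquire confounder evidence through neighbors;
    * six *high-lift* keywords (D020-D022, R010-R012), each linked to 4
      dedicated genes nothing else touches — expected lift ≈ 10 and
      expected joint count ≈ 25, the working material for recovery
      statistics;
    * a hub gene G010 with 12 otherwise-untouched gene partners;
    * two 3-disease blocks (D030-D032, D033-D035) each sharing a 12-gene
      set, giving correlated disease profiles for clustering.  Wide
      low-excess blocks keep the disease marginals (and hence per-pair
      lifts) at the level of a 6-gene block while doubling the informative
      rows the profile bootstrap can resample.

    Planted excesses: 0.012 (0.0075 for the blocks).  Background pairs sit
    at lift 1.
    """
    genes = [f"G{i:03d}" for i in range(100)]
    q = 0.012
    pairs: list[PlantedPair] = []
    # Demo neighborhood.
    pairs += [PlantedPair(g, "D000", q) for g in genes[0:8]]
    pairs += [PlantedPair(g, "R000", q) for g in (genes[0], genes[1], genes[4], genes[5])]
    pairs += [PlantedPair(g, "D001", q) for g in (genes[2], genes[3], genes[6], genes[7])]
    clique = genes[0:4]
    pairs += [
        PlantedPair(clique[i], clique[j], q)
        for i in range(4)
        for j in range(i + 1, 4)
    ]
    pairs += [
        PlantedPair("G004", "G002", q),
        PlantedPair("G004", "G006", q),
        PlantedPair("G005", "G003", q),
        PlantedPair("G005", "G007", q),
    ]
    # High-lift keywords on dedicated genes G040..G063.
    for k, keyword in enumerate(["D020", "D021", "D022", "R010", "R011", "R012"]):
        for g in genes[40 + 4 * k : 44 + 4 * k]:
            pairs.append(PlantedPair(g, keyword, q))
    return GeneratorConfig(
        seed=seed,
        planted_pairs=tuple(pairs),
        planted_blocks=(
            DiseaseBlock(("D030", "D031", "D032"), tuple(genes[70:82]), 0.0075),
            DiseaseBlock(("D033", "D034", "D035"), tuple(genes[84:96]), 0.0075),
        ),
        planted_hub=PlantedHub("G010", tuple(genes[11:23]), q),
    )


def planted_cross_pairs(config: GeneratorConfig) -> frozenset[tuple[str, str]]:
    """Planted gene–disease and gene–drug pairs, canonically ordered."""
    gene_ids = set(config.gene_ids())
    out = set()
    for pair in config.expanded_pairs():
        in_genes = (pair.gene in gene_ids, pair.keyword in gene_ids)
        if in_genes.count(True) == 1:
            out.add(tuple(sorted((pair.gene, pair.keyword))))
    return frozenset(out)


def qualifying_cross_pairs(
    config: GeneratorConfig,
    min_lift: float = 8.0,
    min_expected_lc: float = 15.0,
) -> frozenset[tuple[str, str]]:
    """Planted cross pairs in the detectable regime.

    Recovery guarantees apply to planted pairs whose model-expected lift
    and joint document count clear the stated floors; auxiliary planted
    structure (demo neighborhoods, disease blocks) couples concepts more
    weakly and is assessed by its own recovery statistics, not here.
    """
    return frozenset(
        pair
        for pair in planted_cross_pairs(config)
        if expected_pair_lift(config, *pair) >= min_lift
        and expected_pair_joint_docs(config, *pair) >= min_expected_lc
    )


def planted_profile_matrix(
    n_genes: int,
    block_sizes: Sequence[int],
    within_correlation: float,
    seed: int,
    scale: float = 12.0,
    center: float = 50.0,
) -> tuple[ProfileMatrix, list[list[str]]]:
    """Profile matrix with disease blocks of known within-block correlation.

    Each block shares a latent gene factor: column = sqrt(rho)*factor +
    sqrt(1-rho)*noise, so within-block correlation targets ``rho`` and
    between-block correlation 0.  Values are mapped to an rs-like scale
    (center ± scale, clipped to [0, 100]).  Returns the matrix and the
    disease-id blocks.
    """
    if not 0.0 <= within_correlation <= 1.0:
        raise ValidationError("within_correlation must lie in [0, 1]")
    import pandas as pd

    rng = np.random.default_rng(seed)
    columns: dict[str, np.ndarray] = {}
    blocks: list[list[str]] = []
    d = 0
    for b, size in enumerate(block_sizes):
        factor = rng.standard_normal(n_genes)
        block_ids = []
        for _ in range(size):
            noise = rng.standard_normal(n_genes)
            z = (
                np.sqrt(within_correlation) * factor
                + np.sqrt(1.0 - within_correlation) * noise
            )
            cid = f"D{d:03d}"
            columns[cid] = np.clip(center + scale * z, 0.0, 100.0)
            block_ids.append(cid)
            d += 1
        blocks.append(block_ids)
    frame = pd.DataFrame(columns, index=[f"G{i:03d}" for i in range(n_genes)])
    return ProfileMatrix(frame), blocks
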