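import pytest

from litnet.corpus import Corpus, Document
from litnet.tagger import tag_corpus
from litnet.thesaurus import Concept, Thesaurus


@pytest.fixture
def tiny_thesaurus() -> Thesaurus:
    """Four concepts incl. an overlapping synonym pair and an ambiguity."""
    return Thesaurus(
        [
            Concept("G1", "gene", "PCK2", frozenset({"PCK2", "PEPCK-M"})),
            Concept("G2", "gene", "insulin receptor", frozenset({"insulin receptor", "INSR"})),
            Concept("D1", "disease", "insulin resistance", frozenset({"insulin resistance"})),
            Concept("R1", "drug", "dexamethasone", frozenset({"dexamethasone", "DEX"})),
            Concept("R2", "drug", "insulin", frozenset({"insulin"})),
        ]
    )


@pytest.fixture
def tiny_corpus() -> Corpus:
    return Corpus(
        [
            Document("d1", "PCK2 is induced by dexamethasone", "pck2 responds. PCK2 again."),
            Document("d2", "Insulin receptor substrate studies", "insulin resistance in muscle"),
            Document("d3", "A title only document", ""),
            Document("d4", "insulin signalling", "dexamethasone and insulin resistance"),
            Document("d5", "Unrelated work", "nothing relevant here"),
        ]
    )


@pytest.fixture
def tiny_index(tiny_corpus, tiny_thesaurus):
    return tag_corpus(tiny_corpus, tiny_thesaurus)
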