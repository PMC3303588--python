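import numpy as np
import pytest

from gcpnet import (
    CorpusSpec,
    NetworkSpec,
    OccurrenceCorpus,
    Thesaurus,
    ThesaurusEntry,
    simulate_corpus,
    simulate_network,
)
from gcpnet.cohesion import ProfileSet
from gcpnet.profiles import ConceptProfile


@pytest.fixture(scope="session")
def small_corpus_spec():
    """Scaled-down corpus for fast unit tests (same structure as default)."""
    return CorpusSpec(n_documents=2100, n_genes=100, pool_size=10, seed=11)


@pytest.fixture(scope="session")
def small_sim(small_corpus_spec):
    return simulate_corpus(small_corpus_spec)


@pytest.fixture(scope="session")
def small_network_sim():
    return simulate_network(NetworkSpec(seed=5))


@pytest.fixture
def tiny_corpus():
    """Hand-built corpus: 4 documents, 1 disease, 3 genes."""
    pairs = {
        ("doc1", "DIS"), ("doc1", "G1"),
        ("doc2", "DIS"), ("doc2", "G1"), ("doc2", "G2"),
        ("doc3", "G2"), ("doc3", "G3"),
        ("doc4", "G3"),
    }
    return OccurrenceCorpus(pairs)


@pytest.fixture
def tiny_thesaurus():
    return Thesaurus(
        [
            ThesaurusEntry("DIS", "lupus", "disease", ("SLE",)),
            ThesaurusEntry("G1", "gene one", "gene", ("g1a", "g1b")),
            ThesaurusEntry("G2", "gene two", "gene"),
            ThesaurusEntry("G3", "gene three", "gene", ("shared-name",)),
            ThesaurusEntry("G4", "gene four", "gene", ("shared-name",)),
        ]
    )


def make_profile(concept_id, weights):
    """Normalised profile from a gene -> raw-weight mapping."""
    return ConceptProfile(concept_id, dict(weights)).normalize()


def random_profile_set(n_profiles, n_genes, rng):
    """Random non-negative normalised profiles over a shared vocabulary."""
    genes = [f"g{i}" for i in range(n_genes)]
    profiles = []
    for i in range(n_profiles):
        w = rng.random(n_genes) * (rng.random(n_genes) < 0.7)
        if not w.any():
            w[rng.integers(n_genes)] = 1.0
        profiles.append(make_profile(f"c{i}", dict(zip(genes, w))))
    return ProfileSet(profiles)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
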