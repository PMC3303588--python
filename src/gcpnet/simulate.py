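"""Synthetic corpora and interaction networks with planted structure.

Every stage of the pipeline is testable without external downloads:

* :func:`simulate_corpus` emits a MedLine-like occurrence corpus in which
  each document mentions exactly one disease concept and a random set of
  gene concepts.  Planted disease pairs share a pool of genes that are
  co-mentioned at an elevated rate in their documents, so those pairs carry
  a genuine literature signal for the cohesion score to detect; all other
  gene mentions occur at a background rate.

* :func:`simulate_network` emits a referenced edge list: an Erdos-Renyi
  background in which every edge carries its own reference, planted
  intermediate nodes wired to several seed genes, and "high-throughput" hub
  references that each support many edges and must be purged by the
  reference filter.

Both generators are bit-reproducible for a given seed and return their
ground truth alongside the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .corpus import OccurrenceCorpus, Thesaurus, ThesaurusEntry
from .network import ReferencedEdge

DEFAULT_PLANTED_PAIRS = (("D1", "D2"), ("D3", "D4"), ("D5", "D6"))


@dataclass
class CorpusSpec:
    """Parameters of the synthetic literature corpus.

    Defaults model a seven-disease study with three planted disease pairs,
    each pair sharing a 20-gene pool co-mentioned at 5% per pair document
    against a 0.5% background mention rate, over 20,000 documents and a
    500-gene vocabulary.
    """

    n_diseases: int = 7
    n_genes: int = 500
    n_documents: int = 20000
    planted_pairs: tuple[tuple[str, str], ...] = DEFAULT_PLANTED_PAIRS
    pool_size: int = 20
    p_comention_shared: float = 0.05
    p_comention_background: float = 0.005
    seed: int = 17

    def validate(self) -> None:
        if self.n_diseases < 1 or self.n_genes < 1 or self.n_documents < 1:
            raise ValueError("corpus dimensions must be positive")
        for p in (self.p_comention_shared, self.p_comention_background):
            if not 0.0 <= p <= 1.0:
                raise ValueError("mention probabilities must lie in [0, 1]")
        if self.p_comention_shared < self.p_comention_background:
            raise ValueError("p_comention_shared must be >= p_comention_background")
        names = [d for pair in self.planted_pairs for d in pair]
        if len(names) != len(set(names)):
            raise ValueError("planted pairs must be disjoint")
        diseases = set(self.disease_ids)
        if not set(names) <= diseases:
            raise ValueError("planted pairs must reference declared diseases")
        if len(self.planted_pairs) * self.pool_size > self.n_genes:
            raise ValueError("shared gene pools exceed the gene vocabulary")

    @property
    def disease_ids(self) -> list[str]:
        return [f"D{i + 1}" for i in range(self.n_diseases)]

    @property
    def gene_ids(self) -> list[str]:
        width = len(str(self.n_genes))
        return [f"G{i + 1:0{width}d}" for i in range(self.n_genes)]


@dataclass
class CorpusGroundTruth:
    planted_pairs: list[tuple[str, str]]
    shared_pools: dict[str, list[str]]  # "D1+D2" -> pool gene ids
    spec: CorpusSpec

    def to_yaml(self, path: str | Path) -> None:
        payload = {
            "planted_pairs": [list(p) for p in self.planted_pairs],
            "shared_pools": {k: list(v) for k, v in self.shared_pools.items()},
            "spec": {
                "n_diseases": self.spec.n_diseases,
                "n_genes": self.spec.n_genes,
                "n_documents": self.spec.n_documents,
                "pool_size": self.spec.pool_size,
                "p_comention_shared": self.spec.p_comention_shared,
                "p_comention_background": self.spec.p_comention_background,
                "seed": self.spec.seed,
            },
        }
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))


@dataclass
class SimulatedCorpus:
    corpus: OccurrenceCorpus
    thesaurus: Thesaurus
    truth: CorpusGroundTruth


def make_thesaurus(spec: CorpusSpec) -> Thesaurus:
    """Thesaurus over the synthetic disease and gene concepts."""
    entries = [
        ThesaurusEntry(d, f"disease {d[1:]}", "disease", (f"syndrome {d[1:]}",))
        for d in spec.disease_ids
    ]
    entries += [ThesaurusEntry(g, f"gene {g[1:]}", "gene") for g in spec.gene_ids]
    return Thesaurus(entries)


def simulate_corpus(spec: CorpusSpec | None = None) -> SimulatedCorpus:
    """Generate an occurrence corpus with planted disease-pair structure.

    Documents are assigned one disease each (round-robin, so every disease
    receives an equal share).  For a document of a paired disease, each gene
    of the pair's shared pool is mentioned with probability
    ``p_comention_shared`` and every other gene with
    ``p_comention_background``; documents of unpaired diseases use the
    background rate throughout.
    """
    spec = spec or CorpusSpec()
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    diseases = spec.disease_ids
    genes = np.array(spec.gene_ids)

    pools: dict[str, list[str]] = {}
    pool_of_disease: dict[str, np.ndarray] = {}
    pool_genes = rng.permutation(spec.n_genes)
    for i, (d1, d2) in enumerate(spec.planted_pairs):
        idx = np.sort(pool_genes[i * spec.pool_size:(i + 1) * spec.pool_size])
        pools[f"{d1}+{d2}"] = [str(g) for g in genes[idx]]
        pool_of_disease[d1] = idx
        pool_of_disease[d2] = idx

    doc_disease = np.arange(spec.n_documents) % spec.n_diseases
    width = len(str(spec.n_documents))
    doc_ids = np.array([f"M{i + 1:0{width}d}" for i in range(spec.n_documents)])

    occurrences: set[tuple[str, str]] = set()
    for di, disease in enumerate(diseases):
        rows = np.where(doc_disease == di)[0]
        p = np.full(spec.n_genes, spec.p_comention_background)
        if disease in pool_of_disease:
            p[pool_of_disease[disease]] = spec.p_comention_shared
        hits = rng.random((rows.size, spec.n_genes)) < p[None, :]
        r, c = np.nonzero(hits)
        occurrences.update(zip(doc_ids[rows[r]], genes[c]))
        occurrences.update((doc_ids[i], disease) for i in rows)

    corpus = OccurrenceCorpus(occurrences, documents=set(doc_ids))
    truth = CorpusGroundTruth(
        planted_pairs=[tuple(p) for p in spec.planted_pairs],
        shared_pools=pools,
        spec=spec,
    )
    return SimulatedCorpus(corpus=corpus, thesaurus=make_thesaurus(spec), truth=truth)


@dataclass
class NetworkSpec:
    """Parameters of the synthetic referenced interaction network.

    The background is Erdos-Renyi over the non-planted proteins with one
    unique reference per edge.  Planted intermediates connect only to seed
    genes; hub references each support ``hub_reference_links`` extra edges
    (above the default 4-link cap) with no other support, so the reference
    filter must purge them.
    """

    n_proteins: int = 150
    edge_probability: float = 0.02
    n_seeds: int = 10
    seed_gene_names: tuple[str, ...] = ()
    n_planted_intermediates: int = 5
    links_per_intermediate: int = 4
    n_hub_references: int = 2
    hub_reference_links: int = 10
    seed: int = 17

    def validate(self) -> None:
        if not 0.0 <= self.edge_probability <= 1.0:
            raise ValueError("edge_probability must lie in [0, 1]")
        if min(self.n_proteins, len(self.seed_genes)) < 2:
            raise ValueError("need at least 2 proteins and 2 seeds")
        if self.n_planted_intermediates < 0 or self.n_hub_references < 0:
            raise ValueError("counts must be non-negative")
        if self.links_per_intermediate > len(self.seed_genes):
            raise ValueError("cannot wire an intermediate to more seeds than exist")
        n_internal_seeds = 0 if self.seed_gene_names else self.n_seeds
        if n_internal_seeds + self.n_planted_intermediates > self.n_proteins:
            raise ValueError("seeds plus planted intermediates exceed the protein count")

    @property
    def protein_ids(self) -> list[str]:
        width = len(str(self.n_proteins))
        return [f"P{i + 1:0{width}d}" for i in range(self.n_proteins)]

    @property
    def seed_genes(self) -> list[str]:
        """Explicit seed symbols if given, else the first ``n_seeds`` proteins."""
        if self.seed_gene_names:
            return [s.upper() for s in self.seed_gene_names]
        return self.protein_ids[: self.n_seeds]

    @property
    def planted_intermediates(self) -> list[str]:
        return self.protein_ids[self.n_proteins - self.n_planted_intermediates:]


@dataclass
class NetworkGroundTruth:
    seeds: list[str]
    planted: dict[str, list[str]]       # intermediate -> wired seed genes
    purged_edges: list[tuple[str, str]]  # edges the reference filter must remove
    spec: NetworkSpec

    def to_yaml(self, path: str | Path) -> None:
        payload = {
            "seeds": list(self.seeds),
            "planted": {k: list(v) for k, v in self.planted.items()},
            "purged_edges": [list(e) for e in self.purged_edges],
            "spec": {
                "n_proteins": self.spec.n_proteins,
                "edge_probability": self.spec.edge_probability,
                "n_seeds": self.spec.n_seeds,
                "n_planted_intermediates": self.spec.n_planted_intermediates,
                "links_per_intermediate": self.spec.links_per_intermediate,
                "n_hub_references": self.spec.n_hub_references,
                "hub_reference_links": self.spec.hub_reference_links,
                "seed": self.spec.seed,
            },
        }
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))


@dataclass
class SimulatedNetwork:
    edges: list[ReferencedEdge]
    truth: NetworkGroundTruth


def simulate_network(spec: NetworkSpec | None = None) -> SimulatedNetwork:
    """Generate a referenced edge list with planted intermediates."""
    spec = spec or NetworkSpec()
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    proteins = spec.protein_ids
    seeds = spec.seed_genes
    planted = spec.planted_intermediates
    ordinary = [p for p in proteins if p not in set(seeds) | set(planted)]
    if spec.seed_gene_names and set(seeds) & set(planted):
        raise ValueError("explicit seed names collide with planted intermediate ids")

    ref_counter = 0

    def next_ref() -> str:
        nonlocal ref_counter
        ref_counter += 1
        return f"R{ref_counter:05d}"

    edges: list[ReferencedEdge] = []
    # Erdos-Renyi background over seeds + ordinary proteins
    bg_nodes = seeds + ordinary
    n_bg = len(bg_nodes)
    iu, ju = np.triu_indices(n_bg, k=1)
    pick = rng.random(iu.size) < spec.edge_probability
    existing: set[tuple[str, str]] = set()
    for i, j in zip(iu[pick], ju[pick]):
        a, b = sorted((bg_nodes[i], bg_nodes[j]))
        existing.add((a, b))
        edges.append(ReferencedEdge(a, b, frozenset([next_ref()]), frozenset(["sim"])))

    # planted intermediates wired only to seed genes
    truth_planted: dict[str, list[str]] = {}
    for node in planted:
        wired = sorted(
            rng.choice(len(seeds), size=spec.links_per_intermediate, replace=False)
        )
        truth_planted[node] = [seeds[i] for i in wired]
        for s in truth_planted[node]:
            a, b = sorted((node, s))
            existing.add((a, b))
            edges.append(ReferencedEdge(a, b, frozenset([next_ref()]), frozenset(["sim"])))

    # hub references: extra edges among ordinary proteins, supported only by
    # a single high-throughput reference that the 4-link cap must invalidate
    purged: list[tuple[str, str]] = []
    for h in range(spec.n_hub_references):
        ref = f"HUB{h + 1}"
        added = 0
        attempts = 0
        while added < spec.hub_reference_links:
            attempts += 1
            if attempts > 100 * spec.hub_reference_links:
                raise ValueError("cannot place hub edges; network too dense")
            i, j = rng.choice(len(ordinary), size=2, replace=False)
            a, b = sorted((ordinary[i], ordinary[j]))
            if (a, b) in existing:
                continue
            existing.add((a, b))
            edges.append(ReferencedEdge(a, b, frozenset([ref]), frozenset(["sim-hub"])))
            purged.append((a, b))
            added += 1

    truth = NetworkGroundTruth(
        seeds=list(seeds),
        planted=truth_planted,
        purged_edges=sorted(purged),
        spec=spec,
    )
    return SimulatedNetwork(edges=edges, truth=truth)


def write_edge_list(edges: list[ReferencedEdge], path: str | Path) -> None:
    """Write edges in the SIF-like TSV dialect the readers consume."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("proteinA\tproteinB\trefs\tsource\n")
        for e in sorted(edges, key=lambda e: e.key):
            fh.write(
                f"{e.a}\t{e.b}\t{';'.join(sorted(e.references))}\t"
                f"{';'.join(sorted(e.sources)) or 'sim'}\n"
            )
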