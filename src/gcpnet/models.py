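"""Model/Results surface for the two pipeline stages.

:class:`ConceptClustering` fits the literature stage: genetic concept
profiles for a set of disease concepts, their pairwise matching scores,
hierarchical clustering, a planar projection, and a permutation-tested
cohesion score with per-gene contributions for every cluster in the merge
tree.

:class:`SeedNetworkAnalysis` fits the validation stage: a reference-filtered
interaction background, the seed subnetwork at path length <= 2, and
binomial-proportion z-scores for the intermediate nodes.

Both ``fit()`` methods return Results objects carrying the estimates and a
``summary()`` table, in the spirit of statsmodels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import cohesion as _cohesion
from . import network as _network  # noqa: F401  (used in annotations)
from .cohesion import (
    CohesionResult,
    Dendrogram,
    ProfileSet,
    Projection,
    hierarchical_cluster,
    permutation_pvalue,
    project_2d,
    similarity_matrix,
)
from .corpus import (
    ConceptMappingReport,
    OccurrenceCorpus,
    Thesaurus,
    map_concepts,
    read_occurrences,
    read_thesaurus,
)
from .network import (
    IntermediateScore,
    ReferencedEdge,
    Subnetwork,
    build_background,
    extract_subnetwork,
    filter_by_reference,
    read_edge_lists,
    score_intermediates,
    scores_to_frame,
    write_subnetwork,
)
from .profiles import build_profile_matrix

logger = logging.getLogger(__name__)


class ConceptClustering:
    """Cluster disease concepts by their genetic concept profiles.

    Parameters
    ----------
    corpus
        Document-concept occurrence record.
    thesaurus
        Concept thesaurus; its gene-class entries define the profile
        vocabulary.
    concepts
        Concept ids to cluster (default: every disease-class concept that
        occurs in the corpus).
    weight_method
        Association weight: ``uncertainty`` (default), ``pmi`` or ``raw``.
    permutation_universe
        ``"all"`` (default) draws random comparison groups from the profiles
        of every corpus concept in the thesaurus — the full concept space, as
        a literature-wide null; ``"concepts"`` restricts draws to the
        clustered concepts themselves.
    """

    def __init__(
        self,
        corpus: OccurrenceCorpus,
        thesaurus: Thesaurus,
        concepts: Sequence[str] | None = None,
        weight_method: str = "uncertainty",
        permutation_universe: str = "all",
    ):
        if permutation_universe not in ("all", "concepts"):
            raise ValueError("permutation_universe must be 'all' or 'concepts'")
        self.corpus = corpus
        self.thesaurus = thesaurus
        self.weight_method = weight_method
        self.permutation_universe = permutation_universe
        self.mapping_report: ConceptMappingReport | None = None
        if concepts is None:
            concepts = [
                c
                for c in thesaurus.concepts_of_class("disease")
                if c in corpus.concepts
            ]
        missing = [c for c in concepts if c not in corpus.concepts]
        if missing:
            raise ValueError(f"concepts absent from corpus: {missing}")
        if len(concepts) < 2:
            raise ValueError("need at least 2 concepts to cluster")
        self.concepts = list(concepts)

    @classmethod
    def from_files(
        cls,
        occurrences_path: str | Path,
        thesaurus_path: str | Path,
        concept_names: Sequence[str] | None = None,
        **kwargs,
    ) -> "ConceptClustering":
        """Build from TSV inputs, mapping free-text concept names on the way.

        Ambiguous names are excluded (with a warning) and recorded in the
        ``mapping_report``; unmapped names raise.
        """
        corpus = read_occurrences(occurrences_path)
        thesaurus = read_thesaurus(thesaurus_path)
        concepts = None
        report = None
        if concept_names is not None:
            report = map_concepts(list(concept_names), thesaurus)
            if report.unmapped:
                raise ValueError(f"unmapped concept names: {report.unmapped}")
            concepts = [report.resolved[n] for n in report.resolved]
        model = cls(corpus, thesaurus, concepts=concepts, **kwargs)
        model.mapping_report = report
        return model

    def fit(
        self,
        iterations: int = 200,
        linkage: str = "average",
        seed: int = 17,
    ) -> "ConceptClusteringResults":
        """Build profiles and run clustering, projection and cohesion tests."""
        if iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.permutation_universe == "all":
            universe_ids = sorted(
                set(self.concepts)
                | {c for c in self.thesaurus.entries if c in self.corpus.concepts}
            )
        else:
            universe_ids = list(self.concepts)
        matrix = build_profile_matrix(
            self.corpus, universe_ids, self.thesaurus, self.weight_method
        )
        universe = ProfileSet.from_matrix(matrix)
        kept = set(universe.concept_ids)
        concepts = [c for c in self.concepts if c in kept]
        dropped = [c for c in self.concepts if c not in kept]
        if dropped:
            logger.warning("degenerate profiles excluded from clustering: %s", dropped)
        if len(concepts) < 2:
            raise ValueError("fewer than 2 non-degenerate profiles to cluster")

        sub = pd.DataFrame(
            universe.subset(concepts), index=concepts, columns=universe.gene_ids
        )
        concept_set = ProfileSet.from_matrix(sub)
        sim = similarity_matrix(concept_set)
        dendro = hierarchical_cluster(sim, linkage=linkage)
        projection = project_2d(sim)

        rng = np.random.default_rng(seed)
        cohesion_results = []
        for group in dendro.merge_groups():
            if len(group) >= len(universe):
                # the only same-size draw is the group itself: P is exactly 1
                M = universe.subset(group)
                score = float(_cohesion.cohesion_score(M))
                contributions = {}
                if score > 0:
                    gs = _cohesion.gene_contributions(
                        ProfileSet.from_matrix(
                            pd.DataFrame(M, index=group, columns=universe.gene_ids)
                        )
                    )
                    contributions = gs
                cohesion_results.append(
                    CohesionResult(group=group, score=score, p_value=1.0,
                                   iterations=iterations,
                                   contributions=contributions)
                )
                continue
            cohesion_results.append(
                permutation_pvalue(group, universe, iterations=iterations, rng_seed=rng)
            )
        return ConceptClusteringResults(
            model=self,
            profiles=concept_set,
            universe_size=len(universe),
            similarity=sim,
            dendrogram=dendro,
            projection=projection,
            cohesion=cohesion_results,
            iterations=iterations,
            linkage=linkage,
            seed=seed,
            dropped_concepts=dropped,
        )


@dataclass
class ConceptClusteringResults:
    """Fitted literature stage: similarity, clusters, cohesion, projection."""

    model: ConceptClustering
    profiles: ProfileSet
    universe_size: int
    similarity: pd.DataFrame
    dendrogram: Dendrogram
    projection: Projection
    cohesion: list[CohesionResult]
    iterations: int
    linkage: str
    seed: int
    dropped_concepts: list[str]

    def cohesion_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "cluster": "+".join(r.group),
                    "size": len(r.group),
                    "score": r.score,
                    "p_value": r.p_value,
                    "iterations": r.iterations,
                }
                for r in self.cohesion
            ]
        )

    def contributions_frame(self, cutoff_pct: float = 0.0) -> pd.DataFrame:
        """Long table cluster x gene x contribution, descending within cluster."""
        rows = []
        for r in self.cohesion:
            for gene, pct in r.top_genes(cutoff_pct):
                rows.append(
                    {"cluster": "+".join(r.group), "gene": gene,
                     "contribution_pct": pct}
                )
        return pd.DataFrame(rows, columns=["cluster", "gene", "contribution_pct"])

    def significant_clusters(self, p_threshold: float = 0.05) -> list[CohesionResult]:
        return [r for r in self.cohesion if r.p_value <= p_threshold]

    def gene_shortlist(
        self, contribution_cutoff_pct: float = 0.1, p_threshold: float = 0.05
    ) -> list[str]:
        """Genes contributing more than the cutoff to any significant cluster.

        The union over clusters with permutation P at or below
        ``p_threshold``; this is the seed list handed to the network stage.
        """
        genes: set[str] = set()
        for r in self.significant_clusters(p_threshold):
            genes.update(g for g, _ in r.top_genes(contribution_cutoff_pct))
        return sorted(genes)

    def summary(self) -> str:
        lines = [
            "Concept profile clustering",
            "==========================",
            f"concepts clustered:   {len(self.profiles)}"
            + (f"  (dropped degenerate: {self.dropped_concepts})" if self.dropped_concepts else ""),
            f"gene vocabulary:      {len(self.model.thesaurus.gene_vocabulary)}",
            f"documents:            {self.model.corpus.n_documents}",
            f"weight method:        {self.model.weight_method}",
            f"linkage:              {self.linkage}",
            f"permutation universe: {self.universe_size} profiles "
            f"({self.model.permutation_universe})",
            f"iterations:           {self.iterations}   seed: {self.seed}",
            f"projection stress:    {self.projection.stress:.4f}",
            "",
            "Cluster cohesion (merge order)",
            "------------------------------",
        ]
        frame = self.cohesion_frame()
        lines.append(
            frame.to_string(
                index=False,
                formatters={"score": "{:.4f}".format, "p_value": "{:.3f}".format},
            )
        )
        return "\n".join(lines)

    def save(self, outdir: str | Path) -> dict[str, Path]:
        """Write similarity, cohesion, contributions, projection, newick."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "similarity": outdir / "similarity.tsv",
            "cohesion": outdir / "cohesion.tsv",
            "contributions": outdir / "contributions.tsv",
            "projection": outdir / "projection.tsv",
            "dendrogram": outdir / "dendrogram.nwk",
        }
        self.similarity.to_csv(paths["similarity"], sep="\t", index_label="concept_id",
                               float_format="%.12g")
        self.cohesion_frame().to_csv(paths["cohesion"], sep="\t", index=False,
                                     float_format="%.12g")
        self.contributions_frame().to_csv(paths["contributions"], sep="\t",
                                          index=False, float_format="%.12g")
        self.projection.write(paths["projection"])
        paths["dendrogram"].write_text(self.dendrogram.to_newick() + "\n")
        return paths

    def plot_dendrogram(self, ax=None):
        """Dendrogram of the concept merge tree (matplotlib axis)."""
        from matplotlib import pyplot as plt
        from scipy.cluster import hierarchy

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 4))
        hierarchy.dendrogram(
            self.dendrogram.linkage, labels=self.dendrogram.labels, ax=ax
        )
        ax.set_ylabel("distance (1 - matching score)")
        return ax

    def plot_projection(self, ax=None):
        """Scatter of the 2-D concept projection with labels."""
        from matplotlib import pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 5))
        coords = self.projection.coordinates
        ax.scatter(coords["x"], coords["y"])
        for cid, row in coords.iterrows():
            ax.annotate(str(cid), (row["x"], row["y"]),
                        textcoords="offset points", xytext=(4, 4))
        ax.set_xlabel("dimension 1")
        ax.set_ylabel("dimension 2")
        ax.set_aspect("equal")
        return ax


def read_seed_list(path: str | Path) -> list[str]:
    """Plain-text seed list, one gene symbol per line ('#' comments allowed)."""
    seeds = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            seeds.append(line.upper())
    if not seeds:
        raise ValueError(f"{path}: empty seed list")
    return seeds


class SeedNetworkAnalysis:
    """Validate a gene set on a referenced interaction background.

    Parameters
    ----------
    edges
        Referenced interaction records (merged undirected edges).
    seeds
        Gene symbols anchoring the subnetwork.
    max_links_per_reference
        High-throughput cap: references supporting more edges are invalid.
    max_path_length
        Seed-to-seed path cap; 2 admits single intermediate nodes.
    include_intermediate_edges
        Whether intermediate-intermediate edges count toward K.
    """

    def __init__(
        self,
        edges: Sequence[ReferencedEdge],
        seeds: Sequence[str],
        max_links_per_reference: int = 4,
        max_path_length: int = 2,
        include_intermediate_edges: bool = True,
    ):
        if len(seeds) < 2:
            raise ValueError("need at least 2 seed genes")
        self.edges = list(edges)
        self.seeds = [s.upper() for s in seeds]
        self.max_links_per_reference = max_links_per_reference
        self.max_path_length = max_path_length
        self.include_intermediate_edges = include_intermediate_edges

    @classmethod
    def from_files(
        cls,
        edge_paths: Sequence[str | Path],
        seeds_path: str | Path,
        **kwargs,
    ) -> "SeedNetworkAnalysis":
        return cls(read_edge_lists(list(edge_paths)), read_seed_list(seeds_path), **kwargs)

    def fit(self, z_cutoff: float = 2.5) -> "SeedNetworkResults":
        filtered = filter_by_reference(self.edges, self.max_links_per_reference)
        background = build_background(filtered)
        subnetwork = extract_subnetwork(
            background,
            self.seeds,
            max_path_length=self.max_path_length,
            include_intermediate_edges=self.include_intermediate_edges,
        )
        scores = score_intermediates(subnetwork, background, cutoff=z_cutoff)
        return SeedNetworkResults(
            model=self,
            background=background,
            subnetwork=subnetwork,
            scores=scores,
            z_cutoff=z_cutoff,
            n_edges_before_filter=len(self.edges),
        )


@dataclass
class SeedNetworkResults:
    """Fitted network stage: background, subnetwork, intermediate scores."""

    model: SeedNetworkAnalysis
    background: "_network.nx.Graph"
    subnetwork: Subnetwork
    scores: list[IntermediateScore]
    z_cutoff: float
    n_edges_before_filter: int

    @property
    def N(self) -> int:
        return self.background.graph["N"]

    @property
    def K(self) -> int:
        return self.subnetwork.K

    @property
    def significant(self) -> list[IntermediateScore]:
        return [s for s in self.scores if s.significant]

    def scores_frame(self) -> pd.DataFrame:
        return scores_to_frame(self.scores)

    def summary(self) -> str:
        lines = [
            "Seed subnetwork analysis",
            "========================",
            f"edges before filter:  {self.n_edges_before_filter}",
            f"background links N:   {self.N}",
            f"seeds found:          {len(self.subnetwork.seeds)} "
            f"(missing: {len(self.subnetwork.missing_seeds)})",
            f"subnetwork links K:   {self.K}",
            f"intermediates:        {len(self.scores)} "
            f"({len(self.significant)} significant at z > {self.z_cutoff})",
            "",
        ]
        frame = self.scores_frame()
        if len(frame):
            lines.append(
                frame.to_string(index=False, formatters={"z-score": "{:.3f}".format})
            )
        return "\n".join(lines)

    def save(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "graphml": outdir / "subnetwork.graphml",
            "scores": outdir / "intermediate_scores.tsv",
            "missing_seeds": outdir / "missing_seeds.txt",
        }
        write_subnetwork(self.subnetwork, self.scores, paths["graphml"], paths["scores"])
        paths["missing_seeds"].write_text(
            "".join(f"{s}\n" for s in self.subnetwork.missing_seeds)
        )
        return paths
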