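"""Reference-filtered interaction backgrounds and seed-subnetwork scoring.

The background network is the union of referenced protein-protein
interaction records after a high-throughput filter: any single reference
(publication) supporting more than ``max_links_per_reference`` edges is
treated as a high-throughput artifact and invalidated everywhere; an edge
survives if at least one valid reference remains.  No minimum-reference
filter is applied.

Seed genes are looked up in the background and connected through paths of
length at most two: the subnetwork contains the seeds plus every
*intermediate* node adjacent to at least two distinct seeds.  Each
intermediate is scored with a one-sample binomial proportion z statistic
comparing its fraction of seed-directed links (k of its n background links)
against the background link rate p0 = K/N, where K is the subnetwork edge
count and N the background edge count:

    z = (k/n - p0) / sqrt(p0 (1 - p0) / n)

Intermediates with z strictly above the cutoff (default 2.5) are significant.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

SCORE_COLUMNS = [
    "Gene name",
    "Link",
    "Link in background",
    "Links to seed",
    "Links in subnetwork",
    "z-score",
]


class EdgeParseError(ValueError):
    """Raised when an interaction edge file is malformed."""


@dataclass
class ReferencedEdge:
    """Undirected interaction record with supporting reference ids."""

    a: str
    b: str
    references: frozenset[str]
    sources: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.a == self.b:
            raise ValueError(f"self-loop {self.a!r}")
        if self.a > self.b:
            self.a, self.b = self.b, self.a
        if not self.references:
            raise ValueError(f"edge {self.a}-{self.b} carries no reference")

    @property
    def key(self) -> tuple[str, str]:
        return (self.a, self.b)


def merge_edges(records: Iterable[ReferencedEdge]) -> list[ReferencedEdge]:
    """Union duplicate (A,B)/(B,A) records into single undirected edges."""
    merged: dict[tuple[str, str], ReferencedEdge] = {}
    for rec in records:
        prev = merged.get(rec.key)
        if prev is None:
            merged[rec.key] = rec
        else:
            merged[rec.key] = ReferencedEdge(
                rec.a,
                rec.b,
                prev.references | rec.references,
                prev.sources | rec.sources,
            )
    return [merged[k] for k in sorted(merged)]


def read_edge_lists(paths: Sequence[str | Path]) -> list[ReferencedEdge]:
    """Read SIF-like TSVs ``proteinA<TAB>proteinB<TAB>refs<TAB>source``.

    Symbols are uppercased; references are semicolon-separated; duplicate
    records are merged with reference union; self-loops are dropped with a
    warning.  Files may or may not carry a header line.
    """
    records: list[ReferencedEdge] = []
    for path in paths:
        path = Path(path)
        n_before = len(records)
        with path.open("r", encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line:
                    continue
                parts = line.split("\t")
                if lineno == 1 and parts[0].lower() in ("proteina", "protein_a"):
                    continue
                if len(parts) < 3 or not parts[0] or not parts[1]:
                    raise EdgeParseError(f"{path}:{lineno}: malformed line {line!r}")
                a, b = parts[0].upper(), parts[1].upper()
                if a == b:
                    logger.warning("%s:%d: dropping self-loop %s", path, lineno, a)
                    continue
                refs = frozenset(r for r in parts[2].split(";") if r)
                if not refs:
                    raise EdgeParseError(f"{path}:{lineno}: edge without references")
                source = frozenset([parts[3]] if len(parts) > 3 and parts[3] else [])
                records.append(ReferencedEdge(a, b, refs, source))
        logger.info("read %d edge records from %s", len(records) - n_before, path)
    return merge_edges(records)


def filter_by_reference(
    edges: Sequence[ReferencedEdge], max_links_per_reference: int = 4
) -> list[ReferencedEdge]:
    """Invalidate high-throughput references and drop unsupported edges.

    A reference supporting more than ``max_links_per_reference`` merged
    edges is invalid everywhere; an edge survives iff it retains at least
    one valid reference.  The operation is idempotent.
    """
    if max_links_per_reference < 1:
        raise ValueError("max_links_per_reference must be >= 1")
    edges = merge_edges(edges)
    support: dict[str, int] = {}
    for e in edges:
        for r in e.references:
            support[r] = support.get(r, 0) + 1
    invalid = {r for r, n in support.items() if n > max_links_per_reference}
    if invalid:
        logger.info(
            "invalidating %d high-throughput references (> %d links each)",
            len(invalid), max_links_per_reference,
        )
    kept = []
    for e in edges:
        refs = e.references - invalid
        if refs:
            kept.append(ReferencedEdge(e.a, e.b, frozenset(refs), e.sources))
    logger.info("reference filter kept %d of %d edges", len(kept), len(edges))
    return kept


def build_background(edges: Sequence[ReferencedEdge]) -> nx.Graph:
    """Simple undirected background graph; ``G.graph['N']`` is the link count."""
    if not edges:
        raise ValueError("no edges remain to build a background network")
    G = nx.Graph()
    for e in merge_edges(edges):
        G.add_edge(
            e.a, e.b,
            references=";".join(sorted(e.references)),
            sources=";".join(sorted(e.sources)),
        )
    G.graph["N"] = G.number_of_edges()
    return G


@dataclass
class Subnetwork:
    """Seed subnetwork at path length <= 2 within a background graph."""

    graph: nx.Graph
    seeds: list[str]
    intermediates: list[str]
    missing_seeds: list[str]
    seed_links: dict[str, int]  # intermediate -> distinct-seed adjacency k
    include_intermediate_edges: bool = True

    @property
    def K(self) -> int:
        return self.graph.graph["K"]


def extract_subnetwork(
    background: nx.Graph,
    seeds: Sequence[str],
    max_path_length: int = 2,
    include_intermediate_edges: bool = True,
) -> Subnetwork:
    """Connect seeds through paths of length at most ``max_path_length``.

    With the default length 2, the subnetwork nodes are the seeds found in
    the background plus every non-seed node adjacent to >= 2 distinct seeds
    (the only way a length-2 seed-to-seed path can pass through a non-seed
    node).  Edges are the background edges induced on that node set; with
    ``include_intermediate_edges=False`` intermediate-intermediate edges are
    left out of the subnetwork link count K.
    """
    if max_path_length not in (1, 2):
        raise ValueError("max_path_length must be 1 or 2")
    seed_set = {s.upper() for s in seeds}
    present = sorted(s for s in seed_set if s in background)
    missing = sorted(seed_set - set(present))
    if missing:
        logger.info("%d of %d seeds absent from background: %s",
                    len(missing), len(seed_set), missing)
    if len(present) < 2:
        raise ValueError("fewer than 2 seed genes present in the background network")

    seed_links: dict[str, int] = {}
    intermediates: list[str] = []
    if max_path_length == 2:
        for node in background:
            if node in seed_set:
                continue
            k = sum(1 for nb in background.neighbors(node) if nb in seed_set)
            if k >= 2:
                intermediates.append(node)
                seed_links[node] = k
        intermediates.sort()

    nodes = set(present) | set(intermediates)
    sub = background.subgraph(nodes).copy()
    if not include_intermediate_edges:
        drop = [
            (u, v) for u, v in sub.edges
            if u not in seed_set and v not in seed_set
        ]
        sub.remove_edges_from(drop)
    for node in sub.nodes:
        sub.nodes[node]["role"] = "seed" if node in seed_set else "intermediate"
    sub.graph["K"] = sub.number_of_edges()
    return Subnetwork(
        graph=sub,
        seeds=present,
        intermediates=intermediates,
        missing_seeds=missing,
        seed_links=seed_links,
        include_intermediate_edges=include_intermediate_edges,
    )


def intermediate_zscore(n: int, k: int, K: int, N: int) -> float:
    """One-sample binomial proportion z of a node's seed-directed link rate.

    ``n``: the node's background links; ``k``: its links to seed nodes;
    ``K``: subnetwork links; ``N``: background links.  Tests k/n against the
    background rate p0 = K/N.
    """
    if n < 1:
        raise ValueError("node must have at least one background link")
    if not 0 <= k <= n:
        raise ValueError("seed links k must satisfy 0 <= k <= n")
    if not 1 <= K < N:
        raise ValueError("require 1 <= K < N")
    p0 = K / N
    return (k / n - p0) / math.sqrt(p0 * (1.0 - p0) / n)


@dataclass
class IntermediateScore:
    """Binomial-proportion score of one intermediate node."""

    node: str
    n: int          # background degree ("Link")
    k: int          # links to distinct seeds
    K: int          # subnetwork links
    N: int          # background links
    z: float
    significant: bool


def score_intermediates(
    subnetwork: Subnetwork, background: nx.Graph, cutoff: float = 2.5
) -> list[IntermediateScore]:
    """Score every intermediate, sorted by z descending (ties by name).

    ``significant`` is strict: z > cutoff.
    """
    N = background.graph["N"]
    K = subnetwork.K
    scores = []
    for node in subnetwork.intermediates:
        n = background.degree(node)
        k = subnetwork.seed_links[node]
        z = intermediate_zscore(n, k, K, N)
        scores.append(
            IntermediateScore(node, n, k, K, N, z, significant=z > cutoff)
        )
    scores.sort(key=lambda s: (-s.z, s.node))
    return scores


def scores_to_frame(scores: Sequence[IntermediateScore]) -> pd.DataFrame:
    """Score table with the canonical column order."""
    return pd.DataFrame(
        [
            {
                "Gene name": s.node,
                "Link": s.n,
                "Link in background": s.N,
                "Links to seed": s.k,
                "Links in subnetwork": s.K,
                "z-score": s.z,
            }
            for s in scores
        ],
        columns=SCORE_COLUMNS,
    )


def write_subnetwork(
    subnetwork: Subnetwork,
    scores: Sequence[IntermediateScore],
    graphml_path: str | Path,
    table_path: str | Path,
) -> None:
    """Write the annotated subnetwork (GraphML) and the score table (TSV)."""
    G = subnetwork.graph.copy()
    by_node = {s.node: s for s in scores}
    for node in G.nodes:
        s = by_node.get(node)
        if s is not None:
            G.nodes[node]["z"] = float(s.z)
            G.nodes[node]["significant"] = bool(s.significant)
    nx.write_graphml(G, str(graphml_path))
    scores_to_frame(scores).to_csv(table_path, sep="\t", index=False,
                                   float_format="%.6g")
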