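"""Profile matching, group cohesion, permutation tests, clustering, projection.

The matching score of two L2-normalised non-negative profiles is their inner
product, which lies in [0, 1].  The cohesion of a group of m profiles is the
average of the inner products of all C(m, 2) profile pairs.  Its statistical
interpretation comes from a permutation test: the P-value is the fraction of
random same-size groups, drawn from a comparison universe of profiles, whose
cohesion reaches the observed score.

Hierarchical clustering and the planar projection both operate on the
distance d = 1 - matching score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .profiles import ConceptProfile

logger = logging.getLogger(__name__)

LINKAGE_METHODS = ("average", "complete", "single")


class ProfileSet:
    """Ordered collection of non-degenerate normalised profiles.

    Profiles share a gene vocabulary implicitly (absent genes weigh 0); the
    set materialises them as a dense matrix for fast pairwise arithmetic.
    """

    def __init__(self, profiles: Sequence[ConceptProfile]):
        profiles = list(profiles)
        if len(profiles) < 2:
            raise ValueError("a profile set needs at least 2 profiles")
        ids = [p.concept_id for p in profiles]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate concept ids in profile set")
        for p in profiles:
            if p.degenerate:
                raise ValueError(f"degenerate profile {p.concept_id!r} not allowed")
            if not p.normalized:
                raise ValueError(f"profile {p.concept_id!r} is not normalised")
        self.concept_ids = ids
        genes = sorted({g for p in profiles for g in p.weights})
        self.gene_ids = genes
        gene_pos = {g: j for j, g in enumerate(genes)}
        M = np.zeros((len(profiles), len(genes)))
        for i, p in enumerate(profiles):
            for g, w in p.weights.items():
                M[i, gene_pos[g]] = w
        self.matrix = M

    @classmethod
    def from_matrix(cls, matrix: pd.DataFrame) -> "ProfileSet":
        """Build from a normalised concept x gene matrix, dropping zero rows."""
        norms = np.sqrt((matrix.values ** 2).sum(axis=1))
        keep = norms > 0
        dropped = list(matrix.index[~keep])
        if dropped:
            logger.warning("excluding degenerate profiles: %s", dropped)
        obj = cls.__new__(cls)
        obj.concept_ids = [str(c) for c in matrix.index[keep]]
        if len(obj.concept_ids) < 2:
            raise ValueError("a profile set needs at least 2 non-degenerate profiles")
        obj.gene_ids = [str(g) for g in matrix.columns]
        obj.matrix = matrix.values[keep].astype(float)
        return obj

    def __len__(self) -> int:
        return len(self.concept_ids)

    def index_of(self, concept_id: str) -> int:
        return self.concept_ids.index(concept_id)

    def subset(self, concept_ids: Sequence[str]) -> np.ndarray:
        """Row matrix of the named concepts (order preserved)."""
        return self.matrix[[self.index_of(c) for c in concept_ids]]


def matching_score(p1: ConceptProfile, p2: ConceptProfile) -> float:
    """Inner product of two normalised profiles; in [0, 1]."""
    for p in (p1, p2):
        if p.degenerate:
            raise ValueError(f"degenerate profile {p.concept_id!r}")
        if not p.normalized:
            raise ValueError(f"profile {p.concept_id!r} is not normalised")
    small, large = sorted((p1.weights, p2.weights), key=len)
    return float(sum(w * large.get(g, 0.0) for g, w in small.items()))


def _group_cohesion(M: np.ndarray) -> float:
    """Mean pairwise inner product of the rows of a unit-norm matrix.

    Uses sum-vector algebra: with s = sum of rows and each row unit-norm,
    sum of pairwise dots = (|s|^2 - m) / 2.
    """
    m = M.shape[0]
    s = M.sum(axis=0)
    return float((s @ s - m) / (m * (m - 1)))


def cohesion_score(group: ProfileSet | np.ndarray) -> float:
    """Average inner product over all profile pairs of a group (m >= 2)."""
    M = group.matrix if isinstance(group, ProfileSet) else np.asarray(group)
    if M.shape[0] < 2:
        raise ValueError("cohesion requires at least 2 profiles")
    return _group_cohesion(M)


def gene_contributions(group: ProfileSet) -> dict[str, float]:
    """Percentage contribution of each gene to the group cohesion score.

    contribution(g) = 100 * mean over pairs of w_i(g) w_j(g) / cohesion.
    Contributions are non-negative and sum to 100 when cohesion > 0.
    """
    M = group.matrix
    m = M.shape[0]
    if m < 2:
        raise ValueError("contributions require at least 2 profiles")
    score = _group_cohesion(M)
    if score <= 0:
        raise ValueError("gene contributions are undefined for zero cohesion")
    s = M.sum(axis=0)
    per_gene = (s * s - (M * M).sum(axis=0)) / (m * (m - 1))  # mean pairwise product
    pct = 100.0 * per_gene / score
    return {g: float(p) for g, p in zip(group.gene_ids, pct) if p > 0}


@dataclass
class CohesionResult:
    """Cohesion of a concept group with its permutation P-value.

    ``p_value`` is r / iterations where r counts random same-size groups
    whose cohesion reaches the observed score; ``contributions`` maps gene
    id -> percentage of the score (empty when the score is 0).
    """

    group: list[str]
    score: float
    p_value: float
    iterations: int
    contributions: dict[str, float] = field(default_factory=dict)

    def top_genes(self, cutoff_pct: float = 0.1) -> list[tuple[str, float]]:
        """Genes contributing more than ``cutoff_pct`` percent, descending."""
        items = [(g, p) for g, p in self.contributions.items() if p > cutoff_pct]
        return sorted(items, key=lambda gp: (-gp[1], gp[0]))


def permutation_pvalue(
    group: Sequence[str],
    universe: ProfileSet,
    iterations: int = 200,
    rng_seed: int | np.random.Generator = 17,
) -> CohesionResult:
    """Permutation probability of the observed group cohesion.

    Draws ``iterations`` uniform random subsets of size ``len(group)`` from
    the universe (without replacement within a draw; draws may overlap the
    observed group) and reports the fraction whose cohesion is at least the
    observed score.  Deterministic for a given seed.
    """
    group = list(group)
    m = len(group)
    if m < 2:
        raise ValueError("group must contain at least 2 concepts")
    if len(universe) <= m:
        raise ValueError("universe must be strictly larger than the group")
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    Mg = universe.subset(group)
    observed = _group_cohesion(Mg)

    n = len(universe)
    hits = 0
    for _ in range(iterations):
        idx = rng.choice(n, size=m, replace=False)
        if _group_cohesion(universe.matrix[idx]) >= observed:
            hits += 1
    p = hits / iterations

    contributions: dict[str, float] = {}
    if observed > 0:
        s = Mg.sum(axis=0)
        per_gene = (s * s - (Mg * Mg).sum(axis=0)) / (m * (m - 1))
        pct = 100.0 * per_gene / observed
        contributions = {
            g: float(v) for g, v in zip(universe.gene_ids, pct) if v > 0
        }
    return CohesionResult(
        group=group,
        score=observed,
        p_value=p,
        iterations=iterations,
        contributions=contributions,
    )


def similarity_matrix(profiles: ProfileSet) -> pd.DataFrame:
    """Square symmetric matrix of pairwise matching scores (diagonal 1)."""
    S = profiles.matrix @ profiles.matrix.T
    np.fill_diagonal(S, 1.0)
    S = np.clip((S + S.T) / 2.0, 0.0, 1.0)
    return pd.DataFrame(S, index=profiles.concept_ids, columns=profiles.concept_ids)


def _check_similarity(sim: pd.DataFrame) -> np.ndarray:
    S = np.asarray(sim.values, dtype=float)
    if S.shape[0] != S.shape[1]:
        raise ValueError("similarity matrix must be square")
    if not np.allclose(S, S.T, atol=1e-9):
        raise ValueError("similarity matrix must be symmetric")
    if not np.allclose(np.diag(S), 1.0, atol=1e-9):
        raise ValueError("similarity diagonal must be 1")
    return S


@dataclass
class Dendrogram:
    """Agglomerative merge tree over concepts (scipy linkage encoding)."""

    labels: list[str]
    linkage: np.ndarray  # scipy (n-1) x 4 linkage matrix

    @property
    def merge_heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def merge_groups(self) -> list[list[str]]:
        """Leaf labels under each internal node, in merge order."""
        n = len(self.labels)
        members: dict[int, list[str]] = {i: [self.labels[i]] for i in range(n)}
        groups = []
        for step, (i, j, _, _) in enumerate(self.linkage):
            merged = sorted(members[int(i)] + members[int(j)])
            members[n + step] = merged
            groups.append(merged)
        return groups

    def to_newick(self) -> str:
        """Newick string with branch lengths spanning merge heights."""
        tree = hierarchy.to_tree(self.linkage)

        def render(node, parent_height: float) -> str:
            length = parent_height - (node.dist if not node.is_leaf() else 0.0)
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:.10g}"
            left = render(node.left, node.dist)
            right = render(node.right, node.dist)
            return f"({left},{right}):{length:.10g}"

        root = tree
        left = render(root.left, root.dist)
        right = render(root.right, root.dist)
        return f"({left},{right});"


def hierarchical_cluster(sim: pd.DataFrame, linkage: str = "average") -> Dendrogram:
    """Agglomerative clustering on distance d = 1 - similarity.

    Concepts are processed in lexicographic id order, which fixes the merge
    order when distances tie.
    """
    if linkage not in LINKAGE_METHODS:
        raise ValueError(f"unknown linkage {linkage!r}; choose from {LINKAGE_METHODS}")
    S = _check_similarity(sim)
    order = np.argsort(np.asarray(sim.index, dtype=str))
    labels = [str(sim.index[i]) for i in order]
    D = 1.0 - S[np.ix_(order, order)]
    np.fill_diagonal(D, 0.0)
    Z = hierarchy.linkage(squareform(D, checks=False), method=linkage)
    return Dendrogram(labels=labels, linkage=Z)


@dataclass
class Projection:
    """2-D embedding of concepts from classical (Torgerson) scaling."""

    coordinates: pd.DataFrame  # columns x, y
    eigenvalues: np.ndarray
    stress: float

    def write(self, path) -> None:
        self.coordinates.to_csv(path, sep="\t", index_label="concept_id",
                                float_format="%.12g")


def project_2d(sim: pd.DataFrame) -> Projection:
    """Classical metric multidimensional scaling of d = 1 - similarity.

    Double-centres the squared distance matrix, takes the top two
    eigencoordinates, and reports raw-stress diagnostics plus the eigenvalue
    spectrum (negative eigenvalues flag non-Euclidean distances).
    """
    S = _check_similarity(sim)
    D = 1.0 - S
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    eigval, eigvec = np.linalg.eigh(B)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    if (eigval < -1e-9).any():
        logger.info(
            "non-Euclidean distances: most negative eigenvalue %.3g", eigval.min()
        )
    if eigval[0] <= 1e-12:
        logger.warning("all concepts equivalent; projecting every point to the origin")
        coords = np.zeros((n, 2))
    else:
        lam = np.clip(eigval[:2], 0.0, None)
        coords = eigvec[:, :2] * np.sqrt(lam)
    Dhat = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))
    stress = float(np.sqrt(((D - Dhat) ** 2).sum() / max((D ** 2).sum(), 1e-300)))
    frame = pd.DataFrame(coords, index=sim.index, columns=["x", "y"])
    return Projection(coordinates=frame, eigenvalues=eigval, stress=stress)
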