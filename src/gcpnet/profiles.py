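"""Weighted genetic concept profiles from document-level co-occurrence.

A concept profile represents a concept as a sparse weighted vector over the
gene vocabulary of a thesaurus.  The weight of a gene is an association
strength computed from the 2x2 document co-occurrence table of the concept
and the gene.  The default weight is the symmetric uncertainty coefficient

    U(c, g) = 2 * I(c; g) / (H(c) + H(g))

with mutual information and entropies in nats, clamped to zero for
negatively associated pairs (observed co-occurrence at or below the
independence expectation).  Alternatives are positive pointwise mutual
information (``pmi``) and the raw co-occurrence count (``raw``).

Profiles are L2-normalised before any inner product so that matching scores
of profile pairs lie in [0, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .corpus import OccurrenceCorpus, Thesaurus

logger = logging.getLogger(__name__)

WEIGHT_METHODS = ("uncertainty", "pmi", "raw")


@dataclass(frozen=True)
class ContingencyTable:
    """Document-level 2x2 co-occurrence table for a concept pair.

    ``a`` documents contain both concepts, ``b`` only the first, ``c`` only
    the second and ``d`` neither; ``T = a + b + c + d`` is the corpus size.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


def contingency(corpus: OccurrenceCorpus, concept1: str, concept2: str) -> ContingencyTable:
    """2x2 document co-occurrence table of two concepts.

    Concepts absent from the corpus contribute empty document sets, so the
    corresponding cells are zero.
    """
    docs1 = corpus.documents_with(concept1)
    docs2 = corpus.documents_with(concept2)
    a = len(docs1 & docs2)
    b = len(docs1) - a
    c = len(docs2) - a
    d = corpus.n_documents - a - b - c
    return ContingencyTable(a, b, c, d)


def _entropy2(p: float) -> float:
    """Entropy (nats) of a Bernoulli(p) variable; 0*log(0) = 0."""
    if p <= 0.0 or p >= 1.0:
        return 0.0
    return -(p * np.log(p) + (1.0 - p) * np.log(1.0 - p))


def association_weight(table: ContingencyTable, method: str = "uncertainty") -> float:
    """Association strength of a concept pair from its 2x2 table.

    All methods return 0 when the concepts never co-occur (``a == 0``), and
    the ``uncertainty`` and ``pmi`` weights are clamped to 0 when the
    observed co-occurrence rate does not exceed the independence expectation
    ``(a+b)(a+c)/T^2``.
    """
    if method not in WEIGHT_METHODS:
        raise ValueError(f"unknown weight method {method!r}; choose from {WEIGHT_METHODS}")
    T = table.total
    if T <= 0:
        raise ValueError("contingency table total must be positive")
    a, b, c, d = table.a, table.b, table.c, table.d
    if a == 0:
        return 0.0
    if method == "raw":
        return float(a)

    p1 = (a + b) / T   # P(first concept present)
    p2 = (a + c) / T   # P(second concept present)
    p11 = a / T
    if p11 <= p1 * p2:  # at or below independence: no positive association
        return 0.0
    if method == "pmi":
        return float(np.log(p11 / (p1 * p2)))

    h1 = _entropy2(p1)
    h2 = _entropy2(p2)
    if h1 + h2 == 0.0:
        logger.warning("degenerate marginals in contingency table; weight set to 0")
        return 0.0
    mi = 0.0
    for pij, pi, pj in (
        (a / T, p1, p2),
        (b / T, p1, 1 - p2),
        (c / T, 1 - p1, p2),
        (d / T, 1 - p1, 1 - p2),
    ):
        if pij > 0:
            mi += pij * np.log(pij / (pi * pj))
    return float(max(0.0, 2.0 * mi / (h1 + h2)))


@dataclass
class ConceptProfile:
    """One concept's weighted sparse vector over the gene vocabulary.

    ``weights`` maps gene id -> non-negative weight; genes absent from the
    map carry weight 0.  ``normalized`` marks an L2 norm of 1; a profile with
    no positive weight is ``degenerate`` and excluded from clustering.
    """

    concept_id: str
    weights: dict[str, float]
    normalized: bool = False

    def __post_init__(self) -> None:
        for gene, w in self.weights.items():
            if not np.isfinite(w) or w < 0:
                raise ValueError(f"invalid weight {w!r} for gene {gene!r}")

    @property
    def degenerate(self) -> bool:
        return not any(w > 0 for w in self.weights.values())

    def normalize(self) -> "ConceptProfile":
        """Return the L2-normalised profile (no-op on degenerate profiles)."""
        norm = float(np.sqrt(sum(w * w for w in self.weights.values())))
        if norm == 0.0:
            return ConceptProfile(self.concept_id, dict(self.weights), normalized=True)
        return ConceptProfile(
            self.concept_id,
            {g: w / norm for g, w in self.weights.items() if w > 0},
            normalized=True,
        )

    def to_vector(self, gene_order: Sequence[str]) -> np.ndarray:
        return np.array([self.weights.get(g, 0.0) for g in gene_order])


def build_profile(
    corpus: OccurrenceCorpus,
    concept: str,
    thesaurus: Thesaurus,
    method: str = "uncertainty",
) -> ConceptProfile:
    """Build the genetic concept profile of one concept.

    One weight per gene-class thesaurus concept with a positive association;
    the profile is L2-normalised.  A concept that co-occurs with no gene
    yields a degenerate profile (flagged, to be excluded from clustering).
    """
    if concept not in corpus.concepts:
        raise ValueError(f"concept {concept!r} absent from corpus")
    weights: dict[str, float] = {}
    for gene in thesaurus.gene_vocabulary:
        if gene == concept:
            continue  # self-association excluded from a concept's own profile
        w = association_weight(contingency(corpus, concept, gene), method)
        if w > 0:
            weights[gene] = w
    profile = ConceptProfile(concept, weights).normalize()
    if profile.degenerate:
        logger.warning("profile for %r is degenerate (no associated genes)", concept)
    return profile


def build_profile_matrix(
    corpus: OccurrenceCorpus,
    concepts: Sequence[str],
    thesaurus: Thesaurus,
    method: str = "uncertainty",
) -> pd.DataFrame:
    """Vectorised profile construction for many concepts at once.

    Returns an L2-row-normalised DataFrame (rows = concepts, columns = gene
    vocabulary).  Rows of degenerate profiles are all-zero.  Agrees with
    :func:`build_profile` applied per concept.
    """
    if method not in WEIGHT_METHODS:
        raise ValueError(f"unknown weight method {method!r}")
    genes = thesaurus.gene_vocabulary
    concepts = list(concepts)
    all_cols = sorted(set(concepts) | set(genes))
    X, _, cols = corpus.to_matrix(all_cols)
    pos = {c: i for i, c in enumerate(cols)}
    T = corpus.n_documents

    Xc = X[:, [pos[c] for c in concepts]]
    Xg = X[:, [pos[g] for g in genes]]
    A = np.asarray((Xc.T @ Xg).todense(), dtype=float)           # co-occurrence counts
    mc = np.asarray(Xc.sum(axis=0)).ravel().astype(float)        # concept margins
    mg = np.asarray(Xg.sum(axis=0)).ravel().astype(float)        # gene margins

    if method == "raw":
        W = A.copy()
    else:
        p11 = A / T
        p1 = (mc / T)[:, None]
        p2 = (mg / T)[None, :]
        indep = p1 * p2
        if method == "pmi":
            with np.errstate(divide="ignore", invalid="ignore"):
                W = np.where(p11 > indep, np.log(np.where(p11 > 0, p11, 1.0) / np.where(indep > 0, indep, 1.0)), 0.0)
        else:
            p10 = p1 - p11
            p01 = p2 - p11
            p00 = 1.0 - p1 - p2 + p11

            def xlogx_ratio(p, q):
                out = np.zeros_like(p)
                mask = p > 0
                out[mask] = p[mask] * np.log(p[mask] / q[mask])
                return out

            mi = (
                xlogx_ratio(p11, p1 * p2)
                + xlogx_ratio(p10, p1 * (1 - p2))
                + xlogx_ratio(p01, (1 - p1) * p2)
                + xlogx_ratio(p00, (1 - p1) * (1 - p2))
            )
            h1 = np.array([_entropy2(p) for p in mc / T])[:, None]
            h2 = np.array([_entropy2(p) for p in mg / T])[None, :]
            hsum = h1 + h2
            with np.errstate(divide="ignore", invalid="ignore"):
                W = np.where((p11 > indep) & (hsum > 0), 2.0 * mi / np.where(hsum > 0, hsum, 1.0), 0.0)
        W = np.clip(W, 0.0, None)
    W[A == 0] = 0.0
    # a concept's own column carries no self-association weight
    for i, c in enumerate(concepts):
        if c in set(genes):
            W[i, genes.index(c)] = 0.0

    norms = np.sqrt((W * W).sum(axis=1))
    nz = norms > 0
    W[nz] = W[nz] / norms[nz, None]
    return pd.DataFrame(W, index=pd.Index(concepts, name="concept_id"), columns=genes)


def profiles_from_matrix(matrix: pd.DataFrame) -> list[ConceptProfile]:
    """Convert a normalised profile matrix into :class:`ConceptProfile`s."""
    out = []
    for cid, row in matrix.iterrows():
        weights = {g: float(w) for g, w in row.items() if w > 0}
        out.append(ConceptProfile(str(cid), weights, normalized=True))
    return out


def write_profiles(profiles: Sequence[ConceptProfile], path: str | Path) -> None:
    """Write profiles as ``concept_id<TAB>gene_id<TAB>weight`` (12 sig. digits)."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("concept_id\tgene_id\tweight\n")
        for p in profiles:
            for gene in sorted(p.weights):
                fh.write(f"{p.concept_id}\t{gene}\t{p.weights[gene]:.12g}\n")


def read_profiles(path: str | Path) -> list[ConceptProfile]:
    df = pd.read_csv(path, sep="\t", dtype={"concept_id": str, "gene_id": str})
    profiles = []
    for cid, group in df.groupby("concept_id", sort=True):
        weights = dict(zip(group["gene_id"], group["weight"].astype(float)))
        norm = float(np.sqrt(sum(w * w for w in weights.values())))
        profiles.append(
            ConceptProfile(str(cid), weights, normalized=abs(norm - 1.0) < 1e-9)
        )
    return profiles
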