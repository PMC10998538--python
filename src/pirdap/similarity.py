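"""Similarity networks for piRNAs and diseases, and the heterogeneous graph.

piRNA similarity S_p fuses normalized Smith-Waterman sequence similarity
with Gaussian interaction-profile (GIP) kernel similarity of adjacency
rows.  Disease similarity S_d fuses ontology-DAG semantic similarity with
GIP similarity of adjacency columns.  The heterogeneous adjacency stacks
the blocks

    A_h = [[S_p, A], [A^T, S_d]].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from Bio import Align

from .io import DiseaseOntology, PirnaRecord


@dataclass
class SimilarityMatrix:
    """Square symmetric similarity matrix with unit diagonal, entries in [0,1]."""

    ids: list
    M: np.ndarray

    def __post_init__(self) -> None:
        self.M = np.asarray(self.M, dtype=float)
        k = len(self.ids)
        if self.M.shape != (k, k):
            raise ValueError(f"matrix shape {self.M.shape} does not match {k} ids")
        if not np.allclose(self.M, self.M.T, atol=1e-10):
            raise ValueError("similarity matrix must be symmetric")
        if not np.allclose(np.diag(self.M), 1.0, atol=1e-8):
            raise ValueError("similarity matrix must have unit diagonal")
        if self.M.min() < -1e-10 or self.M.max() > 1 + 1e-10:
            raise ValueError("similarity values must lie in [0, 1]")
        self.M = np.clip(self.M, 0.0, 1.0)


@dataclass
class HeteroGraph:
    """Block matrix [[S_p, A], [A^T, S_d]] over m piRNAs then n diseases."""

    A_h: np.ndarray
    m: int
    n: int


# ---------------------------------------------------------------------------
# sequence similarity


def _aligner(match: float, mismatch: float, gap: float) -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "local"
    al.match_score = match
    al.mismatch_score = mismatch
    al.open_gap_score = gap     # linear gap penalty
    al.extend_gap_score = gap
    return al


def sw_raw_score(seq_a: str, seq_b: str, match: float = 2.0,
                 mismatch: float = -1.0, gap: float = -1.0) -> float:
    """Best Smith-Waterman local alignment score under linear gap penalty.

    Returns 0 when no positive-scoring local alignment exists.
    """
    if not seq_a or not seq_b:
        raise ValueError("cannot align an empty sequence")
    if match <= 0:
        raise ValueError("match score must be positive")
    return float(_aligner(match, mismatch, gap).score(seq_a, seq_b))


def seq_similarity(pirnas: Sequence[PirnaRecord], match: float = 2.0,
                   mismatch: float = -1.0, gap: float = -1.0) -> SimilarityMatrix:
    """Normalized Smith-Waterman similarity: SW(i,j)/sqrt(SW(i,i)*SW(j,j))."""
    al = _aligner(match, mismatch, gap)
    m = len(pirnas)
    raw = np.zeros((m, m))
    for i in range(m):
        for j in range(i, m):
            raw[i, j] = raw[j, i] = al.score(pirnas[i].sequence, pirnas[j].sequence)
    self_scores = np.diag(raw)
    # with a positive match score every self-alignment is positive
    M = raw / np.sqrt(np.outer(self_scores, self_scores))
    np.fill_diagonal(M, 1.0)
    return SimilarityMatrix(ids=[p.id for p in pirnas], M=np.clip(M, 0.0, 1.0))


# ---------------------------------------------------------------------------
# GIP kernel


def gip_similarity(profiles: np.ndarray, ids: Sequence[str]) -> SimilarityMatrix:
    """Gaussian interaction-profile kernel over binary profile rows.

    M[i,j] = exp(-lam * ||row_i - row_j||^2) with the bandwidth
    lam = 1 / mean_k ||row_k||^2 estimated from the data.
    """
    P = np.asarray(profiles, dtype=float)
    norms_sq = (P ** 2).sum(axis=1)
    mean_norm = norms_sq.mean()
    if mean_norm == 0:
        raise ValueError("GIP undefined: zero mean profile norm")
    lam = 1.0 / mean_norm
    sq_dist = norms_sq[:, None] + norms_sq[None, :] - 2.0 * P @ P.T
    sq_dist = np.maximum(sq_dist, 0.0)
    M = np.exp(-lam * sq_dist)
    np.fill_diagonal(M, 1.0)
    return SimilarityMatrix(ids=list(ids), M=M)


# ---------------------------------------------------------------------------
# ontology semantic similarity


def semantic_contribution(ontology: DiseaseOntology, disease: str,
                          theta: float = 0.5) -> dict:
    """Decayed semantic contribution of each ancestor term to ``disease``.

    The disease itself contributes 1; an ancestor t contributes
    max over children t' of t (within the disease's ancestor closure) of
    theta * contribution(t').
    """
    if disease not in ontology.nodes:
        raise KeyError(f"disease {disease!r} not in ontology")
    closure = {disease} | set(ontology.ancestors(disease))
    # children within the closure: reverse of child->parent edges
    children_in = {t: set() for t in closure}
    for c, p in ontology.parent_edges:
        if c in closure and p in closure:
            children_in[p].add(c)

    contrib = {disease: 1.0}

    def weight(t):
        if t in contrib:
            return contrib[t]
        contrib[t] = max(theta * weight(c) for c in children_in[t])
        return contrib[t]

    for t in closure:
        weight(t)
    return contrib


def semantic_similarity(ontology: DiseaseOntology, diseases: Sequence[str],
                        theta: float = 0.5) -> SimilarityMatrix:
    """Shared-ancestor semantic similarity between diseases on the DAG.

    For diseases i, j with contribution maps S_i, S_j over their ancestor
    closures T_i, T_j:

        sim(i,j) = sum_{t in T_i & T_j} (S_i(t) + S_j(t))
                   / (sum_{T_i} S_i + sum_{T_j} S_j)

    Diseases absent from the ontology fall back to a Kronecker-delta row
    (similar only to themselves) with a warning.
    """
    diseases = list(diseases)
    contribs = []
    missing = []
    for d in diseases:
        if d in ontology.nodes:
            contribs.append(semantic_contribution(ontology, d, theta))
        else:
            contribs.append(None)
            missing.append(d)
    if missing:
        warnings.warn(f"diseases missing from ontology, using delta rows: {missing}")
    n = len(diseases)
    M = np.eye(n)
    totals = [sum(c.values()) if c is not None else 1.0 for c in contribs]
    for i in range(n):
        for j in range(i + 1, n):
            ci, cj = contribs[i], contribs[j]
            if ci is None or cj is None:
                continue
            shared = set(ci) & set(cj)
            if shared:
                M[i, j] = M[j, i] = (
                    sum(ci[t] + cj[t] for t in shared) / (totals[i] + totals[j])
                )
    return SimilarityMatrix(ids=diseases, M=M)


# ---------------------------------------------------------------------------
# fusion and heterogeneous graph


def fuse_mean(m1: SimilarityMatrix, m2: SimilarityMatrix) -> SimilarityMatrix:
    """Elementwise mean of two similarity matrices over the same ids."""
    if m1.ids != m2.ids:
        raise ValueError("cannot fuse similarity matrices with different ids")
    return SimilarityMatrix(ids=list(m1.ids), M=(m1.M + m2.M) / 2.0)


def pirna_similarity(pirnas: Sequence[PirnaRecord], A: np.ndarray,
                     match: float = 2.0, mismatch: float = -1.0,
                     gap: float = -1.0,
                     seq_sim: SimilarityMatrix | None = None) -> SimilarityMatrix:
    """Fused piRNA similarity: mean of sequence and GIP similarity.

    ``seq_sim`` may be passed to reuse a precomputed sequence similarity
    (it does not depend on A, unlike the GIP part).
    """
    ids = [p.id for p in pirnas]
    if seq_sim is None:
        seq_sim = seq_similarity(pirnas, match, mismatch, gap)
    gip = gip_similarity(np.asarray(A), ids)
    return fuse_mean(seq_sim, gip)


def disease_similarity(ontology: DiseaseOntology, diseases: Sequence[str],
                       A: np.ndarray, theta: float = 0.5,
                       sem_sim: SimilarityMatrix | None = None) -> SimilarityMatrix:
    """Fused disease similarity: mean of semantic and GIP similarity."""
    if sem_sim is None:
        sem_sim = semantic_similarity(ontology, diseases, theta)
    gip = gip_similarity(np.asarray(A).T, list(diseases))
    return fuse_mean(sem_sim, gip)


def build_hetero(S_p: SimilarityMatrix, A: np.ndarray,
                 S_d: SimilarityMatrix) -> HeteroGraph:
    """Assemble the (m+n) x (m+n) heterogeneous adjacency block matrix."""
    A = np.asarray(A, dtype=float)
    m, n = len(S_p.ids), len(S_d.ids)
    if A.shape != (m, n):
        raise ValueError(f"A has shape {A.shape}, expected ({m}, {n})")
    A_h = np.block([[S_p.M, A], [A.T, S_d.M]])
    return HeteroGraph(A_h=A_h, m=m, n=n)
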