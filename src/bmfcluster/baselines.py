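"""Comparison methods: the Markov Cluster Algorithm and a spectral
quasi-clique method.

MCL simulates flow on the graph by alternating expansion (matrix power,
flow spreading) and inflation (entrywise power with column rescaling, flow
contraction); flow thickens inside natural clusters and evaporates between
them, and the inflation exponent controls cluster granularity.  The
spectral method eigendecomposes the adjacency matrix, takes the nodes
carrying the top alpha_sc% absolute entries of each leading eigenvector as
a candidate quasi-clique, and discards members connected to fewer than
beta_sc% of the rest of the candidate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.sparse.csgraph import connected_components

from .graph_io import ComplexSet, PPIGraph

logger = logging.getLogger(__name__)

__all__ = ["MCLParams", "SCParams", "mcl", "spectral_cluster"]


@dataclass(frozen=True)
class MCLParams:
    """MCL settings; inflation 1.8 is the most frequently used value and 2 is
    the classical expansion power.  ``prune_threshold`` zeroes tiny flow
    entries for tractability; set it to 0 for exact iteration."""

    inflation: float = 1.8
    expansion: int = 2
    max_iter: int = 200
    tol: float = 1e-8
    prune_threshold: float = 1e-5

    def __post_init__(self) -> None:
        if self.inflation <= 1:
            raise ValueError("inflation must exceed 1 for flow contraction")
        if self.expansion < 2:
            raise ValueError("expansion must be an integer >= 2")


@dataclass(frozen=True)
class SCParams:
    """Spectral quasi-clique settings.  ``alpha_sc`` and ``beta_sc`` are
    percentages; SC(10%, 1%) selects the top 10% absolute entries of each
    leading eigenvector and keeps nodes linked to at least 1% of the rest of
    their candidate cluster.  ``n_eigs`` is the number of leading
    eigenvectors; by default, the number of eigenvalues above the mean
    degree."""

    alpha_sc: float = 10.0
    beta_sc: float = 1.0
    n_eigs: int | None = None

    def __post_init__(self) -> None:
        if not 0 < self.alpha_sc <= 100:
            raise ValueError("alpha_sc must be a percentage in (0, 100]")
        if not 0 < self.beta_sc <= 100:
            raise ValueError("beta_sc must be a percentage in (0, 100]")


def _normalize_columns(m: np.ndarray) -> np.ndarray:
    s = m.sum(axis=0, keepdims=True)
    s[s == 0] = 1.0
    return m / s


def mcl(g: PPIGraph, p: MCLParams = MCLParams()) -> ComplexSet:
    """Markov clustering of a PPI graph into a partition of the node set.

    Self-loops of weight 1 are added before column normalization (standard
    practice; it damps the parity oscillation of flow on bipartite-like
    subgraphs).  Iteration stops when the matrix change drops below ``tol``
    or after ``max_iter`` rounds.  Clusters are the weakly connected
    components of the limit matrix's nonzero structure, which is a partition
    by construction; components are numbered by their lowest node index.
    """
    if g.n_nodes == 0:
        raise ValueError("empty graph")
    m = g.adjacency.astype(float) + np.eye(g.n_nodes)
    m = _normalize_columns(m)
    for _ in range(p.max_iter):
        expanded = np.linalg.matrix_power(m, p.expansion)
        inflated = expanded ** p.inflation
        if p.prune_threshold > 0:
            inflated[inflated < p.prune_threshold] = 0.0
        inflated = _normalize_columns(inflated)
        change = np.abs(inflated - m).max()
        m = inflated
        if change < p.tol:
            break
    else:
        logger.info("MCL stopped at max_iter without reaching its attractor")
    support = m > max(p.prune_threshold, 1e-12)
    n_comp, labels = connected_components(support, directed=True, connection="weak")
    order: dict[int, int] = {}
    for lab in labels:  # renumber components by first (lowest) node index
        order.setdefault(int(lab), len(order))
    groups: list[list[str]] = [[] for _ in range(n_comp)]
    for node, lab in zip(g.nodes, labels):
        groups[order[int(lab)]].append(node)
    return ComplexSet.from_sets(
        groups, names=[f"M{i + 1}" for i in range(n_comp)], partition=True
    )


def spectral_cluster(g: PPIGraph, p: SCParams = SCParams()) -> ComplexSet:
    """Quasi-cliques from the adjacency spectrum; clusters may overlap.

    For each of the leading eigenvectors, the candidate cluster holds the
    nodes with the floor(n * alpha_sc / 100) largest absolute entries; nodes
    adjacent to fewer than beta_sc% of the candidate's other members are
    then discarded in one pass.  Candidates that select no nodes are skipped
    with a log entry and empty results are dropped.
    """
    if g.n_nodes == 0:
        raise ValueError("empty graph")
    adj = g.adjacency.astype(float)
    evals, evecs = np.linalg.eigh(adj)
    idx = np.argsort(evals)[::-1]  # largest algebraic eigenvalues first
    evals, evecs = evals[idx], evecs[:, idx]
    if p.n_eigs is not None:
        n_eigs = min(p.n_eigs, g.n_nodes)
    else:
        mean_degree = adj.sum() / g.n_nodes
        n_eigs = max(1, int((evals > mean_degree).sum()))
    k_sel = int(g.n_nodes * p.alpha_sc / 100.0)
    clusters: list[list[str]] = []
    for e in range(n_eigs):
        if k_sel == 0:
            logger.info("alpha_sc=%s selects zero nodes; eigenvector %d skipped", p.alpha_sc, e)
            continue
        vec = np.abs(evecs[:, e])
        # top-k by absolute value; stable lowest-index order among ties
        candidate = np.sort(np.argsort(-vec, kind="stable")[:k_sel])
        if candidate.size > 1:
            links = adj[np.ix_(candidate, candidate)].sum(axis=1)
            required = p.beta_sc / 100.0 * (candidate.size - 1)
            candidate = candidate[links >= required]
        if candidate.size == 0:
            continue
        clusters.append([g.nodes[i] for i in candidate])
    return ComplexSet.from_sets(clusters, names=[f"SC{i + 1}" for i in range(len(clusters))])
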