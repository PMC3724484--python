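"""Generators for every input the experiments need.

Test graphs are built from complex catalogues by cliquifying each complex
(every two member proteins of a common complex are linked).  Perturbed
graphs X_{a,d} simulate the false positives and false negatives of
high-throughput interaction screens: a fraction ``a`` of the original edge
count is added as random non-edges and a fraction ``d`` is deleted from the
original edges.  Planted complex catalogues stand in for curated reference
sets so all benchmarks run without any database download, and the
expression-matrix generator plants constant non-overlapping biclusters in
Gaussian noise for the biclustering mode.

All generators are pure functions of their arguments, seed included.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .graph_io import ComplexSet, PPIGraph

__all__ = [
    "PerturbationSpec",
    "ExpressionMatrix",
    "BiclusterSet",
    "DEFAULT_PERTURBATION_GRID",
    "complexes_to_graph",
    "perturb_graph",
    "generate_planted_complexes",
    "generate_expression_biclusters",
    "binarize_expression",
]

#: Benchmark grid of (added, deleted) edge fractions, with 10 replicate
#: seeds per cell in the standard robustness protocol.
DEFAULT_PERTURBATION_GRID: tuple[tuple[float, float], ...] = tuple(
    (a, d)
    for a in (0.0, 0.05, 0.1, 0.2, 0.4, 0.8, 1.0)
    for d in (0.0, 0.05, 0.1, 0.2, 0.4, 0.8)
)


def _round_half_away(x: float) -> int:
    """round(x) with ties going away from zero, for reproducible edge counts."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass(frozen=True)
class PerturbationSpec:
    """Edge-alteration fractions relative to the original edge count."""

    a: float
    d: float
    seed: int

    def __post_init__(self) -> None:
        if self.a < 0:
            raise ValueError("addition fraction a must be >= 0")
        if not 0 <= self.d <= 1:
            raise ValueError("deletion fraction d must be in [0, 1]")

    def counts(self, n_edges: int) -> tuple[int, int]:
        """(edges to add, edges to delete) for a graph with ``n_edges``."""
        return _round_half_away(self.a * n_edges), _round_half_away(self.d * n_edges)


@dataclass(frozen=True)
class ExpressionMatrix:
    """A genes x conditions real matrix with row/column labels."""

    values: np.ndarray
    genes: tuple[str, ...]
    conditions: tuple[str, ...]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.genes), len(self.conditions)):
            raise ValueError("values shape does not match labels")
        if not np.isfinite(v).all():
            raise ValueError("expression values must be finite")
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class BiclusterSet:
    """Ground-truth or predicted biclusters as (row-set, column-set) pairs."""

    biclusters: tuple[tuple[frozenset[int], frozenset[int]], ...]

    def __post_init__(self) -> None:
        for rows, cols in self.biclusters:
            if not rows or not cols:
                raise ValueError("biclusters must have non-empty row and column sets")

    def __len__(self) -> int:
        return len(self.biclusters)

    def __iter__(self):
        return iter(self.biclusters)

    def row_sets(self) -> list[frozenset[int]]:
        return [rows for rows, _ in self.biclusters]


def complexes_to_graph(cs: ComplexSet) -> PPIGraph:
    """Build a test graph by linking the proteins within each complex.

    Nodes are the full universe of the complex set (background proteins
    become isolated nodes); two distinct proteins are adjacent iff they share
    at least one complex, so each complex induces a clique.
    """
    if len(cs) == 0 and not cs.background:
        raise ValueError("empty complex set")
    order: dict[str, None] = {}
    for _, members in cs:
        for v in sorted(members):
            order.setdefault(v)
    for v in sorted(cs.background):
        order.setdefault(v)
    nodes = tuple(order)
    index = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    adj = np.zeros((n, n), dtype=np.int8)
    for _, members in cs:
        idx = np.fromiter((index[v] for v in sorted(members)), dtype=int)
        adj[np.ix_(idx, idx)] = 1
    np.fill_diagonal(adj, 0)
    return PPIGraph(nodes, adj)


def perturb_graph(g: PPIGraph, spec: PerturbationSpec) -> PPIGraph:
    """Return X_{a,d}: the graph with round(a|E|) random non-edges added and
    round(d|E|) random original edges deleted.

    Additions are sampled without replacement from the ORIGINAL graph's
    non-adjacent off-diagonal pairs and deletions from the ORIGINAL edge set,
    so the two samples cannot collide and the output edge count is exactly
    |E| + round(a|E|) - round(d|E|).  The node set never changes.
    """
    n = g.n_nodes
    n_add, n_del = spec.counts(g.edge_count)
    iu, ju = np.triu_indices(n, k=1)
    upper = g.adjacency[iu, ju]
    edge_pos = np.flatnonzero(upper == 1)
    nonedge_pos = np.flatnonzero(upper == 0)
    if n_add > nonedge_pos.size:
        raise ValueError(
            f"cannot add {n_add} edges: only {nonedge_pos.size} non-edges available"
        )
    rng = np.random.default_rng(spec.seed)
    add = rng.choice(nonedge_pos, size=n_add, replace=False) if n_add else []
    delete = rng.choice(edge_pos, size=n_del, replace=False) if n_del else []
    new_upper = upper.copy()
    new_upper[add] = 1
    new_upper[delete] = 0
    adj = np.zeros((n, n), dtype=np.int8)
    adj[iu, ju] = new_upper
    adj += adj.T
    return PPIGraph(g.nodes, adj)


def generate_planted_complexes(
    k: int,
    size_range: tuple[int, int] = (3, 10),
    n_extra: int = 0,
    overlap_frac: float = 0.0,
    seed: int = 0,
) -> ComplexSet:
    """Plant ``k`` complexes with sizes uniform in ``size_range``.

    A fraction ``overlap_frac`` of the complexes (rounded) shares one member
    with a previously generated complex; ``n_extra`` background proteins
    belong to no complex and surface as isolated nodes in the test graph.
    Protein identifiers are YP0001, YP0002, ... in generation order.
    """
    lo, hi = size_range
    if lo < 2:
        raise ValueError("minimum complex size must be >= 2")
    if k < 1:
        raise ValueError("k must be >= 1")
    if not 0 <= overlap_frac <= 1:
        raise ValueError("overlap_frac must be in [0, 1]")
    rng = np.random.default_rng(seed)
    sizes = rng.integers(lo, hi + 1, size=k)
    n_overlapping = _round_half_away(overlap_frac * k)
    # the first complex cannot borrow a member from an earlier one
    overlap_flags = np.zeros(k, dtype=bool)
    if n_overlapping and k > 1:
        chosen = rng.choice(np.arange(1, k), size=min(n_overlapping, k - 1), replace=False)
        overlap_flags[chosen] = True
    counter = 0

    def fresh() -> str:
        nonlocal counter
        counter += 1
        return f"YP{counter:04d}"

    complexes: list[frozenset[str]] = []
    for i in range(k):
        members = {fresh() for _ in range(int(sizes[i]))}
        if overlap_flags[i]:
            donor = complexes[int(rng.integers(0, i))]
            shared = sorted(donor)[int(rng.integers(0, len(donor)))]
            # swap one fresh member for the shared one, keeping the size
            members.discard(sorted(members)[0])
            members.add(shared)
        complexes.append(frozenset(members))
    background = frozenset(fresh() for _ in range(n_extra))
    return ComplexSet.from_sets(
        complexes,
        names=[f"R{i + 1}" for i in range(k)],
        background=background,
    )


def generate_expression_biclusters(
    n_genes: int = 100,
    n_conds: int = 50,
    k: int = 10,
    signal: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[ExpressionMatrix, BiclusterSet]:
    """Plant ``k`` non-overlapping constant biclusters in Gaussian noise.

    Block ``i`` occupies rows [i*br, (i+1)*br) and columns [i*bc, (i+1)*bc)
    with br = n_genes // k and bc = n_conds // k, mirroring the constant,
    non-overlapping design of the standard synthetic biclustering benchmark.
    Background cells are N(0, noise_sd^2); bicluster cells are
    signal + N(0, noise_sd^2).  Returns the matrix and the ground truth.
    """
    br, bc = n_genes // k, n_conds // k
    if br < 1 or bc < 1:
        raise ValueError(f"{k} non-overlapping biclusters do not fit in the matrix")
    rng = np.random.default_rng(seed)
    values = rng.normal(0.0, noise_sd, size=(n_genes, n_conds)) if noise_sd > 0 else np.zeros((n_genes, n_conds))
    blocks = []
    for i in range(k):
        rows = range(i * br, (i + 1) * br)
        cols = range(i * bc, (i + 1) * bc)
        values[np.ix_(list(rows), list(cols))] += signal
        blocks.append((frozenset(rows), frozenset(cols)))
    genes = tuple(f"g{i + 1}" for i in range(n_genes))
    conds = tuple(f"c{j + 1}" for j in range(n_conds))
    return ExpressionMatrix(values, genes, conds), BiclusterSet(tuple(blocks))


def binarize_expression(x: ExpressionMatrix, threshold: float | None = None, signal: float = 1.0) -> np.ndarray:
    """Threshold an expression matrix to {0,1}: entry 1 iff value >= threshold.

    The default threshold is signal/2, the midpoint between the zero-mean
    background and the planted signal level; in the zero-noise limit this
    reproduces the exact block indicator matrix.
    """
    if threshold is None:
        threshold = signal / 2.0
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    return (x.values >= threshold).astype(np.int8)
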