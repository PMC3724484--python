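"""Independent brute-force oracles used by the test suite.

Everything here is written as directly as possible from the definitions —
nested loops, explicit enumeration — and shares no code path with the
package implementations it checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

from bmfcluster.graph_io import ComplexSet


# ---------------------------------------------------------------------------
# evaluation criteria by nested-loop summation


def brute_criteria(ref_sets: list[set], pred_sets: list[set]) -> dict:
    n = len(ref_sets)
    m = len(pred_sets)
    T = [[len(ref_sets[i] & pred_sets[j]) for j in range(m)] for i in range(n)]
    Ni = [len(s) for s in ref_sets]
    sn = sum(max(T[i]) for i in range(n)) / sum(Ni)
    col_total = sum(T[i][j] for i in range(n) for j in range(m))
    if col_total == 0:
        ppv = 0.0
    else:
        ppv = sum(max(T[i][j] for i in range(n)) for j in range(m)) / col_total
    acc = math.sqrt(sn * ppv)
    sep_sum = 0.0
    for i in range(n):
        for j in range(m):
            row = sum(T[i])
            col = sum(T[k][j] for k in range(n))
            if row > 0 and col > 0:
                sep_sum += (T[i][j] / row) * (T[i][j] / col)
    sep = math.sqrt((sep_sum / n) * (sep_sum / m))
    return {"sn": sn, "ppv": ppv, "acc": acc, "sep": sep}


def random_complex_sets(rng: np.random.Generator, n_proteins: int = 30):
    """A random (reference, prediction) pair over a shared protein pool;
    references may overlap, predictions partition a random subset."""
    proteins = [f"p{i}" for i in range(n_proteins)]
    n_ref = int(rng.integers(2, 7))
    ref = []
    for _ in range(n_ref):
        size = int(rng.integers(2, 8))
        ref.append(set(rng.choice(proteins, size=size, replace=False)))
    perm = list(rng.permutation(proteins))
    n_pred = int(rng.integers(2, 7))
    cuts = sorted(rng.choice(np.arange(1, n_proteins), size=n_pred - 1, replace=False))
    bounds = [0] + [int(c) for c in cuts] + [n_proteins]
    pred = [set(perm[a:b]) for a, b in zip(bounds, bounds[1:]) if b > a]
    return ref, pred


def to_complex_set(sets: list[set], prefix: str) -> ComplexSet:
    return ComplexSet.from_sets(sets, names=[f"{prefix}{i}" for i in range(len(sets))])


# ---------------------------------------------------------------------------
# harmony by direct summation, and its exhaustive maximization


def brute_harmony_symmetric(x: np.ndarray, assign, kappa: float = 1.0) -> float:
    """H for a symmetric model whose parameters are the kappa-smoothed
    estimates of the given assignment, empty clusters pruned; pairwise terms
    summed entry by entry."""
    assign = np.asarray(assign)
    labels = sorted(set(assign.tolist()))
    z = np.array([labels.index(a) for a in assign])
    m = len(labels)
    N = z.size
    counts = [int((z == j).sum()) for j in range(m)]
    alpha = [(c + kappa) / (N + m * kappa) for c in counts]
    P = N * (N - 1) // 2
    D = 0
    for r in range(N):
        for t in range(r + 1, N):
            recon = 1 if z[r] == z[t] else 0
            if recon != x[r, t]:
                D += 1
    eps = (D + kappa) / (P + 2 * kappa)
    h = sum(math.log(alpha[z[t]]) for t in range(N))
    h += D * math.log(eps) + (P - D) * math.log(1 - eps)
    if kappa != 1.0:
        h += (kappa - 1.0) * sum(math.log(a) for a in alpha)
    return h


def enumerate_max_harmony(x: np.ndarray, m_max: int, kappa: float = 1.0) -> float:
    """Exhaustive maximum of H over all assignments of N items into at most
    m_max clusters (first item pinned to cluster 0 by label symmetry)."""
    N = x.shape[0]
    best = -np.inf
    for rest in itertools.product(range(m_max), repeat=N - 1):
        h = brute_harmony_symmetric(x, (0,) + rest, kappa)
        if h > best:
            best = h
    return best


def planted_flip_instance(rng: np.random.Generator, n_max: int = 8, k_max: int = 3):
    """A small planted-partition adjacency with a few random pair flips."""
    N = int(rng.integers(5, n_max + 1))
    k = int(rng.integers(2, k_max + 1))
    z = rng.integers(0, k, N)
    x = (z[:, None] == z[None, :]).astype(np.int8)
    np.fill_diagonal(x, 0)
    iu, ju = np.triu_indices(N, 1)
    n_flip = int(rng.integers(0, 3))
    if n_flip:
        flip = rng.choice(iu.size, n_flip, replace=False)
        x[iu[flip], ju[flip]] ^= 1
        x[ju[flip], iu[flip]] ^= 1
    return x, z


# ---------------------------------------------------------------------------
# a minimal independent MCL (dense, no pruning)


def reference_mcl_partition(adj: np.ndarray, inflation: float, n_iter: int = 200) -> list[set]:
    m = adj.astype(float) + np.eye(adj.shape[0])
    m = m / m.sum(axis=0, keepdims=True)
    for _ in range(n_iter):
        m2 = m @ m
        m2 = m2**inflation
        m2 = m2 / m2.sum(axis=0, keepdims=True)
        if np.abs(m2 - m).max() < 1e-10:
            m = m2
            break
        m = m2
    support = m > 1e-9
    n = adj.shape[0]
    # union-find over the nonzero structure, treated as undirected
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(n):
            if support[i, j]:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[ri] = rj
    groups: dict[int, set] = {}
    for i in range(n):
        groups.setdefault(find(i), set()).add(i)
    return list(groups.values())
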