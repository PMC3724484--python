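"""Binary matrix factorization under Bayesian Ying-Yang harmony learning.

The model approximates a binary matrix X by a Boolean product of two binary
matrices, X ~ A Y, under a hard single-membership constraint: every column
of Y (item) and every row of A (feature) carries exactly one 1, so the
factorization is a co-clustering of rows and columns.  For an undirected
PPI network X is the symmetric zero-diagonal adjacency matrix and A is tied
to Y^T, so the clusters are disjoint protein groups sharing the same
interaction pattern — the predicted complexes.

Generative model.  Item t joins cluster j with probability alpha_j and
feature r with probability beta_j; each modeled entry of X is then an
independent Bernoulli flip of the Boolean reconstruction with a single
symmetric error rate eps (one noise channel for both false-positive and
false-negative interactions).  alpha and beta carry symmetric Dirichlet
priors with a shared concentration-style hyperparameter kappa, and eps a
matching Beta-style smoothing.  In symmetric mode only the unordered pairs
r < t are modeled: the diagonal is not an observation and modeling ordered
pairs would count every interaction twice.

Fitting maximizes the harmony functional

    H = sum_t ln alpha[c(t)] + sum_r ln beta[g(r)]
        + D ln eps + (P - D) ln(1 - eps)
        + (kappa - 1) (sum_j ln alpha_j + sum_j ln beta_j)

where c, g are the hard assignments, P the number of modeled entries and D
the number of entries on which X and the reconstruction disagree (the
feature and beta terms drop out in symmetric mode).  The alternation is:
a Yang-step reassigning every item (and feature) to its individually best
cluster against the start-of-step state; a Ying-step re-estimating
alpha, beta, eps with kappa-smoothing; and a Model-Selection-Step deleting
clusters left empty, which is how the cluster count falls automatically
from m_init to the supported number of clusters — maximizing H pays a prior
cost for clusters that explain nothing.  Because H is non-convex the fit is
restarted from several random initializations and the restart with the
highest harmony wins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import NamedTuple, Sequence

import numpy as np

from .graph_io import ComplexSet
from .synthetic_data import BiclusterSet

logger = logging.getLogger(__name__)

__all__ = [
    "BMFModel",
    "FitConfig",
    "FitTrace",
    "TraceRecord",
    "FitResult",
    "init_factorization",
    "reconstruction",
    "harmony",
    "yang_step",
    "ying_step",
    "model_selection_step",
    "fit",
    "fit_multi",
    "model_to_clusters",
    "model_to_biclusters",
]


class TraceRecord(NamedTuple):
    iteration: int
    harmony: float
    m: int
    n_reassigned: int


FitTrace = list[TraceRecord]


@dataclass
class BMFModel:
    """State of the factorization: hard assignments plus parameters.

    ``item_assign[t]`` is the cluster of column t (the single 1 in column t
    of Y); ``feat_assign[r]`` the cluster of row r (the single 1 in row r of
    A).  In symmetric mode ``feat_assign`` is None and A = Y^T by
    construction.  ``alpha``/``beta`` are the cluster probabilities for
    items/features, ``eps`` the Bernoulli flip rate of the reconstruction,
    ``kappa`` the shared smoothing hyperparameter and ``m`` the current
    cluster count (never grows during fitting).
    """

    item_assign: np.ndarray
    alpha: np.ndarray
    eps: float
    kappa: float
    m: int
    symmetric: bool
    feat_assign: np.ndarray | None = None
    beta: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.item_assign = np.asarray(self.item_assign, dtype=np.intp)
        self.alpha = np.asarray(self.alpha, dtype=float)
        if self.symmetric:
            if self.feat_assign is not None or self.beta is not None:
                raise ValueError("symmetric mode ties A = Y^T; no feature state")
        else:
            if self.feat_assign is None or self.beta is None:
                raise ValueError("rectangular mode needs feature assignments and beta")
            self.feat_assign = np.asarray(self.feat_assign, dtype=np.intp)
            self.beta = np.asarray(self.beta, dtype=float)
        self._validate()

    def _validate(self) -> None:
        if self.m < 1:
            raise ValueError("cluster count must be >= 1")
        if not 0 < self.eps < 1:
            raise ValueError("eps must lie in (0, 1)")
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")
        for name, vec, assign in (
            ("alpha", self.alpha, self.item_assign),
            ("beta", self.beta, self.feat_assign),
        ):
            if vec is None:
                continue
            if vec.shape != (self.m,):
                raise ValueError(f"{name} must have length m")
            if (vec < 0).any() or abs(vec.sum() - 1.0) > 1e-9:
                raise ValueError(f"{name} must be a probability vector")
            if assign.size and (assign.min() < 0 or assign.max() >= self.m):
                raise ValueError("assignment out of cluster range")

    # -- matrix views -------------------------------------------------------
    @property
    def n_items(self) -> int:
        return self.item_assign.size

    @property
    def n_features(self) -> int:
        return self.n_items if self.symmetric else self.feat_assign.size

    @property
    def Y(self) -> np.ndarray:
        """m x N indicator matrix; exactly one 1 per column."""
        y = np.zeros((self.m, self.n_items), dtype=np.int8)
        y[self.item_assign, np.arange(self.n_items)] = 1
        return y

    @property
    def A(self) -> np.ndarray:
        """n x m indicator matrix; exactly one 1 per row (= Y^T if symmetric)."""
        if self.symmetric:
            return self.Y.T
        a = np.zeros((self.n_features, self.m), dtype=np.int8)
        a[np.arange(self.n_features), self.feat_assign] = 1
        return a

    def item_counts(self) -> np.ndarray:
        return np.bincount(self.item_assign, minlength=self.m)

    def feat_counts(self) -> np.ndarray:
        assign = self.item_assign if self.symmetric else self.feat_assign
        return np.bincount(assign, minlength=self.m)

    def copy(self) -> "BMFModel":
        return replace(
            self,
            item_assign=self.item_assign.copy(),
            alpha=self.alpha.copy(),
            feat_assign=None if self.feat_assign is None else self.feat_assign.copy(),
            beta=None if self.beta is None else self.beta.copy(),
        )


@dataclass(frozen=True)
class FitConfig:
    """Fitting configuration.

    ``m_init`` is the starting (upper-bound) cluster count; 300 suits
    complex-catalogue-scale PPI graphs and 600 large real networks.
    ``kappa`` is the shared Dirichlet/Beta smoothing hyperparameter
    (default 1).  ``tol`` is a per-modeled-entry harmony tolerance: the
    alternation stops when |dH| < tol * (#modeled entries), when no
    assignment changes, or after ``max_iter`` cycles.
    """

    m_init: int = 300
    kappa: float = 1.0
    max_iter: int = 200
    tol: float = 1e-9
    seed: int = 0
    restarts: int = 1
    symmetric: bool = True

    def __post_init__(self) -> None:
        if self.m_init < 1:
            raise ValueError("m_init must be >= 1")
        if self.restarts < 1:
            raise ValueError("restarts must be >= 1")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")


class FitResult(NamedTuple):
    model: BMFModel
    trace: FitTrace
    seed: int
    harmony: float


# ---------------------------------------------------------------------------
# helpers

def _check_binary(x: np.ndarray, symmetric: bool) -> np.ndarray:
    x = np.asarray(x)
    if x.ndim != 2:
        raise ValueError("input must be a 2-D matrix")
    if not np.isin(x, (0, 1)).all():
        raise ValueError("input matrix must be binary")
    if symmetric:
        if x.shape[0] != x.shape[1]:
            raise ValueError("symmetric mode requires a square matrix")
        if (x != x.T).any():
            raise ValueError("symmetric mode requires a symmetric matrix")
        if np.diagonal(x).any():
            raise ValueError("symmetric mode requires a zero diagonal")
    return x.astype(np.float64, copy=False)


def _n_modeled(x: np.ndarray, symmetric: bool) -> int:
    n, N = x.shape
    return N * (N - 1) // 2 if symmetric else n * N


def _disagreements(x: np.ndarray, model: BMFModel) -> int:
    """Entries (unordered pairs in symmetric mode) where X differs from the
    Boolean reconstruction."""
    if model.symmetric:
        z = model.item_assign
        counts = model.item_counts()
        same_pairs = int((counts * (counts - 1) // 2).sum())
        iu, ju = np.triu_indices(z.size, k=1)
        ones = x[iu, ju] == 1
        agree_ones = int((z[iu][ones] == z[ju][ones]).sum())
        total_ones = int(ones.sum())
        return (same_pairs - agree_ones) + (total_ones - agree_ones)
    zr, zc = model.feat_assign, model.item_assign
    rc = model.feat_counts()
    cc = model.item_counts()
    recon_ones = int((rc * cc).sum())
    rows, cols = np.nonzero(x)
    agree_ones = int((zr[rows] == zc[cols]).sum())
    total_ones = rows.size
    return (recon_ones - agree_ones) + (total_ones - agree_ones)


def _smoothed_probs(counts: np.ndarray, kappa: float) -> np.ndarray:
    total = counts.sum() + counts.size * kappa
    return (counts + kappa) / total


# ---------------------------------------------------------------------------
# the algorithm's steps

def init_factorization(x: np.ndarray, cfg: FitConfig) -> BMFModel:
    """Random hard initialization: every item (and feature, in rectangular
    mode) joins one of m_init clusters uniformly; parameters are then set by
    the kappa-smoothed estimators from that assignment."""
    x = _check_binary(x, cfg.symmetric)
    rng = np.random.default_rng(cfg.seed)
    n, N = x.shape
    item_assign = rng.integers(0, cfg.m_init, size=N)
    if cfg.symmetric:
        model = BMFModel(
            item_assign=item_assign,
            alpha=np.full(cfg.m_init, 1.0 / cfg.m_init),
            eps=0.5,
            kappa=cfg.kappa,
            m=cfg.m_init,
            symmetric=True,
        )
    else:
        feat_assign = rng.integers(0, cfg.m_init, size=n)
        model = BMFModel(
            item_assign=item_assign,
            alpha=np.full(cfg.m_init, 1.0 / cfg.m_init),
            eps=0.5,
            kappa=cfg.kappa,
            m=cfg.m_init,
            symmetric=False,
            feat_assign=feat_assign,
            beta=np.full(cfg.m_init, 1.0 / cfg.m_init),
        )
    return ying_step(x, model)


def reconstruction(model: BMFModel) -> np.ndarray:
    """Boolean product A Y: entry (r, t) is 1 iff feature r and item t sit in
    the same cluster.  In symmetric mode the diagonal is reported as written
    (it is 1 within any cluster) but never enters the likelihood."""
    zr = model.item_assign if model.symmetric else model.feat_assign
    return (zr[:, None] == model.item_assign[None, :]).astype(np.int8)


def harmony(x: np.ndarray, model: BMFModel) -> float:
    """The harmony functional H evaluated at the model's hard assignments."""
    x = _check_binary(x, model.symmetric)
    n, N = x.shape
    if N != model.n_items or n != model.n_features:
        raise ValueError("matrix shape does not match model")
    alpha_used = model.alpha[model.item_assign]
    if (alpha_used <= 0).any():
        raise ValueError("assignment to a zero-probability cluster")
    h = float(np.log(alpha_used).sum())
    if not model.symmetric:
        beta_used = model.beta[model.feat_assign]
        if (beta_used <= 0).any():
            raise ValueError("assignment to a zero-probability cluster")
        h += float(np.log(beta_used).sum())
    P = _n_modeled(x, model.symmetric)
    D = _disagreements(x, model)
    h += D * np.log(model.eps) + (P - D) * np.log(1.0 - model.eps)
    if model.kappa != 1.0:
        prior = float(np.log(model.alpha).sum())
        if not model.symmetric:
            prior += float(np.log(model.beta).sum())
        h += (model.kappa - 1.0) * prior
    return h


def _yang_scores(
    x: np.ndarray, assign_other: np.ndarray, counts_other: np.ndarray,
    probs: np.ndarray, eps: float, exclude_self: bool,
) -> np.ndarray:
    """Per-item score of joining each cluster, up to an item-wise constant.

    For item t and cluster j the harmony contribution is
    ln p_j + e_tj ln(1-eps) + (k_j - e_tj) ln eps
           + (d_t - e_tj) ln eps + (M - k_j - d_t + e_tj) ln(1-eps)
    with k_j the size of cluster j on the opposite side (minus the item
    itself in symmetric mode), e_tj the item's links into cluster j, d_t its
    degree and M the number of opposite entries.  Dropping terms constant in
    j this is ln p_j + (k_j - 2 e_tj)(ln eps - ln(1-eps)).
    """
    m = probs.size
    one_hot = np.zeros((assign_other.size, m))
    one_hot[np.arange(assign_other.size), assign_other] = 1.0
    links = x @ one_hot  # (items x clusters) when x is passed transposed appropriately
    k = counts_other[None, :] - (one_hot if exclude_self else 0.0)
    with np.errstate(divide="ignore"):
        logp = np.log(probs)[None, :]
    return logp + (k - 2.0 * links) * (np.log(eps) - np.log1p(-eps))


def _sequential_sweep(x: np.ndarray, model: BMFModel) -> np.ndarray:
    """One deterministic coordinate-ascent sweep over the items of a
    symmetric model: items are visited in index order and each is moved to
    its best cluster given the CURRENT assignment of all others.

    In the symmetric model an item's score depends on the other items'
    clusters, so moving everyone at once against the stale state lets
    whole groups pile into the same cluster and the factorization collapse;
    one-at-a-time moves each weakly increase the harmony at fixed
    parameters, which makes the sweep stable.  Ties go to the lowest
    cluster index and the fixed visiting order keeps runs reproducible.
    """
    z = model.item_assign.copy()
    m = model.m
    N = z.size
    counts = np.bincount(z, minlength=m).astype(np.int64)
    one_hot = np.zeros((N, m))
    one_hot[np.arange(N), z] = 1.0
    links = x @ one_hot  # links[t, j]: edges from t into cluster j
    with np.errstate(divide="ignore"):
        log_alpha = np.log(model.alpha)
    gap = np.log(model.eps) - np.log1p(-model.eps)
    for t in range(N):
        k = counts.astype(float)
        k[z[t]] -= 1.0  # cluster size excluding the item itself
        j_new = int(np.argmax(log_alpha + (k - 2.0 * links[t]) * gap))
        j_old = int(z[t])
        if j_new != j_old:
            z[t] = j_new
            counts[j_old] -= 1
            counts[j_new] += 1
            nbr = np.flatnonzero(x[t])
            links[nbr, j_old] -= 1.0
            links[nbr, j_new] += 1.0
    return z


def yang_step(x: np.ndarray, model: BMFModel) -> BMFModel:
    """Reassign every item (and feature) to its individually best cluster;
    ties go to the lowest cluster index.

    Symmetric mode sweeps the items sequentially in index order, each move
    scored against the current state (see :func:`_sequential_sweep` for why
    a fully synchronous update is unstable here).  Rectangular mode updates
    all columns synchronously against the current rows and then all rows
    against the freshly updated columns; within a block the scores do not
    depend on each other, so the block update is exact coordinate ascent.
    """
    x = _check_binary(x, model.symmetric)
    out = model.copy()
    if model.symmetric:
        out.item_assign = _sequential_sweep(x, model)
    else:
        item_scores = _yang_scores(
            x.T, model.feat_assign, model.feat_counts(), model.alpha, model.eps,
            exclude_self=False,
        )
        out.item_assign = np.argmax(item_scores, axis=1)
        feat_scores = _yang_scores(
            x, out.item_assign, out.item_counts(), model.beta, model.eps,
            exclude_self=False,
        )
        out.feat_assign = np.argmax(feat_scores, axis=1)
    return out


def ying_step(x: np.ndarray, model: BMFModel) -> BMFModel:
    """Re-estimate the parameters from the current hard assignments with
    kappa-smoothing: alpha_j = (n_j + kappa)/(N + m kappa) (beta analogous)
    and eps = (D + kappa)/(P + 2 kappa).  With kappa > 0 everything stays in
    the open simplex; with kappa = 0 an empty cluster yields a zero that the
    next Model-Selection-Step removes."""
    x = _check_binary(x, model.symmetric)
    out = model.copy()
    out.alpha = _smoothed_probs(out.item_counts(), out.kappa)
    if not out.symmetric:
        out.beta = _smoothed_probs(out.feat_counts(), out.kappa)
    P = _n_modeled(x, out.symmetric)
    D = _disagreements(x, out)
    out.eps = float(np.clip((D + out.kappa) / (P + 2.0 * out.kappa), 1e-12, 1 - 1e-12))
    return out


def model_selection_step(model: BMFModel) -> BMFModel:
    """Delete clusters that hold nothing.

    Symmetric mode removes item-empty clusters; rectangular mode removes
    clusters empty of both items and features (a cluster still holding rows
    shapes the reconstruction and must survive).  Surviving assignments are
    untouched; alpha and beta are reindexed and renormalized and m drops.
    """
    item_counts = model.item_counts()
    if model.symmetric:
        keep = item_counts > 0
    else:
        keep = (item_counts > 0) | (model.feat_counts() > 0)
    if not keep.any():
        raise ValueError("degenerate model: pruning would remove the last cluster")
    if keep.all():
        return model
    new_index = np.cumsum(keep) - 1
    out = model.copy()
    out.m = int(keep.sum())
    out.item_assign = new_index[out.item_assign]
    out.alpha = out.alpha[keep]
    out.alpha = out.alpha / out.alpha.sum()
    if not out.symmetric:
        out.feat_assign = new_index[out.feat_assign]
        out.beta = out.beta[keep]
        out.beta = out.beta / out.beta.sum()
    return out


def _assignment_key(model: BMFModel) -> tuple:
    if model.symmetric:
        return tuple(model.item_assign.tolist())
    return tuple(model.item_assign.tolist()), tuple(model.feat_assign.tolist())


def fit(x: np.ndarray, cfg: FitConfig) -> FitResult:
    """Run the Ying-Yang alternation from one random initialization.

    Cycles Yang-step, Ying-step, Model-Selection-Step until the assignment
    is a fixed point, the harmony change falls below tol * (#modeled
    entries), or max_iter is reached.  Synchronous reassignment can in
    principle oscillate, so a cycle detector (hash of the assignment vector)
    terminates with the best-harmony state seen.
    """
    x = _check_binary(x, cfg.symmetric)
    model = init_factorization(x, cfg)
    model = model_selection_step(model)
    h = harmony(x, model)
    trace: FitTrace = [TraceRecord(0, h, model.m, 0)]
    tol = cfg.tol * _n_modeled(x, cfg.symmetric)
    best_model, best_h = model, h
    seen: set[tuple] = {_assignment_key(model)}
    for it in range(1, cfg.max_iter + 1):
        prev_items = model.item_assign
        prev_feats = None if cfg.symmetric else model.feat_assign
        model = yang_step(x, model)
        n_changed = int((model.item_assign != prev_items).sum())
        if prev_feats is not None:
            n_changed += int((model.feat_assign != prev_feats).sum())
        model = ying_step(x, model)
        model = model_selection_step(model)
        h_new = harmony(x, model)
        trace.append(TraceRecord(it, h_new, model.m, n_changed))
        if h_new >= best_h:
            best_model, best_h = model, h_new
        if n_changed == 0 or abs(h_new - h) < tol:
            break
        key = _assignment_key(model)
        if key in seen:
            logger.debug("assignment cycle detected at iteration %d", it)
            break
        seen.add(key)
        h = h_new
    else:
        logger.debug("max_iter reached without a fixed point")
    return FitResult(best_model, trace, cfg.seed, best_h)


def fit_multi(x: np.ndarray, cfg: FitConfig) -> tuple[BMFModel, list[FitResult]]:
    """Run ``cfg.restarts`` independent fits with seeds seed, seed+1, ... and
    return the harmony-best model plus every restart's result, so both the
    best-restart and the average-over-restarts evaluation protocols can be
    computed downstream."""
    results = []
    for r in range(cfg.restarts):
        results.append(fit(x, replace(cfg, seed=cfg.seed + r)))
    best = max(results, key=lambda res: res.harmony)
    return best.model, results


# ---------------------------------------------------------------------------
# exporting fitted models

def model_to_clusters(model: BMFModel, nodes: Sequence[str]) -> ComplexSet:
    """Turn a symmetric fit into a predicted complex set: one complex per
    surviving cluster, disjoint by the single-membership constraint."""
    if len(nodes) != model.n_items:
        raise ValueError("node list length does not match model")
    nodes = list(nodes)
    groups: list[list[str]] = [[] for _ in range(model.m)]
    for t, j in enumerate(model.item_assign):
        groups[j].append(nodes[t])
    return ComplexSet.from_sets(
        [g for g in groups if g],
        names=[f"B{j + 1}" for j, g in enumerate(groups) if g],
        partition=True,
    )


def model_to_biclusters(model: BMFModel) -> BiclusterSet:
    """Extract (row-set, column-set) biclusters from a rectangular fit:
    clusters holding at least one feature AND at least one item.  Clusters
    holding only background rows (or only columns) reconstruct nothing and
    are not biclusters."""
    if model.symmetric:
        raise ValueError("biclusters are defined for rectangular fits")
    pairs = []
    for j in range(model.m):
        rows = frozenset(np.flatnonzero(model.feat_assign == j).tolist())
        cols = frozenset(np.flatnonzero(model.item_assign == j).tolist())
        if rows and cols:
            pairs.append((rows, cols))
    return BiclusterSet(tuple(pairs))
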