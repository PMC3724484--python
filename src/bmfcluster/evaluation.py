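"""Complex-prediction criteria and the biclustering match score.

Given a reference catalogue of n complexes and a predicted set of m
clusters, let T_ij be the number of proteins shared by reference complex i
and predicted cluster j, and N_i the size of reference complex i.  The four
criteria are

    Sn  = sum_i max_j T_ij / sum_i N_i          (coverage of the reference)
    PPV = sum_j max_i T_ij / sum_j T_.j         (purity of the predictions)
    Acc = sqrt(Sn * PPV)                        (their geometric mean)
    Sep = sqrt(Sep_co * Sep_cl),  sep_ij = (T_ij / T_i.) * (T_ij / T_.j),
          Sep_co = sum_ij sep_ij / n,  Sep_cl = sum_ij sep_ij / m

with T_i. and T_.j the row and column sums of T.  Sn alone rewards one
giant cluster and PPV alone rewards singletons; Acc balances the two and
Sep measures bidirectional one-to-one correspondence.  Zero-marginal terms
(0/0) count as 0 throughout.

The biclustering match score is the mean, over one set of biclusters, of
the best Jaccard overlap of its gene (row) sets with the other set:
relevance scores the found biclusters against the truth, recovery the truth
against the found.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .graph_io import ComplexSet
from .synthetic_data import BiclusterSet

logger = logging.getLogger(__name__)

__all__ = [
    "ContingencyTable",
    "EvalReport",
    "contingency",
    "sensitivity",
    "ppv",
    "accuracy",
    "separation",
    "evaluate",
    "match_score",
]


@dataclass(frozen=True)
class ContingencyTable:
    """Shared-protein counts between reference and predicted complexes.

    ``row_sizes`` are the reference complex sizes N_i, which can exceed the
    row sums when reference proteins appear in no prediction; predicted
    proteins outside the reference universe likewise contribute nothing
    to T.
    """

    T: np.ndarray
    row_sizes: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.T, dtype=np.int64)
        sizes = np.asarray(self.row_sizes, dtype=np.int64)
        if t.ndim != 2 or sizes.shape != (t.shape[0],):
            raise ValueError("T must be 2-D with one size per reference row")
        if (t < 0).any():
            raise ValueError("overlap counts must be non-negative")
        if (t.max(axis=1, initial=0) > sizes).any():
            raise ValueError("an overlap exceeds its reference complex size")
        object.__setattr__(self, "T", t)
        object.__setattr__(self, "row_sizes", sizes)

    @property
    def n_ref(self) -> int:
        return self.T.shape[0]

    @property
    def n_pred(self) -> int:
        return self.T.shape[1]

    @property
    def row_sums(self) -> np.ndarray:
        return self.T.sum(axis=1)

    @property
    def col_sums(self) -> np.ndarray:
        return self.T.sum(axis=0)


@dataclass(frozen=True)
class EvalReport:
    sn: float
    ppv: float
    acc: float
    sep: float
    n_clusters: int

    def __post_init__(self) -> None:
        if abs(self.acc - math.sqrt(self.sn * self.ppv)) > 1e-12:
            raise ValueError("acc must be the geometric mean of sn and ppv")

    def as_dict(self) -> dict:
        return {
            "sn": self.sn,
            "ppv": self.ppv,
            "acc": self.acc,
            "sep": self.sep,
            "n_clusters": self.n_clusters,
        }


def contingency(reference: ComplexSet, predicted: ComplexSet) -> ContingencyTable:
    """Exact pairwise intersection counts between the two collections."""
    if len(reference) == 0 or len(predicted) == 0:
        raise ValueError("reference and prediction must be non-empty")
    ref_sets = reference.members()
    pred_sets = predicted.members()
    t = np.zeros((len(ref_sets), len(pred_sets)), dtype=np.int64)
    for i, r in enumerate(ref_sets):
        for j, p in enumerate(pred_sets):
            t[i, j] = len(r & p)
    sizes = np.fromiter((len(r) for r in ref_sets), dtype=np.int64)
    return ContingencyTable(t, sizes)


def sensitivity(ct: ContingencyTable) -> float:
    """Sn: fraction of reference proteins captured by each complex's
    best-covering prediction."""
    total = int(ct.row_sizes.sum())
    if total == 0:
        raise ValueError("reference complexes are empty")
    return float(ct.T.max(axis=1).sum() / total)


def ppv(ct: ContingencyTable) -> float:
    """PPV: fraction of the predictions' reference-annotated memberships that
    fall in each prediction's dominant reference complex; 0 when no
    prediction touches the reference."""
    denom = int(ct.col_sums.sum())
    if denom == 0:
        return 0.0
    return float(ct.T.max(axis=0).sum() / denom)


def accuracy(sn: float, ppv_value: float) -> float:
    """Geometric mean of sensitivity and positive predictive value."""
    if not (0 <= sn <= 1 and 0 <= ppv_value <= 1):
        raise ValueError("sn and ppv must lie in [0, 1]")
    return math.sqrt(sn * ppv_value)


def separation(ct: ContingencyTable) -> float:
    """Sep: geometric mean of the complex-wise and cluster-wise averages of
    the doubly normalized overlaps (T_ij / T_i.) * (T_ij / T_.j)."""
    t = ct.T.astype(float)
    row = ct.row_sums.astype(float)
    col = ct.col_sums.astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        sep_ij = np.where(
            (row[:, None] > 0) & (col[None, :] > 0),
            (t / np.where(row[:, None] == 0, 1, row[:, None]))
            * (t / np.where(col[None, :] == 0, 1, col[None, :])),
            0.0,
        )
    total = float(sep_ij.sum())
    return math.sqrt((total / ct.n_ref) * (total / ct.n_pred))


def evaluate(reference: ComplexSet, predicted: ComplexSet) -> EvalReport:
    """All four criteria for one prediction against one reference."""
    ct = contingency(reference, predicted)
    sn = sensitivity(ct)
    p = ppv(ct)
    return EvalReport(
        sn=sn,
        ppv=p,
        acc=accuracy(sn, p),
        sep=separation(ct),
        n_clusters=len(predicted),
    )


def match_score(first: BiclusterSet, second: BiclusterSet) -> float:
    """Mean best gene-dimension Jaccard score of ``first`` against ``second``.

    relevance  = match_score(found, truth)
    recovery   = match_score(truth, found)

    An empty set on either side scores 0 with a warning (nothing to match).
    """
    if len(first) == 0:
        logger.warning("scoring an empty bicluster set; score is 0")
        return 0.0
    if len(second) == 0:
        logger.warning("matching against an empty bicluster set; score is 0")
        return 0.0
    total = 0.0
    for rows1 in first.row_sets():
        best = max(
            len(rows1 & rows2) / len(rows1 | rows2) for rows2 in second.row_sets()
        )
        total += best
    return total / len(first)
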