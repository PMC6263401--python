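"""The learning stack: class balancing, CFS feature selection, weighted KNN.

All three pieces are implemented from first principles:

* ``balance_weights`` reweighs instances so each class carries the same
  total weight while the grand total is preserved (instance of class c
  gets N_total / (n_classes * N_c));
* correlation-based feature selection (CFS) scores a subset S of k
  features by the merit
      M_S = k * mean|r_cf| / sqrt(k + k (k-1) * mean|r_ff|),
  favouring features correlated with the class but not with each other,
  and searches subsets with a forward best-first search that stops after
  five consecutive non-improving expansions;
* the KNN classifier (default k = 9) min-max normalizes features to [0, 1]
  using training bounds only, and predicts by the larger summed instance
  weight among the k nearest training rows (Euclidean), rows tied with the
  k-th distance included. The weighted vote fraction for the positive
  class is the ranking score used for ROC/PRC curves.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "BalancedWeights",
    "balance_weights",
    "class_correlations",
    "cfs_merit",
    "cfs_select",
    "KnnModel",
    "knn_fit",
    "knn_predict",
]

POSITIVE = "high"


# --------------------------------------------------------------------------
# class balancing


@dataclass(frozen=True)
class BalancedWeights:
    weights: np.ndarray  # per instance
    per_class_total: dict[str, float]

    @property
    def grand_total(self) -> float:
        return float(self.weights.sum())


def balance_weights(labels) -> BalancedWeights:
    """Equalize the total weight of every class, preserving the grand total.

    Each instance of class c receives N_total / (n_classes * N_c), so every
    class's weight total is N_total / n_classes.
    """
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if (counts == 0).any() or len(classes) < 2:
        raise ValueError("balancing needs at least one instance of each of >= 2 classes")
    n_total = len(y)
    per_inst = {c: n_total / (len(classes) * nc) for c, nc in zip(classes, counts)}
    w = np.array([per_inst[c] for c in y], dtype=float)
    totals = {c: float(w[y == c].sum()) for c in classes}
    return BalancedWeights(w, totals)


# --------------------------------------------------------------------------
# correlation-based feature selection


def class_correlations(X: np.ndarray, y01: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Absolute Pearson feature-class and feature-feature correlations.

    The class is coded {0, 1}, so the feature-class term is the
    point-biserial correlation. Zero-variance columns get correlation 0.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y01, dtype=float)
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    sx = Xc.std(axis=0)
    sy = yc.std()
    ok = sx > 0
    r_cf = np.zeros(X.shape[1])
    if sy > 0:
        r_cf[ok] = np.abs((Xc[:, ok] * yc[:, None]).mean(axis=0) / (sx[ok] * sy))
    with np.errstate(invalid="ignore", divide="ignore"):
        C = np.corrcoef(X, rowvar=False)
    C = np.abs(np.nan_to_num(C, nan=0.0))
    np.fill_diagonal(C, 1.0)
    return r_cf, C


def cfs_merit(subset, r_cf: np.ndarray, r_ff: np.ndarray) -> float:
    """Merit of a feature subset: k*rcf / sqrt(k + k(k-1)*rff).

    ``rcf`` is the subset's mean absolute feature-class correlation, ``rff``
    the mean absolute correlation over its distinct feature pairs. The empty
    subset has merit 0 by convention.
    """
    idx = np.fromiter(subset, dtype=int)
    k = idx.size
    if k == 0:
        return 0.0
    rcf = float(r_cf[idx].mean())
    if k == 1:
        return rcf
    sub = r_ff[np.ix_(idx, idx)]
    rff = float((sub.sum() - k) / (k * (k - 1)))  # off-diagonal mean
    return k * rcf / np.sqrt(k + k * (k - 1) * rff)


def cfs_select(
    X: np.ndarray,
    y01: np.ndarray,
    stale_limit: int = 5,
) -> list[int]:
    """Forward best-first search over feature subsets maximizing CFS merit.

    Starts from the empty set; repeatedly expands the best unexpanded
    subset by adding one feature, and stops after ``stale_limit``
    consecutive expansions that fail to improve the best merit seen.
    Deterministic: ties break toward the lexicographically smaller subset.
    Zero-variance columns are excluded up front.
    """
    X = np.asarray(X, dtype=float)
    n_feat = X.shape[1]
    if n_feat < 1:
        raise ValueError("need at least one feature column")
    r_cf, r_ff = class_correlations(X, y01)
    usable = [j for j in range(n_feat) if X[:, j].std() > 0]

    start: frozenset[int] = frozenset()
    # heap of (-merit, sorted subset tuple); tuple ordering breaks merit ties
    heap: list[tuple[float, tuple[int, ...]]] = [(0.0, ())]
    seen = {start}
    best_subset, best_merit = (), 0.0
    stale = 0
    while heap and stale < stale_limit:
        neg_m, sub = heapq.heappop(heap)
        improved = False
        for j in usable:
            if j in sub:
                continue
            child = tuple(sorted(sub + (j,)))
            fz = frozenset(child)
            if fz in seen:
                continue
            seen.add(fz)
            m = cfs_merit(child, r_cf, r_ff)
            heapq.heappush(heap, (-m, child))
            if m > best_merit + 1e-12:
                best_merit, best_subset = m, child
                improved = True
        stale = 0 if improved else stale + 1
    return list(best_subset)


def cfs_select_table(table: pd.DataFrame, feature_cols: list[str]) -> list[str]:
    """CFS on a feature table; returns the selected column names."""
    X = table[feature_cols].to_numpy(dtype=float)
    y01 = (table["label"].to_numpy() == POSITIVE).astype(float)
    idx = cfs_select(X, y01)
    return [feature_cols[j] for j in idx]


# --------------------------------------------------------------------------
# k-nearest-neighbor classifier


@dataclass
class KnnModel:
    X: np.ndarray  # min-max normalized training matrix
    y01: np.ndarray  # 1 = positive class
    weights: np.ndarray
    mins: np.ndarray
    ranges: np.ndarray
    k: int = 9
    classes: tuple[str, str] = ("low", "high")  # index 0/1
    feature_names: list[str] = field(default_factory=list)


def _normalize(X, mins, ranges):
    return (X - mins) / ranges


def knn_fit(
    X: np.ndarray,
    labels,
    weights: np.ndarray | None = None,
    k: int = 9,
    feature_names: list[str] | None = None,
) -> KnnModel:
    """Store the training matrix min-max normalized to [0, 1] per feature."""
    X = np.asarray(X, dtype=float)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > X.shape[0]:
        raise ValueError(f"k={k} exceeds the {X.shape[0]} training instances")
    y = np.asarray(labels)
    y01 = (y == POSITIVE).astype(int)
    if weights is None:
        weights = np.ones(len(y))
    mins = X.min(axis=0)
    ranges = X.max(axis=0) - mins
    ranges[ranges == 0] = 1.0  # constant feature: maps to 0, carries no distance
    return KnnModel(
        _normalize(X, mins, ranges),
        y01,
        np.asarray(weights, dtype=float),
        mins,
        ranges,
        k,
        feature_names=list(feature_names or []),
    )


def knn_predict(model: KnnModel, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Predict classes and positive-class scores for query rows.

    The vote among the k nearest training rows (all rows tied with the k-th
    distance included) is weighted by instance weight; the score is the
    positive class's share of the included weight. A tied vote falls back
    to the single nearest neighbor's class.
    """
    Q = np.atleast_2d(np.asarray(Q, dtype=float))
    if Q.shape[1] != model.X.shape[1]:
        raise ValueError(
            f"query has {Q.shape[1]} features, model expects {model.X.shape[1]}"
        )
    Qn = _normalize(Q, model.mins, model.ranges)
    preds = np.empty(len(Qn), dtype=object)
    scores = np.empty(len(Qn), dtype=float)
    chunk = 256
    for lo in range(0, len(Qn), chunk):
        q = Qn[lo : lo + chunk]
        d2 = ((q[:, None, :] - model.X[None, :, :]) ** 2).sum(axis=2)
        for r in range(len(q)):
            row = d2[r]
            order = np.argsort(row, kind="stable")
            dk = row[order[model.k - 1]]
            included = np.flatnonzero(row <= dk + 1e-12)
            w = model.weights[included]
            pos = float(w[model.y01[included] == 1].sum())
            tot = float(w.sum())
            neg = tot - pos
            if pos > neg:
                cls = 1
            elif neg > pos:
                cls = 0
            else:  # tie: the single nearest neighbor decides
                cls = int(model.y01[order[0]])
            preds[lo + r] = model.classes[cls]
            scores[lo + r] = pos / tot if tot > 0 else 0.5
    return preds, scores
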