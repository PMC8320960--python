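"""Correlation-based feature selection (CFS) with best-first search.

CFS scores a feature subset S of size k by Hall's merit

    Merit(S) = k * mean(|r_cf|) / sqrt(k + k*(k-1) * mean(|r_ff|))

where ``r_cf`` are feature-class correlations of the members and ``r_ff``
their pairwise inter-correlations: subsets of features that each predict
the class but do not duplicate one another score highest.  Correlations
are point-biserial (feature vs binary class) and Pearson
(feature-feature), in absolute value - a continuous-data simplification
of the discretised symmetric-uncertainty variant; the
:class:`CorrelationTables` container isolates this choice so another
measure can be swapped in.

The search is bidirectional best-first: starting from the empty set,
repeatedly expand the best unexpanded subset by all single-feature
additions and deletions, stopping after ``stale_limit`` (default 5)
consecutive expansions that fail to improve the best merit.  Ties are
broken by feature order, so the search is fully deterministic.

The alpha/beta intersection protocol runs the selection independently on
the feature tables of unenhanced (alpha) and enhanced (beta) images and
keeps the features common to both - features that survive the enhancement
perturbation are the robust ones.
"""

from __future__ import annotations

import heapq
import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "CorrelationTables",
    "SelectionResult",
    "correlation_tables",
    "cfs_merit",
    "best_first",
    "exhaustive_search",
    "select_features",
    "intersect_protocol",
    "stability_check",
]


@dataclass
class CorrelationTables:
    """Absolute feature-class and feature-feature correlation magnitudes."""

    r_cf: np.ndarray  # (n,)
    r_ff: np.ndarray  # (n, n), symmetric, unit diagonal
    names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.r_cf = np.abs(np.asarray(self.r_cf, dtype=np.float64))
        self.r_ff = np.abs(np.asarray(self.r_ff, dtype=np.float64))
        n = self.r_cf.size
        if self.r_ff.shape != (n, n):
            raise ValueError("r_ff must be square and match r_cf length")
        if not self.names:
            self.names = [f"f{i:03d}" for i in range(n)]

    @property
    def n_features(self) -> int:
        return self.r_cf.size


@dataclass
class SelectionResult:
    subset: list[str]
    merit: float
    indices: list[int]
    fold_subsets: list[list[str]] = field(default_factory=list)


def _safe_corr(x: np.ndarray, y: np.ndarray) -> float:
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


def correlation_tables(
    X: np.ndarray | pd.DataFrame, y: np.ndarray
) -> CorrelationTables:
    """Point-biserial class correlations and Pearson inter-correlations."""
    if isinstance(X, pd.DataFrame):
        names = [str(c) for c in X.columns]
        X = X.to_numpy(dtype=np.float64)
    else:
        X = np.asarray(X, dtype=np.float64)
        names = []
    y = np.asarray(y, dtype=np.float64)
    n = X.shape[1]
    r_cf = np.array([_safe_corr(X[:, j], y) for j in range(n)])
    sd = X.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r_ff = np.corrcoef(X, rowvar=False)
    r_ff = np.where(np.isfinite(r_ff), r_ff, 0.0)
    r_ff[np.arange(n), np.arange(n)] = 1.0
    r_ff[sd == 0, :] = 0.0
    r_ff[:, sd == 0] = 0.0
    r_ff[np.arange(n), np.arange(n)] = 1.0
    return CorrelationTables(r_cf=r_cf, r_ff=r_ff, names=names)


def cfs_merit(subset, tables: CorrelationTables) -> float:
    """Hall's CFS merit of a subset of feature indices (empty set -> 0)."""
    idx = sorted(subset)
    k = len(idx)
    if k == 0:
        return 0.0
    rcf = float(tables.r_cf[idx].mean())
    if k == 1:
        return rcf
    sub = tables.r_ff[np.ix_(idx, idx)]
    rff = float((sub.sum() - k) / (k * (k - 1)))
    denom = k + k * (k - 1) * rff
    return k * rcf / np.sqrt(denom) if denom > 0 else 0.0


def best_first(
    tables: CorrelationTables, stale_limit: int = 5
) -> SelectionResult:
    """Bidirectional best-first subset search over the CFS merit.

    Expands the best open subset by every single-feature addition and
    deletion; terminates after ``stale_limit`` consecutive expansions that
    do not improve the best merit seen.  Deterministic: the open list is
    ordered by (merit, insertion order) and children are generated in
    feature order.
    """
    n = tables.n_features
    if n == 0:
        raise ValueError("need at least one feature")
    counter = itertools.count()
    start: frozenset[int] = frozenset()
    open_heap: list[tuple[float, int, frozenset[int]]] = [
        (-0.0, next(counter), start)
    ]
    visited: set[frozenset[int]] = {start}
    best_set, best_merit = start, 0.0
    stale = 0
    eps = 1e-12
    while open_heap and stale < stale_limit:
        _, _, node = heapq.heappop(open_heap)
        improved = False
        for j in range(n):
            child = node | {j} if j not in node else node - {j}
            if child in visited:
                continue
            visited.add(child)
            m = cfs_merit(child, tables)
            heapq.heappush(open_heap, (-m, next(counter), child))
            if m > best_merit + eps:
                best_merit, best_set = m, child
                improved = True
        stale = 0 if improved else stale + 1
    indices = sorted(best_set)
    return SelectionResult(
        subset=[tables.names[i] for i in indices],
        merit=best_merit,
        indices=indices,
    )


def exhaustive_search(tables: CorrelationTables) -> SelectionResult:
    """Merit-maximising subset by full enumeration (oracle; <= ~20 features)."""
    n = tables.n_features
    best_idx: tuple[int, ...] = ()
    best_merit = 0.0
    for k in range(1, n + 1):
        for combo in itertools.combinations(range(n), k):
            m = cfs_merit(combo, tables)
            if m > best_merit + 1e-12:
                best_merit, best_idx = m, combo
    return SelectionResult(
        subset=[tables.names[i] for i in best_idx],
        merit=best_merit,
        indices=list(best_idx),
    )


def _as_xy(table: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    """Split a feature table with a ``label`` column into X and binary y."""
    y = (table["label"].astype(str) == "malignant").to_numpy(dtype=float)
    X = table.drop(columns=[c for c in ("label", "id") if c in table.columns])
    return X, y


def select_features(table: pd.DataFrame, stale_limit: int = 5) -> SelectionResult:
    """CFS + best-first on a feature table (``label`` column required)."""
    X, y = _as_xy(table)
    return best_first(correlation_tables(X, y), stale_limit=stale_limit)


def intersect_protocol(
    table_unenhanced: pd.DataFrame,
    table_enhanced: pd.DataFrame,
    stale_limit: int = 5,
) -> SelectionResult:
    """Alpha/beta protocol: intersect the selections of both image variants.

    Falls back to the unenhanced (alpha) selection with a warning when the
    intersection is empty.
    """
    alpha = select_features(table_unenhanced, stale_limit=stale_limit)
    beta = select_features(table_enhanced, stale_limit=stale_limit)
    beta_set = set(beta.subset)
    common = [f for f in alpha.subset if f in beta_set]
    if not common:
        warnings.warn("alpha/beta intersection empty; falling back to alpha")
        common = alpha.subset
    X, y = _as_xy(table_unenhanced)
    names = [str(c) for c in X.columns]
    idx = [names.index(f) for f in common]
    merit = cfs_merit(idx, correlation_tables(X, y))
    return SelectionResult(subset=common, merit=merit, indices=idx)


def stability_check(
    table: pd.DataFrame, n_folds: int = 10, seed: int = 1, stale_limit: int = 5
) -> SelectionResult:
    """Per-fold selection stability under stratified cross-validation.

    Selection runs on each fold's *training* portion only.  The consensus
    subset holds the features selected in a majority of folds; the result
    carries every fold's subset for Jaccard-style stability reporting.
    """
    X, y = _as_xy(table)
    if np.unique(y).size < 2:
        raise ValueError("both classes must be present for stratified folds")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    fold_subsets: list[list[str]] = []
    votes: dict[str, int] = {}
    for train_idx, _ in skf.split(X, y):
        res = best_first(
            correlation_tables(X.iloc[train_idx], y[train_idx]),
            stale_limit=stale_limit,
        )
        fold_subsets.append(res.subset)
        for f in res.subset:
            votes[f] = votes.get(f, 0) + 1
    names = [str(c) for c in X.columns]
    consensus = [f for f in names if votes.get(f, 0) > n_folds // 2]
    idx = [names.index(f) for f in consensus]
    merit = cfs_merit(idx, correlation_tables(X, y)) if idx else 0.0
    return SelectionResult(
        subset=consensus, merit=merit, indices=idx, fold_subsets=fold_subsets
    )
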