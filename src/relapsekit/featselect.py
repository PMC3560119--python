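"""Correlation-based (CFS) and wrapper feature-subset selection.

CFS scores a subset S of k features by the merit

    merit_S = k * r_cf / sqrt(k + k (k - 1) * r_ff)

where ``r_cf`` is the mean feature–class correlation and ``r_ff`` the mean
pairwise feature–feature correlation over the subset.  Correlation is the
symmetrical uncertainty ``SU(X, Y) = 2 I(X; Y) / (H(X) + H(Y))`` computed
after equal-frequency discretization of numeric features, so nominal and
numeric columns are handled uniformly.

The wrapper selector scores candidate subsets by the stratified
cross-validated accuracy of the target classifier itself.  Both selectors
run a forward best-first search that stops after a fixed number of
non-improving expansions.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .containers import FeatureTable, NUMERIC, ValidationError, check_fields


@dataclass
class CfsConfig:
    discretization_bins: int = 4
    stall_limit: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        check_fields(
            self,
            discretization_bins=(lambda b: b >= 2, "need at least 2 bins"),
            stall_limit=(lambda s: s >= 1, "must be >= 1"),
        )


@dataclass
class WrapperConfig:
    inner_folds: int = 5
    stall_limit: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        check_fields(
            self,
            inner_folds=(lambda f: f >= 2, "need at least 2 inner folds"),
            stall_limit=(lambda s: s >= 1, "must be >= 1"),
        )


# -- symmetrical uncertainty -------------------------------------------------

def _discretize_column(col: pd.Series, kind: str, bins: int) -> np.ndarray:
    if kind == NUMERIC:
        binned = pd.qcut(col.rank(method="first"), q=bins,
                         labels=False, duplicates="drop")
        return binned.to_numpy()
    codes, _ = pd.factorize(col)
    return codes


def _entropy(codes: np.ndarray) -> float:
    counts = np.bincount(codes[codes >= 0])
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log2(p)).sum())


def _joint_entropy(a: np.ndarray, b: np.ndarray) -> float:
    joint = a.astype(np.int64) * (b.max() + 1) + b
    return _entropy(pd.factorize(joint)[0])


def symmetrical_uncertainty(a: np.ndarray, b: np.ndarray) -> float:
    """2 I(a;b) / (H(a) + H(b)); 0 when both are constant."""
    ha, hb = _entropy(a), _entropy(b)
    if ha + hb == 0:
        return 0.0
    mi = ha + hb - _joint_entropy(a, b)
    return max(0.0, 2.0 * mi / (ha + hb))


class _CorrelationCache:
    """Discretizes a table once and memoizes pairwise SU values."""

    def __init__(self, table: FeatureTable, bins: int):
        if table.label is None:
            raise ValidationError("CFS requires a labeled table")
        self.codes = {c: _discretize_column(table.data[c], table.kinds[c], bins)
                      for c in table.data.columns}
        self.codes["__class__"] = table.label.to_numpy(int)
        self._su: dict[tuple[str, str], float] = {}

    def su(self, a: str, b: str) -> float:
        key = (a, b) if a <= b else (b, a)
        if key not in self._su:
            self._su[key] = symmetrical_uncertainty(self.codes[a], self.codes[b])
        return self._su[key]

    def class_corr(self, feature: str) -> float:
        return self.su(feature, "__class__")


def cfs_merit(subset, table: FeatureTable,
              cfg: CfsConfig | None = None,
              _cache: _CorrelationCache | None = None) -> float:
    """CFS merit of a feature subset; the k=1 case is the class correlation."""
    subset = list(subset)
    if not subset:
        raise ValidationError("cfs_merit requires a nonempty subset")
    if cfg is None:
        cfg = CfsConfig()
    cache = _cache or _CorrelationCache(table, cfg.discretization_bins)
    k = len(subset)
    r_cf = np.mean([cache.class_corr(f) for f in subset])
    if k == 1:
        return float(r_cf)
    r_ff = np.mean([cache.su(a, b)
                    for i, a in enumerate(subset) for b in subset[i + 1:]])
    return float(k * r_cf / np.sqrt(k + k * (k - 1) * r_ff))


def _best_first(features: list[str], score_fn, stall_limit: int):
    """Forward best-first search over feature subsets.

    Maintains a priority queue of frontier subsets; expanding a subset adds
    each unused feature.  The search stops after ``stall_limit`` consecutive
    expansions that fail to improve on the best subset seen.  Ties prefer
    smaller subsets, then lexicographically earlier ones, making the result
    invariant to column order.
    """
    def key(subset):
        return (len(subset), sorted(subset))

    start = frozenset()
    best_subset, best_score = None, -np.inf
    counter = 0
    frontier = [(-0.0, 0, [])]      # (-score, tiebreak counter, subset list)
    scored = {start: 0.0}
    stall = 0
    while frontier and stall < stall_limit:
        _, _, subset = heapq.heappop(frontier)
        improved = False
        for f in features:
            if f in subset:
                continue
            candidate = frozenset(subset) | {f}
            if candidate in scored:
                continue
            score = score_fn(sorted(candidate))
            scored[candidate] = score
            counter += 1
            heapq.heappush(frontier, (-score, counter, sorted(candidate)))
            if score > best_score + 1e-12 or (
                    best_subset is not None
                    and abs(score - best_score) <= 1e-12
                    and key(candidate) < key(best_subset)):
                best_subset, best_score = sorted(candidate), score
                improved = True
        stall = 0 if improved else stall + 1
    return best_subset or [], best_score


def cfs_select(table: FeatureTable, cfg: CfsConfig | None = None) -> list[str]:
    """Best-first forward search maximizing the CFS merit."""
    if cfg is None:
        cfg = CfsConfig()
    if not len(table.data.columns):
        raise ValidationError("table has no features")
    cache = _CorrelationCache(table, cfg.discretization_bins)
    features = sorted(table.data.columns)
    subset, _ = _best_first(
        features, lambda s: cfs_merit(s, table, cfg, _cache=cache),
        cfg.stall_limit)
    return subset


def _cv_accuracy(table: FeatureTable, features: list[str], learner_factory,
                 cfg: WrapperConfig) -> float:
    """Stratified k-fold accuracy of the learner on a feature subset."""
    y = table.label.to_numpy(int)
    n_splits = min(cfg.inner_folds, np.bincount(y).min())
    if n_splits < 2:
        raise ValidationError("a class is too small for inner CV")
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True,
                          random_state=cfg.seed)
    sub = table.select_features(features)
    correct = 0
    for train_idx, test_idx in skf.split(np.zeros(len(y)), y):
        model = learner_factory()
        model.fit(sub.subset_rows(train_idx))
        pred = model.predict(sub.subset_rows(test_idx))
        correct += int((pred == y[test_idx]).sum())
    return correct / len(y)


def wrapper_select(table: FeatureTable, learner_factory,
                   cfg: WrapperConfig | None = None) -> list[str]:
    """Forward best-first search scored by inner-CV accuracy of the learner.

    The empty subset scores as the majority-class rate, so the returned
    subset never scores below that baseline.  Deterministic given the seed;
    ties break toward smaller subsets, then lexicographic order.
    """
    if cfg is None:
        cfg = WrapperConfig()
    if table.label is None:
        raise ValidationError("wrapper selection requires a labeled table")
    y = table.label.to_numpy(int)
    baseline = float(np.bincount(y).max() / len(y))
    features = sorted(table.data.columns)

    def score_fn(subset):
        try:
            return _cv_accuracy(table, list(subset), learner_factory, cfg)
        except ValidationError:
            raise
        except Exception as exc:  # learner failure: add subset context
            raise RuntimeError(
                f"learner failed on subset {sorted(subset)}: {exc}") from exc

    subset, score = _best_first(features, score_fn, cfg.stall_limit)
    if score < baseline:
        return []
    return subset
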