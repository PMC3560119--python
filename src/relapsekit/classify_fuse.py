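"""Per-source classifiers, evaluation schemes, metric panel and fusion.

Two reference learners are implemented natively — a mixed naive Bayes
(Laplace-smoothed nominal likelihoods, Gaussian numeric likelihoods) and an
information-gain decision tree — while any further learner (SVM, random
forest, neural network, ...) participates through the plugin contract: a
factory returning an object with ``fit(table)``, ``predict(table)`` and
``predict_scores(table)``.

Evaluation follows the study's two schemes: stratified 10-fold cross
validation (per-fold metrics averaged, dispersion as a standard deviation)
and leave-one-patient-out (metrics pooled over the held-out predictions).
Class rebalancing and feature selection, when requested, are re-fitted
inside each training fold so no synthetic copy of a test patient ever
reaches training.

The metric panel is sensitivity, specificity, accuracy, Cohen's kappa and
the rank-based (Mann–Whitney) AUC with midrank tie handling.  Per-source
decisions are merged by weighted majority voting; prediction ties resolve
to relapse, the costly error direction in relapse surveillance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold

from .containers import FeatureTable, NOMINAL, NUMERIC, ValidationError
from .preprocess import SmoteConfig, smote

_VAR_FLOOR = 1e-9


# -- native learners ---------------------------------------------------------

class NaiveBayes:
    """Class-conditional independence model over mixed features."""

    def __init__(self, laplace: float = 1.0):
        self.laplace = laplace

    def fit(self, table: FeatureTable) -> "NaiveBayes":
        if table.label is None:
            raise ValidationError("training requires labels")
        y = table.label.to_numpy(int)
        self.classes_ = np.unique(y)
        self.priors_ = {c: float((y == c).mean()) for c in self.classes_}
        self.kinds_ = dict(table.kinds)
        self.nominal_levels_ = {}
        self.nominal_loglik_ = {}
        self.gaussian_ = {}
        for col in table.data.columns:
            if table.kinds[col] == NOMINAL:
                levels = sorted(table.data[col].dropna().astype(str).unique())
                self.nominal_levels_[col] = levels
                tab = {}
                for c in self.classes_:
                    vals = table.data[col][y == c].astype(str)
                    counts = np.array([float((vals == v).sum()) for v in levels])
                    probs = (counts + self.laplace) / (
                        counts.sum() + self.laplace * len(levels))
                    tab[c] = dict(zip(levels, np.log(probs)))
                self.nominal_loglik_[col] = tab
            else:
                stats = {}
                for c in self.classes_:
                    vals = table.data[col][y == c].to_numpy(float)
                    stats[c] = (float(vals.mean()),
                                max(float(vals.var(ddof=0)), _VAR_FLOOR))
                self.gaussian_[col] = stats
        return self

    def _log_posterior(self, table: FeatureTable) -> np.ndarray:
        n = table.n_patients
        logp = np.zeros((n, len(self.classes_)))
        for j, c in enumerate(self.classes_):
            logp[:, j] = np.log(self.priors_[c]) if self.priors_[c] > 0 else -np.inf
            for col in table.data.columns:
                if self.kinds_[col] == NOMINAL:
                    tab = self.nominal_loglik_[col][c]
                    # unseen level: uniform fallback over known levels
                    fallback = -np.log(len(self.nominal_levels_[col]) or 1)
                    logp[:, j] += np.array([
                        tab.get(str(v), fallback)
                        for v in table.data[col]])
                else:
                    mu, var = self.gaussian_[col][c]
                    x = table.data[col].to_numpy(float)
                    logp[:, j] += -0.5 * (np.log(2 * np.pi * var)
                                          + (x - mu) ** 2 / var)
        return logp

    def predict_scores(self, table: FeatureTable) -> np.ndarray:
        """P(relapse = 1 | x) per patient."""
        logp = self._log_posterior(table)
        logp -= logp.max(axis=1, keepdims=True)
        p = np.exp(logp)
        p /= p.sum(axis=1, keepdims=True)
        if 1 in self.classes_:
            return p[:, list(self.classes_).index(1)]
        return np.zeros(table.n_patients)

    def predict(self, table: FeatureTable) -> np.ndarray:
        return (self.predict_scores(table) >= 0.5).astype(int)


class _TreeNode:
    __slots__ = ("feature", "kind", "threshold", "category", "left", "right",
                 "prob")

    def __init__(self, prob, feature=None, kind=None, threshold=None,
                 category=None, left=None, right=None):
        self.prob = prob
        self.feature = feature
        self.kind = kind
        self.threshold = threshold
        self.category = category
        self.left = left
        self.right = right


def _entropy_of(y: np.ndarray) -> float:
    if len(y) == 0:
        return 0.0
    p = np.bincount(y, minlength=2) / len(y)
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


class DecisionTree:
    """Binary recursive partitioning on information gain.

    Numeric features split on midpoint thresholds; nominal features on a
    one-category-versus-rest test.  Growth stops at pure nodes, at
    ``max_depth`` or when a split would create a leaf smaller than
    ``min_leaf``.
    """

    def __init__(self, max_depth: int = 10, min_leaf: int = 2):
        self.max_depth = max_depth
        self.min_leaf = min_leaf

    def fit(self, table: FeatureTable) -> "DecisionTree":
        if table.label is None:
            raise ValidationError("training requires labels")
        self.kinds_ = dict(table.kinds)
        y = table.label.to_numpy(int)
        self.root_ = self._grow(table.data, y, depth=0)
        return self

    def _leaf(self, y: np.ndarray) -> _TreeNode:
        return _TreeNode(prob=float(y.mean()) if len(y) else 0.5)

    def _grow(self, data: pd.DataFrame, y: np.ndarray, depth: int) -> _TreeNode:
        if depth >= self.max_depth or len(np.unique(y)) <= 1 \
                or len(y) < 2 * self.min_leaf:
            return self._leaf(y)
        parent_entropy = _entropy_of(y)
        best = None      # (gain, feature, kind, threshold/category, mask)
        for col in data.columns:
            if self.kinds_[col] == NUMERIC:
                x = data[col].to_numpy(float)
                order = np.unique(x)
                for a, b in zip(order[:-1], order[1:]):
                    thr = (a + b) / 2
                    mask = x <= thr
                    gain = self._gain(parent_entropy, y, mask)
                    if gain is not None and (best is None or gain > best[0]):
                        best = (gain, col, NUMERIC, thr, mask)
            else:
                x = data[col].astype(str).to_numpy()
                for cat in np.unique(x):
                    mask = x == cat
                    gain = self._gain(parent_entropy, y, mask)
                    if gain is not None and (best is None or gain > best[0]):
                        best = (gain, col, NOMINAL, cat, mask)
        if best is None or best[0] <= 1e-12:
            return self._leaf(y)
        _, col, kind, cut, mask = best
        node = _TreeNode(prob=float(y.mean()), feature=col, kind=kind,
                         threshold=cut if kind == NUMERIC else None,
                         category=cut if kind == NOMINAL else None)
        node.left = self._grow(data[mask], y[mask], depth + 1)
        node.right = self._grow(data[~mask], y[~mask], depth + 1)
        return node

    def _gain(self, parent_entropy, y, mask):
        n_left = int(mask.sum())
        n_right = len(y) - n_left
        if n_left < self.min_leaf or n_right < self.min_leaf:
            return None
        child = (n_left * _entropy_of(y[mask])
                 + n_right * _entropy_of(y[~mask])) / len(y)
        return parent_entropy - child

    def _route(self, node: _TreeNode, row: pd.Series) -> float:
        while node.feature is not None:
            if node.kind == NUMERIC:
                go_left = float(row[node.feature]) <= node.threshold
            else:
                go_left = str(row[node.feature]) == node.category
            node = node.left if go_left else node.right
        return node.prob

    def predict_scores(self, table: FeatureTable) -> np.ndarray:
        return np.array([self._route(self.root_, row)
                         for _, row in table.data.iterrows()])

    def predict(self, table: FeatureTable) -> np.ndarray:
        return (self.predict_scores(table) >= 0.5).astype(int)


class SklearnLearner:
    """Plugin adapter wrapping any sklearn-style estimator.

    Nominal features are one-hot encoded with the training levels; numeric
    features pass through.
    """

    def __init__(self, estimator):
        self.estimator = estimator

    def _encode(self, table: FeatureTable) -> np.ndarray:
        blocks = []
        for col in table.data.columns:
            if table.kinds[col] == NOMINAL:
                levels = self.levels_[col]
                vals = table.data[col].astype(str)
                blocks.append(np.column_stack([(vals == v).to_numpy(float)
                                               for v in levels]))
            else:
                blocks.append(table.data[col].to_numpy(float)[:, None])
        return np.hstack(blocks)

    def fit(self, table: FeatureTable) -> "SklearnLearner":
        self.levels_ = {c: sorted(table.data[c].dropna().astype(str).unique())
                        for c in table.nominal_columns()}
        self.estimator.fit(self._encode(table), table.label.to_numpy(int))
        return self

    def predict_scores(self, table: FeatureTable) -> np.ndarray:
        x = self._encode(table)
        if hasattr(self.estimator, "predict_proba"):
            proba = self.estimator.predict_proba(x)
            classes = list(self.estimator.classes_)
            return proba[:, classes.index(1)] if 1 in classes \
                else np.zeros(len(x))
        return self.estimator.predict(x).astype(float)

    def predict(self, table: FeatureTable) -> np.ndarray:
        return (self.predict_scores(table) >= 0.5).astype(int)


_KINDS = {"nb": NaiveBayes, "dt": DecisionTree}


def train_classifier(table: FeatureTable, kind: str = "nb", seed: int = 0,
                     plugin_factory=None):
    """Train a learner on a complete labeled table.

    ``kind`` is ``"nb"``, ``"dt"`` or ``"plugin"`` (with a factory).  The
    native learners are deterministic, so ``seed`` only matters for plugins
    that consume it.
    """
    if kind == "plugin":
        if plugin_factory is None:
            raise ValidationError("plugin kind requires plugin_factory")
        model = plugin_factory()
    elif kind in _KINDS:
        model = _KINDS[kind]()
    else:
        raise ValidationError(
            f"unknown learner kind {kind!r}; available: nb, dt, plugin")
    if table.data.isna().any().any():
        raise ValidationError("training table must be imputed first")
    return model.fit(table)


# -- metric panel ------------------------------------------------------------

@dataclass
class EvalReport:
    accuracy: float
    sensitivity: float
    specificity: float
    kappa: float
    auc: float
    n: int = 0
    dispersion: dict[str, float] = field(default_factory=dict)

    def as_row(self) -> dict[str, float]:
        return {"Acc": self.accuracy, "Se": self.sensitivity,
                "Sp": self.specificity, "Kappa": self.kappa, "AUC": self.auc}


def mann_whitney_auc(scores: np.ndarray, truth: np.ndarray) -> float:
    """AUC by the rank formulation with midrank tie handling."""
    n1 = int((truth == 1).sum())
    n0 = int((truth == 0).sum())
    if n1 == 0 or n0 == 0:
        return float("nan")
    ranks = rankdata(scores)
    return float((ranks[truth == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def compute_metrics(predicted, truth, scores=None) -> EvalReport:
    """Panel of Se/Sp/Acc/kappa/AUC from aligned predictions and labels."""
    predicted = np.asarray(predicted, dtype=int)
    truth = np.asarray(truth, dtype=int)
    if predicted.shape != truth.shape:
        raise ValidationError("predictions and labels differ in length")
    tp = int(((predicted == 1) & (truth == 1)).sum())
    fn = int(((predicted == 0) & (truth == 1)).sum())
    tn = int(((predicted == 0) & (truth == 0)).sum())
    fp = int(((predicted == 1) & (truth == 0)).sum())
    n = len(truth)
    acc = (tp + tn) / n if n else float("nan")
    se = tp / (tp + fn) if tp + fn else float("nan")
    sp = tn / (tn + fp) if tn + fp else float("nan")
    p_yes = ((tp + fp) / n) * ((tp + fn) / n)
    p_no = ((tn + fn) / n) * ((tn + fp) / n)
    pe = p_yes + p_no
    po = acc
    if abs(1 - pe) < 1e-12:
        kappa = 1.0 if abs(po - 1) < 1e-12 else 0.0
    else:
        kappa = (po - pe) / (1 - pe)
    if scores is None:
        scores = predicted.astype(float)
    auc = mann_whitney_auc(np.asarray(scores, dtype=float), truth)
    return EvalReport(acc, se, sp, kappa, auc, n=n)


# -- evaluation schemes ------------------------------------------------------

def _fit_fold(table, train_idx, learner_factory, smote_cfg, selector):
    train = table.subset_rows(train_idx)
    if smote_cfg is not None:
        train = smote(train, smote_cfg)
    features = table.feature_names
    if selector is not None:
        features = selector(train)
        train = train.select_features(features)
    model = learner_factory()
    model.fit(train)
    return model, features


def evaluate(table: FeatureTable, learner_factory, scheme: str = "cv10",
             seed: int = 0, smote_cfg: SmoteConfig | None = None,
             selector=None, n_folds: int = 10) -> EvalReport:
    """Evaluate a learner under stratified 10-fold CV or leave-one-out.

    ``learner_factory`` builds a fresh learner per fold; ``selector``, when
    given, maps a training FeatureTable to a feature list and is refit per
    fold, as is SMOTE.  ``cv10`` averages per-fold metrics and reports their
    standard deviation; ``lopo`` pools the held-out predictions.
    """
    if table.label is None:
        raise ValidationError("evaluation requires labels")
    y = table.label.to_numpy(int)
    if len(np.unique(y)) < 2:
        raise ValidationError("both classes must be present")
    if scheme == "cv10":
        n_splits = min(n_folds, int(np.bincount(y).min()))
        skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
        fold_reports = []
        for train_idx, test_idx in skf.split(np.zeros(len(y)), y):
            if len(np.unique(y[train_idx])) < 2:
                warnings.warn("training fold lost a class; fold skipped")
                continue
            model, features = _fit_fold(table, train_idx, learner_factory,
                                        smote_cfg, selector)
            test = table.subset_rows(test_idx).select_features(features)
            fold_reports.append(compute_metrics(
                model.predict(test), y[test_idx], model.predict_scores(test)))
        metrics = np.array([[r.accuracy, r.sensitivity, r.specificity,
                             r.kappa, r.auc] for r in fold_reports])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            means = np.nanmean(metrics, axis=0)
            stds = np.nanstd(metrics, axis=0, ddof=1)
        names = ["accuracy", "sensitivity", "specificity", "kappa", "auc"]
        return EvalReport(*means, n=len(y),
                          dispersion=dict(zip(names, stds)))
    if scheme == "lopo":
        preds = np.empty(len(y), dtype=int)
        scores = np.empty(len(y), dtype=float)
        valid = np.ones(len(y), dtype=bool)
        for i in range(len(y)):
            train_idx = np.array([j for j in range(len(y)) if j != i])
            if len(np.unique(y[train_idx])) < 2:
                warnings.warn(f"fold {i}: training lost a class; fold skipped")
                valid[i] = False
                continue
            model, features = _fit_fold(table, train_idx, learner_factory,
                                        smote_cfg, selector)
            test = table.subset_rows(np.array([i])).select_features(features)
            preds[i] = int(model.predict(test)[0])
            scores[i] = float(model.predict_scores(test)[0])
        report = compute_metrics(preds[valid], y[valid], scores[valid])
        return report
    raise ValidationError(f"unknown scheme {scheme!r} (cv10|lopo)")


# -- weighted majority fusion ------------------------------------------------

@dataclass
class FusionModel:
    """Normalized nonnegative weight per source and a fixed tie rule."""

    weights: dict[str, float]
    tie_rule: str = "relapse"

    def __post_init__(self) -> None:
        if not self.weights:
            raise ValidationError("fusion requires at least one source")
        if any(w < 0 for w in self.weights.values()):
            raise ValidationError("weights must be nonnegative")
        total = sum(self.weights.values())
        if total <= 0:
            raise ValidationError("weights must not all be zero")
        self.weights = {s: w / total for s, w in self.weights.items()}


def fit_fusion_weights(reports: dict[str, EvalReport],
                       mode: str = "accuracy") -> FusionModel:
    """Weights proportional to per-source accuracy, or uniform."""
    if mode == "uniform":
        return FusionModel({s: 1.0 for s in reports})
    if mode == "accuracy":
        return FusionModel({s: r.accuracy for s, r in reports.items()})
    raise ValidationError(f"unknown weighting mode {mode!r}")


def fuse(predictions: dict[str, pd.DataFrame],
         model: FusionModel) -> pd.DataFrame:
    """Merge per-source votes into a consensus prediction per patient.

    Each source frame is indexed by patient id with columns ``label`` (0/1)
    and optionally ``score``.  A patient absent from a source simply loses
    that source's weight (renormalized); a patient with no sources at all is
    an error.  The fused score is the relapse-voting weight share; ties go
    to relapse.
    """
    patients: list = []
    for df in predictions.values():
        for p in df.index:
            if p not in patients:
                patients.append(p)
    unknown = set(predictions) - set(model.weights)
    if unknown:
        raise ValidationError(f"sources without weights: {sorted(unknown)}")
    rows = []
    for p in patients:
        available = {s: df for s, df in predictions.items() if p in df.index}
        total = sum(model.weights[s] for s in available)
        if total <= 0:
            raise ValidationError(f"no source available for patient {p}")
        relapse_w = sum(model.weights[s]
                        for s, df in available.items()
                        if int(df.at[p, "label"]) == 1)
        score = relapse_w / total
        label = 1 if score >= 0.5 else 0      # tie resolves to relapse
        rows.append((p, label, score))
    return pd.DataFrame(rows, columns=["patient_id", "label", "score"]) \
        .set_index("patient_id")
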