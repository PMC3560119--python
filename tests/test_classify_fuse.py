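"""Native learners, evaluation schemes, metric panel and fusion."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from relapsekit.classify_fuse import (DecisionTree, EvalReport, FusionModel,
                                      NaiveBayes, SklearnLearner,
                                      compute_metrics, evaluate,
                                      fit_fusion_weights, fuse,
                                      mann_whitney_auc, train_classifier)
from relapsekit.containers import (FeatureTable, NOMINAL, NUMERIC,
                                   ValidationError)
from relapsekit.preprocess import SmoteConfig
from tests.conftest import make_table


def _table(columns, kinds, label):
    df = pd.DataFrame(columns, index=[f"P{i}" for i in range(len(label))])
    return FeatureTable(df, kinds, label=pd.Series(label, index=df.index))


class TestNaiveBayes:
    def test_laplace_smoothed_posterior_matches_hand_computation(self):
        """Counts (3/4 vs 1/4 positive), Laplace 1 -> P(c1 | pos) = 2/3."""
        t = _table({"f": ["pos", "pos", "pos", "neg",
                          "pos", "neg", "neg", "neg"]},
                   {"f": NOMINAL}, [1, 1, 1, 1, 0, 0, 0, 0])
        model = NaiveBayes(laplace=1.0).fit(t)
        query = _table({"f": ["pos"]}, {"f": NOMINAL}, [0])
        assert model.predict_scores(query)[0] == pytest.approx(2 / 3)

    def test_gaussian_numeric_likelihood_orders_correctly(self):
        t = _table({"x": [0.0, 0.1, -0.1, 5.0, 5.1, 4.9]},
                   {"x": NUMERIC}, [0, 0, 0, 1, 1, 1])
        model = NaiveBayes().fit(t)
        q = _table({"x": [4.8, 0.2]}, {"x": NUMERIC}, [1, 0])
        scores = model.predict_scores(q)
        assert scores[0] > 0.9 and scores[1] < 0.1


class TestDecisionTree:
    def test_pure_table_yields_single_leaf(self):
        t = _table({"x": [1.0, 2.0, 3.0]}, {"x": NUMERIC}, [1, 1, 1])
        model = DecisionTree().fit(t)
        assert model.root_.feature is None
        assert model.predict(t).tolist() == [1, 1, 1]

    def test_separable_numeric_split_found(self):
        t = _table({"x": [0.0, 1.0, 2.0, 10.0, 11.0, 12.0]},
                   {"x": NUMERIC}, [0, 0, 0, 1, 1, 1])
        model = DecisionTree(min_leaf=1).fit(t)
        assert model.predict(t).tolist() == [0, 0, 0, 1, 1, 1]

    def test_unknown_kind_lists_available(self):
        t = _table({"x": [0.0, 1.0]}, {"x": NUMERIC}, [0, 1])
        with pytest.raises(ValidationError, match="nb, dt, plugin"):
            train_classifier(t, kind="boost")


class TestMetrics:
    def test_confusion_panel_from_known_table(self):
        """TP 7, FN 4, TN 12, FP 0 -> Se 63.6%, Sp 100%."""
        truth = [1] * 11 + [0] * 12
        pred = [1] * 7 + [0] * 4 + [0] * 12
        rep = compute_metrics(pred, truth)
        assert rep.sensitivity * 100 == pytest.approx(63.6, abs=0.05)
        assert rep.specificity == pytest.approx(1.0)
        assert rep.accuracy == pytest.approx(19 / 23)

    def test_all_correct_gives_kappa_one(self):
        rep = compute_metrics([1, 0, 1, 0], [1, 0, 1, 0])
        assert rep.kappa == pytest.approx(1.0)
        assert rep.accuracy == 1.0

    def test_constant_scores_give_auc_half(self):
        rep = compute_metrics([1, 1, 0, 0], [1, 0, 1, 0],
                              scores=[0.5, 0.5, 0.5, 0.5])
        assert rep.auc == pytest.approx(0.5)

    @given(st.integers(0, 2 ** 20))
    def test_panel_matches_bruteforce_oracle(self, seed):
        """Se/Sp/Acc/kappa recomputed cell-by-cell; AUC by pair counting."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 30))
        truth = rng.integers(0, 2, n)
        if truth.min() == truth.max():
            truth[0] = 1 - truth[0]
        pred = rng.integers(0, 2, n)
        scores = rng.random(n).round(1)      # coarse grid to force ties
        rep = compute_metrics(pred, truth, scores)
        tp = sum(1 for p, t in zip(pred, truth) if p == 1 and t == 1)
        fn = sum(1 for p, t in zip(pred, truth) if p == 0 and t == 1)
        tn = sum(1 for p, t in zip(pred, truth) if p == 0 and t == 0)
        fp = sum(1 for p, t in zip(pred, truth) if p == 1 and t == 0)
        if tp + fn:
            assert rep.sensitivity == pytest.approx(tp / (tp + fn))
        if tn + fp:
            assert rep.specificity == pytest.approx(tn / (tn + fp))
        assert rep.accuracy == pytest.approx((tp + tn) / n)
        po = (tp + tn) / n
        pe = ((tp + fp) * (tp + fn) + (tn + fn) * (tn + fp)) / n ** 2
        if abs(1 - pe) > 1e-12:
            assert rep.kappa == pytest.approx((po - pe) / (1 - pe))
        # AUC oracle: all positive/negative pairs, ties count half
        pairs = wins = 0.0
        for i in range(n):
            for j in range(n):
                if truth[i] == 1 and truth[j] == 0:
                    pairs += 1
                    wins += (1.0 if scores[i] > scores[j]
                             else 0.5 if scores[i] == scores[j] else 0.0)
        assert rep.auc == pytest.approx(wins / pairs)


class _ConstantLearner:
    def __init__(self, label=0):
        self.label = label

    def fit(self, table):
        return self

    def predict(self, table):
        return np.full(table.n_patients, self.label, dtype=int)

    def predict_scores(self, table):
        return np.full(table.n_patients, float(self.label))


class _RecordingLearner(NaiveBayes):
    seen: list = []

    def fit(self, table):
        type(self).seen.append(set(table.patient_ids))
        return super().fit(table)


class TestEvaluate:
    def test_perfect_learner_tops_every_metric_under_both_schemes(self):
        t = make_table(n=30)
        t.data["marker"] = np.where(t.label == 1, 10.0, -10.0)
        for scheme in ("cv10", "lopo"):
            rep = evaluate(t, DecisionTree, scheme=scheme, seed=0)
            assert rep.accuracy == pytest.approx(1.0)
            assert rep.kappa == pytest.approx(1.0)
            assert rep.auc == pytest.approx(1.0)

    def test_constant_majority_learner_on_26_60_cohort(self):
        """All-majority predictions pool to accuracy 60/86 and kappa 0."""
        rng = np.random.default_rng(0)
        y = np.array([1] * 26 + [0] * 60)
        df = pd.DataFrame({"x": rng.normal(size=86)},
                          index=[f"P{i}" for i in range(86)])
        t = FeatureTable(df, {"x": NUMERIC},
                         label=pd.Series(y, index=df.index))
        rep = evaluate(t, _ConstantLearner, scheme="lopo", seed=0)
        assert rep.accuracy == pytest.approx(60 / 86)
        assert rep.kappa == pytest.approx(0.0)
        assert rep.n == 86       # lopo fold count = patient count

    def test_no_test_patient_leaks_into_training_fold(self):
        """With SMOTE active, held-out ids never appear in training folds."""
        t = make_table(n=24)
        _RecordingLearner.seen = []
        evaluate(t, _RecordingLearner, scheme="lopo", seed=0,
                 smote_cfg=SmoteConfig(k_neighbors=3, seed=0))
        all_ids = list(t.patient_ids)
        assert len(_RecordingLearner.seen) == 24
        for i, seen in enumerate(_RecordingLearner.seen):
            assert all_ids[i] not in seen


class TestFusion:
    def _preds(self, votes):
        return {s: pd.DataFrame({"label": v},
                                index=[f"P{i}" for i in range(len(v))])
                for s, v in votes.items()}

    def test_single_source_fusion_is_identity(self):
        preds = self._preds({"clinical": [1, 0, 1]})
        fused = fuse(preds, FusionModel({"clinical": 1.0}))
        assert fused.label.tolist() == [1, 0, 1]

    def test_three_of_four_equal_weight_votes(self):
        preds = self._preds({"a": [1], "b": [1], "c": [1], "d": [0]})
        fused = fuse(preds, FusionModel({s: 1.0 for s in "abcd"}))
        assert fused.label.iloc[0] == 1
        assert fused.score.iloc[0] == pytest.approx(0.75)

    def test_dominant_weight_overrides_majority(self):
        preds = self._preds({"a": [1], "b": [0], "c": [0], "d": [0]})
        fused = fuse(preds, FusionModel({"a": 0.7, "b": 0.1, "c": 0.1,
                                         "d": 0.1}))
        assert fused.label.iloc[0] == 1

    def test_exact_tie_resolves_to_relapse(self):
        preds = self._preds({"a": [1], "b": [0]})
        fused = fuse(preds, FusionModel({"a": 0.5, "b": 0.5}))
        assert fused.label.iloc[0] == 1

    @given(st.integers(0, 1000))
    def test_uniform_weights_equal_simple_majority_for_odd_sources(self, seed):
        rng = np.random.default_rng(seed)
        votes = {f"s{k}": rng.integers(0, 2, 5).tolist() for k in range(3)}
        preds = self._preds(votes)
        fused = fuse(preds, fit_fusion_weights(
            {s: EvalReport(1, 1, 1, 1, 1) for s in votes}, mode="uniform"))
        stacked = np.array(list(votes.values()))
        majority = (stacked.sum(axis=0) >= 2).astype(int)
        assert fused.label.tolist() == majority.tolist()

    def test_accuracy_weights_normalize(self):
        reports = {s: EvalReport(a, 0, 0, 0, 0)
                   for s, a in zip("abcd", (0.8, 0.8, 0.8, 0.95))}
        model = fit_fusion_weights(reports)
        assert sum(model.weights.values()) == pytest.approx(1.0)
        assert model.weights["a"] == pytest.approx(0.8 / 3.35)
        assert model.weights["d"] == pytest.approx(0.95 / 3.35)

    def test_missing_source_renormalizes_and_empty_errors(self):
        preds = {"a": pd.DataFrame({"label": [1]}, index=["P0"]),
                 "b": pd.DataFrame({"label": [0]}, index=["P1"])}
        fused = fuse(preds, FusionModel({"a": 0.9, "b": 0.1}))
        assert fused.loc["P0", "label"] == 1
        assert fused.loc["P1", "label"] == 0


class TestPlugin:
    def test_sklearn_adapter_round_trip(self):
        from sklearn.linear_model import LogisticRegression
        t = make_table(n=30)
        model = train_classifier(
            t, kind="plugin",
            plugin_factory=lambda: SklearnLearner(LogisticRegression()))
        scores = model.predict_scores(t)
        assert scores.shape == (30,)
        assert mann_whitney_auc(scores, t.label.to_numpy()) > 0.8
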