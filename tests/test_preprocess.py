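"""Cleaning, imputation, SMOTE and probe-QC contracts."""

import numpy as np
import pandas as pd
import pytest

from relapsekit.containers import (ExpressionMatrix, FeatureTable, NOMINAL,
                                   NUMERIC, ValidationError)
from relapsekit.preprocess import (SmoteConfig, drop_sparse_features, impute,
                                   filter_probes, smote)
from relapsekit.synthgen import CohortSpec, generate_baseline_cohort


def _table(columns, kinds, label=None):
    df = pd.DataFrame(columns)
    df.index = [f"P{i}" for i in range(len(df))]
    return FeatureTable(df, kinds,
                        None if label is None
                        else pd.Series(label, index=df.index))


class TestDropSparse:
    def test_sparsity_rule_is_strict(self):
        """>90% missing drops the column; exactly 90% retains it."""
        n = 100
        cols = {
            "over": [np.nan] * 91 + [1.0] * 9,
            "exact": [np.nan] * 90 + [1.0] * 10,
            "full": list(np.arange(float(n))),
        }
        t = _table(cols, {c: NUMERIC for c in cols})
        out = drop_sparse_features(t, 0.9)
        assert out.feature_names == ["exact", "full"]

    def test_idempotent_and_label_preserved(self):
        t = _table({"a": [np.nan, np.nan, 1.0], "b": [1.0, 2.0, 3.0]},
                   {"a": NUMERIC, "b": NUMERIC}, label=[0, 1, 0])
        once = drop_sparse_features(t, 0.5)
        twice = drop_sparse_features(once, 0.5)
        assert once.feature_names == twice.feature_names == ["b"]
        assert once.label.tolist() == [0, 1, 0]


class TestImpute:
    def test_mode_and_mean_fills(self):
        t = _table({"nom": ["a", "a", "b", None],
                    "num": [1.0, 2.0, 3.0, np.nan]},
                   {"nom": NOMINAL, "num": NUMERIC})
        out = impute(t)
        assert out.data.loc["P3", "nom"] == "a"
        assert out.data.loc["P3", "num"] == pytest.approx(2.0)
        # observed values untouched
        assert out.data.loc["P0", "num"] == 1.0

    def test_identity_on_complete_table_and_idempotence(self):
        t = _table({"num": [1.0, 2.0, np.nan]}, {"num": NUMERIC})
        once = impute(t)
        pd.testing.assert_frame_equal(impute(once).data, once.data)
        complete = _table({"num": [1.0, 2.0]}, {"num": NUMERIC})
        pd.testing.assert_frame_equal(impute(complete).data, complete.data)

    def test_all_missing_column_raises(self):
        t = _table({"num": [np.nan, np.nan]}, {"num": NUMERIC})
        with pytest.raises(ValidationError, match="drop_sparse_features"):
            impute(t)


class TestSmote:
    def _cohort(self, n_min=26, n_maj=60, seed=0):
        rng = np.random.default_rng(seed)
        y = np.array([1] * n_min + [0] * n_maj)
        df = pd.DataFrame({
            "x": rng.normal(y * 2.0, 1.0),
            "y": rng.normal(0, 1.0, size=len(y)),
            "cat": rng.choice(["u", "v"], size=len(y)),
        }, index=[f"P{i}" for i in range(len(y))])
        return FeatureTable(df, {"x": NUMERIC, "y": NUMERIC, "cat": NOMINAL},
                            label=pd.Series(y, index=df.index))

    def test_parity_appends_exactly_the_deficit(self):
        """26 vs 60 balanced to parity needs exactly 34 synthetic rows."""
        out = smote(self._cohort(), SmoteConfig(seed=1))
        counts = out.label.value_counts()
        assert counts[0] == counts[1] == 60
        assert out.synthetic.sum() == 34
        # originals unchanged, in place, unflagged
        assert not out.synthetic.iloc[:86].any()

    def test_synthetic_rows_are_convex_combinations(self):
        t = self._cohort(seed=3)
        out = smote(t, SmoteConfig(seed=3))
        minority = t.data[t.label == 1][["x", "y"]].to_numpy()
        synth = out.data[out.synthetic][["x", "y"]].to_numpy()
        for row in synth:
            residual = min(
                self._segment_residual(row, a, b)
                for i, a in enumerate(minority) for b in minority[i:])
            assert residual < 1e-9

    @staticmethod
    def _segment_residual(p, a, b):
        d = b - a
        denom = float(d @ d)
        lam = 0.0 if denom == 0 else float(np.clip((p - a) @ d / denom, 0, 1))
        return float(np.linalg.norm(a + lam * d - p))

    def test_degenerate_identical_minority_yields_copies(self):
        y = [1] * 6 + [0] * 10
        df = pd.DataFrame({"x": [5.0] * 6 + list(range(10)),
                           "y": [2.0] * 6 + list(range(10))},
                          index=[f"P{i}" for i in range(16)])
        t = FeatureTable(df, {"x": NUMERIC, "y": NUMERIC},
                         label=pd.Series(y, index=df.index))
        out = smote(t, SmoteConfig(k_neighbors=3, seed=0))
        synth = out.data[out.synthetic]
        assert (synth["x"] == 5.0).all() and (synth["y"] == 2.0).all()

    def test_nominal_values_copied_from_seed_sample(self):
        out = smote(self._cohort(seed=4), SmoteConfig(seed=4))
        assert set(out.data[out.synthetic]["cat"]) <= {"u", "v"}

    def test_small_minority_raises_with_advice(self):
        t = self._cohort(n_min=4, n_maj=10)
        with pytest.raises(ValidationError, match="smaller k"):
            smote(t, SmoteConfig(k_neighbors=5))


class TestFilterProbes:
    def _matrix(self):
        probes = [f"p{i}" for i in range(10)]
        values = pd.DataFrame(np.arange(20.0).reshape(10, 2), index=probes,
                              columns=["s1", "s2"])
        ann = pd.DataFrame({"is_control": [True, True] + [False] * 8,
                            "duplicate_of": ["", "", "", "p4", "", "", "", "",
                                             "", ""],
                            "quality_flag": [False] * 9 + [True]},
                           index=probes)
        return ExpressionMatrix(values, ann)

    def test_flag_arithmetic(self):
        """2 control + 1 duplicate + 1 low-quality out of 10 leaves 6."""
        out = filter_probes(self._matrix())
        assert out.n_probes == 6
        # first occurrence of the p3/p4 duplicate group is kept
        assert "p3" in out.probe_ids and "p4" not in out.probe_ids

    def test_full_scale_qc_retains_33491(self):
        """Default probe-flag fractions reduce 45,015 probes to 33,491."""
        spec = CohortSpec(n_patients=4, n_relapsers=2, n_clinical=2,
                          n_imaging=2, missing_heavy_features=0, seed=0)
        _, _, tissue, _, _ = generate_baseline_cohort(spec)
        assert tissue.n_probes == 45015
        assert filter_probes(tissue).n_probes == 33491

    def test_identity_on_clean_annotation(self):
        m = self._matrix()
        ann = m.annotation.copy()
        ann[:] = False
        ann["duplicate_of"] = ""
        out = filter_probes(ExpressionMatrix(m.values, ann))
        assert list(out.probe_ids) == list(m.probe_ids)

    def test_output_has_no_flags_or_duplicate_groups(self):
        out = filter_probes(self._matrix())
        assert not out.annotation.is_control.any()
        assert not out.annotation.quality_flag.any()
        groups = [d or p for p, d in out.annotation.duplicate_of.items()]
        assert len(groups) == len(set(groups))

    def test_missing_annotation_raises(self):
        with pytest.raises(ValidationError, match="annotation"):
            filter_probes(ExpressionMatrix(self._matrix().values, None))
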