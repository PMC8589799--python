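import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar

from oracles import mcnemar_exact_enumeration

from longiperf.evaluate import (
    CVConfig,
    MetricError,
    binary_metrics,
    collapse_confusion,
    confusion_from_labels,
    mcnemar,
    repeated_cv,
    run_comparison_suite,
    select_feature_columns,
)


def _feature_frame(rng, labels, n_feat=6):
    cols = (
        [f"TP1_ZrBV_F{i}" for i in range(n_feat // 2)]
        + [f"TP1_T2_F{i}" for i in range(n_feat - n_feat // 2)]
    )
    X = pd.DataFrame(
        rng.normal(size=(len(labels), n_feat)),
        columns=cols,
        index=[f"s{i}" for i in range(len(labels))],
    )
    return X, pd.Series(labels, index=X.index)


class _OracleStub:
    """Classifier stub that reads the true label off the DataFrame index."""

    def __init__(self, truth):
        self.truth = truth

    def fit(self, X, y):
        return self

    def predict(self, X):
        return self.truth.loc[X.index].to_numpy(dtype=object)


class _ConstantStub:
    def __init__(self, label):
        self.label = label

    def fit(self, X, y):
        return self

    def predict(self, X):
        return np.full(len(X), self.label, dtype=object)


class _RecordingStub(_ConstantStub):
    """Asserts the model never sees its own test fold during fit."""

    def __init__(self):
        super().__init__("PD")
        self.train_idx = None

    def fit(self, X, y):
        self.train_idx = set(X.index)
        return self

    def predict(self, X):
        assert self.train_idx is not None
        assert self.train_idx.isdisjoint(set(X.index)), "test fold leaked into fit"
        return super().predict(X)


class TestRepeatedCV:
    def test_oracle_classifier_has_zero_error(self, rng):
        labels = ["PD"] * 6 + ["PsP"] * 5 + ["SD"] * 5
        X, y = _feature_frame(rng, labels)
        res = repeated_cv(
            X, y, CVConfig(n_iterations=5, seed=0),
            model_factory=lambda seed: _OracleStub(y),
        )
        assert res.iteration_errors == [0.0] * 5
        assert res.median_error == res.mean_error == 0.0

    def test_constant_prediction_error_is_exact_fraction(self, rng):
        labels = ["PD"] * 12 + ["PsP"] * 4 + ["SD"] * 4
        X, y = _feature_frame(rng, labels)
        res = repeated_cv(
            X, y, CVConfig(n_iterations=4, seed=1),
            model_factory=lambda seed: _ConstantStub("PD"),
        )
        assert res.iteration_errors == [0.40] * 4

    def test_folds_never_leak_into_fit(self, rng):
        labels = ["PD"] * 8 + ["PsP"] * 4 + ["SD"] * 4
        X, y = _feature_frame(rng, labels)
        repeated_cv(
            X, y, CVConfig(n_iterations=3, seed=2),
            model_factory=lambda seed: _RecordingStub(),
        )

    def test_reproducible_for_fixed_seed(self, small_features):
        from conftest import split_xy

        X, y = split_xy(small_features)
        cfg = CVConfig(n_iterations=2, seed=3)
        r1 = repeated_cv(X, y, cfg)
        r2 = repeated_cv(X, y, cfg)
        assert r1.iteration_errors == r2.iteration_errors
        pd.testing.assert_frame_equal(r1.confusion, r2.confusion)

    def test_pooled_confusion_implies_mean_error(self, rng):
        labels = ["PD"] * 6 + ["PsP"] * 4 + ["SD"] * 4
        X, y = _feature_frame(rng, labels)
        res = repeated_cv(
            X, y, CVConfig(n_iterations=6, seed=4),
            model_factory=lambda seed: _ConstantStub("PsP"),
        )
        total = res.confusion.to_numpy().sum()
        correct = np.trace(res.confusion.to_numpy())
        assert res.mean_error == pytest.approx(1 - correct / total)

    def test_small_class_rejected(self, rng):
        labels = ["PD"] * 10 + ["PsP"] * 1 + ["SD"] * 5
        X, y = _feature_frame(rng, labels)
        with pytest.raises(ValueError, match="fewer than n_folds"):
            repeated_cv(X, y, CVConfig(n_iterations=1))


class TestFeatureSelection:
    def test_modality_and_region_filters(self, tiny_features):
        cols_p = select_feature_columns(tiny_features, "perfusion")
        cols_s = select_feature_columns(tiny_features, "structural")
        cols_c = select_feature_columns(tiny_features, "combined")
        assert all(c.split("_")[1] in ("ZrBV", "ZrBF") for c in cols_p)
        assert all(c.split("_")[1] in ("T1", "T1Gad", "T2", "FLAIR") for c in cols_s)
        assert set(cols_c) == set(cols_p) | set(cols_s)
        tp1 = select_feature_columns(tiny_features, "combined", ("TP1",))
        assert all(c.startswith("TP1_") for c in tp1)
        assert len(tp1) == 6 * 18


class TestBinaryMetrics:
    def test_group_sensitivity_reproduced(self):
        # 37 positives split 32 detected / 5 missed -> 86.49% sensitivity
        cm = pd.DataFrame(
            [[32, 5], [7, 20]], index=["PD", "rest"], columns=["PD", "rest"]
        )
        m = binary_metrics(cm)
        assert m["sensitivity"] == 86.49

    def test_perfect_sensitivity(self):
        cm = pd.DataFrame(
            [[7, 0], [3, 10]], index=["PD", "rest"], columns=["PD", "rest"]
        )
        assert binary_metrics(cm)["sensitivity"] == 100.0

    def test_all_cells_equal_gives_fifty_percent(self):
        cm = pd.DataFrame(
            [[4, 4], [4, 4]], index=["PD", "rest"], columns=["PD", "rest"]
        )
        m = binary_metrics(cm)
        assert m["sensitivity"] == m["specificity"] == 50.0

    def test_three_class_collapse_and_accuracy_identity(self):
        cm3 = confusion_from_labels(
            ["PD", "PD", "PsP", "PsP", "SD", "SD"],
            ["PD", "PsP", "PsP", "PD", "SD", "SD"],
        )
        cm2 = collapse_confusion(cm3, "PD")
        m = binary_metrics(cm3)
        P = cm2.iloc[0].sum()
        N = cm2.iloc[1].sum()
        acc = (m["sensitivity"] * P + m["specificity"] * N) / (P + N)
        assert m["accuracy"] == pytest.approx(acc, abs=0.01)

    def test_zero_denominator_raises_named_error(self):
        cm = pd.DataFrame(
            [[0, 0], [2, 3]], index=["PD", "rest"], columns=["PD", "rest"]
        )
        with pytest.raises(MetricError, match="sensitivity"):
            binary_metrics(cm)


def _labels_with_discordance(b, c, n=40):
    """Truth plus model/rater labels realising exactly b and c."""
    truth = ["PD"] * n
    model = ["PD"] * n
    rater = ["PD"] * n
    for i in range(b):
        rater[i] = "SD"  # model right, rater wrong
    for i in range(b, b + c):
        model[i] = "SD"
    return model, rater, truth


class TestMcNemar:
    def test_no_discordance_gives_p_one(self):
        m, r, t = _labels_with_discordance(0, 0)
        res = mcnemar(m, r, t)
        assert res.p_value == 1.0 and res.b == res.c == 0

    def test_hand_computed_binomial_tails(self):
        res = mcnemar(*_labels_with_discordance(5, 0))
        assert res.p_value == pytest.approx(0.0625)
        res = mcnemar(*_labels_with_discordance(1, 9))
        assert res.p_value == pytest.approx(0.021484375)

    @pytest.mark.parametrize("b,c", [(0, 3), (2, 2), (1, 6), (4, 8), (6, 6)])
    def test_exact_p_matches_full_enumeration(self, b, c):
        res = mcnemar(*_labels_with_discordance(b, c))
        assert res.method == "exact"
        assert res.p_value == pytest.approx(mcnemar_exact_enumeration(b, c))

    @pytest.mark.parametrize("b,c", [(5, 2), (0, 9), (3, 3)])
    def test_exact_p_matches_statsmodels(self, b, c):
        res = mcnemar(*_labels_with_discordance(b, c))
        table = [[0, b], [c, 0]]
        sm = sm_mcnemar(table, exact=True)
        assert res.p_value == pytest.approx(float(sm.pvalue))

    def test_chi_square_with_continuity_correction_above_threshold(self):
        res = mcnemar(*_labels_with_discordance(20, 10, n=60))
        assert res.method == "chi2_cc"
        assert res.statistic == pytest.approx((abs(20 - 10) - 1) ** 2 / 30)
        sm = sm_mcnemar([[0, 20], [10, 0]], exact=False, correction=True)
        assert res.p_value == pytest.approx(float(sm.pvalue))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            mcnemar(["PD"], ["PD", "SD"], ["PD", "SD"])


class TestComparisonSuite:
    def test_grid_bookkeeping_and_report_shape(self, rng, tmp_path):
        labels = ["PD"] * 6 + ["PsP"] * 4 + ["SD"] * 4
        cols = [
            f"{region}_{m}_F{i}"
            for region in ("TP1", "TP2", "Diff21")
            for m in ("ZrBV", "T2")
            for i in range(2)
        ]
        X = pd.DataFrame(
            rng.normal(size=(len(labels), len(cols))),
            columns=cols,
            index=[f"s{i}" for i in range(len(labels))],
        )
        table = X.copy()
        table.insert(0, "class_label", labels)
        table.insert(1, "rater_label", labels)
        report = run_comparison_suite(
            table,
            CVConfig(n_iterations=2, seed=0),
            timepoint_sets={
                "TP1": ("TP1",),
                "TP1+TP2": ("TP1", "TP2"),
                "all": None,
            },
            model_factory=lambda seed: _ConstantStub("PD"),
            out_dir=tmp_path,
        )
        assert len(report["runs"]) == 9  # 3 feature sets x 3 time-point sets
        assert (tmp_path / "report.json").exists()
        assert (tmp_path / "error_rates.svg").exists()
        assert "mcnemar_model_vs_rater" in report
        assert report["rater_metrics"]["accuracy_3class"] == 100.0
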