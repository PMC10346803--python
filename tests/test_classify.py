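"""Split protocol, normalisation, metrics, tuning, and comparisons."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import roc_auc_score

from ehgpreterm.balance import balance_classes
from ehgpreterm.classify_evaluate import (RunConfig, compare_classifiers,
                                          evaluate, make_split,
                                          minmax_normalize, roc_points,
                                          run_experiment,
                                          sensitivity_real_only,
                                          trapezoid_auc, tune_train)
from conftest import make_feature_table


def _balanced_pe_te(seed=0):
    table = make_feature_table(143, 19, seed=7)
    return balance_classes(table, seed=seed).frame


class TestMakeSplit:
    def test_all_real_preterm_held_out(self):
        frame = _balanced_pe_te()
        plan = make_split(frame, seed=1)
        test = frame.iloc[plan.test_rows]
        train = frame.iloc[plan.train_val_rows]
        n_real_pre_test = ((test["label"] == "preterm")
                           & (test["provenance"] == "real")).sum()
        assert n_real_pre_test == 19
        assert not ((train["label"] == "preterm")
                    & (train["provenance"] == "real")).any()

    def test_term_fraction_close_to_30_percent(self):
        frame = _balanced_pe_te()
        plan = make_split(frame, test_frac=0.3, seed=2)
        test = frame.iloc[plan.test_rows]
        n_term_test = (test["label"] == "term").sum()
        assert abs(n_term_test - 0.3 * 143) <= 1

    def test_partition_is_exact(self):
        frame = _balanced_pe_te()
        plan = make_split(frame, seed=3)
        together = np.sort(np.concatenate([plan.train_val_rows,
                                           plan.test_rows]))
        assert np.array_equal(together, np.arange(len(frame)))

    def test_deterministic_per_seed(self):
        frame = _balanced_pe_te()
        a, b = make_split(frame, seed=5), make_split(frame, seed=5)
        assert np.array_equal(a.test_rows, b.test_rows)
        c = make_split(frame, seed=6)
        assert not np.array_equal(a.test_rows, c.test_rows)

    def test_no_real_preterm_is_protocol_error(self):
        table = make_feature_table(10, 0, n_features=4)
        with pytest.raises(ValueError, match="real preterm"):
            make_split(table)

    def test_no_synthetic_preterm_warns_degenerate(self, caplog):
        table = make_feature_table(10, 3, n_features=4)
        plan = make_split(table, seed=0)
        assert "single class" in caplog.text
        test = table.iloc[plan.test_rows]
        assert (test["label"] == "preterm").sum() == 3


class TestMinMaxNormalize:
    def test_train_maps_to_unit_interval(self):
        train = np.array([[2.0], [4.0], [6.0]])
        tr, te, lo, hi = minmax_normalize(train, np.array([[8.0]]))
        assert tr[:, 0].tolist() == [0.0, 0.5, 1.0]
        assert te[0, 0] == 1.5  # extrapolation beyond train max allowed

    def test_round_trip_inverse(self):
        rng = np.random.default_rng(0)
        train = rng.uniform(-5, 5, size=(30, 4))
        test = rng.uniform(-9, 9, size=(10, 4))
        tr, te, lo, hi = minmax_normalize(train, test)
        assert np.abs(tr * (hi - lo) + lo - train).max() < 1e-12
        assert np.abs(te * (hi - lo) + lo - test).max() < 1e-12

    def test_degenerate_feature_passes_as_half(self, caplog):
        train = np.array([[1.0, 7.0], [2.0, 7.0]])
        tr, te, _, _ = minmax_normalize(train, np.array([[1.5, 9.0]]))
        assert np.all(tr[:, 1] == 0.5) and te[0, 1] == 0.5
        assert "degenerate" in caplog.text

    def test_test_statistics_never_consulted(self):
        rng = np.random.default_rng(1)
        train = rng.uniform(size=(20, 3))
        test_a = rng.uniform(size=(5, 3))
        test_b = test_a + 100.0  # mutated test set
        tr_a, _, lo_a, hi_a = minmax_normalize(train, test_a)
        tr_b, _, lo_b, hi_b = minmax_normalize(train, test_b)
        assert np.array_equal(tr_a, tr_b)
        assert np.array_equal(lo_a, lo_b) and np.array_equal(hi_a, hi_b)


class TestROCAndAUC:
    @pytest.mark.parametrize("seed", range(10))
    def test_auc_equals_rank_statistic(self, seed):
        rng = np.random.default_rng(seed)
        y = rng.integers(0, 2, size=40)
        if y.min() == y.max():
            y[0] = 1 - y[0]
        scores = np.round(rng.uniform(size=40), 2)  # ties likely
        auc = trapezoid_auc(*roc_points(y, scores))
        pos, neg = scores[y == 1], scores[y == 0]
        ranks = stats.rankdata(np.concatenate([pos, neg]))
        u_pos = ranks[:pos.size].sum() - pos.size * (pos.size + 1) / 2
        assert auc == pytest.approx(u_pos / (pos.size * neg.size), abs=1e-12)
        assert auc == pytest.approx(roc_auc_score(y, scores), abs=1e-12)

    def test_roc_monotone(self):
        rng = np.random.default_rng(3)
        y = rng.integers(0, 2, size=50)
        fpr, tpr = roc_points(y, rng.uniform(size=50))
        assert np.all(np.diff(fpr) >= 0) and np.all(np.diff(tpr) >= 0)
        assert fpr[0] == 0.0 and tpr[-1] == 1.0


class _FixedModel:
    """Deterministic stub scoring rows by their first feature."""

    def predict_proba(self, X):
        s = np.asarray(X)[:, 0]
        return np.column_stack([1 - s, s])


class TestEvaluate:
    def test_perfect_scores(self):
        X = np.array([[0.9], [0.8], [0.1], [0.2]])
        y = np.array([1, 1, 0, 0])
        rep = evaluate(_FixedModel(), X, y)
        assert (rep.sen, rep.spe, rep.acc) == (100.0, 100.0, 100.0)
        assert rep.auc == 1.0

    def test_17_of_19_sensitivity(self):
        scores = np.r_[np.full(17, 0.9), [0.1, 0.2], np.full(10, 0.05)]
        y = np.r_[np.ones(19), np.zeros(10)].astype(int)
        rep = evaluate(_FixedModel(), scores[:, None], y)
        assert rep.tp == 17 and rep.fn == 2
        assert rep.sen == pytest.approx(100 * 17 / 19)  # 89.47%
        assert rep.acc == pytest.approx(100 * 27 / 29)

    def test_metric_identities(self):
        rng = np.random.default_rng(4)
        y = rng.integers(0, 2, size=60)
        rep = evaluate(_FixedModel(), rng.uniform(size=(60, 1)), y)
        total = rep.tp + rep.fn + rep.tn + rep.fp
        assert total == 60
        assert rep.acc == pytest.approx(100 * (rep.tp + rep.tn) / total)
        p, n = rep.tp + rep.fn, rep.tn + rep.fp
        assert rep.acc == pytest.approx((rep.sen * p + rep.spe * n) / (p + n))

    def test_single_class_reports_absent_metrics(self):
        rep = evaluate(_FixedModel(), np.array([[0.9], [0.2]]),
                       np.array([1, 1]))
        assert rep.spe is None and rep.auc is None
        assert rep.sen == 50.0


class TestRealOnlySensitivity:
    def test_counts_only_real_preterm_rows(self):
        X = np.array([[0.9], [0.1], [0.9], [0.9]])
        y = np.array([1, 1, 1, 0])
        prov = np.array(["real", "real", "synthetic", "real"])
        sen = sensitivity_real_only(_FixedModel(), X, y, prov)
        assert sen == 50.0  # 1 of the 2 real preterm rows

    def test_all_term_predictions_give_zero(self):
        X = np.zeros((3, 1))
        y = np.array([1, 1, 1])
        prov = np.array(["real"] * 3)
        assert sensitivity_real_only(_FixedModel(), X, y, prov) == 0.0

    def test_no_real_preterm_rejected(self):
        with pytest.raises(ValueError, match="real preterm"):
            sensitivity_real_only(_FixedModel(), np.zeros((2, 1)),
                                  np.array([0, 0]), np.array(["real"] * 2))


class TestTuneTrain:
    @pytest.mark.parametrize("name", ["adaboost", "svm", "dt", "rf"])
    def test_separable_toy_reaches_high_cv_auc(self, name):
        rng = np.random.default_rng(0)
        X = np.r_[rng.normal(0, 0.3, (100, 2)), rng.normal(3, 0.3, (100, 2))]
        y = np.r_[np.zeros(100), np.ones(100)].astype(int)
        tuned = tune_train(X, y, name, cv_folds=5, budget=3, seed=1)
        assert tuned.cv_auc >= 0.99

    def test_shuffled_labels_give_chance_auc(self):
        # budget 1 so no selection bias inflates the null CV AUC
        rng = np.random.default_rng(2)
        aucs = []
        for seed in range(3):
            X = rng.uniform(size=(200, 3))
            y = rng.permutation(np.r_[np.zeros(100), np.ones(100)]).astype(int)
            aucs.append(tune_train(X, y, "dt", cv_folds=5, budget=1,
                                   seed=seed).cv_auc)
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.1)

    def test_budget_recorded(self):
        rng = np.random.default_rng(4)
        X = rng.uniform(size=(40, 2))
        y = np.r_[np.zeros(20), np.ones(20)].astype(int)
        tuned = tune_train(X, y, "dt", cv_folds=4, budget=5, tuner="bayes",
                           seed=0)
        assert len(tuned.evals) == 5
        assert tuned.cv_auc == tuned.evals["cv_auc"].max()


class TestCompareClassifiers:
    def test_identical_vectors_no_rejection(self):
        sen = {"a": np.full(10, 90.0), "b": np.full(10, 90.0)}
        out = compare_classifiers(sen)
        assert not out["significant"].any()
        assert (out["p_raw"] == 1.0).all()

    def test_disjoint_distributions_rejected(self):
        rng = np.random.default_rng(5)
        sen = {"good": 90 + rng.uniform(0, 2, 10),
               "bad": 60 + rng.uniform(0, 2, 10)}
        out = compare_classifiers(sen)
        assert out["significant"].all()

    def test_holm_adjustment_monotone(self):
        rng = np.random.default_rng(6)
        sen = {"a": 90 + rng.uniform(0, 5, 10),
               "b": 88 + rng.uniform(0, 5, 10),
               "c": 60 + rng.uniform(0, 5, 10)}
        out = compare_classifiers(sen)
        assert (out["p_holm"] >= out["p_raw"] - 1e-15).all()

    def test_unequal_repeats_rejected(self):
        with pytest.raises(ValueError, match="equal"):
            compare_classifiers({"a": np.ones(5), "b": np.ones(6)})


class TestRunExperiment:
    def test_repeat_runs_are_deterministic(self):
        table = make_feature_table(30, 6, seed=1, shift=2.0)
        cfg = RunConfig(classifiers=("dt",), n_repeats=2, cv_folds=3,
                        tuner_budget=2, seed=42)
        a = run_experiment(table, cfg)
        b = run_experiment(table, cfg)
        pd.testing.assert_frame_equal(a.per_repeat, b.per_repeat)

    def test_report_covers_all_classifiers_and_repeats(self, tmp_path):
        table = make_feature_table(30, 6, seed=2, shift=2.0)
        cfg = RunConfig(classifiers=("dt", "rf"), n_repeats=2, cv_folds=3,
                        tuner_budget=2, seed=0)
        report = run_experiment(table, cfg)
        assert len(report.per_repeat) == 4
        assert set(report.per_repeat["classifier"]) == {"dt", "rf"}
        assert report.comparisons is not None
        assert report.protocol_violations == 0
        report.save(tmp_path)
        assert (tmp_path / "report.json").exists()
        assert (tmp_path / "metrics.csv").exists()
        assert (tmp_path / "roc.csv").exists()
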