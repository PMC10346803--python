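"""Real-preterm-held-out classification protocol and its evaluation.

The central methodological rule: synthetic preterm rows exist only to
train, every *real* preterm row is reserved for testing.  This prevents
the optimistic bias of evaluating on interpolated minority samples — a
sensitivity of 90% on a balanced table says little if the errors
concentrate on the real recordings.  Term rows are split 70/30.

Pipeline per repeat: balance -> feature screen -> split -> min-max
normalisation (train statistics only) -> hyperparameter tuning by
Gaussian-process expected improvement over stratified 10-fold CV AUC ->
test-set metrics (Sen/Spe/Acc from the confusion counts at the 0.5
probability threshold, AUC by trapezoidal integration of the full ROC
sweep) plus the sensitivity restricted to real preterm rows.  Classifiers
are compared by paired t-tests on repeat-wise sensitivities with Holm's
step-down correction.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import Matern, WhiteKernel
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from sklearn.model_selection import StratifiedKFold
from statsmodels.stats.multitest import multipletests

from .balance import BalancedTable, balance_classes
from .io_ehg import feature_columns
from .select import select_features

logger = logging.getLogger("ehgpreterm")

__all__ = ["SplitPlan", "MetricsReport", "RunConfig", "ExperimentReport",
           "make_split", "minmax_normalize", "tune_train", "evaluate",
           "sensitivity_real_only", "compare_classifiers", "run_experiment",
           "roc_points", "trapezoid_auc"]

POSITIVE = "preterm"  # the clinically positive class

# hyperparameter search boxes: (low, high, log-scale?, integer?)
SEARCH_SPACES: dict[str, dict[str, tuple[float, float, bool, bool]]] = {
    "adaboost": {"n_estimators": (10, 500, True, True),
                 "learning_rate": (0.01, 1.0, True, False)},
    "svm": {"C": (1e-3, 1e3, True, False),
            "gamma": (1e-3, 1e3, True, False)},
    "dt": {"max_depth": (1, 20, False, True),
           "min_samples_leaf": (1, 20, False, True)},
    "rf": {"n_estimators": (50, 500, True, True),
           "max_depth": (2, 20, False, True)},
}


def build_model(name: str, params: dict, seed: int):
    if name == "adaboost":
        return AdaBoostClassifier(random_state=seed, **params)
    if name == "svm":
        return SVC(kernel="rbf", probability=True, random_state=seed,
                   **params)
    if name == "dt":
        return DecisionTreeClassifier(random_state=seed, **params)
    if name == "rf":
        return RandomForestClassifier(random_state=seed, n_jobs=1, **params)
    raise ValueError(f"unknown classifier {name!r}")


# ---------------------------------------------------------------------------
# Split and normalisation
# ---------------------------------------------------------------------------

@dataclass
class SplitPlan:
    """Row partition honouring the real-preterm-test-only constraint."""

    train_val_rows: np.ndarray  # positional indices into the table
    test_rows: np.ndarray
    seed: int

    def check(self, table: pd.DataFrame) -> None:
        """Assert the protocol invariants on the given table."""
        train = table.iloc[self.train_val_rows]
        test = table.iloc[self.test_rows]
        real_pre_train = ((train["label"] == POSITIVE)
                          & (train["provenance"] == "real")).sum()
        if real_pre_train:
            raise AssertionError(
                f"{real_pre_train} real preterm rows leaked into training")
        n_real_pre = ((table["label"] == POSITIVE)
                      & (table["provenance"] == "real")).sum()
        n_real_pre_test = ((test["label"] == POSITIVE)
                           & (test["provenance"] == "real")).sum()
        if n_real_pre_test != n_real_pre:
            raise AssertionError("not all real preterm rows are in the test set")
        both = np.intersect1d(self.train_val_rows, self.test_rows)
        if both.size:
            raise AssertionError("train/test overlap")
        if self.train_val_rows.size + self.test_rows.size != len(table):
            raise AssertionError("split does not cover the table")


def make_split(table: pd.DataFrame, test_frac: float = 0.3,
               seed: int = 0) -> SplitPlan:
    """Partition a balanced table: all real preterm rows to test, all
    synthetic preterm rows to train, term rows split at ``test_frac``."""
    labels = table["label"].to_numpy()
    prov = table["provenance"].to_numpy()
    idx = np.arange(len(table))
    real_preterm = idx[(labels == POSITIVE) & (prov == "real")]
    syn_preterm = idx[(labels == POSITIVE) & (prov != "real")]
    term = idx[labels != POSITIVE]
    if real_preterm.size == 0:
        raise ValueError("make_split: no real preterm rows to test on")
    if syn_preterm.size == 0:
        logger.warning("make_split: no synthetic preterm rows — "
                       "training set has a single class")
    rng = np.random.default_rng(seed)
    term_shuffled = rng.permutation(term)
    n_test_term = int(round(test_frac * term.size))
    test = np.sort(np.concatenate([real_preterm,
                                   term_shuffled[:n_test_term]]))
    train = np.sort(np.concatenate([syn_preterm,
                                    term_shuffled[n_test_term:]]))
    plan = SplitPlan(train, test, seed)
    plan.check(table)
    return plan


def minmax_normalize(train: np.ndarray, test: np.ndarray,
                     ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Scale features to [0, 1] using TRAIN minima/maxima only.

    Test values may leave [0, 1]; a degenerate train feature (max == min)
    maps to the uninformative constant 0.5 on both sides.
    """
    train = np.asarray(train, dtype=float)
    test = np.asarray(test, dtype=float)
    lo = train.min(axis=0)
    hi = train.max(axis=0)
    span = hi - lo
    degenerate = span == 0
    if degenerate.any():
        logger.warning("minmax_normalize: %d degenerate features",
                       int(degenerate.sum()))
        span = np.where(degenerate, 1.0, span)
    train_n = (train - lo) / span
    test_n = (test - lo) / span
    train_n[:, degenerate] = 0.5
    test_n[:, degenerate] = 0.5
    return train_n, test_n, lo, hi


# ---------------------------------------------------------------------------
# Hyperparameter tuning (GP expected improvement)
# ---------------------------------------------------------------------------

def _to_unit(params: dict, space: dict) -> np.ndarray:
    u = []
    for name, (lo, hi, log, _) in space.items():
        x = params[name]
        if log:
            u.append((np.log(x) - np.log(lo)) / (np.log(hi) - np.log(lo)))
        else:
            u.append((x - lo) / (hi - lo))
    return np.array(u)


def _from_unit(u: np.ndarray, space: dict) -> dict:
    params = {}
    for val, (name, (lo, hi, log, integer)) in zip(u, space.items()):
        if log:
            x = float(np.exp(np.log(lo) + val * (np.log(hi) - np.log(lo))))
        else:
            x = float(lo + val * (hi - lo))
        params[name] = int(round(x)) if integer else x
    return params


def _cv_auc(name: str, params: dict, X: np.ndarray, y: np.ndarray,
            cv_folds: int, seed: int) -> tuple[float, list[float]]:
    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    fold_aucs = []
    for tr, va in skf.split(X, y):
        model = build_model(name, params, seed)
        model.fit(X[tr], y[tr])
        scores = model.predict_proba(X[va])[:, 1]
        fold_aucs.append(trapezoid_auc(*roc_points(y[va], scores)))
    return float(np.mean(fold_aucs)), fold_aucs


@dataclass
class TunedModel:
    name: str
    model: object
    best_params: dict
    cv_auc: float
    fold_aucs: list[float]
    evals: pd.DataFrame  # one row per tried configuration


def tune_train(X: np.ndarray, y: np.ndarray, name: str,
               cv_folds: int = 10, budget: int = 30,
               tuner: str = "bayes", seed: int = 0) -> TunedModel:
    """Tune one classifier by CV AUC and refit it on all of train_val.

    ``tuner="bayes"`` runs Gaussian-process expected-improvement search
    (random initialisation, Matern-5/2 surrogate); ``tuner="random"`` is
    pure seeded random search with the same budget.
    """
    space = SEARCH_SPACES[name]
    dim = len(space)
    rng = np.random.default_rng(seed)
    min_class = np.bincount(y.astype(int)).min()
    cv_folds = min(cv_folds, int(min_class))
    if cv_folds < 2:
        raise ValueError("tune_train: a class has fewer than 2 members")

    tried_u: list[np.ndarray] = []
    scores: list[float] = []
    records = []

    def _evaluate(u: np.ndarray) -> float:
        params = _from_unit(u, space)
        auc, _ = _cv_auc(name, params, X, y, cv_folds, seed)
        tried_u.append(u)
        scores.append(auc)
        records.append({**params, "cv_auc": auc})
        return auc

    n_init = budget if tuner == "random" else min(max(budget // 3, 4), budget)
    for _ in range(n_init):
        _evaluate(rng.uniform(size=dim))

    if tuner == "bayes":
        kernel = Matern(nu=2.5) + WhiteKernel(noise_level=1e-4)
        for _ in range(budget - n_init):
            gp = GaussianProcessRegressor(kernel=kernel, normalize_y=True,
                                          random_state=seed)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                gp.fit(np.vstack(tried_u), np.array(scores))
            cand = rng.uniform(size=(256, dim))
            mu, sd = gp.predict(cand, return_std=True)
            best = max(scores)
            sd = np.maximum(sd, 1e-9)
            z = (mu - best - 0.01) / sd
            ei = (mu - best - 0.01) * stats.norm.cdf(z) + sd * stats.norm.pdf(z)
            _evaluate(cand[int(np.argmax(ei))])
    elif tuner != "random":
        raise ValueError(f"unknown tuner {tuner!r}")

    i_best = int(np.argmax(scores))
    best_params = _from_unit(tried_u[i_best], space)
    _, fold_aucs = _cv_auc(name, best_params, X, y, cv_folds, seed)
    model = build_model(name, best_params, seed)
    model.fit(X, y)
    return TunedModel(name, model, best_params, float(scores[i_best]),
                      fold_aucs, pd.DataFrame(records))


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def roc_points(y_true: np.ndarray, scores: np.ndarray,
               ) -> tuple[np.ndarray, np.ndarray]:
    """ROC curve (FPR, TPR) from sweeping the threshold over all scores."""
    y_true = np.asarray(y_true).astype(bool)
    scores = np.asarray(scores, dtype=float)
    order = np.argsort(-scores, kind="stable")
    y_sorted = y_true[order]
    s_sorted = scores[order]
    tps = np.cumsum(y_sorted)
    fps = np.cumsum(~y_sorted)
    # keep the last point of each tied-score run
    distinct = np.nonzero(np.diff(s_sorted))[0]
    cut = np.r_[distinct, y_true.size - 1]
    p = max(int(y_true.sum()), 1)
    n = max(int((~y_true).sum()), 1)
    tpr = np.r_[0.0, tps[cut] / p]
    fpr = np.r_[0.0, fps[cut] / n]
    return fpr, tpr


def trapezoid_auc(fpr: np.ndarray, tpr: np.ndarray) -> float:
    return float(np.trapezoid(tpr, fpr))


@dataclass
class MetricsReport:
    """Confusion counts, Sen/Spe/Acc (percent), ROC and AUC."""

    tp: int
    fn: int
    tn: int
    fp: int
    sen: float | None
    spe: float | None
    acc: float
    roc: list[tuple[float, float]]
    auc: float | None
    sen_real_only: float | None = None

    def to_dict(self) -> dict:
        d = asdict(self)
        d["roc"] = [list(p) for p in self.roc]
        return d


def evaluate(model, X_test: np.ndarray, y_test: np.ndarray,
             threshold: float = 0.5) -> MetricsReport:
    """Test-set metrics: counts at ``threshold``, ROC/AUC over all scores."""
    y_test = np.asarray(y_test).astype(int)
    if y_test.size == 0:
        raise ValueError("evaluate: empty test set")
    scores = model.predict_proba(X_test)[:, 1]
    pred = (scores >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (y_test == 1)))
    fn = int(np.sum((pred == 0) & (y_test == 1)))
    tn = int(np.sum((pred == 0) & (y_test == 0)))
    fp = int(np.sum((pred == 1) & (y_test == 0)))
    sen = 100.0 * tp / (tp + fn) if tp + fn else None
    spe = 100.0 * tn / (tn + fp) if tn + fp else None
    acc = 100.0 * (tp + tn) / y_test.size
    if y_test.min() == y_test.max():
        roc, auc = [], None
    else:
        fpr, tpr = roc_points(y_test, scores)
        roc = list(zip(fpr.tolist(), tpr.tolist()))  # (1 - Spe, Sen)
        auc = trapezoid_auc(fpr, tpr)
    return MetricsReport(tp, fn, tn, fp, sen, spe, acc, roc, auc)


def sensitivity_real_only(model, X_test: np.ndarray, y_test: np.ndarray,
                          provenance: np.ndarray,
                          threshold: float = 0.5) -> float:
    """Sensitivity restricted to real preterm test rows, in percent."""
    y_test = np.asarray(y_test).astype(int)
    mask = (y_test == 1) & (np.asarray(provenance) == "real")
    if not mask.any():
        raise ValueError("sensitivity_real_only: no real preterm test rows")
    scores = model.predict_proba(X_test[mask])[:, 1]
    return float(100.0 * np.mean(scores >= threshold))


def compare_classifiers(sen_by_classifier: dict[str, np.ndarray],
                        alpha: float = 0.05) -> pd.DataFrame:
    """Pairwise paired t-tests on repeat-wise sensitivities, Holm-adjusted."""
    names = list(sen_by_classifier)
    if len(names) < 2:
        raise ValueError("compare_classifiers: need >=2 classifiers")
    lengths = {len(np.asarray(v)) for v in sen_by_classifier.values()}
    if len(lengths) != 1 or lengths.pop() < 2:
        raise ValueError("compare_classifiers: need equal n_repeats >= 2")
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a = np.asarray(sen_by_classifier[names[i]], dtype=float)
            b = np.asarray(sen_by_classifier[names[j]], dtype=float)
            if np.allclose(a - b, (a - b)[0]):
                logger.warning("compare_classifiers: zero-variance "
                               "difference %s vs %s", names[i], names[j])
                p = 1.0  # constant difference carries no paired evidence
            else:
                p = float(stats.ttest_rel(a, b).pvalue)
            rows.append({"a": names[i], "b": names[j], "p_raw": p})
    out = pd.DataFrame(rows)
    reject, p_holm, _, _ = multipletests(out["p_raw"], alpha, "holm")
    out["p_holm"] = p_holm
    out["significant"] = reject
    return out


# ---------------------------------------------------------------------------
# Full experiment
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Settings for a repeated-run experiment."""

    classifiers: tuple[str, ...] = ("adaboost", "svm", "dt", "rf")
    n_repeats: int = 10
    cv_folds: int = 10
    tuner: str = "bayes"
    tuner_budget: int = 30
    test_frac: float = 0.3
    alpha: float = 0.05
    balance_strategy: str = "sasyno"
    threshold: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")
        unknown = set(self.classifiers) - set(SEARCH_SPACES)
        if unknown:
            raise ValueError(f"unknown classifiers {sorted(unknown)}")


@dataclass
class ExperimentReport:
    """Aggregated output of ``run_experiment``."""

    config: RunConfig
    per_repeat: pd.DataFrame  # classifier, repeat, seed, sen/spe/acc/auc, ...
    summary: pd.DataFrame     # classifier x metric mean/sd
    comparisons: pd.DataFrame | None
    selected_features: list[list[str]]
    protocol_violations: int = 0
    #: (1-Spe, Sen) ROC points of the final repeat, per classifier
    roc_curves: dict[str, list[tuple[float, float]]] = field(
        default_factory=dict)

    def save(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        summary = self.summary.copy()
        summary.columns = ["_".join(c) for c in summary.columns]
        payload = {
            "config": asdict(self.config),
            "summary": summary.reset_index().to_dict("records"),
            "comparisons": (None if self.comparisons is None
                            else self.comparisons.to_dict("records")),
            "protocol_violations": self.protocol_violations,
            "n_selected_per_repeat": [len(s) for s in self.selected_features],
        }
        (out_dir / "report.json").write_text(
            json.dumps(payload, indent=2, sort_keys=True) + "\n")
        self.per_repeat.to_csv(out_dir / "metrics.csv", index=False)
        if self.roc_curves:
            roc_rows = [
                {"classifier": name, "fpr": fpr, "tpr": tpr}
                for name, pts in self.roc_curves.items()
                for fpr, tpr in pts]
            pd.DataFrame(roc_rows).to_csv(out_dir / "roc.csv", index=False)


def run_experiment(table: pd.DataFrame,
                   config: RunConfig = RunConfig()) -> ExperimentReport:
    """Run the full balanced / screened / held-out protocol ``n_repeats``
    times with per-repeat seeds and aggregate the metrics.

    ``table`` is an unbalanced single-group feature table of real rows.
    Each repeat re-balances, re-screens, and re-splits with a fresh seed,
    then tunes and tests every configured classifier.  The protocol
    invariant (no real preterm row in training) is asserted on every
    repeat; violations would raise.
    """
    config.validate()
    rows = []
    selected_all: list[list[str]] = []
    roc_curves: dict[str, list[tuple[float, float]]] = {}
    for rep in range(config.n_repeats):
        rep_seed = (config.seed + 7919 * rep) % (2**31)
        balanced: BalancedTable = balance_classes(
            table, seed=rep_seed, strategy=config.balance_strategy)
        selection = select_features(balanced.frame, alpha=config.alpha)
        reduced = selection.reduce(balanced.frame)
        selected_all.append(selection.selected)
        if not selection.selected:
            raise RuntimeError("no features survived the screen")

        plan = make_split(reduced, config.test_frac, seed=rep_seed)
        plan.check(reduced)  # protocol invariant, every repeat
        feats = selection.selected
        train = reduced.iloc[plan.train_val_rows]
        test = reduced.iloc[plan.test_rows]
        X_tr, X_te, _, _ = minmax_normalize(
            train[feats].to_numpy(), test[feats].to_numpy())
        y_tr = (train["label"] == POSITIVE).to_numpy().astype(int)
        y_te = (test["label"] == POSITIVE).to_numpy().astype(int)
        prov_te = test["provenance"].to_numpy()

        for name in config.classifiers:
            tuned = tune_train(X_tr, y_tr, name, config.cv_folds,
                               config.tuner_budget, config.tuner, rep_seed)
            report = evaluate(tuned.model, X_te, y_te, config.threshold)
            report.sen_real_only = sensitivity_real_only(
                tuned.model, X_te, y_te, prov_te, config.threshold)
            roc_curves[name] = report.roc
            rows.append({
                "classifier": name, "repeat": rep, "seed": rep_seed,
                "n_selected": len(feats), "cv_auc": tuned.cv_auc,
                "sen": report.sen, "spe": report.spe, "acc": report.acc,
                "auc": report.auc, "sen_real_only": report.sen_real_only,
                "tp": report.tp, "fn": report.fn,
                "tn": report.tn, "fp": report.fp,
            })

    per_repeat = pd.DataFrame(rows)
    metric_cols = ["sen", "spe", "acc", "auc", "sen_real_only"]
    summary = per_repeat.groupby("classifier")[metric_cols].agg(["mean", "std"])

    comparisons = None
    if len(config.classifiers) >= 2 and config.n_repeats >= 2:
        sen_by = {name: per_repeat.loc[per_repeat["classifier"] == name,
                                       "sen"].to_numpy()
                  for name in config.classifiers}
        comparisons = compare_classifiers(sen_by, config.alpha)

    return ExperimentReport(config, per_repeat, summary, comparisons,
                            selected_all, protocol_violations=0,
                            roc_curves=roc_curves)
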