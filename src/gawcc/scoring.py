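"""Wrapper fitness: cross-validated SVM evaluation of candidate feature subsets.

Fitness follows the accuracy score

    Score = Accuracy = (TP + TN) / (TP + TN + FP + FN)

for classification (mean held-out accuracy over k folds), and -RMSE for
regression so that both tasks are maximized by the optimizers.  The full
metric panel (SEN, SPC, PRE, FPR, ACC, F-measure, Cohen's kappa, AUC; RMSE
and Pearson r for regression) is pooled over the held-out predictions.

The learner is a pluggable contract: any object with ``fit`` / ``predict``
(and ``decision_function`` for classification AUC) works.  The default is an
RBF support-vector machine with C=1 and gamma = 1 / n_selected_features.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.metrics import cohen_kappa_score, roc_auc_score
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.svm import SVC, SVR

from .candidates import CandidateSolution
from .datasets import CLASSIFICATION, FeatureTable

__all__ = [
    "ConfusionCounts",
    "EvalResult",
    "CvPlan",
    "make_cv_plan",
    "accuracy",
    "panel_metrics",
    "panel_from_predictions",
    "roc_auc",
    "regression_metrics",
    "evaluate_subset",
    "SubsetEvaluator",
    "default_learner",
    "UndefinedMetricError",
    "EvaluationBudgetExceeded",
    "DegenerateMetricWarning",
]


class UndefinedMetricError(ValueError):
    """A metric was requested on input where it has no defined value."""


class EvaluationBudgetExceeded(RuntimeError):
    """The evaluator's fresh-evaluation budget for the current run is spent.

    The optimizers catch this and terminate gracefully with their current
    best state; cache hits never consume budget.
    """


class DegenerateMetricWarning(UserWarning):
    """A zero-denominator metric cell was reported as 0."""


@dataclass(frozen=True)
class ConfusionCounts:
    """Pooled binary (one-vs-rest) confusion counts."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "tn", "fp", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class EvalResult:
    """Cross-validated fitness plus the metric panel for one candidate.

    ``fitness`` is the quantity the optimizers maximize: mean held-out
    accuracy for classification, -RMSE for regression.  ``nof`` is the
    number of selected features.
    """

    fitness: float
    metrics: dict
    nof: int


@dataclass(frozen=True)
class CvPlan:
    """A frozen k-fold partition: per-sample fold ids, stratified for classification."""

    k: int
    seed: int
    fold_ids: np.ndarray

    def __post_init__(self) -> None:
        fold_ids = np.asarray(self.fold_ids, dtype=int)
        object.__setattr__(self, "fold_ids", fold_ids)
        if self.k < 2:
            raise ValueError("k must be >= 2")
        sizes = np.bincount(fold_ids, minlength=self.k)
        if sizes.max() - sizes.min() > 1:
            raise ValueError("fold sizes must differ by at most 1")

    def folds(self):
        for f in range(self.k):
            test = np.flatnonzero(self.fold_ids == f)
            train = np.flatnonzero(self.fold_ids != f)
            yield train, test


def make_cv_plan(table: FeatureTable, k: int = 5, seed: int = 0) -> CvPlan:
    """Build a seeded k-fold plan (stratified by label for classification)."""
    n = table.n_samples
    fold_ids = np.empty(n, dtype=int)
    if table.task == CLASSIFICATION:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        split_y = table.labels
    else:
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
        split_y = None
    for f, (_, test) in enumerate(splitter.split(np.zeros((n, 1)), split_y)):
        fold_ids[test] = f
    return CvPlan(k=k, seed=seed, fold_ids=fold_ids)


# ---------------------------------------------------------------------------
# metric arithmetic


def accuracy(counts: ConfusionCounts) -> float:
    """(TP + TN) / (TP + TN + FP + FN)."""
    if counts.total == 0:
        raise UndefinedMetricError("accuracy undefined on zero counts")
    return (counts.tp + counts.tn) / counts.total


def _safe_div(num: float, den: float, what: str) -> float:
    if den == 0:
        warnings.warn(
            f"{what} has zero denominator; reported as 0",
            DegenerateMetricWarning,
            stacklevel=3,
        )
        return 0.0
    return num / den


def panel_metrics(counts: ConfusionCounts) -> dict:
    """SEN/SPC/PRE/FPR/ACC/F-measure from one binary confusion table.

    Zero-denominator cells are reported as 0 with a
    :class:`DegenerateMetricWarning`.
    """
    if counts.total == 0:
        raise UndefinedMetricError("metrics undefined on zero counts")
    sen = _safe_div(counts.tp, counts.tp + counts.fn, "SEN")
    spc = _safe_div(counts.tn, counts.tn + counts.fp, "SPC")
    pre = _safe_div(counts.tp, counts.tp + counts.fp, "PRE")
    fpr = _safe_div(counts.fp, counts.fp + counts.tn, "FPR")
    f = _safe_div(2 * pre * sen, pre + sen, "F_measure")
    return {
        "SEN": sen,
        "SPC": spc,
        "PRE": pre,
        "FPR": fpr,
        "ACC": accuracy(counts),
        "F_measure": f,
    }


def panel_from_predictions(y_true: np.ndarray, y_pred: np.ndarray) -> dict:
    """Full classification panel from pooled held-out predictions.

    Binary tasks use the plain binary confusion table (second class in sorted
    label order is "positive"); multi-class tasks macro-average SEN, SPC,
    PRE, FPR and F over one-vs-rest tables.  ACC is pooled accuracy and
    C_kappa is standard Cohen's kappa, both computed on the raw labels.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape or y_true.size == 0:
        raise UndefinedMetricError("need equal non-empty prediction vectors")
    classes = np.unique(y_true)
    per_class = []
    targets = classes[1:] if len(classes) == 2 else classes
    for c in targets:
        t, p = y_true == c, y_pred == c
        counts = ConfusionCounts(
            tp=int(np.sum(t & p)),
            tn=int(np.sum(~t & ~p)),
            fp=int(np.sum(~t & p)),
            fn=int(np.sum(t & ~p)),
        )
        per_class.append(panel_metrics(counts))
    panel = {
        k: float(np.mean([m[k] for m in per_class]))
        for k in ("SEN", "SPC", "PRE", "FPR", "F_measure")
    }
    panel["ACC"] = float(np.mean(y_true == y_pred))
    panel["C_kappa"] = float(cohen_kappa_score(y_true, y_pred))
    return panel


def roc_auc(scores, labels) -> float:
    """Rank-based AUC (normalized Mann-Whitney statistic; ties count 1/2)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise UndefinedMetricError("AUC needs both classes present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def regression_metrics(pred, real) -> dict:
    """RMSE and Pearson correlation between predicted and real labels."""
    pred = np.asarray(pred, dtype=float)
    real = np.asarray(real, dtype=float)
    if pred.shape != real.shape or pred.size == 0:
        raise UndefinedMetricError("need equal non-empty vectors")
    rmse = float(np.sqrt(np.mean((pred - real) ** 2)))
    if np.std(real) == 0:
        raise UndefinedMetricError("correlation undefined for constant labels")
    if np.std(pred) == 0:
        corr = 0.0  # constant predictor carries no linear signal
    else:
        corr = float(stats.pearsonr(pred, real)[0])
    return {"RMSE": rmse, "correlation": corr}


# ---------------------------------------------------------------------------
# cross-validated evaluation


def default_learner(task: str, n_selected: int):
    """RBF SVM with C=1 and gamma = 1/n_selected (classification or regression)."""
    gamma = 1.0 / max(n_selected, 1)
    if task == CLASSIFICATION:
        return SVC(C=1.0, kernel="rbf", gamma=gamma)
    return SVR(C=1.0, kernel="rbf", gamma=gamma)


def _fold_impute(train_X: np.ndarray, test_X: np.ndarray):
    """Mean-impute both splits from training-fold column means (no leakage)."""
    if not np.isnan(train_X).any() and not np.isnan(test_X).any():
        return train_X, test_X
    means = np.nanmean(train_X, axis=0)
    means = np.where(np.isnan(means), 0.0, means)
    train_X = np.where(np.isnan(train_X), means, train_X)
    test_X = np.where(np.isnan(test_X), means, test_X)
    return train_X, test_X


def evaluate_subset(
    table: FeatureTable,
    cs: CandidateSolution,
    plan: CvPlan,
    learner_factory=default_learner,
    with_panel: bool = True,
) -> EvalResult:
    """Score one candidate subset under the k-fold plan.

    Trains only on training folds (mean imputation re-fitted per fold when
    the table has missing values).  Classification fitness is the mean
    held-out accuracy; the panel is pooled over held-out predictions.
    Deterministic given (table, plan, candidate).
    """
    cs.validate_against(table.n_features)
    X = table.columns(cs.indices)
    y = table.labels
    n = table.n_samples
    classification = table.task == CLASSIFICATION

    pooled_pred = np.empty(n, dtype=y.dtype)
    pooled_scores = None
    fold_acc = []
    for train, test in plan.folds():
        if classification and len(np.unique(y[train])) < len(np.unique(y)):
            raise UndefinedMetricError("a training fold is missing a class")
        Xtr, Xte = _fold_impute(X[train], X[test])
        model = learner_factory(table.task, len(cs))
        model.fit(Xtr, y[train])
        pred = model.predict(Xte)
        pooled_pred[test] = pred
        if classification:
            fold_acc.append(float(np.mean(pred == y[test])))
            if with_panel and hasattr(model, "decision_function"):
                dec = model.decision_function(Xte)
                if pooled_scores is None:
                    pooled_scores = np.zeros(
                        (n,) if dec.ndim == 1 else (n, dec.shape[1])
                    )
                pooled_scores[test] = dec

    if classification:
        fitness = float(np.mean(fold_acc))
        if not with_panel:
            return EvalResult(fitness=fitness, metrics={}, nof=len(cs))
        metrics = panel_from_predictions(y, pooled_pred)
        metrics["AUC"] = _pooled_auc(y, pooled_scores)
        return EvalResult(fitness=fitness, metrics=metrics, nof=len(cs))

    metrics = regression_metrics(pooled_pred.astype(float), y)
    result = EvalResult(
        fitness=-metrics["RMSE"],
        metrics=metrics if with_panel else {},
        nof=len(cs),
    )
    return result


def _pooled_auc(y: np.ndarray, scores) -> float:
    """Macro one-vs-rest AUC from pooled decision values (binary: plain AUC)."""
    if scores is None:
        return float("nan")
    classes = np.unique(y)
    if len(classes) == 2:
        return roc_auc(np.asarray(scores).reshape(-1), y == classes[1])
    scores = np.asarray(scores)
    aucs = []
    for j, c in enumerate(classes):
        col = scores[:, j] if scores.ndim == 2 else scores
        aucs.append(roc_auc(col, y == c))
    return float(np.mean(aucs))


class SubsetEvaluator:
    """Caching fitness oracle bound to one (table, plan, learner) triple.

    The WCC operators call the cost function heavily; identical index sets
    are scored once and served from cache afterwards (the evaluation is
    deterministic, so caching is exact).  ``n_evals`` counts cache misses —
    the evaluation-count budget used when comparing methods.
    """

    def __init__(
        self,
        table: FeatureTable,
        plan: CvPlan,
        learner_factory=default_learner,
    ):
        self.table = table
        self.plan = plan
        self.learner_factory = learner_factory
        self._cache: dict[tuple[int, ...], float] = {}
        self.n_evals = 0
        self._budget_stop: int | None = None

    @property
    def n_features(self) -> int:
        return self.table.n_features

    def set_budget(self, budget: int | None) -> None:
        """Allow at most ``budget`` further cache-miss evaluations.

        Used to give competing methods identical evaluation-count budgets
        (the reproducible analogue of an equal wall-clock allowance).
        ``None`` removes the limit.
        """
        self._budget_stop = None if budget is None else self.n_evals + budget

    def fitness(self, cs: CandidateSolution) -> float:
        key = cs.indices
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        if self._budget_stop is not None and self.n_evals >= self._budget_stop:
            raise EvaluationBudgetExceeded(
                f"evaluation budget spent after {self.n_evals} evaluations"
            )
        result = evaluate_subset(
            self.table, cs, self.plan, self.learner_factory, with_panel=False
        )
        self.n_evals += 1
        self._cache[key] = result.fitness
        return result.fitness

    def evaluate(self, cs: CandidateSolution) -> EvalResult:
        """Full metric panel (not cached; used for final reporting)."""
        return evaluate_subset(self.table, cs, self.plan, self.learner_factory)
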