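"""Composed selection methods and the multi-execution comparison protocol.

The two-step wrapper method runs the GA to stagnation and hands its terminal
population to the WCC stage; the filter-wrapper variant replaces the GA with
an entropy-filter reduction and searches the reduced space with a standalone
WCC.  Standalone GA, standalone WCC, the five filters and the no-selection
SVM baseline share the same cross-validation plan so comparisons are
like-for-like.  The experiment protocol repeats a method over independent
seeded executions and summarizes the terminal fitness distribution (mean,
STD, t-based confidence interval, Welch test against a reference method).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .candidates import CandidateSolution
from .datasets import FeatureTable
from .filters import filter_scores, select_top_k
from .ga import GaConfig, ga_run
from .scoring import CvPlan, EvalResult, SubsetEvaluator, make_cv_plan
from .wcc import WccConfig, random_seed_population, wcc_run

__all__ = [
    "PipelineConfig",
    "FsReport",
    "run_method",
    "run_ga_wcc",
    "run_en_wcc",
    "run_standalone_ga",
    "run_standalone_wcc",
    "run_filter_method",
    "run_baseline_svm",
    "compare_executions",
    "summarize_executions",
    "run_experiment",
    "WRAPPER_METHODS",
    "ALL_METHODS",
]

WRAPPER_METHODS = ("GA_WCC", "EN_WCC", "GA", "WCC")
ALL_METHODS = WRAPPER_METHODS + ("PC", "LA", "EN", "MI", "FI")


@dataclass(frozen=True)
class PipelineConfig:
    """Everything one run needs: method, engine configs, CV plan settings.

    Published defaults: GA population 100, WCC population 20 with match time
    2 standalone; inside GA_WCC the WCC inherits the GA's population (100)
    and uses match time 1.  ``filter_k`` is both the filter-method subset
    size and the EN_WCC reduction size.
    """

    method: str = "GA_WCC"
    ga: GaConfig = field(default_factory=GaConfig)
    wcc: WccConfig = field(default_factory=WccConfig)
    filter_k: int = 20
    bins: int = 10
    folds: int = 5
    executions: int = 1
    eval_budget: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in ALL_METHODS:
            raise ValueError(f"unknown method {self.method!r}")
        if self.executions < 1:
            raise ValueError("executions must be >= 1")


@dataclass(frozen=True)
class FsReport:
    """Final selected subset plus everything needed to audit the run."""

    method: str
    best: CandidateSolution
    nof: int
    panel: EvalResult
    trajectory: tuple[float, ...]
    feature_names: tuple[str, ...]
    seed: int
    config: dict
    n_evals: int = 0
    per_execution: tuple[float, ...] | None = None
    summary_stats: dict | None = None

    def __post_init__(self) -> None:
        if self.nof != len(self.best):
            raise ValueError("nof must equal the selected-subset length")

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "selected_indices": list(self.best.indices),
            "selected_features": [
                self.feature_names[i - 1] for i in self.best.indices
            ],
            "nof": self.nof,
            "fitness": self.panel.fitness,
            "metrics": {k: float(v) for k, v in self.panel.metrics.items()},
            "trajectory": [float(x) for x in self.trajectory],
            "seed": self.seed,
            "config": self.config,
            "n_evals": self.n_evals,
            "per_execution": (
                None
                if self.per_execution is None
                else [float(x) for x in self.per_execution]
            ),
            "summary_stats": self.summary_stats,
        }


def _config_echo(cfg: PipelineConfig) -> dict:
    return {
        "method": cfg.method,
        "ga": vars(cfg.ga).copy(),
        "wcc": vars(cfg.wcc).copy(),
        "filter_k": cfg.filter_k,
        "bins": cfg.bins,
        "folds": cfg.folds,
        "executions": cfg.executions,
        "eval_budget": cfg.eval_budget,
        "seed": cfg.seed,
    }


def _make_evaluator(table: FeatureTable, cfg: PipelineConfig) -> SubsetEvaluator:
    plan = make_cv_plan(table, k=cfg.folds, seed=cfg.seed)
    return SubsetEvaluator(table, plan)


def _report(
    table, cfg, best, trajectory, evaluator, method=None
) -> FsReport:
    panel = evaluator.evaluate(best)
    return FsReport(
        method=method or cfg.method,
        best=best,
        nof=len(best),
        panel=panel,
        trajectory=tuple(float(x) for x in trajectory),
        feature_names=table.feature_names,
        seed=cfg.seed,
        config=_config_echo(cfg),
        n_evals=evaluator.n_evals,
    )


def run_ga_wcc(
    table: FeatureTable, cfg: PipelineConfig, evaluator: SubsetEvaluator | None = None
) -> FsReport:
    """Two-step method: GA to stagnation, then WCC on the hand-off population.

    The WCC stage keeps the GA's full population and uses match time 1.
    A per-run evaluation budget, when configured, spans both phases.
    """
    evaluator = evaluator or _make_evaluator(table, cfg)
    evaluator.set_budget(cfg.eval_budget)
    rng = np.random.default_rng(cfg.seed)
    ga_result = ga_run(evaluator, replace(cfg.ga, seed=cfg.seed), rng=rng)
    wcc_cfg = replace(
        cfg.wcc,
        pop_size=len(ga_result.population),
        match_time=1,
        top_count=min(cfg.wcc.top_count, len(ga_result.population)),
        seed=cfg.seed,
    )
    wcc_result = wcc_run(evaluator, list(ga_result.population), wcc_cfg, rng=rng)
    trajectory = ga_result.trajectory + wcc_result.trajectory
    return _report(table, cfg, wcc_result.best, trajectory, evaluator, "GA_WCC")


def run_en_wcc(
    table: FeatureTable, cfg: PipelineConfig, evaluator: SubsetEvaluator | None = None
) -> FsReport:
    """Filter-wrapper variant: entropy reduction, then standalone WCC.

    The entropy filter keeps the top ``filter_k`` features; a randomly
    initialized WCC (published standalone settings) searches within the
    reduced index set; reported indices are mapped back to the original
    1-based coordinates.
    """
    if cfg.filter_k > table.n_features:
        raise ValueError("filter_k exceeds the number of features")
    ranking = filter_scores(table, "EN", bins=cfg.bins)
    kept = select_top_k(ranking, cfg.filter_k)  # original 1-based indices
    reduced = table.subset(kept.indices)
    sub_cfg = replace(cfg, method="WCC")
    sub_eval = _make_evaluator(reduced, sub_cfg)
    sub_eval.set_budget(cfg.eval_budget)
    rng = np.random.default_rng(cfg.seed)
    wcc_cfg = replace(cfg.wcc, seed=cfg.seed)
    seed_pop = random_seed_population(sub_eval, wcc_cfg, rng=rng)
    result = wcc_run(sub_eval, seed_pop, wcc_cfg, rng=rng)
    # map reduced-space indices back to original coordinates
    mapped = CandidateSolution.from_values(
        kept.indices[i - 1] for i in result.best.indices
    )
    evaluator = evaluator or _make_evaluator(table, cfg)
    panel = evaluator.evaluate(mapped)
    return FsReport(
        method="EN_WCC",
        best=mapped,
        nof=len(mapped),
        panel=panel,
        trajectory=tuple(float(x) for x in result.trajectory),
        feature_names=table.feature_names,
        seed=cfg.seed,
        config=_config_echo(cfg),
        n_evals=sub_eval.n_evals,
    )


def run_standalone_ga(
    table: FeatureTable, cfg: PipelineConfig, evaluator: SubsetEvaluator | None = None
) -> FsReport:
    evaluator = evaluator or _make_evaluator(table, cfg)
    evaluator.set_budget(cfg.eval_budget)
    result = ga_run(evaluator, replace(cfg.ga, seed=cfg.seed))
    return _report(table, cfg, result.best, result.trajectory, evaluator, "GA")


def run_standalone_wcc(
    table: FeatureTable, cfg: PipelineConfig, evaluator: SubsetEvaluator | None = None
) -> FsReport:
    """Standalone WCC: random initial population, published settings
    (population 20, match time 2)."""
    evaluator = evaluator or _make_evaluator(table, cfg)
    evaluator.set_budget(cfg.eval_budget)
    rng = np.random.default_rng(cfg.seed)
    wcc_cfg = replace(cfg.wcc, seed=cfg.seed)
    seed_pop = random_seed_population(evaluator, wcc_cfg, rng=rng)
    result = wcc_run(evaluator, seed_pop, wcc_cfg, rng=rng)
    return _report(table, cfg, result.best, result.trajectory, evaluator, "WCC")


def run_filter_method(
    table: FeatureTable, cfg: PipelineConfig, evaluator: SubsetEvaluator | None = None
) -> FsReport:
    """One filter baseline at k = filter_k, evaluated by the wrapper scorer."""
    ranking = filter_scores(table, cfg.method, bins=cfg.bins)
    best = select_top_k(ranking, cfg.filter_k)
    evaluator = evaluator or _make_evaluator(table, cfg)
    fitness = evaluator.fitness(best)
    return _report(table, cfg, best, [fitness], evaluator)


def run_baseline_svm(table: FeatureTable, plan: CvPlan) -> EvalResult:
    """The SVM with no feature selection: evaluate the full index set."""
    all_features = CandidateSolution.from_values(range(1, table.n_features + 1))
    evaluator = SubsetEvaluator(table, plan)
    return evaluator.evaluate(all_features)


def run_method(
    table: FeatureTable, cfg: PipelineConfig, evaluator: SubsetEvaluator | None = None
) -> FsReport:
    """Dispatch one method by name."""
    if cfg.method == "GA_WCC":
        return run_ga_wcc(table, cfg, evaluator)
    if cfg.method == "EN_WCC":
        return run_en_wcc(table, cfg, evaluator)
    if cfg.method == "GA":
        return run_standalone_ga(table, cfg, evaluator)
    if cfg.method == "WCC":
        return run_standalone_wcc(table, cfg, evaluator)
    return run_filter_method(table, cfg, evaluator)


# ---------------------------------------------------------------------------
# multi-execution statistics


def compare_executions(runs_a, runs_b, test: str = "welch") -> dict:
    """Two-sample comparison of terminal fitness lists.

    ``welch`` (default, ANOVA-consistent for two groups) or ``ranksum``.
    Two degenerate equal-constant samples yield p = 1 by convention.
    """
    a = np.asarray(runs_a, dtype=float)
    b = np.asarray(runs_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each execution list needs >= 2 entries")
    if np.std(a) == 0 and np.std(b) == 0:
        if a[0] == b[0]:
            return {"p_value": 1.0, "test_statistic": 0.0, "test": test}
    if test == "welch":
        res = stats.ttest_ind(a, b, equal_var=False)
    elif test == "ranksum":
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
    else:
        raise ValueError(f"unknown test {test!r}")
    return {
        "p_value": float(res.pvalue),
        "test_statistic": float(res.statistic),
        "test": test,
    }


def summarize_executions(runs, confidence: float = 0.95) -> dict:
    """Mean, sample STD and t-based confidence interval of execution results."""
    x = np.asarray(runs, dtype=float)
    if x.size < 2:
        raise ValueError("need >= 2 executions to summarize")
    mean = float(np.mean(x))
    std = float(np.std(x, ddof=1))
    if std == 0:
        lo = hi = mean
    else:
        half = stats.t.ppf(0.5 + confidence / 2, df=x.size - 1) * std / np.sqrt(x.size)
        lo, hi = mean - half, mean + half
    return {
        "mean": mean,
        "std": std,
        "ci_low": float(lo),
        "ci_high": float(hi),
        "confidence": confidence,
        "n": int(x.size),
    }


def run_experiment(
    table: FeatureTable,
    cfg: PipelineConfig,
    reference_runs=None,
    share_evaluator: bool = True,
) -> FsReport:
    """Repeat one method over ``cfg.executions`` seeded runs.

    Returns the best-of-executions report (the full terminal-fitness
    distribution is retained in ``per_execution``) with summary statistics
    and, when ``reference_runs`` is given, a Welch test against it.  A
    shared evaluation cache across executions is exact (scoring is
    deterministic given the plan) and mirrors an identical
    evaluation-count budget across methods.
    """
    evaluator = _make_evaluator(table, cfg) if share_evaluator else None
    reports = []
    for e in range(cfg.executions):
        run_cfg = replace(cfg, seed=cfg.seed + e)
        reports.append(run_method(table, run_cfg, evaluator))
    terminal = tuple(r.panel.fitness for r in reports)
    best_report = reports[int(np.argmax(terminal))]
    summary = (
        summarize_executions(terminal) if cfg.executions >= 2 else None
    )
    if summary is not None and reference_runs is not None:
        summary.update(compare_executions(terminal, reference_runs))
    return replace(
        best_report,
        per_execution=terminal,
        summary_stats=summary,
        config=_config_echo(cfg),
    )
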