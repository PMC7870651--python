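"""Filter baselines: Pearson, Laplacian, entropy, mutual information, Fisher.

Each filter assigns every feature a relevance score without training a
learner; top-k truncation then yields a candidate subset.  These serve both
as standalone baselines and as the reduction step of the two-step
entropy-filter + WCC variant.

Conventions (the standard textbook forms):

- PC: absolute Pearson correlation between feature and label (higher better).
- FI: Fisher score, class-size-weighted between-class variance of class
  means over pooled within-class variance (higher better).
- MI: mutual information in bits between the equal-frequency-binned feature
  and the label (higher better).
- EN: information gain — label entropy minus conditional label entropy
  given the binned feature (higher better).
- LA: Laplacian score on a k-nearest-neighbor heat-kernel graph
  (lower better: locality-preserving features score small).

Constant features receive the method's null value (0 for PC/FI/MI/EN, 1 for
LA) and are flagged degenerate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .candidates import CandidateSolution
from .datasets import CLASSIFICATION, FeatureTable
from .scoring import CvPlan, EvalResult, evaluate_subset

__all__ = [
    "FilterRanking",
    "filter_scores",
    "select_top_k",
    "filter_sweep",
    "FILTER_METHODS",
]

FILTER_METHODS = ("PC", "LA", "EN", "MI", "FI")

HIGHER_BETTER = "higher_better"
LOWER_BETTER = "lower_better"


@dataclass(frozen=True)
class FilterRanking:
    """Per-feature scores plus the direction in which better points."""

    scores: np.ndarray
    direction: str
    method: str
    degenerate: np.ndarray  # boolean mask of constant columns

    def __post_init__(self) -> None:
        object.__setattr__(self, "scores", np.asarray(self.scores, dtype=float))
        object.__setattr__(self, "degenerate", np.asarray(self.degenerate, dtype=bool))
        if self.direction not in (HIGHER_BETTER, LOWER_BETTER):
            raise ValueError(f"unknown direction {self.direction!r}")


def _label_codes(labels: np.ndarray) -> np.ndarray:
    _, codes = np.unique(labels, return_inverse=True)
    return codes


def _equal_frequency_bins(x: np.ndarray, bins: int) -> np.ndarray:
    """Quantile binning; duplicate edges collapse so discrete data keeps its levels."""
    qs = np.quantile(x, np.linspace(0, 1, bins + 1)[1:-1])
    edges = np.unique(qs)
    return np.digitize(x, edges, right=True)


def _entropy_bits(codes: np.ndarray) -> float:
    counts = np.bincount(codes)
    p = counts[counts > 0] / codes.size
    return float(-np.sum(p * np.log2(p)))


def _joint_distribution(x_codes: np.ndarray, y_codes: np.ndarray) -> np.ndarray:
    joint = np.zeros((x_codes.max() + 1, y_codes.max() + 1))
    np.add.at(joint, (x_codes, y_codes), 1.0)
    return joint / x_codes.size


def _mutual_information_bits(x_codes: np.ndarray, y_codes: np.ndarray) -> float:
    """Plug-in MI of two discrete code vectors, in bits."""
    joint = _joint_distribution(x_codes, y_codes)
    px = joint.sum(axis=1, keepdims=True)
    py = joint.sum(axis=0, keepdims=True)
    mask = joint > 0
    return float(np.sum(joint[mask] * np.log2(joint[mask] / (px @ py)[mask])))


def _conditional_label_entropy_bits(x_codes: np.ndarray, y_codes: np.ndarray) -> float:
    """H(y | x) = -sum_xy p(x,y) log2 p(y|x), in bits."""
    joint = _joint_distribution(x_codes, y_codes)
    px = joint.sum(axis=1, keepdims=True)
    mask = joint > 0
    cond = joint / np.where(px > 0, px, 1.0)
    return float(-np.sum(joint[mask] * np.log2(cond[mask])))


def _pearson_scores(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    yc = y - y.mean()
    sy = np.sqrt(np.sum(yc**2))
    Xc = X - X.mean(axis=0)
    sx = np.sqrt(np.sum(Xc**2, axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc.T @ yc) / (sx * sy)
    return np.abs(np.nan_to_num(r, nan=0.0))


def _fisher_scores(X: np.ndarray, codes: np.ndarray) -> np.ndarray:
    """Sum_c n_c (mu_c - mu)^2  /  Sum_c n_c sigma_c^2 (per feature)."""
    mu = X.mean(axis=0)
    num = np.zeros(X.shape[1])
    den = np.zeros(X.shape[1])
    for c in np.unique(codes):
        Xc = X[codes == c]
        nc = Xc.shape[0]
        num += nc * (Xc.mean(axis=0) - mu) ** 2
        den += nc * Xc.var(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        s = num / den
    # zero pooled within-class variance: perfect separation -> +inf score;
    # a fully constant feature (num also 0) scores 0
    s[(den == 0) & (num > 0)] = np.inf
    s[(den == 0) & (num == 0)] = 0.0
    return s


def _laplacian_scores(
    X: np.ndarray, knn: int, kernel_width: float | None
) -> np.ndarray:
    """Laplacian score (He et al. form): f~' L f~ / f~' D f~ on a kNN heat graph."""
    n = X.shape[0]
    D = squareform(pdist(X))
    if kernel_width is None:
        off = D[np.triu_indices(n, k=1)]
        kernel_width = float(np.median(off)) if off.size else 1.0
    if kernel_width <= 0:
        kernel_width = 1.0
    # symmetric kNN adjacency
    order = np.argsort(D, axis=1)
    adj = np.zeros((n, n), dtype=bool)
    k = min(knn, n - 1)
    rows = np.repeat(np.arange(n), k)
    adj[rows, order[:, 1 : k + 1].ravel()] = True
    adj |= adj.T
    W = np.where(adj, np.exp(-(D**2) / (kernel_width**2)), 0.0)
    d = W.sum(axis=1)
    total = d.sum()
    scores = np.empty(X.shape[1])
    for j in range(X.shape[1]):
        f = X[:, j]
        f_t = f - (f @ d) / total  # weighted centering
        den = f_t @ (d * f_t)
        if den <= 0:
            scores[j] = 1.0
            continue
        num = f_t @ (d * f_t) - f_t @ (W @ f_t)  # f' L f with L = D - W
        scores[j] = num / den
    return scores


def filter_scores(
    table: FeatureTable,
    method: str,
    bins: int = 10,
    knn: int = 5,
    kernel_width: float | None = None,
) -> FilterRanking:
    """Score every feature with one of the five filter methods.

    EN/MI/FI require classification labels; PC and LA accept either task.
    ``bins`` controls the equal-frequency discretization for EN/MI.
    """
    method = method.upper()
    if method not in FILTER_METHODS:
        raise ValueError(f"unknown filter method {method!r}")
    X = table.matrix
    if np.isnan(X).any():
        raise ValueError("canonicalize the table before filter scoring")
    degenerate = X.std(axis=0) == 0

    if method in ("EN", "MI", "FI") and table.task != CLASSIFICATION:
        raise ValueError(f"{method} requires classification labels")

    if method == "PC":
        y = (
            _label_codes(table.labels).astype(float)
            if table.task == CLASSIFICATION
            else table.labels.astype(float)
        )
        scores = _pearson_scores(X, y)
        direction = HIGHER_BETTER
    elif method == "FI":
        scores = _fisher_scores(X, _label_codes(table.labels))
        direction = HIGHER_BETTER
    elif method in ("MI", "EN"):
        codes = _label_codes(table.labels)
        h_y = _entropy_bits(codes)
        scores = np.empty(table.n_features)
        for j in range(table.n_features):
            xb = _equal_frequency_bins(X[:, j], bins)
            if method == "MI":
                scores[j] = _mutual_information_bits(xb, codes)
            else:  # EN: information gain H(y) - H(y|x)
                scores[j] = h_y - _conditional_label_entropy_bits(xb, codes)
        direction = HIGHER_BETTER
    else:  # LA
        scores = _laplacian_scores(X, knn=knn, kernel_width=kernel_width)
        direction = LOWER_BETTER

    scores = scores.copy()
    scores[degenerate] = 1.0 if method == "LA" else 0.0
    return FilterRanking(
        scores=scores, direction=direction, method=method, degenerate=degenerate
    )


def select_top_k(ranking: FilterRanking, k: int) -> CandidateSolution:
    """The k best 1-based indices per direction; ties broken by ascending index."""
    n = len(ranking.scores)
    if not 1 <= k <= n:
        raise ValueError(f"k={k} outside [1, {n}]")
    key = -ranking.scores if ranking.direction == HIGHER_BETTER else ranking.scores
    order = np.lexsort((np.arange(n), key))  # stable: score, then index
    return CandidateSolution.from_values(order[:k] + 1)


def filter_sweep(
    table: FeatureTable,
    method: str,
    k_grid,
    plan: CvPlan,
    bins: int = 10,
    **filter_kwargs,
) -> dict[int, EvalResult]:
    """Evaluate the top-k subset of one filter over a grid of k values."""
    ranking = filter_scores(table, method, bins=bins, **filter_kwargs)
    out: dict[int, EvalResult] = {}
    for k in k_grid:
        cs = select_top_k(ranking, int(k))
        out[int(k)] = evaluate_subset(table, cs, plan)
    return out
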