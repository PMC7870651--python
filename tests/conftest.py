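import numpy as np
import pytest

from gawcc.candidates import CandidateSolution
from gawcc.datasets import FeatureTable
from gawcc.scoring import make_cv_plan
from gawcc.synthetic import SyntheticSpec, make_classification


class ScriptedRng:
    """Deterministic stand-in for numpy's Generator: pops scripted draws.

    Each scripted value is validated against the requested range so a test
    that drifts out of sync with the implementation's draw order fails
    loudly instead of silently testing the wrong scenario.
    """

    def __init__(self, values):
        self.values = list(values)

    def integers(self, low, high=None, size=None):
        if size is not None:
            return np.array([self.integers(low, high) for _ in range(size)])
        if high is None:
            low, high = 0, low
        v = self.values.pop(0)
        assert low <= v < high, f"scripted draw {v} outside [{low}, {high})"
        return v


@pytest.fixture
def scripted_rng():
    return ScriptedRng


class DictEvaluator:
    """Deterministic toy fitness oracle over index sets (no SVM involved).

    Scores each subset by a fixed per-feature utility minus a small
    per-feature cost, so the optimum is a known subset and every subset has
    a distinct, reproducible score.
    """

    def __init__(self, n_features, utilities=None, cost=0.01):
        self.n_features = n_features
        if utilities is None:
            rng = np.random.default_rng(12345)
            utilities = rng.uniform(-0.1, 0.2, size=n_features)
        self.utilities = np.asarray(utilities, dtype=float)
        self.cost = cost
        self.n_evals = 0

    def fitness(self, cs: CandidateSolution) -> float:
        self.n_evals += 1
        idx = np.asarray(cs.indices) - 1
        return float(self.utilities[idx].sum() - self.cost * len(idx))

    def exhaustive_best(self):
        # optimum of an additive score: every strictly profitable feature
        keep = np.flatnonzero(self.utilities > self.cost) + 1
        if keep.size == 0:
            keep = np.array([int(np.argmax(self.utilities)) + 1])
        return CandidateSolution.from_values(keep)


@pytest.fixture
def dict_evaluator():
    return DictEvaluator


@pytest.fixture(scope="session")
def separable_table():
    """Tiny table whose labels equal the sign of feature 1; features 2-5 noise."""
    rng = np.random.default_rng(7)
    n = 60
    f1 = np.concatenate([rng.normal(-3, 0.3, n // 2), rng.normal(3, 0.3, n // 2)])
    noise = rng.normal(0, 1, size=(n, 4))
    matrix = np.column_stack([f1, noise])
    labels = np.array(["neg"] * (n // 2) + ["pos"] * (n // 2))
    perm = rng.permutation(n)
    return FeatureTable(
        matrix[perm], labels[perm], ("f1", "f2", "f3", "f4", "f5"), "classification"
    )


@pytest.fixture(scope="session")
def separable_plan(separable_table):
    return make_cv_plan(separable_table, k=5, seed=0)


@pytest.fixture(scope="session")
def planted_small():
    """Moderate-signal planted table used by GA/WCC/pipeline tests."""
    spec = SyntheticSpec(
        n_samples=100,
        n_positive=3,
        n_neutral=12,
        n_negative=3,
        effect_size=1.5,
        seed=11,
    )
    return make_classification(spec)
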