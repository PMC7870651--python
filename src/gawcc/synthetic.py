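"""Planted-feature benchmark generator.

Features fall into three classes: *positive* features carry class (or
target) signal, *neutral* features are label-independent noise, and
*negative* features are actively misleading — they carry the same kind of
structure as positive ones but aligned to a random relabeling of the
samples, so a learner that picks them up chases phantom classes.  Column
positions of the three groups are shuffled; the returned ground truth
records the 1-based index sets so selector output can be scored for
precision and recall over the planted positives.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .candidates import CandidateSolution
from .datasets import CLASSIFICATION, REGRESSION, FeatureTable

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "make_classification",
    "make_regression",
    "recovery_metrics",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for a planted table.

    ``effect_size`` is the standardized separation between adjacent class
    means on each positive feature (classification) in units of
    ``noise_sd``; for regression, positive features enter the target with
    unit coefficients.  ``balance`` gives class proportions (default equal).
    ``n_redundant`` appends noisy copies of random positive features.
    """

    n_samples: int = 200
    n_positive: int = 5
    n_neutral: int = 40
    n_negative: int = 5
    n_classes: int = 2
    effect_size: float = 4.0
    noise_sd: float = 1.0
    balance: tuple[float, ...] | None = None
    n_redundant: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_positive, self.n_neutral, self.n_negative) < 0:
            raise ValueError("feature counts must be non-negative")
        if self.n_positive + self.n_neutral + self.n_negative < 1:
            raise ValueError("need at least one feature")
        if self.n_classes < 2:
            raise ValueError("need >= 2 classes")
        if self.n_samples < 2 * self.n_classes:
            raise ValueError("degenerate spec: need >= 2 samples per class")
        if self.effect_size < 0 or self.noise_sd <= 0:
            raise ValueError("effect_size >= 0 and noise_sd > 0 required")
        if self.balance is not None:
            if len(self.balance) != self.n_classes:
                raise ValueError("balance length must equal n_classes")
            if not np.isclose(sum(self.balance), 1.0):
                raise ValueError("balance proportions must sum to 1")

    @property
    def n_features(self) -> int:
        return self.n_positive + self.n_neutral + self.n_negative + self.n_redundant


@dataclass(frozen=True)
class GroundTruth:
    """1-based index sets of the planted feature groups."""

    positive: tuple[int, ...]
    neutral: tuple[int, ...]
    negative: tuple[int, ...]
    redundant: tuple[int, ...] = ()


def _class_sizes(spec: SyntheticSpec) -> np.ndarray:
    props = (
        np.asarray(spec.balance)
        if spec.balance is not None
        else np.full(spec.n_classes, 1.0 / spec.n_classes)
    )
    sizes = np.floor(props * spec.n_samples).astype(int)
    # distribute the remainder to the largest fractional parts
    rem = spec.n_samples - sizes.sum()
    frac = props * spec.n_samples - sizes
    for i in np.argsort(-frac)[:rem]:
        sizes[i] += 1
    return sizes


def _informative_block(
    labels: np.ndarray, n_cols: int, spec: SyntheticSpec, rng
) -> np.ndarray:
    """Class-conditional Gaussian columns: adjacent class means are
    effect_size * noise_sd apart."""
    means = labels[:, None] * spec.effect_size * spec.noise_sd
    return means + rng.normal(0.0, spec.noise_sd, size=(labels.size, n_cols))


def _assemble(
    blocks: dict[str, np.ndarray], labels: np.ndarray, task: str, rng
) -> tuple[FeatureTable, GroundTruth]:
    group_of: list[str] = []
    cols: list[np.ndarray] = []
    for group in ("positive", "neutral", "negative", "redundant"):
        block = blocks.get(group)
        if block is None or block.shape[1] == 0:
            continue
        for j in range(block.shape[1]):
            cols.append(block[:, j])
            group_of.append(group)
    perm = rng.permutation(len(cols))
    matrix = np.column_stack([cols[i] for i in perm])
    placed: dict[str, list[int]] = {
        "positive": [], "neutral": [], "negative": [], "redundant": []
    }
    for new_pos, old in enumerate(perm):
        placed[group_of[old]].append(new_pos + 1)
    names = tuple(f"f{j + 1}" for j in range(matrix.shape[1]))
    table = FeatureTable(matrix, labels, names, task)
    truth = GroundTruth(
        positive=tuple(sorted(placed["positive"])),
        neutral=tuple(sorted(placed["neutral"])),
        negative=tuple(sorted(placed["negative"])),
        redundant=tuple(sorted(placed["redundant"])),
    )
    return table, truth


def make_classification(spec: SyntheticSpec) -> tuple[FeatureTable, GroundTruth]:
    """Planted classification table.

    Positive features are class-conditional Gaussians; negative features are
    the same construction driven by a random permutation of the labels, so
    their marginal structure mimics signal while misleading the learner.
    """
    rng = np.random.default_rng(spec.seed)
    sizes = _class_sizes(spec)
    labels = np.repeat(np.arange(spec.n_classes), sizes)
    rng.shuffle(labels)

    blocks = {
        "positive": _informative_block(labels, spec.n_positive, spec, rng),
        "neutral": rng.normal(
            0.0, spec.noise_sd, size=(spec.n_samples, spec.n_neutral)
        ),
        "negative": _informative_block(
            rng.permutation(labels), spec.n_negative, spec, rng
        ),
    }
    if spec.n_redundant:
        if spec.n_positive == 0:
            raise ValueError("redundant copies need at least one positive feature")
        src = rng.integers(0, spec.n_positive, size=spec.n_redundant)
        blocks["redundant"] = blocks["positive"][:, src] + rng.normal(
            0.0, 0.1 * spec.noise_sd, size=(spec.n_samples, spec.n_redundant)
        )
    return _assemble(blocks, labels, CLASSIFICATION, rng)


def make_regression(spec: SyntheticSpec) -> tuple[FeatureTable, GroundTruth]:
    """Planted regression table: target = sum of positive features + noise.

    Negative features correlate with a permuted copy of the target.
    """
    rng = np.random.default_rng(spec.seed)
    pos = rng.normal(0.0, 1.0, size=(spec.n_samples, spec.n_positive))
    target = pos.sum(axis=1) + rng.normal(0.0, spec.noise_sd, size=spec.n_samples)
    perm_target = rng.permutation(target)
    blocks = {
        "positive": pos,
        "neutral": rng.normal(
            0.0, spec.noise_sd, size=(spec.n_samples, spec.n_neutral)
        ),
        "negative": perm_target[:, None]
        + rng.normal(0.0, spec.noise_sd, size=(spec.n_samples, spec.n_negative)),
    }
    if spec.n_redundant:
        if spec.n_positive == 0:
            raise ValueError("redundant copies need at least one positive feature")
        src = rng.integers(0, spec.n_positive, size=spec.n_redundant)
        blocks["redundant"] = pos[:, src] + rng.normal(
            0.0, 0.1, size=(spec.n_samples, spec.n_redundant)
        )
    return _assemble(blocks, target, REGRESSION, rng)


def recovery_metrics(
    selected: CandidateSolution, truth: GroundTruth
) -> dict[str, float]:
    """Precision and recall of the selected set against the planted positives."""
    if not truth.positive:
        raise ValueError("recall undefined: empty positive set")
    sel = set(selected.indices)
    pos = set(truth.positive)
    hit = len(sel & pos)
    return {"precision": hit / len(sel), "recall": hit / len(pos)}
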