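"""Candidate solutions: variable-length, duplicate-free, sorted feature-index sets.

Both optimizers (the genetic algorithm and the world-competitive-contests
stage) manipulate the same encoding: a candidate holds the 1-based indices of
the selected features, sorted ascending with duplicates removed.  Operators
that overwrite a position may therefore *shrink* a candidate — the mechanism
by which the search trims the feature count — and can never grow it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator

__all__ = ["CandidateSolution"]


@dataclass(frozen=True)
class CandidateSolution:
    """An immutable, sorted, duplicate-free set of 1-based feature indices."""

    indices: tuple[int, ...]

    def __post_init__(self) -> None:
        idx = tuple(int(i) for i in self.indices)
        if len(idx) == 0:
            raise ValueError("candidate must select at least one feature")
        if any(i < 1 for i in idx):
            raise ValueError(f"indices must be >= 1, got {idx}")
        if list(idx) != sorted(set(idx)):
            raise ValueError(
                f"indices must be strictly increasing without duplicates: {idx}"
            )
        object.__setattr__(self, "indices", idx)

    @classmethod
    def from_values(cls, values: Iterable[int]) -> "CandidateSolution":
        """Build from raw draws: deduplicate and sort (the canonical repair)."""
        return cls(tuple(sorted(set(int(v) for v in values))))

    def validate_against(self, n_features: int) -> None:
        if self.indices[-1] > n_features:
            raise ValueError(
                f"index {self.indices[-1]} exceeds n_features={n_features}"
            )

    def __len__(self) -> int:
        return len(self.indices)

    def __iter__(self) -> Iterator[int]:
        return iter(self.indices)

    def __contains__(self, item: int) -> bool:
        return item in set(self.indices)
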