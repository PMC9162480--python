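"""Scoring of the six-dimension, 12-item hybrid mental-workload scale.

The instrument blends NASA-TLX and SWAT: twelve items rated on a 0-100
bipolar scale (administered in steps of 10) feed six dimensions — mental
demands (MD), physical demands (PD), temporal demands (TD), perceived risk
(PR), frustration level (FL) and performance (Pe). A dimension score is the
mean of its items. Per-respondent dimension weights come from 15 pairwise
comparisons of the six dimensions: the weight of a dimension is the number
of comparisons it won divided by 15, so weights are multiples of 1/15 that
sum to one. The overall mental-workload score (PMW) is the weight-weighted
sum of dimension scores; it is a convex combination and therefore bounded by
the extreme dimension scores.

Scalar single-respondent types live here alongside vectorized scoring over a
whole survey frame (:func:`score_frame`).
"""

from __future__ import annotations

import dataclasses
from collections import Counter
from typing import Mapping

import numpy as np
import pandas as pd

from . import schema

__all__ = [
    "ScaleDefinition",
    "DimensionRatings",
    "DimensionScores",
    "PairwiseComparisons",
    "DimensionWeights",
    "MentalWorkloadAssessment",
    "score_dimensions",
    "derive_weights",
    "compute_pmw",
    "score_frame",
]


@dataclasses.dataclass(frozen=True)
class ScaleDefinition:
    """Item -> dimension assignment of the scale.

    The 12-item / 6-dimension structure is fixed; the exact assignment is
    configurable (default: two consecutive items per dimension).
    """

    item_to_dimension: Mapping[str, str]

    @classmethod
    def default(cls) -> "ScaleDefinition":
        return cls(schema.default_item_map())

    def __post_init__(self) -> None:
        if len(self.item_to_dimension) != schema.N_ITEMS:
            raise ValueError(f"expected {schema.N_ITEMS} items")
        dims = set(self.item_to_dimension.values())
        missing = set(schema.DIMENSIONS) - dims
        if missing:
            raise ValueError(f"dimension(s) with zero items: {sorted(missing)}")

    def items_of(self, dimension: str) -> list[str]:
        return [i for i, d in self.item_to_dimension.items() if d == dimension]


@dataclasses.dataclass(frozen=True)
class DimensionRatings:
    """Ratings of the 12 items, each in [0, 100]."""

    items: Mapping[str, float]
    scale: ScaleDefinition = dataclasses.field(default_factory=ScaleDefinition.default)

    def __post_init__(self) -> None:
        if set(self.items) != set(self.scale.item_to_dimension):
            raise ValueError("item identifiers do not match the scale definition")
        for k, v in self.items.items():
            if not 0 <= v <= 100:
                raise ValueError(f"item {k} rating {v} outside [0,100]")


@dataclasses.dataclass(frozen=True)
class DimensionScores:
    scores: Mapping[str, float]

    def __post_init__(self) -> None:
        if set(self.scores) != set(schema.DIMENSIONS):
            raise ValueError("all six dimensions must be present")


@dataclasses.dataclass(frozen=True)
class PairwiseComparisons:
    """One winning dimension per unordered pair; all 15 pairs exactly once."""

    picks: Mapping[tuple[str, str], str]

    def __post_init__(self) -> None:
        expected = set(schema.DIMENSION_PAIRS)
        got = {tuple(sorted(p, key=schema.DIMENSIONS.index)) for p in self.picks}
        if got != expected or len(self.picks) != schema.N_COMPARISONS:
            missing = expected - got
            extra = got - expected
            raise ValueError(
                f"comparisons must cover each of the 15 pairs exactly once "
                f"(missing {sorted(missing)}, unexpected {sorted(extra)})"
            )
        for pair, winner in self.picks.items():
            if winner not in pair:
                raise ValueError(f"winner {winner!r} not a member of pair {pair}")


@dataclasses.dataclass(frozen=True)
class DimensionWeights:
    weights: Mapping[str, float]

    def __post_init__(self) -> None:
        total = sum(self.weights.values())
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"weights sum to {total}, expected 1")


@dataclasses.dataclass(frozen=True)
class MentalWorkloadAssessment:
    """One task group's full assessment: ratings plus comparisons."""

    ratings: DimensionRatings
    comparisons: PairwiseComparisons
    task_group: str = "communication"

    def pmw(self) -> float:
        return compute_pmw(score_dimensions(self.ratings), derive_weights(self.comparisons))


def score_dimensions(ratings: DimensionRatings) -> DimensionScores:
    """Dimension score = arithmetic mean of its items' ratings."""
    out = {}
    for dim in schema.DIMENSIONS:
        items = ratings.scale.items_of(dim)
        out[dim] = float(np.mean([ratings.items[i] for i in items]))
    return DimensionScores(out)


def derive_weights(comparisons: PairwiseComparisons) -> DimensionWeights:
    """Weight = number of pairwise wins / 15."""
    wins = Counter(comparisons.picks.values())
    return DimensionWeights(
        {d: wins.get(d, 0) / schema.N_COMPARISONS for d in schema.DIMENSIONS}
    )


def compute_pmw(scores: DimensionScores, weights: DimensionWeights) -> float:
    """Overall mental workload: weighted sum of dimension scores."""
    return float(
        sum(scores.scores[d] * weights.weights[d] for d in schema.DIMENSIONS)
    )


# ---------------------------------------------------------------------------
# Vectorized scoring over a survey frame
# ---------------------------------------------------------------------------

def score_frame(
    frame: pd.DataFrame,
    group: str,
    scale: ScaleDefinition | None = None,
) -> pd.DataFrame:
    """Score one task group's assessment for every row of a survey frame.

    Returns a DataFrame indexed like ``frame`` with one column per dimension
    score, one ``w_<dim>`` column per weight, and ``pmw``.
    """
    if group not in schema.TASK_GROUPS:
        raise ValueError(f"unknown task group {group!r}")
    scale = scale or ScaleDefinition.default()
    out = pd.DataFrame(index=frame.index)
    for dim in schema.DIMENSIONS:
        cols = [
            schema.item_column(group, int(i)) for i in scale.items_of(dim)
        ]
        out[dim] = frame[cols].mean(axis=1)
    wins = pd.DataFrame(0.0, index=frame.index, columns=list(schema.DIMENSIONS))
    for pair in schema.DIMENSION_PAIRS:
        picks = frame[schema.pick_column(group, pair)]
        for dim in pair:
            wins[dim] += (picks == dim).astype(float)
    for dim in schema.DIMENSIONS:
        out[f"w_{dim}"] = wins[dim] / schema.N_COMPARISONS
    out["pmw"] = sum(
        out[d] * out[f"w_{d}"] for d in schema.DIMENSIONS
    )
    return out
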