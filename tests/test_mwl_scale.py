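"""Scale scoring: dimension means, pairwise weights, weighted total."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pcw import schema
from pcw.mwl_scale import (
    DimensionRatings,
    DimensionScores,
    DimensionWeights,
    PairwiseComparisons,
    ScaleDefinition,
    compute_pmw,
    derive_weights,
    score_dimensions,
    score_frame,
)
from pcw.synthetic_data import GeneratorConfig, sample_population

# ---------------------------------------------------------------------------
# independent brute-force oracles
# ---------------------------------------------------------------------------

def oracle_dimension_means(items: dict, mapping: dict) -> dict:
    sums, counts = {}, {}
    for item, rating in items.items():
        d = mapping[item]
        sums[d] = sums.get(d, 0.0) + rating
        counts[d] = counts.get(d, 0) + 1
    return {d: sums[d] / counts[d] for d in sums}


def oracle_pmw(items: dict, mapping: dict, picks: dict) -> float:
    means = oracle_dimension_means(items, mapping)
    total = 0.0
    for d in schema.DIMENSIONS:
        wins = sum(1 for w in picks.values() if w == d)
        total += means[d] * wins / 15.0
    return total


def make_ratings(values) -> DimensionRatings:
    return DimensionRatings({str(k + 1): v for k, v in enumerate(values)})


def ranking_picks(order) -> PairwiseComparisons:
    """Picks implied by a strict ranking (first element beats everything)."""
    rank = {d: i for i, d in enumerate(order)}
    return PairwiseComparisons(
        {p: min(p, key=rank.get) for p in schema.DIMENSION_PAIRS}
    )


picks_strategy = st.tuples(*[st.booleans() for _ in range(15)]).map(
    lambda bs: PairwiseComparisons(
        {p: p[b] for p, b in zip(schema.DIMENSION_PAIRS, bs)}
    )
)
ratings_strategy = st.lists(
    st.integers(0, 10).map(lambda k: 10.0 * k), min_size=12, max_size=12
).map(make_ratings)


class TestScoreDimensions:
    def test_all_zero(self):
        scores = score_dimensions(make_ratings([0.0] * 12))
        assert all(v == 0 for v in scores.scores.values())

    def test_pair_mean(self):
        ratings = make_ratings([40, 60] + [0] * 10)
        assert score_dimensions(ratings).scores["MD"] == 50

    def test_matches_oracle_on_distinct_values(self):
        values = [10, 80, 30, 50, 0, 100, 20, 60, 40, 90, 70, 10]
        ratings = make_ratings(values)
        expected = oracle_dimension_means(ratings.items, ratings.scale.item_to_dimension)
        assert score_dimensions(ratings).scores == pytest.approx(expected)

    def test_out_of_range_rating_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            make_ratings([150] + [0] * 11)

    def test_dimension_without_items_is_config_error(self):
        mapping = {str(k): "MD" for k in range(1, 13)}
        with pytest.raises(ValueError, match="zero items"):
            ScaleDefinition(mapping)


class TestDeriveWeights:
    def test_full_strict_ranking_forces_counts_5_to_0(self):
        weights = derive_weights(ranking_picks(schema.DIMENSIONS))
        expected = dict(zip(schema.DIMENSIONS, [5, 4, 3, 2, 1, 0]))
        for d, k in expected.items():
            assert weights.weights[d] == pytest.approx(k / 15)

    def test_total_loser_has_zero_weight(self):
        weights = derive_weights(ranking_picks(schema.DIMENSIONS))
        assert weights.weights["Pe"] == 0.0

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(picks_strategy)
    def test_weights_sum_to_one_and_are_multiples_of_one_fifteenth(self, picks):
        weights = derive_weights(picks)
        assert sum(weights.weights.values()) == pytest.approx(1.0, abs=1e-12)
        for w in weights.weights.values():
            assert (15 * w) == pytest.approx(round(15 * w))
            assert 0 <= w <= 5 / 15

    def test_missing_pair_rejected(self):
        picks = {p: p[0] for p in schema.DIMENSION_PAIRS[:-1]}
        picks[("MD", "PD")] = "MD"  # duplicate-by-omission: 14 distinct pairs
        with pytest.raises(ValueError, match="15 pairs"):
            PairwiseComparisons(picks)

    def test_foreign_winner_rejected(self):
        picks = {p: p[0] for p in schema.DIMENSION_PAIRS}
        picks[("MD", "PD")] = "TD"
        with pytest.raises(ValueError, match="not a member"):
            PairwiseComparisons(picks)


class TestComputePmw:
    def test_constant_scores_give_constant(self):
        scores = DimensionScores({d: 42.0 for d in schema.DIMENSIONS})
        weights = derive_weights(ranking_picks(schema.DIMENSIONS))
        assert compute_pmw(scores, weights) == pytest.approx(42.0)

    def test_hand_computed_weighted_sum(self):
        scores = DimensionScores(
            dict(zip(schema.DIMENSIONS, [60, 50, 40, 70, 30, 80]))
        )
        weights = DimensionWeights(
            dict(zip(schema.DIMENSIONS, [5 / 15, 4 / 15, 3 / 15, 2 / 15, 1 / 15, 0]))
        )
        assert compute_pmw(scores, weights) == pytest.approx(52.667, abs=5e-4)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(ratings_strategy, picks_strategy)
    def test_convex_combination_bounds(self, ratings, picks):
        pmw = compute_pmw(score_dimensions(ratings), derive_weights(picks))
        scores = score_dimensions(ratings).scores
        assert min(scores.values()) - 1e-9 <= pmw <= max(scores.values()) + 1e-9
        assert 0 <= pmw <= 100

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(ratings_strategy, picks_strategy, st.integers(0, 11))
    def test_raising_one_item_never_decreases_pmw(self, ratings, picks, k):
        weights = derive_weights(picks)
        base = compute_pmw(score_dimensions(ratings), weights)
        bumped_items = dict(ratings.items)
        key = str(k + 1)
        bumped_items[key] = min(100.0, bumped_items[key] + 10.0)
        bumped = compute_pmw(score_dimensions(make_ratings(
            [bumped_items[str(i + 1)] for i in range(12)])), weights)
        assert bumped >= base - 1e-9


def test_pmw_matches_bruteforce_oracle_on_random_assessments(rng):
    for _ in range(1000):
        values = 10.0 * rng.integers(0, 11, size=12)
        ratings = make_ratings(values)
        picks = PairwiseComparisons(
            {p: p[rng.integers(0, 2)] for p in schema.DIMENSION_PAIRS}
        )
        got = compute_pmw(score_dimensions(ratings), derive_weights(picks))
        want = oracle_pmw(ratings.items, ratings.scale.item_to_dimension, picks.picks)
        assert got == pytest.approx(want, abs=1e-10)


def test_pmw_invariant_under_pair_order_permutation(rng):
    values = 10.0 * rng.integers(0, 11, size=12)
    ratings = make_ratings(values)
    raw = [(p, p[rng.integers(0, 2)]) for p in schema.DIMENSION_PAIRS]
    a = PairwiseComparisons(dict(raw))
    b = PairwiseComparisons(dict(reversed(raw)))
    base = compute_pmw(score_dimensions(ratings), derive_weights(a))
    assert compute_pmw(score_dimensions(ratings), derive_weights(b)) == base


def test_vectorized_scoring_matches_scalar_path():
    data = sample_population(GeneratorConfig(n=25, seed=5))
    scored = score_frame(data.frame, "comm")
    for idx in [0, 7, 24]:
        row = data.frame.loc[idx]
        items = {
            str(k): row[schema.item_column("comm", k)] for k in range(1, 13)
        }
        picks = {
            p: row[schema.pick_column("comm", p)] for p in schema.DIMENSION_PAIRS
        }
        want = oracle_pmw(items, schema.default_item_map(), picks)
        assert scored.loc[idx, "pmw"] == pytest.approx(want, abs=1e-10)
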