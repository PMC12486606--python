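"""Scoring formula oracles and structural properties of index totals."""

import random

import pytest
from hypothesis import given
from hypothesis import strategies as st

from dietscore.errors import ParameterError
from dietscore.model import (
    ComponentRule,
    Direction,
    IndexDefinition,
    IntakeProfile,
    PopulationId,
    RuleKind,
)
from dietscore.scoring import (
    compute_index_score,
    optimal_profile,
    score_adequacy,
    score_binary_cutoff,
    score_component,
    score_moderation,
    score_ordinal,
    score_processed_meat,
    score_zero_tolerance,
    worst_profile,
)

intakes = st.floats(min_value=0.0, max_value=2000.0, allow_nan=False)


@pytest.mark.parametrize(
    "intake, lower, recommended, expected",
    [
        (125.0, 100.0, 125.0, 10.0),  # at the recommendation
        (100.0, 100.0, 125.0, 0.0),  # at the lower bound
        (112.5, 100.0, 125.0, 5.0),  # midpoint: 10 * 12.5 / 25
        (150.0, 100.0, 125.0, 10.0),  # over-consumption clamps, no penalty
        (0.0, 100.0, 125.0, 0.0),
        (37.5, 0.0, 75.0, 5.0),
    ],
)
def test_adequacy_matches_hand_evaluation(intake, lower, recommended, expected):
    assert score_adequacy(intake, lower, recommended) == pytest.approx(expected)


@pytest.mark.parametrize(
    "intake, recommended, upper, expected",
    [
        (14.0, 14.0, 28.0, 10.0),  # at the recommendation
        (28.0, 14.0, 28.0, 0.0),  # at the upper bound
        (21.0, 14.0, 28.0, 5.0),  # midpoint: 10 * (14 - 7) / 14
        (0.0, 14.0, 28.0, 10.0),  # below recommendation is fully adherent
        (100.0, 14.0, 28.0, 0.0),
    ],
)
def test_moderation_matches_hand_evaluation(intake, recommended, upper, expected):
    assert score_moderation(intake, recommended, upper) == pytest.approx(expected)


@pytest.mark.parametrize(
    "intake, cutoff, expected",
    [(5.0, 11.8, 10.0), (15.0, 11.8, 0.0), (0.0, 31.0, 10.0), (11.8, 11.8, 0.0)],
)
def test_binary_cutoff_low_is_adherent(intake, cutoff, expected):
    assert score_binary_cutoff(intake, cutoff) == expected


def test_binary_cutoff_orientation_switch():
    assert score_binary_cutoff(5.0, 11.8, orientation="high_is_adherent") == 0.0
    assert score_binary_cutoff(15.0, 11.8, orientation="high_is_adherent") == 10.0


@pytest.mark.parametrize("intake, expected", [(0.0, 10.0), (0.1, 0.0), (120.0, 0.0)])
def test_zero_tolerance_alcohol_rule(intake, expected):
    assert score_zero_tolerance(intake) == expected


@pytest.mark.parametrize(
    "intake, expected",
    [(1.0, 10.0), (5.0, 0.0), (3.0, 5.0), (2.0, 10.0), (4.0, 0.0)],
)
def test_processed_meat_two_to_four_gram_rule(intake, expected):
    assert score_processed_meat(intake) == pytest.approx(expected)


@pytest.mark.parametrize(
    "intake, direction, expected",
    [
        (5.0, Direction.LOWER_IS_BETTER, 3),  # below all thresholds
        (35.0, Direction.LOWER_IS_BETTER, 0),  # above all thresholds
        (25.0, Direction.HIGHER_IS_BETTER, 2),
        (30.0, Direction.HIGHER_IS_BETTER, 3),  # closed on the adherent side
        (5.0, Direction.HIGHER_IS_BETTER, 0),
        (15.0, Direction.LOWER_IS_BETTER, 2),
    ],
)
def test_ordinal_band_enumeration(intake, direction, expected):
    rule = ComponentRule(RuleKind.ORDINAL_BAND, bands=(10.0, 20.0, 30.0), direction=direction)
    assert score_ordinal(intake, rule) == expected


def test_invalid_parameters_raise():
    with pytest.raises(ParameterError):
        score_adequacy(10.0, 125.0, 100.0)
    with pytest.raises(ParameterError):
        score_moderation(10.0, 28.0, 14.0)
    with pytest.raises(ParameterError):
        score_binary_cutoff(-1.0, 11.8)


# --- properties --------------------------------------------------------------

_RULES = [
    ComponentRule(RuleKind.ADEQUACY, lower=100.0, recommended=125.0),
    ComponentRule(RuleKind.ADEQUACY, lower=0.0, recommended=75.0),
    ComponentRule(RuleKind.MODERATION, recommended=14.0, upper=28.0),
    ComponentRule(RuleKind.BINARY_CUTOFF, cutoff=11.8),
    ComponentRule(RuleKind.ZERO_TOLERANCE),
    ComponentRule(RuleKind.ORDINAL_BAND, bands=(10.0, 20.0, 30.0), direction=Direction.HIGHER_IS_BETTER),
    ComponentRule(RuleKind.ORDINAL_BAND, bands=(10.0, 20.0, 30.0), direction=Direction.LOWER_IS_BETTER),
]


@given(intake=intakes)
def test_every_rule_scores_within_bounds(intake):
    for rule in _RULES:
        points = score_component(intake, rule)
        assert 0.0 <= points <= rule.max_points
        if rule.kind is RuleKind.ORDINAL_BAND:
            assert float(points).is_integer()


@given(x=intakes, y=intakes)
def test_proportional_rules_are_monotone(x, y):
    lo, hi = sorted((x, y))
    assert score_adequacy(lo, 100.0, 125.0) <= score_adequacy(hi, 100.0, 125.0)
    assert score_moderation(lo, 14.0, 28.0) >= score_moderation(hi, 14.0, 28.0)


@given(x=st.floats(min_value=0.0, max_value=500.0), h=st.floats(min_value=0.0, max_value=1.0))
def test_proportional_rules_are_continuous(x, h):
    # Lipschitz bound implied by piecewise linearity with slope 10/span
    assert abs(score_adequacy(x + h, 100.0, 125.0) - score_adequacy(x, 100.0, 125.0)) <= 10.0 * h / 25.0 + 1e-9
    assert abs(score_moderation(x + h, 14.0, 28.0) - score_moderation(x, 14.0, 28.0)) <= 10.0 * h / 14.0 + 1e-9


def test_index_totals_at_theoretical_extremes(wish, wish2, eat):
    for index in (wish, wish2, eat):
        assert compute_index_score(optimal_profile(index), index).total == index.theoretical_max
        assert compute_index_score(worst_profile(index), index).total == 0.0


def test_one_half_scored_component_lowers_wish2_total_by_five(wish2):
    profile = optimal_profile(wish2)
    # fruits at the midpoint of its adequacy ramp scores 5 instead of 10
    rule = wish2.rule("fruits")
    profile = profile.with_intakes(fruits=(rule.lower + rule.recommended) / 2.0)
    assert compute_index_score(profile, wish2).total == pytest.approx(145.0)


def test_total_is_sum_of_components_and_order_invariant(wish2):
    profile = optimal_profile(wish2).with_intakes(fruits=130.0, eggs=20.0)
    score = compute_index_score(profile, wish2)
    assert score.total == pytest.approx(sum(c.points for c in score.components))

    rng = random.Random(7)
    shuffled = list(wish2.components)
    rng.shuffle(shuffled)
    permuted = IndexDefinition(wish2.name, tuple(shuffled), wish2.per_component_max)
    assert compute_index_score(profile, permuted).total == pytest.approx(score.total)


@given(
    red=st.floats(min_value=0.0, max_value=100.0),
    processed=st.floats(min_value=0.0, max_value=50.0),
    data=st.data(),
)
def test_wish2_total_decomposes_into_wish_plus_new_components(wish, wish2, red, processed, data):
    """WISH on combined red meat equals WISH 2.0's shared 13 components when
    WISH 2.0 sees unprocessed red meat only; the full WISH 2.0 total adds the
    processed-meat and alcohol points on top."""
    alcohol = data.draw(st.sampled_from([0.0, 15.0]))
    base = {
        comp.id: data.draw(intakes, label=comp.id)
        for comp, _ in wish.components
        if comp.id != "red_meat"
    }
    wish_profile = IntakeProfile(PopulationId("P"), {**base, "red_meat": red + processed})
    wish2_profile = IntakeProfile(
        PopulationId("P"),
        {**base, "red_meat": red, "processed_meat": processed, "alcoholic_beverages": alcohol},
    )
    wish_total = compute_index_score(wish_profile, wish).total
    wish2_score = compute_index_score(wish2_profile, wish2)
    by_comp = wish2_score.points_by_component()
    shared = wish2_score.total - by_comp["processed_meat"] - by_comp["alcoholic_beverages"]

    red_rule = wish.rule("red_meat")
    wish_without_red = wish_total - score_moderation(red + processed, red_rule.recommended, red_rule.upper)
    shared_without_red = shared - score_moderation(red, red_rule.recommended, red_rule.upper)
    assert shared_without_red == pytest.approx(wish_without_red)
    # identical red-meat inputs make the shared 13 components coincide,
    # so the WISH 2.0 total is the WISH total plus the two new components
    # (the published tables had both new components at 0 everywhere,
    # hence identical WISH and WISH 2.0 totals)
    if processed == 0.0:
        assert shared == pytest.approx(wish_total)
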