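"""Component scoring rules and index totals.

The two continuous indices (WISH, WISH 2.0) award each food group 0-10
points. Food groups whose consumption should be encouraged use the
*adequacy* formula, rising linearly from a lower recommended intake to
the recommended intake::

    points = 10 * (intake - lower) / (recommended - lower)

Food groups whose consumption should be limited use the *moderation*
formula, falling linearly from the recommended intake to an upper
recommended intake::

    points = 10 * ((upper - recommended) - (intake - recommended)) / (upper - recommended)

Both are clamped to [0, 10]. Saturated oils and added sugar are binary
(10 below the cut-off, 0 at or above); alcoholic beverages follow a
zero-tolerance rule (10 only at zero intake); processed meat uses the
moderation formula over the 2-4 g/day range, i.e. 10 below 2 g/day and
0 above 4 g/day. The EAT-Lancet index scores each group ordinally 0-3
over three thresholds.

Boundary conventions: adequacy at the lower bound scores 0; moderation
at the upper bound scores 0; a binary component exactly at the cut-off
scores 0; ordinal bands are closed on the adherent side. Totals are kept
at full precision — rounding to one decimal is a reporting concern.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ParameterError
from .model import (
    ComponentRule,
    Direction,
    IndexDefinition,
    IntakeProfile,
    PopulationId,
    RuleKind,
    validate_profile,
)

__all__ = [
    "ComponentScore",
    "IndexScore",
    "score_adequacy",
    "score_moderation",
    "score_binary_cutoff",
    "score_zero_tolerance",
    "score_processed_meat",
    "score_ordinal",
    "score_component",
    "compute_index_score",
    "optimal_intake",
    "worst_intake",
    "optimal_profile",
    "worst_profile",
]

#: intakes at or below this count as zero for the zero-tolerance rule,
#: absorbing float noise from upstream crosswalk arithmetic
ZERO_TOLERANCE_EPS = 1e-9


def _check_intake(intake: float) -> float:
    intake = float(intake)
    if not intake >= 0:
        raise ParameterError(f"intake must be non-negative, got {intake}")
    return intake


def score_adequacy(intake: float, lower: float, recommended: float) -> float:
    """Proportional score for an encouraged food group, clamped to [0, 10]."""
    intake = _check_intake(intake)
    if not lower < recommended:
        raise ParameterError(
            f"adequacy requires lower < recommended, got {lower} >= {recommended}"
        )
    raw = 10.0 * (intake - lower) / (recommended - lower)
    return min(10.0, max(0.0, raw))


def score_moderation(intake: float, recommended: float, upper: float) -> float:
    """Proportional score for a limited food group, clamped to [0, 10]."""
    intake = _check_intake(intake)
    if not recommended < upper:
        raise ParameterError(
            f"moderation requires recommended < upper, got {recommended} >= {upper}"
        )
    raw = 10.0 * ((upper - recommended) - (intake - recommended)) / (upper - recommended)
    return min(10.0, max(0.0, raw))


def score_binary_cutoff(
    intake: float, cutoff: float, orientation: str = "low_is_adherent"
) -> float:
    """Bivariate score: 10 on the adherent side of the cut-off, else 0.

    The default orientation awards 10 strictly below the cut-off, keeping
    saturated oils and added sugar consistent with the alcohol rule.
    """
    intake = _check_intake(intake)
    if not cutoff > 0:
        raise ParameterError(f"cutoff must be positive, got {cutoff}")
    below = intake < cutoff
    if orientation == "low_is_adherent":
        return 10.0 if below else 0.0
    if orientation == "high_is_adherent":
        return 0.0 if below else 10.0
    raise ParameterError(f"unknown orientation {orientation!r}")


def score_zero_tolerance(intake: float) -> float:
    """10 points only for (numerically) zero intake, 0 otherwise."""
    intake = _check_intake(intake)
    return 10.0 if intake <= ZERO_TOLERANCE_EPS else 0.0


def score_processed_meat(intake: float) -> float:
    """10 below 2 g/day, 0 above 4 g/day, moderation formula between."""
    return score_moderation(intake, 2.0, 4.0)


def score_ordinal(intake: float, rule: ComponentRule) -> int:
    """Ordinal 0-3 adherence band over the rule's three thresholds.

    ``higher_is_better`` counts bands upward (>= top threshold -> 3);
    ``lower_is_better`` downward (<= bottom threshold -> 3). Bands are
    closed on the adherent side.
    """
    intake = _check_intake(intake)
    if rule.kind is not RuleKind.ORDINAL_BAND:
        raise ParameterError(f"score_ordinal needs an ordinal_band rule, got {rule.kind}")
    t1, t2, t3 = rule.bands
    if rule.direction is Direction.HIGHER_IS_BETTER:
        if intake >= t3:
            return 3
        if intake >= t2:
            return 2
        if intake >= t1:
            return 1
        return 0
    if intake <= t1:
        return 3
    if intake <= t2:
        return 2
    if intake <= t3:
        return 1
    return 0


def score_component(intake: float, rule: ComponentRule) -> float:
    """Dispatch ``intake`` to the rule's scoring function."""
    kind = rule.kind
    if kind is RuleKind.ADEQUACY:
        return score_adequacy(intake, rule.lower, rule.recommended)
    if kind is RuleKind.MODERATION:
        return score_moderation(intake, rule.recommended, rule.upper)
    if kind is RuleKind.BINARY_CUTOFF:
        return score_binary_cutoff(intake, rule.cutoff, rule.cutoff_orientation)
    if kind is RuleKind.ZERO_TOLERANCE:
        return score_zero_tolerance(intake)
    if kind is RuleKind.ORDINAL_BAND:
        return float(score_ordinal(intake, rule))
    raise ParameterError(f"unknown rule kind {kind!r}")


@dataclass(frozen=True)
class ComponentScore:
    component_id: str
    points: float
    rule_kind: RuleKind


@dataclass(frozen=True)
class IndexScore:
    """Per-component points and their sum for one stratum under one index."""

    population_id: PopulationId
    index_name: str
    components: tuple[ComponentScore, ...]

    @property
    def total(self) -> float:
        return float(sum(c.points for c in self.components))

    def points_by_component(self) -> dict[str, float]:
        return {c.component_id: c.points for c in self.components}


def compute_index_score(profile: IntakeProfile, index: IndexDefinition) -> IndexScore:
    """Score every component of ``index`` against ``profile``.

    The profile must carry an intake for every component (see
    :func:`dietscore.model.validate_profile`); extra categories are
    ignored. The order of components does not affect the total.
    """
    validate_profile(profile, index)
    components = tuple(
        ComponentScore(
            component_id=comp.id,
            points=score_component(profile.intakes[comp.id], rule),
            rule_kind=rule.kind,
        )
        for comp, rule in index.components
    )
    return IndexScore(
        population_id=profile.population_id,
        index_name=index.name,
        components=components,
    )


def optimal_intake(rule: ComponentRule) -> float:
    """An intake earning the rule's maximum points."""
    kind = rule.kind
    if kind is RuleKind.ADEQUACY:
        return float(rule.recommended)
    if kind is RuleKind.MODERATION:
        return float(rule.recommended)
    if kind in (RuleKind.BINARY_CUTOFF, RuleKind.ZERO_TOLERANCE):
        return 0.0
    if rule.direction is Direction.HIGHER_IS_BETTER:
        return float(rule.bands[2])
    return 0.0


def worst_intake(rule: ComponentRule) -> float:
    """An intake earning zero points."""
    kind = rule.kind
    if kind is RuleKind.ADEQUACY:
        return float(rule.lower)
    if kind is RuleKind.MODERATION:
        return float(rule.upper)
    if kind is RuleKind.BINARY_CUTOFF:
        return float(rule.cutoff)
    if kind is RuleKind.ZERO_TOLERANCE:
        return 1.0
    if rule.direction is Direction.HIGHER_IS_BETTER:
        return 0.0
    return float(rule.bands[2]) + 1.0


def _profile_at(index: IndexDefinition, pick, population_id: PopulationId | None) -> IntakeProfile:
    pid = population_id or PopulationId("reference")
    return IntakeProfile(pid, {comp.id: pick(rule) for comp, rule in index.components})


def optimal_profile(index: IndexDefinition, population_id: PopulationId | None = None) -> IntakeProfile:
    """A profile meeting every component's optimal intake (scores the
    index's theoretical maximum)."""
    return _profile_at(index, optimal_intake, population_id)


def worst_profile(index: IndexDefinition, population_id: PopulationId | None = None) -> IntakeProfile:
    """A profile at every component's worst intake (scores 0)."""
    return _profile_at(index, worst_intake, population_id)
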