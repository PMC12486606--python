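"""Min-max normalization to theoretical bounds and descriptive comparison.

Raw totals of the three indices live on different scales (0-130, 0-150,
0-42), so cross-index comparison rescales each total to the unit
interval against its index's *theoretical* minimum and maximum::

    x' = (x - min(x)) / (max(x) - min(x))

Summaries use the sample (n-1) standard deviation over population
strata. Reporting conventions: totals to 1 decimal, normalized values
to 2 decimals, SDs to 3 decimals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

from .errors import PairingError, ParameterError, RangeError
from .model import Gender, IndexDefinition, PopulationId

__all__ = [
    "NormalizedScore",
    "ScoreSummary",
    "GenderGapReport",
    "min_max_normalize",
    "summarize_scores",
    "gender_gap",
]


@dataclass(frozen=True)
class NormalizedScore:
    """A unit-interval index score for one population stratum."""

    population_id: PopulationId
    index_name: str
    value: float

    def __post_init__(self):
        if not 0.0 <= self.value <= 1.0:
            raise RangeError(f"normalized value outside [0, 1]: {self.value}")


def min_max_normalize(total: float, index: IndexDefinition) -> float:
    """Rescale a raw total to [0, 1] using the index's theoretical bounds."""
    lo, hi = index.theoretical_min, index.theoretical_max
    if not lo <= total <= hi:
        raise RangeError(
            f"total {total} outside theoretical bounds [{lo}, {hi}] of {index.name}"
        )
    return (float(total) - lo) / (hi - lo)


def normalize_score(total: float, index: IndexDefinition, population_id: PopulationId) -> NormalizedScore:
    return NormalizedScore(
        population_id=population_id,
        index_name=index.name,
        value=min_max_normalize(total, index),
    )


@dataclass(frozen=True)
class ScoreSummary:
    index_name: str
    n: int
    mean: float
    sd: float
    ranking: tuple[PopulationId, ...]


def summarize_scores(values: Iterable[NormalizedScore]) -> ScoreSummary:
    """Mean, sample SD and a descending ranking of normalized scores.

    All scores must belong to the same index; ties in the ranking break
    by ascending population id for determinism. The SD uses the n-1
    denominator and needs at least two values.
    """
    values = list(values)
    names = {v.index_name for v in values}
    if len(names) != 1:
        raise ParameterError(f"summarize_scores needs a single index, got {sorted(names)}")
    n = len(values)
    if n < 2:
        raise ParameterError(f"sample SD undefined for n={n} (need n >= 2)")
    mean = sum(v.value for v in values) / n
    sd = math.sqrt(sum((v.value - mean) ** 2 for v in values) / (n - 1))
    ranking = tuple(
        v.population_id
        for v in sorted(values, key=lambda v: (-v.value, v.population_id))
    )
    return ScoreSummary(index_name=names.pop(), n=n, mean=mean, sd=sd, ranking=ranking)


@dataclass(frozen=True)
class GenderGapReport:
    """Per-country female-minus-male differences on any score scale."""

    differences: Mapping[str, float]
    mean_female: float
    mean_male: float

    @property
    def n_female_higher(self) -> int:
        return sum(1 for d in self.differences.values() if d > 0)


def gender_gap(scores: Mapping[PopulationId, float]) -> GenderGapReport:
    """Pair female/male strata by country and report signed differences.

    ``scores`` maps population strata to values on any scale (raw totals
    or normalized); ``total`` strata are ignored. Every country must have
    both a female and a male entry.
    """
    by_country: dict[str, dict[Gender, float]] = {}
    for pid, value in scores.items():
        if pid.gender is Gender.TOTAL:
            continue
        by_country.setdefault(pid.country, {})[pid.gender] = float(value)
    if not by_country:
        raise PairingError("no gender-stratified scores supplied")
    unpaired = sorted(
        c for c, strata in by_country.items()
        if Gender.FEMALE not in strata or Gender.MALE not in strata
    )
    if unpaired:
        raise PairingError(f"countries missing a gender stratum: {', '.join(unpaired)}")
    diffs = {
        country: strata[Gender.FEMALE] - strata[Gender.MALE]
        for country, strata in sorted(by_country.items())
    }
    n = len(by_country)
    return GenderGapReport(
        differences=diffs,
        mean_female=sum(s[Gender.FEMALE] for s in by_country.values()) / n,
        mean_male=sum(s[Gender.MALE] for s in by_country.values()) / n,
    )
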