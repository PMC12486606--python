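"""Synthetic EFSA-like survey tables and printed regression fixtures.

The generator emulates the structure of summary exports from a
harmonized European food-consumption database: one mean intake (g/day)
per country x gender stratum x source food category. Countries are
drawn around regional dietary *archetypes* (Mediterranean / Western /
Eastern / Northern) whose category means and gender offsets live in
``data/archetypes.yaml``.

Noise is multiplicative lognormal — intakes are non-negative and
variation between countries of a region is proportional to the mean.
Each country gets one lognormal factor per category, shared by its
strata, so a country's gender strata stay coherent; gender multipliers
then scale the female/male strata. The expectation is preserved
(``E[intake] = mean * multiplier``) for any coefficient of variation.

The module also carries two frozen fixtures transcribed from the
published 11-country application: the per-country index totals
(:func:`table1_fixture`) and the four-macro-region map
(:func:`region_fixture`), used as regression oracles for the
normalization and concordance stages.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ParameterError
from .model import Gender, IntakeProfile, PopulationId

__all__ = [
    "ArchetypeSpec",
    "default_archetypes",
    "generate_profiles",
    "Table1Fixture",
    "table1_fixture",
    "region_fixture",
]


@dataclass(frozen=True)
class ArchetypeSpec:
    """One regional dietary archetype.

    ``means`` are category means in g/day; ``female_mult``/``male_mult``
    scale them for the gender strata (categories absent from the maps
    use 1.0); ``cv`` is the per-category lognormal coefficient of
    variation of the between-country noise (scalar applied to all
    categories via :meth:`cv_for`).
    """

    name: str
    means: Mapping[str, float]
    female_mult: Mapping[str, float] = None  # type: ignore[assignment]
    male_mult: Mapping[str, float] = None  # type: ignore[assignment]
    cv: float | Mapping[str, float] = 0.0

    def __post_init__(self):
        means = {str(k): float(v) for k, v in dict(self.means).items()}
        if any(v < 0 for v in means.values()):
            raise ParameterError(f"archetype {self.name!r} has a negative mean intake")
        object.__setattr__(self, "means", means)
        object.__setattr__(self, "female_mult", dict(self.female_mult or {}))
        object.__setattr__(self, "male_mult", dict(self.male_mult or {}))
        cvs = self.cv.values() if isinstance(self.cv, Mapping) else [self.cv]
        if any(float(c) < 0 for c in cvs):
            raise ParameterError(f"archetype {self.name!r} has a negative CV")

    def cv_for(self, category: str) -> float:
        if isinstance(self.cv, Mapping):
            return float(self.cv.get(category, 0.0))
        return float(self.cv)

    def multiplier(self, category: str, gender: Gender) -> float:
        if gender is Gender.FEMALE:
            return float(self.female_mult.get(category, 1.0))
        if gender is Gender.MALE:
            return float(self.male_mult.get(category, 1.0))
        return 1.0


@lru_cache(maxsize=None)
def _archetype_config() -> dict:
    text = resources.files("dietscore").joinpath("data/archetypes.yaml").read_text()
    return yaml.safe_load(text)


def default_archetypes(cv: float | None = None) -> tuple[ArchetypeSpec, ...]:
    """The four packaged regional archetypes.

    ``cv`` overrides the packaged default coefficient of variation
    (0.15) for all categories; pass 0 for deterministic means.
    """
    cfg = _archetype_config()
    cv = cfg["default_cv"] if cv is None else float(cv)
    gm = cfg.get("gender_multipliers", {})
    female = {cat: m["female"] for cat, m in gm.items()}
    male = {cat: m["male"] for cat, m in gm.items()}
    return tuple(
        ArchetypeSpec(name=name, means=means, female_mult=female, male_mult=male, cv=cv)
        for name, means in cfg["archetypes"].items()
    )


def generate_profiles(
    specs: Sequence[ArchetypeSpec],
    countries_per_archetype: int = 3,
    seed: int = 0,
    genders: Sequence[Gender] = (Gender.TOTAL, Gender.FEMALE, Gender.MALE),
) -> tuple[list[IntakeProfile], dict[str, str]]:
    """Draw country x gender intake profiles around the archetype means.

    Returns the profiles (intakes keyed by source-category id) and the
    generating archetype label per country. Country names are synthetic
    (``MED-1``, ``WES-2``, ...). Deterministic given ``seed``: identical
    seed and specs reproduce identical tables.
    """
    if not specs:
        raise ParameterError("need at least one archetype spec")
    if countries_per_archetype < 1:
        raise ParameterError("countries_per_archetype must be >= 1")
    rng = np.random.default_rng(seed)
    profiles: list[IntakeProfile] = []
    labels: dict[str, str] = {}
    for spec in specs:
        for c in range(countries_per_archetype):
            country = f"{spec.name[:3].upper()}-{c + 1}"
            labels[country] = spec.name
            # one country-level lognormal factor per category, shared by strata
            factors = {}
            for category in spec.means:
                cv = spec.cv_for(category)
                if cv == 0.0:
                    factors[category] = 1.0
                else:
                    sigma = math.sqrt(math.log1p(cv * cv))
                    factors[category] = math.exp(rng.normal(0.0, sigma) - sigma * sigma / 2.0)
            for gender in genders:
                gender = Gender(gender)
                intakes = {
                    category: mean * factors[category] * spec.multiplier(category, gender)
                    for category, mean in spec.means.items()
                }
                profiles.append(IntakeProfile(PopulationId(country, gender), intakes))
    return profiles, labels


# ---------------------------------------------------------------------------
# printed fixtures (regression oracles)

# Final index totals of the published 11-country application: one row
# per country, columns = index x stratum. Transcribed verbatim; guarded
# by tests against accidental edits.
_TABLE1_TEXT = """\
country\twish2_total\twish_total\teat_total\twish2_female\twish_female\teat_female\twish2_male\twish_male\teat_male
Italy\t68.6\t68.6\t22\t69.8\t69.8\t23\t56.9\t56.9\t20
Greece\t66.6\t66.6\t20\t66.5\t66.5\t21\t56.5\t56.5\t20
Spain\t59.8\t59.8\t20\t63.0\t63.0\t20\t56.7\t56.7\t19
Sweden\t50.0\t50.0\t17\t52.0\t52.0\t17\t39.3\t39.3\t14
France\t49.3\t49.3\t19\t50.4\t50.4\t19\t47.7\t47.7\t17
the Netherlands\t39.2\t39.2\t17\t40.3\t40.3\t18\t36.5\t36.5\t16
Germany\t39.1\t39.1\t20\t41.6\t41.6\t19\t38.0\t38.0\t20
Belgium\t36.1\t36.1\t17\t47.9\t47.9\t18\t33.2\t33.2\t17
Ireland\t27.2\t27.2\t13\t29.7\t29.7\t15\t26.3\t26.3\t13
Hungary\t23.7\t23.7\t18\t36.6\t36.6\t20\t26.0\t26.0\t17
Poland\t21.1\t21.1\t16\t20.8\t20.8\t15\t20.7\t20.7\t13
"""

_INDEX_COLUMN = {"WISH2.0": "wish2", "WISH": "wish", "EAT-Lancet": "eat"}
_GENDER_SUFFIX = {Gender.TOTAL: "total", Gender.FEMALE: "female", Gender.MALE: "male"}


@dataclass(frozen=True)
class Table1Fixture:
    """Frozen per-country index totals from the published application."""

    data: pd.DataFrame

    @property
    def countries(self) -> tuple[str, ...]:
        return tuple(self.data.index)

    def value(self, country: str, index_name: str, gender: Gender = Gender.TOTAL) -> float:
        from .model import canonical_index_name

        column = f"{_INDEX_COLUMN[canonical_index_name(index_name)]}_{_GENDER_SUFFIX[Gender(gender)]}"
        return float(self.data.loc[country, column])

    def totals(self, index_name: str, gender: Gender = Gender.TOTAL) -> dict[str, float]:
        return {c: self.value(c, index_name, gender) for c in self.countries}


@lru_cache(maxsize=None)
def table1_fixture() -> Table1Fixture:
    """The published per-country totals for all three indices."""
    df = pd.read_csv(io.StringIO(_TABLE1_TEXT), sep="\t", index_col="country")
    df = df.astype(float)
    return Table1Fixture(data=df)


_REGIONS = {
    "Sweden": "North",
    "Ireland": "North",
    "Hungary": "East",
    "Poland": "East",
    "Belgium": "West",
    "France": "West",
    "Germany": "West",
    "the Netherlands": "West",
    "Italy": "South",
    "Spain": "South",
    "Greece": "South",
}


def region_fixture() -> dict[str, str]:
    """The 11-country -> four-macro-region map (North/East/West/South)."""
    return dict(_REGIONS)
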