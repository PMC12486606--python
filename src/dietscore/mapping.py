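"""Mapping source food categories (FoodEx2-style exports) to index components.

Survey exports classify foods their own way; each index needs intakes
per *component*. A :class:`Crosswalk` lists weighted (source category ->
component) assignments for one index, plus the metadata two special
rules require:

* the *red-meat split* — the original WISH folds processed meat into
  red meat, WISH 2.0 carries processed grams in its own component, and
  the EAT-Lancet index routes every red-meat source to beef & lamb or
  pork by the predominant species of the food (e.g. sausages, commonly
  pork-based, go to pork);
* *added-sugar estimation* — contributing categories count toward added
  sugar only in proportion to their added-sugar content (coefficient
  p_c in [0, 1]).

The packaged default crosswalk (``data/crosswalk.yaml``) is an example
for the synthetic survey categories; its sugar coefficients are
illustrative placeholders, not authoritative values. Real exports plug
in their own file with the same schema.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from typing import IO, Mapping, Union

import yaml

from .errors import CoefficientError, CrosswalkError, TaggingError
from .model import (
    IndexDefinition,
    IntakeProfile,
    PopulationId,
    canonical_index_name,
)

__all__ = [
    "MeatTag",
    "SugarCoefficients",
    "CrosswalkEntry",
    "Crosswalk",
    "default_crosswalk",
    "default_sugar_coefficients",
    "load_crosswalk_config",
    "apply_crosswalk",
    "estimate_added_sugar",
    "split_red_meat",
]

_SPECIES = ("beef", "lamb", "pork")


@dataclass(frozen=True)
class MeatTag:
    """Predominant species and processed/unprocessed flag of a meat source."""

    species: str
    processed: bool

    def __post_init__(self):
        if self.species not in _SPECIES:
            raise TaggingError(
                f"species must be one of {_SPECIES}, got {self.species!r}"
            )


@dataclass(frozen=True)
class SugarCoefficients:
    """Per-category proportion of intake counted as added sugar."""

    coefficients: Mapping[str, float]

    def __post_init__(self):
        clean = {}
        for cat, p in dict(self.coefficients).items():
            p = float(p)
            if not 0.0 <= p <= 1.0:
                raise CoefficientError(f"coefficient for {cat!r} outside [0, 1]: {p}")
            clean[str(cat)] = p
        object.__setattr__(self, "coefficients", clean)

    def __contains__(self, category: str) -> bool:
        return category in self.coefficients

    def __getitem__(self, category: str) -> float:
        try:
            return self.coefficients[category]
        except KeyError:
            raise CoefficientError(f"no added-sugar coefficient for {category!r}") from None


@dataclass(frozen=True)
class CrosswalkEntry:
    source: str
    component: str
    weight: float = 1.0

    def __post_init__(self):
        if not 0.0 < self.weight <= 1.0:
            raise CrosswalkError(
                f"weight for {self.source!r} -> {self.component!r} must be in (0, 1], "
                f"got {self.weight}"
            )


@dataclass(frozen=True)
class Crosswalk:
    """Weighted source -> component assignments for one target index."""

    index_name: str
    entries: tuple[CrosswalkEntry, ...]
    ignore: frozenset[str] = frozenset()
    meat_tags: Mapping[str, MeatTag] = None  # type: ignore[assignment]

    def __post_init__(self):
        object.__setattr__(self, "entries", tuple(self.entries))
        object.__setattr__(self, "ignore", frozenset(self.ignore))
        object.__setattr__(self, "meat_tags", dict(self.meat_tags or {}))
        totals: dict[str, float] = {}
        for e in self.entries:
            totals[e.source] = totals.get(e.source, 0.0) + e.weight
        bad = {s: w for s, w in totals.items() if w > 1.0 + 1e-9}
        if bad:
            raise CrosswalkError(f"weights per source category exceed 1: {bad}")

    @property
    def sources(self) -> frozenset[str]:
        return frozenset(e.source for e in self.entries)


def apply_crosswalk(
    raw: Mapping[str, float],
    xw: Crosswalk,
    index: IndexDefinition,
    population_id: PopulationId | None = None,
    strict: bool = True,
) -> tuple[IntakeProfile, tuple[str, ...]]:
    """Aggregate raw category intakes into index-component intakes.

    Each component receives the weighted sum of its mapped sources
    present in ``raw``. Returns the profile plus the raw categories that
    were neither mapped nor explicitly ignorable; with ``strict`` these
    raise :class:`CrosswalkError` instead. A crosswalk entry pointing at
    a component the index lacks is always an error.
    """
    known = set(index.component_ids)
    bad = sorted({e.component for e in xw.entries} - known)
    if bad:
        raise CrosswalkError(
            f"crosswalk targets unknown components of {index.name}: {', '.join(bad)}"
        )
    unmapped = tuple(sorted(set(raw) - xw.sources - xw.ignore))
    if unmapped and strict:
        raise CrosswalkError(
            f"raw categories not mapped and not ignorable: {', '.join(unmapped)}"
        )
    intakes: dict[str, float] = {}
    for e in xw.entries:
        if e.source in raw:
            intakes[e.component] = intakes.get(e.component, 0.0) + e.weight * float(raw[e.source])
    pid = population_id or PopulationId("unnamed")
    return IntakeProfile(pid, intakes), unmapped


def estimate_added_sugar(raw: Mapping[str, float], coef: SugarCoefficients) -> float:
    """Added sugar (g/day) as the coefficient-weighted sum of the
    contributing categories in ``raw``. Every supplied category must
    have a coefficient."""
    total = 0.0
    for category, grams in raw.items():
        total += coef[category] * float(grams)
    return total


def split_red_meat(
    meat_intakes: Mapping[str, float],
    tags: Mapping[str, MeatTag],
    target_index: str,
) -> dict[str, float]:
    """Route red-meat-family grams to the target index's components.

    WISH: everything to ``red_meat``. WISH 2.0: unprocessed grams to
    ``red_meat``, processed grams to ``processed_meat``. EAT-Lancet:
    grams to ``beef_lamb`` or ``pork`` by each source's predominant
    species (processed or not). Untagged sources raise
    :class:`TaggingError`.
    """
    name = canonical_index_name(target_index)
    untagged = sorted(set(meat_intakes) - set(tags))
    if untagged:
        raise TaggingError(f"meat categories without a tag: {', '.join(untagged)}")
    out: dict[str, float] = {}

    def add(component: str, grams: float) -> None:
        out[component] = out.get(component, 0.0) + float(grams)

    for source, grams in meat_intakes.items():
        tag = tags[source]
        if name == "WISH":
            add("red_meat", grams)
        elif name == "WISH2.0":
            add("processed_meat" if tag.processed else "red_meat", grams)
        else:  # EAT-Lancet: species rule
            add("beef_lamb" if tag.species in ("beef", "lamb") else "pork", grams)
    return out


# ---------------------------------------------------------------------------
# config loading

def _parse_config(payload: Mapping) -> dict:
    sugar = SugarCoefficients(payload.get("sugar_coefficients", {}))
    tags = {
        cat: MeatTag(species=t["species"], processed=bool(t["processed"]))
        for cat, t in payload.get("meat_tags", {}).items()
    }
    crosswalks = {}
    for name, spec in payload.get("crosswalks", {}).items():
        entries = tuple(
            CrosswalkEntry(
                source=e["source"], component=e["component"], weight=float(e.get("weight", 1.0))
            )
            for e in spec.get("entries", [])
        )
        crosswalks[name] = Crosswalk(
            index_name=name,
            entries=entries,
            ignore=frozenset(spec.get("ignore", [])),
            meat_tags=tags,
        )
    return {"sugar": sugar, "tags": tags, "crosswalks": crosswalks}


def load_crosswalk_config(source: Union[str, IO[str]]) -> dict:
    """Parse a crosswalk/coefficient YAML into validated objects.

    Returns ``{"sugar": SugarCoefficients, "tags": {category: MeatTag},
    "crosswalks": {index name: Crosswalk}}``.
    """
    return _parse_config(yaml.safe_load(source))


@lru_cache(maxsize=None)
def _default_config() -> dict:
    text = resources.files("dietscore").joinpath("data/crosswalk.yaml").read_text()
    return _parse_config(yaml.safe_load(text))


def default_crosswalk(index_name: str) -> Crosswalk:
    """The packaged example crosswalk for one index (synthetic survey
    categories)."""
    name = canonical_index_name(index_name)
    try:
        return _default_config()["crosswalks"][name]
    except KeyError:
        raise CrosswalkError(f"no default crosswalk for {name}") from None


def default_sugar_coefficients() -> SugarCoefficients:
    return _default_config()["sugar"]
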