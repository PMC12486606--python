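"""Domain model for Planetary Health Diet (PHD) adherence indices.

Three diet-quality indices are built in, all scored from mean food-group
intakes in g/day:

* ``WISH`` — the World Index for Sustainability and Health: 13 food-group
  components, each scored continuously 0-10 (theoretical range 0-130).
* ``WISH2.0`` — WISH extended with two components, processed meat and
  alcoholic beverages (15 components, 0-150). Its red-meat component
  covers unprocessed red meat only; in the original WISH processed meat
  is folded into red meat.
* ``EAT-Lancet`` — an ordinal adherence index: 14 components scored
  0-3 each (0-42), with red meat split into beef & lamb and pork.

Component scoring rules come in five kinds (see :mod:`dietscore.scoring`):
proportional *adequacy* (score rises linearly from a lower bound to the
recommended intake), proportional *moderation* (score falls linearly from
the recommended intake to an upper bound), *binary cut-off*,
*zero tolerance* (alcohol), and *ordinal band* (0-3 over three
thresholds).

Reference intakes derive from the PHD recommendations, except whole
grains in WISH/WISH 2.0 which use the Global Burden of Disease
recommendation of 125 g/day within a 100-150 g range. Values the index
definitions do not pin down (most PHD group targets, all EAT-Lancet band
thresholds) ship as editable defaults in ``data/indices.yaml`` and are
documented there as package defaults, not authoritative constants.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, replace
from functools import lru_cache
from importlib import resources
from typing import IO, Mapping, Union

import yaml

from .errors import DefinitionNotFoundError, ParameterError, ProfileValidationError

__all__ = [
    "Gender",
    "RuleKind",
    "Direction",
    "FoodComponent",
    "ComponentRule",
    "IndexDefinition",
    "PopulationId",
    "IntakeProfile",
    "builtin_index",
    "builtin_index_names",
    "validate_profile",
    "index_to_dict",
    "index_from_dict",
    "dump_index",
    "load_index",
]


class Gender(str, enum.Enum):
    """Population stratum. ``TOTAL`` is its own stratum, not an average
    of ``FEMALE`` and ``MALE`` (survey means for the whole population are
    not a simple mean of the gender strata)."""

    TOTAL = "total"
    FEMALE = "female"
    MALE = "male"


class RuleKind(str, enum.Enum):
    ADEQUACY = "adequacy"
    MODERATION = "moderation"
    BINARY_CUTOFF = "binary_cutoff"
    ZERO_TOLERANCE = "zero_tolerance"
    ORDINAL_BAND = "ordinal_band"


class Direction(str, enum.Enum):
    HIGHER_IS_BETTER = "higher_is_better"
    LOWER_IS_BETTER = "lower_is_better"


@dataclass(frozen=True)
class FoodComponent:
    """One food group of an index. Intakes are always mean g/day."""

    id: str
    display_name: str = ""
    unit: str = "g/day"

    def __post_init__(self):
        if not self.id:
            raise ParameterError("component id must be non-empty")
        if self.unit != "g/day":
            raise ParameterError(f"component {self.id!r}: unit must be g/day")
        if not self.display_name:
            object.__setattr__(self, "display_name", self.id.replace("_", " "))


#: fields a rule kind requires (beyond `kind`); everything else must be absent
_REQUIRED: dict[RuleKind, tuple[str, ...]] = {
    RuleKind.ADEQUACY: ("lower", "recommended"),
    RuleKind.MODERATION: ("recommended", "upper"),
    RuleKind.BINARY_CUTOFF: ("cutoff",),
    RuleKind.ZERO_TOLERANCE: (),
    RuleKind.ORDINAL_BAND: ("bands", "direction"),
}
_PARAM_FIELDS = ("lower", "recommended", "upper", "cutoff", "bands", "direction")


@dataclass(frozen=True)
class ComponentRule:
    """A scoring rule: the kind plus exactly the parameters it needs.

    ``cutoff_orientation`` applies to ``binary_cutoff`` only:
    ``"low_is_adherent"`` (default) awards full points below the cut-off,
    ``"high_is_adherent"`` awards them at or above it. The default keeps
    the binary components consistent with the zero-tolerance alcohol rule
    (less of the discouraged food is better).
    """

    kind: RuleKind
    lower: float | None = None
    recommended: float | None = None
    upper: float | None = None
    cutoff: float | None = None
    bands: tuple[float, float, float] | None = None
    direction: Direction | None = None
    cutoff_orientation: str = "low_is_adherent"

    def __post_init__(self):
        kind = RuleKind(self.kind)
        object.__setattr__(self, "kind", kind)
        if self.direction is not None:
            object.__setattr__(self, "direction", Direction(self.direction))
        if self.bands is not None:
            object.__setattr__(self, "bands", tuple(float(b) for b in self.bands))

        required = _REQUIRED[kind]
        for name in _PARAM_FIELDS:
            value = getattr(self, name)
            if name in required and value is None:
                raise ParameterError(f"{kind.value} rule requires {name!r}")
            if name not in required and value is not None:
                raise ParameterError(f"{kind.value} rule does not take {name!r}")
        if self.cutoff_orientation not in ("low_is_adherent", "high_is_adherent"):
            raise ParameterError(
                f"unknown cutoff_orientation {self.cutoff_orientation!r}"
            )
        if kind is not RuleKind.BINARY_CUTOFF and self.cutoff_orientation != "low_is_adherent":
            raise ParameterError("cutoff_orientation applies to binary_cutoff rules only")

        if kind is RuleKind.ADEQUACY and not self.lower < self.recommended:
            raise ParameterError(
                f"adequacy requires lower < recommended, got {self.lower} >= {self.recommended}"
            )
        if kind is RuleKind.MODERATION and not self.recommended < self.upper:
            raise ParameterError(
                f"moderation requires recommended < upper, got {self.recommended} >= {self.upper}"
            )
        if kind is RuleKind.BINARY_CUTOFF and not self.cutoff > 0:
            raise ParameterError(f"binary_cutoff requires cutoff > 0, got {self.cutoff}")
        if kind is RuleKind.ORDINAL_BAND:
            if len(self.bands) != 3 or not (self.bands[0] < self.bands[1] < self.bands[2]):
                raise ParameterError(
                    f"ordinal_band requires 3 strictly increasing thresholds, got {self.bands}"
                )

    @property
    def max_points(self) -> int:
        return 3 if self.kind is RuleKind.ORDINAL_BAND else 10


@dataclass(frozen=True)
class IndexDefinition:
    """An ordered set of (component, rule) pairs with theoretical bounds.

    ``per_component_max`` is 10 for the continuous indices (WISH,
    WISH 2.0) and 3 for the ordinal EAT-Lancet index; the theoretical
    maximum is the number of components times that value.
    """

    name: str
    components: tuple[tuple[FoodComponent, ComponentRule], ...]
    per_component_max: int

    def __post_init__(self):
        object.__setattr__(
            self,
            "components",
            tuple((comp, rule) for comp, rule in self.components),
        )
        ids = [comp.id for comp, _ in self.components]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ParameterError(f"duplicate component ids in {self.name}: {dupes}")
        for comp, rule in self.components:
            if rule.max_points != self.per_component_max:
                raise ParameterError(
                    f"{self.name}/{comp.id}: rule kind {rule.kind.value} scores up to "
                    f"{rule.max_points}, index expects {self.per_component_max}"
                )

    @property
    def theoretical_min(self) -> float:
        return 0.0

    @property
    def theoretical_max(self) -> float:
        return float(len(self.components) * self.per_component_max)

    @property
    def component_ids(self) -> tuple[str, ...]:
        return tuple(comp.id for comp, _ in self.components)

    def rule(self, component_id: str) -> ComponentRule:
        for comp, rule in self.components:
            if comp.id == component_id:
                return rule
        raise DefinitionNotFoundError(f"{self.name} has no component {component_id!r}")

    def __len__(self) -> int:
        return len(self.components)


@dataclass(frozen=True, order=True)
class PopulationId:
    """One population stratum: a country plus a gender level."""

    country: str
    gender: Gender = Gender.TOTAL

    def __post_init__(self):
        object.__setattr__(self, "gender", Gender(self.gender))

    def __str__(self) -> str:
        return f"{self.country}|{self.gender.value}"


@dataclass(frozen=True)
class IntakeProfile:
    """Mean daily intake (g/day) per food-category id for one stratum.

    Keys are opaque category/component ids; a component an index needs
    but the profile lacks stays *missing* (callers must validate against
    the index) rather than being silently read as zero.
    """

    population_id: PopulationId
    intakes: Mapping[str, float]

    def __post_init__(self):
        clean = {}
        for key, value in dict(self.intakes).items():
            value = float(value)
            if not math.isfinite(value):
                raise ParameterError(f"intake for {key!r} is not finite: {value}")
            if value < 0:
                raise ParameterError(f"intake for {key!r} is negative: {value}")
            clean[str(key)] = value
        object.__setattr__(self, "intakes", clean)

    def __getitem__(self, key: str) -> float:
        return self.intakes[key]

    def with_intakes(self, **updates: float) -> "IntakeProfile":
        merged = dict(self.intakes)
        merged.update(updates)
        return replace(self, intakes=merged)


# ---------------------------------------------------------------------------
# built-in registry

_ALIASES = {
    "wish": "WISH",
    "wish2": "WISH2.0",
    "wish2.0": "WISH2.0",
    "wish 2.0": "WISH2.0",
    "eat": "EAT-Lancet",
    "eat-lancet": "EAT-Lancet",
    "eatlancet": "EAT-Lancet",
}


def canonical_index_name(name: str) -> str:
    """Resolve common spellings (``wish2``, ``eat``) to the canonical name."""
    key = str(name).strip().lower()
    if key in _ALIASES:
        return _ALIASES[key]
    raise DefinitionNotFoundError(
        f"unknown index {name!r}; expected one of WISH, WISH2.0, EAT-Lancet"
    )


def builtin_index_names() -> tuple[str, ...]:
    return ("WISH", "WISH2.0", "EAT-Lancet")


@lru_cache(maxsize=None)
def _builtin_registry() -> dict[str, IndexDefinition]:
    text = resources.files("dietscore").joinpath("data/indices.yaml").read_text()
    payload = yaml.safe_load(text)
    return {name: index_from_dict(name, spec) for name, spec in payload["indices"].items()}


def builtin_index(name: str) -> IndexDefinition:
    """Return the fully parameterized built-in definition for ``name``.

    Accepts canonical names and common aliases (``wish``, ``wish2``,
    ``eat``). Raises :class:`DefinitionNotFoundError` for anything else.
    """
    return _builtin_registry()[canonical_index_name(name)]


def validate_profile(profile: IntakeProfile, index: IndexDefinition) -> IntakeProfile:
    """Return ``profile`` iff it carries an intake for every component of
    ``index``; otherwise raise :class:`ProfileValidationError` naming the
    missing ids (extra, non-index categories are allowed and reported on
    the error only when components are missing)."""
    wanted = set(index.component_ids)
    have = set(profile.intakes)
    missing = sorted(wanted - have)
    if missing:
        extra = sorted(have - wanted)
        raise ProfileValidationError(
            f"profile {profile.population_id} is missing components for "
            f"{index.name}: {', '.join(missing)}",
            missing=missing,
            extra=extra,
        )
    return profile


# ---------------------------------------------------------------------------
# (de)serialization — the round-trippable config format

def _rule_to_dict(rule: ComponentRule) -> dict:
    out: dict = {"kind": rule.kind.value}
    for name in _PARAM_FIELDS:
        value = getattr(rule, name)
        if value is None:
            continue
        if name == "bands":
            out[name] = [float(b) for b in value]
        elif name == "direction":
            out[name] = value.value
        else:
            out[name] = float(value)
    if rule.kind is RuleKind.BINARY_CUTOFF and rule.cutoff_orientation != "low_is_adherent":
        out["cutoff_orientation"] = rule.cutoff_orientation
    return out


def _rule_from_dict(payload: Mapping) -> ComponentRule:
    payload = dict(payload)
    kind = RuleKind(payload.pop("kind"))
    if "bands" in payload:
        payload["bands"] = tuple(payload["bands"])
    return ComponentRule(kind=kind, **payload)


def index_to_dict(index: IndexDefinition) -> dict:
    return {
        "per_component_max": index.per_component_max,
        "components": [
            {"id": comp.id, "display_name": comp.display_name, "rule": _rule_to_dict(rule)}
            for comp, rule in index.components
        ],
    }


def index_from_dict(name: str, payload: Mapping) -> IndexDefinition:
    components = tuple(
        (
            FoodComponent(id=entry["id"], display_name=entry.get("display_name", "")),
            _rule_from_dict(entry["rule"]),
        )
        for entry in payload["components"]
    )
    return IndexDefinition(
        name=name,
        components=components,
        per_component_max=int(payload["per_component_max"]),
    )


def dump_index(index: IndexDefinition, stream: IO[str] | None = None) -> str | None:
    """Serialize one definition to the YAML config format."""
    doc = {"version": 1, "indices": {index.name: index_to_dict(index)}}
    return yaml.safe_dump(doc, stream, sort_keys=False)


def load_index(source: Union[str, IO[str]], name: str | None = None) -> IndexDefinition:
    """Load one definition from YAML text or a stream.

    ``name`` selects among multiple definitions; omitted, the file must
    contain exactly one.
    """
    payload = yaml.safe_load(source)
    indices = payload.get("indices", {})
    if not indices:
        raise DefinitionNotFoundError("config contains no index definitions")
    if name is None:
        if len(indices) != 1:
            raise DefinitionNotFoundError(
                f"config defines {sorted(indices)}; pass name= to choose one"
            )
        name = next(iter(indices))
    if name not in indices:
        raise DefinitionNotFoundError(f"config does not define {name!r}")
    return index_from_dict(name, indices[name])
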