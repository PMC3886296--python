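"""Clinical scenario spaces for appropriateness panels.

A scenario space declares, per patient population, a set of clinical
variables (each with an ordered list of levels) and a list of candidate
treatments.  Scenarios are the Cartesian product of the variable levels;
an *indication* is one (scenario, treatment) pair — the atomic unit an
expert panel rates on the 9-point appropriateness scale.

The packaged default space (``default_space()``) describes the second
rating round of a European panel on iron deficiency in inflammatory bowel
disease: two populations, NAID (non-anaemic iron deficiency, 28 scenarios
x 5 treatments) and IDA (iron deficiency anaemia, 168 scenarios x
6 treatments), 196 scenarios and 1148 indications in total.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any, Mapping, Sequence

import yaml

POPULATIONS = ("NAID", "IDA")

DEFAULT_SPACE_RESOURCE = "round2_default.yaml"


class ConfigError(ValueError):
    """Raised when a scenario-space configuration is malformed."""


class LookupError_(KeyError):
    """Raised when a population, scenario or treatment is unknown."""


@dataclass(frozen=True)
class VariableDef:
    """One clinical variable with its ordered levels."""

    name: str
    levels: tuple[str, ...]
    label: str = ""

    def __post_init__(self) -> None:
        if not self.name:
            raise ConfigError("variable name must be non-empty")
        if len(self.levels) == 0:
            raise ConfigError(f"variable {self.name!r} has an empty level list")
        if len(set(self.levels)) != len(self.levels):
            raise ConfigError(f"variable {self.name!r} has duplicate levels")


@dataclass(frozen=True)
class TreatmentDef:
    """One candidate treatment option."""

    name: str
    label: str = ""

    def __post_init__(self) -> None:
        if not self.name:
            raise ConfigError("treatment name must be non-empty")


@dataclass(frozen=True)
class Scenario:
    """A patient profile: one level assigned to each variable of a population."""

    population: str
    assignment: tuple[tuple[str, str], ...]  # (variable, level) in config order

    @property
    def id(self) -> str:
        parts = [self.population] + [f"{v}={l}" for v, l in self.assignment]
        return "|".join(parts)

    @property
    def assignment_dict(self) -> dict[str, str]:
        return dict(self.assignment)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.id


@dataclass(frozen=True)
class Indication:
    """One (scenario, treatment) pair to be rated."""

    scenario: Scenario
    treatment: str

    @property
    def key(self) -> tuple[str, str]:
        return (self.scenario.id, self.treatment)


@dataclass
class ScenarioSpace:
    """Validated scenario space: per-population variables and treatments."""

    variables: dict[str, list[VariableDef]]
    treatments: dict[str, list[TreatmentDef]]
    version: str = "unversioned"
    _scenario_index: dict[str, Scenario] = field(
        default_factory=dict, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        if not self.variables:
            raise ConfigError("space defines no populations")
        for pop in self.variables:
            if pop not in POPULATIONS:
                raise ConfigError(
                    f"unknown population {pop!r}; expected one of {POPULATIONS}"
                )
        if set(self.variables) != set(self.treatments):
            raise ConfigError("variables and treatments must cover the same populations")
        for pop, vdefs in self.variables.items():
            if not vdefs:
                raise ConfigError(f"population {pop!r} has no variables")
            names = [v.name for v in vdefs]
            if len(set(names)) != len(names):
                raise ConfigError(f"duplicate variable names in population {pop!r}")
        for pop, tdefs in self.treatments.items():
            if not tdefs:
                raise ConfigError(f"population {pop!r} has no treatments")
            names = [t.name for t in tdefs]
            if len(set(names)) != len(names):
                raise ConfigError(f"duplicate treatment names in population {pop!r}")

    # -- enumeration ---------------------------------------------------

    @property
    def populations(self) -> tuple[str, ...]:
        return tuple(self.variables)

    def treatment_names(self, population: str) -> tuple[str, ...]:
        self._check_population(population)
        return tuple(t.name for t in self.treatments[population])

    def _check_population(self, population: str) -> None:
        if population not in self.variables:
            raise LookupError_(
                f"unknown population {population!r}; space has {self.populations}"
            )

    def enumerate_scenarios(self, population: str) -> list[Scenario]:
        """All scenarios of one population, odometer order.

        Variables iterate in config order with the last variable cycling
        fastest; levels keep their declared order.
        """
        self._check_population(population)
        vdefs = self.variables[population]
        names = [v.name for v in vdefs]
        out = []
        for combo in itertools.product(*(v.levels for v in vdefs)):
            out.append(Scenario(population, tuple(zip(names, combo))))
        return out

    def all_scenarios(self) -> list[Scenario]:
        return [s for pop in self.populations for s in self.enumerate_scenarios(pop)]

    def enumerate_indications(self) -> list[Indication]:
        """Every (scenario, applicable treatment) pair, deterministic order."""
        out = []
        for pop in self.populations:
            tnames = self.treatment_names(pop)
            for scen in self.enumerate_scenarios(pop):
                for t in tnames:
                    out.append(Indication(scen, t))
        return out

    def scenario_by_id(self, scenario_id: str) -> Scenario:
        if not self._scenario_index:
            self._scenario_index.update({s.id: s for s in self.all_scenarios()})
        try:
            return self._scenario_index[scenario_id]
        except KeyError:
            raise LookupError_(f"unknown scenario id {scenario_id!r}") from None

    def scenario_for_profile(
        self, population: str, profile: Mapping[str, str]
    ) -> Scenario:
        """Resolve a variable→level mapping to the unique matching scenario.

        The profile must assign every variable of the population; unknown
        variables or levels and missing variables raise with an explicit
        listing.
        """
        self._check_population(population)
        vdefs = self.variables[population]
        names = {v.name for v in vdefs}
        extra = sorted(set(profile) - names)
        if extra:
            raise LookupError_(f"unknown variables for {population}: {extra}")
        missing = sorted(names - set(profile))
        if missing:
            raise LookupError_(f"profile is missing variables: {missing}")
        assignment = []
        for v in vdefs:
            level = profile[v.name]
            if level not in v.levels:
                raise LookupError_(
                    f"unknown level {level!r} for variable {v.name!r}; "
                    f"levels are {list(v.levels)}"
                )
            assignment.append((v.name, level))
        return Scenario(population, tuple(assignment))

    # -- serialisation -------------------------------------------------

    def to_config(self) -> dict[str, Any]:
        pops = {}
        for pop in self.populations:
            pops[pop] = {
                "variables": [
                    {"name": v.name, "label": v.label, "levels": list(v.levels)}
                    for v in self.variables[pop]
                ],
                "treatments": [
                    {"name": t.name, "label": t.label}
                    for t in self.treatments[pop]
                ],
            }
        return {"version": self.version, "populations": pops}


def _require(mapping: Mapping[str, Any], key: str, ctx: str) -> Any:
    if key not in mapping:
        raise ConfigError(f"missing key {key!r} in {ctx}")
    return mapping[key]


def build_scenario_space(config: Mapping[str, Any]) -> ScenarioSpace:
    """Build and validate a :class:`ScenarioSpace` from a parsed config dict.

    Expected structure::

        version: round2-default
        populations:
          NAID:
            variables:  [{name, label, levels: [...]}, ...]
            treatments: [{name, label}, ...]
    """
    if not isinstance(config, Mapping):
        raise ConfigError("config root must be a mapping")
    version = str(config.get("version", "unversioned"))
    pops = _require(config, "populations", "config")
    if not isinstance(pops, Mapping) or not pops:
        raise ConfigError("'populations' must be a non-empty mapping")
    variables: dict[str, list[VariableDef]] = {}
    treatments: dict[str, list[TreatmentDef]] = {}
    for pop, body in pops.items():
        vdefs = []
        for raw in _require(body, "variables", f"population {pop!r}"):
            levels = _require(raw, "levels", f"variable in {pop!r}")
            if not isinstance(levels, Sequence) or isinstance(levels, str):
                raise ConfigError(f"levels of variable {raw.get('name')!r} must be a list")
            vdefs.append(
                VariableDef(
                    name=str(_require(raw, "name", f"variable in {pop!r}")),
                    levels=tuple(str(l) for l in levels),
                    label=str(raw.get("label", "")),
                )
            )
        tdefs = []
        for raw in _require(body, "treatments", f"population {pop!r}"):
            tdefs.append(
                TreatmentDef(
                    name=str(_require(raw, "name", f"treatment in {pop!r}")),
                    label=str(raw.get("label", "")),
                )
            )
        variables[str(pop)] = vdefs
        treatments[str(pop)] = tdefs
    return ScenarioSpace(variables=variables, treatments=treatments, version=version)


def load_space(path: str | Path) -> ScenarioSpace:
    """Load a YAML or JSON scenario-space config from disk."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if path.suffix.lower() == ".json":
        config = json.loads(text)
    else:
        config = yaml.safe_load(text)
    return build_scenario_space(config)


def save_space(space: ScenarioSpace, path: str | Path) -> None:
    path = Path(path)
    config = space.to_config()
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(config, indent=2) + "\n", encoding="utf-8")
    else:
        path.write_text(yaml.safe_dump(config, sort_keys=False), encoding="utf-8")


def default_space() -> ScenarioSpace:
    """The packaged round-2 default space (196 scenarios, 1148 indications)."""
    text = (
        resources.files("ruamkit.data")
        .joinpath(DEFAULT_SPACE_RESOURCE)
        .read_text(encoding="utf-8")
    )
    return build_scenario_space(yaml.safe_load(text))
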