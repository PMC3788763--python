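"""Demographic scenarios, priors with inequality constraints, time-unit conversions.

A scenario is a backward-in-time event list (population merges, admixture
pulses, stepwise size changes) over named populations, parameterised by named
quantities with independent uniform priors truncated by a set of pairwise
inequality constraints.  Eight scenarios of three-population divergence (with
or without admixture) ship as YAML configuration files; users may supply their
own files following the same schema.

Time is measured in generations before present (backward-positive).
Effective sizes are effective numbers of mtDNA gene copies (maternal
lineages), used directly as haploid coalescent sizes; an optional
``size_scaling`` multiplier is applied uniformly if a different convention is
wanted.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import yaml

__all__ = [
    "LifeHistory",
    "generation_time",
    "generations_to_years",
    "years_to_generations",
    "PriorSet",
    "Constraint",
    "ConstraintSet",
    "Event",
    "ScenarioSpec",
    "SCENARIO_IDS",
    "available_scenarios",
    "build_scenario",
    "sample_prior_draw",
    "validate_draw",
]

#: A realised set of parameter values for one scenario, in native units.
ParameterDraw = Dict[str, float]

SAMPLED_POPULATIONS = ("SAG", "NAG", "NC")

SCENARIO_IDS = ("Sc1", "Sc2", "Sc3", "Sc4", "Sc5", "Sc6", "Sc7", "Sc8")

SCHEMA = "coalabc-scenario-v1"


# ---------------------------------------------------------------------------
# Life history and time-unit conversion
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LifeHistory:
    """Adult life-history traits used to convert generations to calendar time.

    Parameters
    ----------
    alpha_days : float
        Adult age at maturity, in days.
    survival_s : float
        Daily adult survival probability (dimensionless, ``0 <= s < 1``).
    days_per_year : float
        Calendar conversion constant; default the Julian year.
    """

    alpha_days: float = 20.0
    survival_s: float = 0.798
    days_per_year: float = 365.25

    def __post_init__(self) -> None:
        if not (0.0 <= self.survival_s < 1.0):
            raise ValueError(
                f"daily survival must satisfy 0 <= s < 1, got {self.survival_s}"
            )
        if self.alpha_days <= 0:
            raise ValueError(f"age at maturity must be positive, got {self.alpha_days}")


def generation_time(life: LifeHistory) -> float:
    """Mean generation time in days: ``T = alpha + s / (1 - s)``.

    The age at maturity plus the mean number of further days an adult
    survives under geometric daily survival.
    """
    return life.alpha_days + life.survival_s / (1.0 - life.survival_s)


def generations_to_years(g: float, life: LifeHistory) -> float:
    """Convert a count of generations before present into years."""
    if g < 0:
        raise ValueError(f"generation count must be nonnegative, got {g}")
    return g * generation_time(life) / life.days_per_year


def years_to_generations(y: float, life: LifeHistory) -> float:
    """Inverse of :func:`generations_to_years`."""
    if y < 0:
        raise ValueError(f"years must be nonnegative, got {y}")
    return y * life.days_per_year / generation_time(life)


# ---------------------------------------------------------------------------
# Priors and constraints
# ---------------------------------------------------------------------------


class PriorSet:
    """Named independent uniform priors, one ``(low, high)`` interval each."""

    def __init__(self, intervals: Mapping[str, Tuple[float, float]]):
        self.intervals: Dict[str, Tuple[float, float]] = {}
        for name, (low, high) in intervals.items():
            low, high = float(low), float(high)
            if not low < high:
                raise ValueError(
                    f"prior for {name!r} must have low < high, got [{low}, {high}]"
                )
            self.intervals[name] = (low, high)

    def __contains__(self, name: str) -> bool:
        return name in self.intervals

    def __iter__(self):
        return iter(self.intervals)

    def __len__(self) -> int:
        return len(self.intervals)

    def bounds(self, name: str) -> Tuple[float, float]:
        return self.intervals[name]

    def names(self) -> List[str]:
        return list(self.intervals)

    def sample(self, rng: np.random.Generator) -> ParameterDraw:
        """One unconstrained joint draw (independent uniforms)."""
        return {
            name: float(rng.uniform(low, high))
            for name, (low, high) in self.intervals.items()
        }

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        body = ", ".join(f"{k}=[{a:g},{b:g}]" for k, (a, b) in self.intervals.items())
        return f"PriorSet({body})"


_CONSTRAINT_RE = re.compile(r"^\s*(\w+)\s*(<=|<)\s*(\w+)\s*$")


@dataclass(frozen=True)
class Constraint:
    """One pairwise inequality between named parameters."""

    left: str
    op: str  # "<" (strict) or "<=" (non-strict)
    right: str

    @classmethod
    def parse(cls, text: str) -> "Constraint":
        m = _CONSTRAINT_RE.match(text)
        if m is None:
            raise ValueError(
                f"cannot parse constraint {text!r}; expected 'a < b' or 'a <= b'"
            )
        return cls(m.group(1), m.group(2), m.group(3))

    def holds(self, draw: Mapping[str, float]) -> bool:
        a, b = draw[self.left], draw[self.right]
        return a < b if self.op == "<" else a <= b

    def __str__(self) -> str:
        return f"{self.left} {self.op} {self.right}"


class ConstraintSet:
    """A conjunction of pairwise inequality constraints."""

    def __init__(self, constraints: Iterable[Constraint | str] = ()):
        self.constraints: List[Constraint] = [
            c if isinstance(c, Constraint) else Constraint.parse(c) for c in constraints
        ]

    def __iter__(self):
        return iter(self.constraints)

    def __len__(self) -> int:
        return len(self.constraints)

    def violations(self, draw: Mapping[str, float]) -> List[str]:
        """Human-readable description of every violated relation."""
        out = []
        for c in self.constraints:
            for name in (c.left, c.right):
                if name not in draw:
                    raise KeyError(f"draw is missing parameter {name!r}")
            if not c.holds(draw):
                out.append(f"violated: {c} (got {draw[c.left]:g} vs {draw[c.right]:g})")
        return out

    def satisfied(self, draw: Mapping[str, float]) -> bool:
        return all(c.holds(draw) for c in self.constraints)


# ---------------------------------------------------------------------------
# Scenario specification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Event:
    """One backward-in-time demographic event.

    ``kind`` is one of:

    - ``merge``: all lineages of ``source`` move into ``dest`` (a forward-time
      population split seen backward);
    - ``admix``: each lineage in ``target`` independently moves to ``donor``
      with probability given by the ``rate`` parameter (a forward-time
      admixture pulse into ``target``);
    - ``resize``: ``population`` changes its size stepwise to the value of the
      ``size`` parameter.

    ``time`` names the parameter giving the event time in generations.
    Events at equal times are applied in listed order.
    """

    time: str
    kind: str  # merge | admix | resize
    source: Optional[str] = None
    dest: Optional[str] = None
    target: Optional[str] = None
    donor: Optional[str] = None
    rate: Optional[str] = None
    population: Optional[str] = None
    size: Optional[str] = None

    def parameter_names(self) -> List[str]:
        names = [self.time]
        if self.kind == "admix":
            names.append(self.rate)
        elif self.kind == "resize":
            names.append(self.size)
        return names


@dataclass
class ScenarioSpec:
    """A fully specified demographic scenario with priors and constraints."""

    id: str
    populations: Tuple[str, ...]
    initial_sizes: Dict[str, str]  # population -> size-parameter name
    events: List[Event]
    priors: PriorSet
    constraints: ConstraintSet
    description: str = ""
    size_scaling: float = 1.0

    def __post_init__(self) -> None:
        self.validate()

    # -- structural validation ------------------------------------------------

    def validate(self) -> None:
        pops = set(self.populations)
        if len(pops) != len(self.populations):
            raise ValueError(f"{self.id}: duplicate population labels")
        for pop, size_param in self.initial_sizes.items():
            if pop not in pops:
                raise ValueError(f"{self.id}: initial size for unknown population {pop!r}")
            if size_param not in self.priors:
                raise ValueError(
                    f"{self.id}: initial size parameter {size_param!r} has no prior"
                )
        missing = pops - set(self.initial_sizes)
        if missing:
            raise ValueError(f"{self.id}: populations without initial size: {sorted(missing)}")

        alive = set(pops)
        for i, ev in enumerate(self.events):
            where = f"{self.id}: event {i} ({ev.kind} at {ev.time})"
            for p in ev.parameter_names():
                if p is None or p not in self.priors:
                    raise ValueError(f"{where}: parameter {p!r} has no prior")
            if ev.kind == "merge":
                if ev.source not in alive or ev.dest not in alive:
                    raise ValueError(f"{where}: merge involves inactive population")
                alive.discard(ev.source)
            elif ev.kind == "admix":
                if ev.target not in alive or ev.donor not in alive:
                    raise ValueError(f"{where}: admixture involves inactive population")
            elif ev.kind == "resize":
                if ev.population not in alive:
                    raise ValueError(f"{where}: resize of inactive population")
            else:
                raise ValueError(f"{where}: unknown event kind {ev.kind!r}")
        if len(alive) != 1:
            raise ValueError(
                f"{self.id}: after all merges {len(alive)} populations remain; "
                "exactly one ancestral population must survive"
            )
        for c in self.constraints:
            for name in (c.left, c.right):
                if name not in self.priors:
                    raise ValueError(
                        f"{self.id}: constraint '{c}' names parameter {name!r} without prior"
                    )

    # -- accessors ------------------------------------------------------------

    def parameter_names(self) -> List[str]:
        """All parameter names, in prior declaration order."""
        return self.priors.names()

    @property
    def root_population(self) -> str:
        alive = set(self.populations)
        for ev in self.events:
            if ev.kind == "merge":
                alive.discard(ev.source)
        (root,) = alive
        return root

    # -- serialisation --------------------------------------------------------

    @classmethod
    def from_dict(cls, cfg: Mapping) -> "ScenarioSpec":
        if cfg.get("schema") != SCHEMA:
            raise ValueError(
                f"unsupported or missing scenario schema {cfg.get('schema')!r}; "
                f"expected {SCHEMA!r}"
            )
        events = []
        for i, e in enumerate(cfg.get("events", [])):
            try:
                events.append(Event(**e))
            except TypeError as exc:
                raise ValueError(f"malformed event {i} in scenario config: {exc}") from exc
        return cls(
            id=str(cfg["id"]),
            populations=tuple(cfg["populations"]),
            initial_sizes=dict(cfg["initial_sizes"]),
            events=events,
            priors=PriorSet(
                {k: tuple(v) for k, v in cfg["priors"].items()}
            ),
            constraints=ConstraintSet(cfg.get("constraints", [])),
            description=cfg.get("description", ""),
            size_scaling=float(cfg.get("size_scaling", 1.0)),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScenarioSpec":
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
        return cls.from_dict(cfg)


# ---------------------------------------------------------------------------
# Shipped scenario catalogue
# ---------------------------------------------------------------------------


def available_scenarios() -> Tuple[str, ...]:
    """Identifiers of the scenario configurations shipped with the package."""
    return SCENARIO_IDS


def build_scenario(id_or_path: str | Path) -> ScenarioSpec:
    """Load a shipped scenario by identifier, or a user config by file path.

    Raises
    ------
    ValueError
        For an unknown identifier (listing the available ones) or a
        malformed configuration file.
    """
    name = str(id_or_path)
    if name in SCENARIO_IDS:
        ref = resources.files("coalabc").joinpath(f"configs/{name.lower()}.yaml")
        with resources.as_file(ref) as path:
            return ScenarioSpec.from_yaml(path)
    path = Path(id_or_path)
    if path.exists():
        return ScenarioSpec.from_yaml(path)
    raise ValueError(
        f"unknown scenario {name!r}; shipped scenarios are {', '.join(SCENARIO_IDS)} "
        "(or pass a path to a scenario config file)"
    )


# ---------------------------------------------------------------------------
# Prior sampling under constraints
# ---------------------------------------------------------------------------


def sample_prior_draw(
    spec: ScenarioSpec,
    rng: np.random.Generator,
    max_attempts: int = 100_000,
) -> ParameterDraw:
    """Draw one parameter set from the constrained joint prior.

    Samples each parameter independently from its uniform prior and rejects
    joint draws violating the scenario's constraint set, so the result is an
    exact draw from the truncated joint prior.  Deterministic given the
    generator state.
    """
    for _ in range(max_attempts):
        draw = spec.priors.sample(rng)
        if spec.constraints.satisfied(draw):
            return draw
    raise RuntimeError(
        f"{spec.id}: no draw satisfying the constraints in {max_attempts} attempts; "
        "the constrained prior may have (near-)zero mass"
    )


def validate_draw(spec: ScenarioSpec, draw: Mapping[str, float]) -> List[str]:
    """List every violated constraint or prior bound; empty list means valid."""
    for name in spec.parameter_names():
        if name not in draw:
            raise KeyError(f"draw is missing parameter {name!r}")
    out = []
    for name in spec.parameter_names():
        low, high = spec.priors.bounds(name)
        v = draw[name]
        if not (low <= v <= high):
            out.append(f"out of bounds: {name}={v:g} not in [{low:g}, {high:g}]")
    out.extend(spec.constraints.violations(draw))
    return out
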