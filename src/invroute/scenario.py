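"""Invasion scenarios as backward-time demographic programs.

A scenario lists populations (each with an effective-size parameter),
backward-time events (``merge``: one population's lineages move into a
parent; ``admixture``: each lineage moves to parent A with probability r,
else parent B), parameter priors, and inequality conditions such as the
founder constraint "the introduced effective size is below every native
effective size". Effective sizes are haploid (numbers of transmitting
females) because the locus is maternally inherited mtDNA.

Parameter draws are rejection-sampled until all conditions hold; event times
are additionally required to respect the listed (backward-time) event order
strictly, so each lineage path sees strictly ordered events.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml


class ScenarioError(ValueError):
    """Raised for structurally invalid scenarios or unsatisfiable conditions."""


# ---------------------------------------------------------------------------
# priors
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PriorSpec:
    """A one-dimensional prior: uniform, loguniform, or gamma.

    ``gamma`` priors are parameterized by ``shape`` and a mean; the mean may
    be fixed (``mean``) or linked at sampling time to another drawn value
    (hierarchical mean-then-locus draws, as used for mutation parameters).
    """

    distribution: str  # uniform | loguniform | gamma
    low: float | None = None
    high: float | None = None
    shape: float | None = None
    mean: float | None = None
    units: str = "dimensionless"
    integer: bool = False

    def __post_init__(self) -> None:
        if self.distribution in ("uniform", "loguniform"):
            if self.low is None or self.high is None or not self.low < self.high:
                raise ScenarioError(
                    f"{self.distribution} prior requires low < high, got "
                    f"[{self.low}, {self.high}]"
                )
            if self.distribution == "loguniform" and self.low <= 0:
                raise ScenarioError("loguniform prior requires low > 0")
        elif self.distribution == "gamma":
            if self.shape is None or self.shape <= 0:
                raise ScenarioError("gamma prior requires shape > 0")
        else:
            raise ScenarioError(f"unknown distribution {self.distribution!r}")

    def sample(self, rng: np.random.Generator, mean: float | None = None) -> float:
        if self.distribution == "uniform":
            x = rng.uniform(self.low, self.high)
        elif self.distribution == "loguniform":
            x = float(np.exp(rng.uniform(np.log(self.low), np.log(self.high))))
        else:  # gamma
            mu = mean if mean is not None else self.mean
            if mu is None:
                raise ScenarioError("gamma prior needs a mean (fixed or linked)")
            x = float(rng.gamma(self.shape, mu / self.shape))
        if self.integer:
            x = float(int(round(x)))
        return float(x)


def prior_from_dict(d: dict[str, Any]) -> PriorSpec:
    return PriorSpec(
        distribution=d["distribution"],
        low=d.get("low"),
        high=d.get("high"),
        shape=d.get("shape"),
        mean=d.get("mean"),
        units=d.get("units", "dimensionless"),
        integer=bool(d.get("integer", False)),
    )


#: default effective-size prior (haploid individuals)
DEFAULT_SIZE_PRIOR = PriorSpec("uniform", 10, 10_000, units="individuals", integer=True)
#: default event-time prior (generations before present)
DEFAULT_TIME_PRIOR = PriorSpec("uniform", 10, 10_000, units="generations")
#: default admixture-rate prior
DEFAULT_RATE_PRIOR = PriorSpec("uniform", 0.001, 0.999)


# ---------------------------------------------------------------------------
# scenario structure
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Population:
    name: str
    size_param: str
    role: str = "native"  # native | introduced


@dataclass(frozen=True)
class DemographicEvent:
    """One backward-time event at symbolic time ``time_param``."""

    time_param: str
    kind: str  # merge | admixture
    child: str
    parent: str | None = None          # merge target
    parent_a: str | None = None        # admixture: goes here with prob rate
    parent_b: str | None = None
    rate_param: str | None = None

    def __post_init__(self) -> None:
        if self.kind == "merge":
            if not self.parent:
                raise ScenarioError("merge event needs a parent")
        elif self.kind == "admixture":
            if not (self.parent_a and self.parent_b and self.rate_param):
                raise ScenarioError("admixture event needs parent_a, parent_b, rate")
        else:
            raise ScenarioError(f"unknown event kind {self.kind!r}")


@dataclass
class Scenario:
    """A rooted backward-time demographic program with priors and conditions."""

    id: str
    populations: list[Population]
    events: list[DemographicEvent]
    conditions: list[str] = field(default_factory=list)
    description: str = ""

    @property
    def population_names(self) -> list[str]:
        return [p.name for p in self.populations]

    def size_param(self, pop_name: str) -> str:
        for p in self.populations:
            if p.name == pop_name:
                return p.size_param
        raise ScenarioError(f"unknown population {pop_name!r}")

    def parameter_names(self) -> list[str]:
        names: list[str] = []
        for p in self.populations:
            if p.size_param not in names:
                names.append(p.size_param)
        for e in self.events:
            if e.time_param not in names:
                names.append(e.time_param)
            if e.rate_param and e.rate_param not in names:
                names.append(e.rate_param)
        return names


@dataclass
class ValidationReport:
    errors: list[str]

    @property
    def valid(self) -> bool:
        return not self.errors


def validate_scenario(
    scenario: Scenario, priors: dict[str, PriorSpec] | None = None
) -> ValidationReport:
    """Structural diagnostics: unique names, single root, events reference
    live populations, every parameter covered by a prior (when given)."""
    errors: list[str] = []
    names = scenario.population_names
    if len(set(names)) != len(names):
        errors.append("population names are not unique")
    active = set(names)
    for i, e in enumerate(scenario.events):
        refs = [e.child] + [p for p in (e.parent, e.parent_a, e.parent_b) if p]
        for r in refs:
            if r not in names:
                errors.append(f"event {i}: unknown population {r!r}")
        if e.child not in active:
            errors.append(f"event {i}: population {e.child!r} already absorbed")
            continue
        parents = [p for p in (e.parent, e.parent_a, e.parent_b) if p]
        for p in parents:
            if p not in active:
                errors.append(f"event {i}: parent {p!r} already absorbed")
        if e.child in parents:
            errors.append(f"event {i}: population {e.child!r} merges into itself")
        active.discard(e.child)
    if len(active) != 1:
        errors.append(
            f"no common root: {sorted(active)} remain after all events"
        )
    if priors is not None:
        for name in scenario.parameter_names():
            if name not in priors:
                errors.append(f"parameter {name!r} has no prior")
    return ValidationReport(errors=errors)


# ---------------------------------------------------------------------------
# condition strings
# ---------------------------------------------------------------------------

_COND_RE = re.compile(r"^\s*(.+?)\s*(<=|>=|<|>)\s*(.+?)\s*$")
_FUNC_RE = re.compile(r"^(min|max)\s*\((.+)\)$")


def _eval_expr(expr: str, values: dict[str, float]) -> float:
    expr = expr.strip()
    m = _FUNC_RE.match(expr)
    if m:
        fn = min if m.group(1) == "min" else max
        args = [_eval_expr(a, values) for a in m.group(2).split(",")]
        return fn(args)
    try:
        return float(expr)
    except ValueError:
        pass
    if expr in values:
        return values[expr]
    raise ScenarioError(f"unknown parameter {expr!r} in condition")


def evaluate_condition(condition: str, values: dict[str, float]) -> bool:
    """Evaluate an inequality string like ``"N4 < min(N1, N2, N3)"``."""
    m = _COND_RE.match(condition)
    if not m:
        raise ScenarioError(f"cannot parse condition {condition!r}")
    lhs, op, rhs = _eval_expr(m.group(1), values), m.group(2), _eval_expr(m.group(3), values)
    return {"<": lhs < rhs, ">": lhs > rhs, "<=": lhs <= rhs, ">=": lhs >= rhs}[op]


# ---------------------------------------------------------------------------
# parameter sampling
# ---------------------------------------------------------------------------

def sample_parameters(
    scenario: Scenario,
    priors: dict[str, PriorSpec],
    rng: np.random.Generator,
    max_rejections: int = 100_000,
) -> dict[str, float]:
    """Rejection-sample one parameter draw satisfying all conditions.

    The listed event order is enforced as strict ordering of the drawn event
    times, in addition to the scenario's explicit inequality conditions.
    """
    report = validate_scenario(scenario, priors)
    if not report.valid:
        raise ScenarioError("; ".join(report.errors))
    time_order = [e.time_param for e in scenario.events]
    for _ in range(max_rejections):
        draw = {name: priors[name].sample(rng) for name in scenario.parameter_names()}
        times = [draw[t] for t in time_order]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            continue
        if all(evaluate_condition(c, draw) for c in scenario.conditions):
            return draw
    raise ScenarioError(
        f"scenario {scenario.id!r}: no accepted draw in {max_rejections} attempts"
    )


# ---------------------------------------------------------------------------
# YAML experiment configs
# ---------------------------------------------------------------------------

@dataclass
class MutationPriorConfig:
    """Hierarchical mutation priors: a uniform mean and a per-locus gamma
    around that mean, for both the substitution rate and the
    transition/transversion coefficient kappa."""

    mean_rate: PriorSpec
    locus_rate_shape: float
    mean_kappa: PriorSpec
    locus_kappa_shape: float
    p_invariant: float = 0.10
    gamma_shape: float = 2.0  # site-rate heterogeneity

    def sample(self, rng: np.random.Generator) -> dict[str, float]:
        mu_mean = self.mean_rate.sample(rng)
        kappa_mean = self.mean_kappa.sample(rng)
        mu = float(rng.gamma(self.locus_rate_shape, mu_mean / self.locus_rate_shape))
        kappa = float(
            rng.gamma(self.locus_kappa_shape, kappa_mean / self.locus_kappa_shape)
        )
        return {
            "mu_mean": mu_mean,
            "mu": mu,
            "kappa_mean": kappa_mean,
            "kappa": kappa,
        }


DEFAULT_MUTATION_PRIORS = MutationPriorConfig(
    mean_rate=PriorSpec("uniform", 1e-7, 1e-5, units="rate per site per generation"),
    locus_rate_shape=2.0,
    mean_kappa=PriorSpec("uniform", 1.5, 20.0),
    locus_kappa_shape=2.0,
)


@dataclass
class ExperimentSpec:
    """A full scenario-choice experiment: populations with sample sizes,
    competing scenarios, priors, mutation model, and ABC settings."""

    name: str
    scenarios: list[Scenario]
    priors: dict[str, PriorSpec]
    mutation: MutationPriorConfig
    sample_sizes: dict[str, int]
    abc_settings: dict[str, Any] = field(default_factory=dict)
    description: str = ""
    #: experiment population -> observed locality/country labels it pools
    groups: dict[str, list[str]] = field(default_factory=dict)

    def validate(self) -> None:
        for sc in self.scenarios:
            report = validate_scenario(sc, self.priors)
            if not report.valid:
                raise ScenarioError(f"scenario {sc.id}: " + "; ".join(report.errors))


def _event_from_dict(d: dict[str, Any]) -> DemographicEvent:
    kind = d.get("kind", "merge")
    return DemographicEvent(
        time_param=d["time"],
        kind=kind,
        child=d["child"],
        parent=d.get("parent"),
        parent_a=d.get("parent_a"),
        parent_b=d.get("parent_b"),
        rate_param=d.get("rate"),
    )


def load_experiment(path: str | Path) -> ExperimentSpec:
    """Load an experiment config (YAML) into an :class:`ExperimentSpec`."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    pops_doc = doc["populations"]
    populations = [
        Population(name=name, size_param=spec["size"], role=spec.get("role", "native"))
        for name, spec in pops_doc.items()
    ]
    sample_sizes = {
        name: int(spec.get("sample_size", 0)) for name, spec in pops_doc.items()
    }
    priors = {name: prior_from_dict(d) for name, d in (doc.get("priors") or {}).items()}
    # fill defaults for any scenario parameter without an explicit prior
    scenarios = []
    for sd in doc["scenarios"]:
        sc_pops_doc = sd.get("populations")
        if sc_pops_doc:
            sc_pops = [
                Population(name=n, size_param=s["size"], role=s.get("role", "native"))
                for n, s in sc_pops_doc.items()
            ]
        else:
            sc_pops = populations
        scenarios.append(
            Scenario(
                id=str(sd["id"]),
                populations=sc_pops,
                events=[_event_from_dict(e) for e in sd["events"]],
                conditions=list(sd.get("conditions") or []),
                description=sd.get("description", ""),
            )
        )
    for sc in scenarios:
        for e in sc.events:
            priors.setdefault(e.time_param, DEFAULT_TIME_PRIOR)
            if e.rate_param:
                priors.setdefault(e.rate_param, DEFAULT_RATE_PRIOR)
        for p in sc.populations:
            priors.setdefault(p.size_param, DEFAULT_SIZE_PRIOR)
    mut_doc = doc.get("mutation") or {}
    mutation = MutationPriorConfig(
        mean_rate=prior_from_dict(
            mut_doc.get(
                "mean_rate",
                {"distribution": "uniform", "low": 1e-7, "high": 1e-5},
            )
        ),
        locus_rate_shape=float(mut_doc.get("locus_rate_shape", 2.0)),
        mean_kappa=prior_from_dict(
            mut_doc.get(
                "mean_kappa", {"distribution": "uniform", "low": 1.5, "high": 20.0}
            )
        ),
        locus_kappa_shape=float(mut_doc.get("locus_kappa_shape", 2.0)),
        p_invariant=float(mut_doc.get("p_invariant", 0.10)),
        gamma_shape=float(mut_doc.get("gamma_shape", 2.0)),
    )
    return ExperimentSpec(
        name=doc.get("name", Path(path).stem),
        scenarios=scenarios,
        priors=priors,
        mutation=mutation,
        sample_sizes=sample_sizes,
        abc_settings=dict(doc.get("abc") or {}),
        description=doc.get("description", ""),
        groups={k: list(v) for k, v in (doc.get("groups") or {}).items()},
    )
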