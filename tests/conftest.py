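"""Shared fixtures: small scenario pairs and toy alignments."""

from __future__ import annotations

import numpy as np
import pytest

from invroute.alignment import Alignment, SequenceRecord
from invroute.scenario import (
    DemographicEvent,
    Population,
    PriorSpec,
    Scenario,
)


def make_alignment(seqs: list[str], pops: list[str] | str = "pop") -> Alignment:
    if isinstance(pops, str):
        pops = [pops] * len(seqs)
    return Alignment(
        [SequenceRecord(id=f"s{i}", population=p, sequence=s)
         for i, (s, p) in enumerate(zip(seqs, pops))]
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20230817)


def single_population_scenario(size_param: str = "N1") -> Scenario:
    return Scenario(
        id="single",
        populations=[Population("pop", size_param)],
        events=[],
    )


def two_population_split(t_low: float = 500.0, t_high: float = 600.0) -> tuple[
    Scenario, dict[str, PriorSpec]
]:
    scenario = Scenario(
        id="split",
        populations=[Population("A", "N1"), Population("B", "N2")],
        events=[DemographicEvent("t1", "merge", child="B", parent="A")],
    )
    priors = {
        "N1": PriorSpec("uniform", 900, 1100, integer=True),
        "N2": PriorSpec("uniform", 400, 600, integer=True),
        "t1": PriorSpec("uniform", t_low, t_high),
    }
    return scenario, priors


def source_choice_pair(
    mutation_tight: bool = True,
) -> tuple[list[Scenario], dict[str, PriorSpec]]:
    """Two well-separated competing scenarios: an introduced population
    founded either from native1 or from native2, with the natives anciently
    diverged."""
    pops = [
        Population("native1", "N1"),
        Population("native2", "N2"),
        Population("introduced", "N3", "introduced"),
    ]
    priors = {
        "N1": PriorSpec("uniform", 2000, 10000, integer=True),
        "N2": PriorSpec("uniform", 2000, 10000, integer=True),
        "N3": PriorSpec("uniform", 10, 200, integer=True),
        "t1": PriorSpec("uniform", 10, 200),
        "t2": PriorSpec("uniform", 5000, 10000),
    }
    cond = ["N3 < min(N1, N2)"]
    s_a = Scenario(
        "from_native1", pops,
        [DemographicEvent("t1", "merge", child="introduced", parent="native1"),
         DemographicEvent("t2", "merge", child="native2", parent="native1")],
        cond,
    )
    s_b = Scenario(
        "from_native2", pops,
        [DemographicEvent("t1", "merge", child="introduced", parent="native2"),
         DemographicEvent("t2", "merge", child="native2", parent="native1")],
        cond,
    )
    return [s_a, s_b], priors


def tight_mutation_priors():
    from invroute.scenario import MutationPriorConfig

    return MutationPriorConfig(
        mean_rate=PriorSpec("uniform", 4.9e-6, 5.1e-6),
        locus_rate_shape=2.0,
        mean_kappa=PriorSpec("uniform", 2.9, 3.1),
        locus_kappa_shape=2.0,
    )
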