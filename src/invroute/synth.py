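"""Study-shaped synthetic data with known ground truth.

Two generators. ``generate_study`` wraps the coalescent engine to produce a
complete input bundle (per-population FASTA, id->population map, JSON truth
record) under a named scenario, so every pipeline stage can be exercised
end-to-end without any external sequence download. ``table1_like_counts``
emulates the global survey's signature count structure — native populations
with a long tail of rare haplotypes, introduced populations dominated by a
single founder haplotype — without simulating sequences at all.

The default emulation uses three native and two introduced populations at
685 bp, mirroring the triplet-source experiments; tests shrink the locus and
the sample sizes for speed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .alignment import Alignment
from .coalescent import simulate_dataset
from .haplotypes import HaplotypeTable, table_from_counts
from .scenario import (
    DEFAULT_MUTATION_PRIORS,
    DEFAULT_RATE_PRIOR,
    DEFAULT_SIZE_PRIOR,
    DEFAULT_TIME_PRIOR,
    DemographicEvent,
    MutationPriorConfig,
    Population,
    PriorSpec,
    Scenario,
)


@dataclass
class TruthRecord:
    """Everything needed to regenerate a synthetic study bit-exactly."""

    scenario_id: str
    parameters: dict[str, float]
    seed: int
    sample_sizes: dict[str, int]
    length: int

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)


def default_invasion_scenario(
    n_native: int = 3, n_introduced: int = 2, admixture: bool = False
) -> tuple[Scenario, dict[str, PriorSpec]]:
    """A study-shaped scenario: native populations on a ladder tree, each
    introduced population founded from the first native one by bottlenecked
    divergence (optionally the last one by admixture of the first native and
    first introduced populations)."""
    natives = [f"native{i+1}" for i in range(n_native)]
    intros = [f"introduced{i+1}" for i in range(n_introduced)]
    pops = [Population(p, f"N_{p}", "native") for p in natives]
    pops += [Population(p, f"N_{p}", "introduced") for p in intros]
    events: list[DemographicEvent] = []
    t_index = 1
    for j, p in enumerate(intros):
        if admixture and j == n_introduced - 1 and intros[0] != p:
            events.append(
                DemographicEvent(
                    time_param=f"t{t_index}", kind="admixture", child=p,
                    parent_a=natives[0], parent_b=intros[0], rate_param="r1",
                )
            )
        else:
            events.append(
                DemographicEvent(
                    time_param=f"t{t_index}", kind="merge", child=p,
                    parent=natives[0],
                )
            )
        t_index += 1
    for older, younger in zip(natives, natives[1:]):
        events.append(
            DemographicEvent(
                time_param=f"t{t_index}", kind="merge", child=younger, parent=older
            )
        )
        t_index += 1
    conditions = [
        f"N_{p} < min({', '.join(f'N_{q}' for q in natives)})" for p in intros
    ]
    priors: dict[str, PriorSpec] = {}
    for p in natives:
        priors[f"N_{p}"] = DEFAULT_SIZE_PRIOR
    for p in intros:
        priors[f"N_{p}"] = PriorSpec("uniform", 10, 2000, units="individuals",
                                     integer=True)
    for e in events:
        priors[e.time_param] = DEFAULT_TIME_PRIOR
        if e.rate_param:
            priors[e.rate_param] = DEFAULT_RATE_PRIOR
    scenario = Scenario(
        id="synthetic-default", populations=pops, events=events,
        conditions=conditions,
        description="bottlenecked introductions from the first native population",
    )
    return scenario, priors


def generate_study(
    scenario: Scenario,
    priors: dict[str, PriorSpec],
    sample_config: dict[str, int],
    seed: int,
    out_dir: str | Path | None = None,
    length: int = 685,
    mutation_priors: MutationPriorConfig | None = None,
) -> tuple[Alignment, TruthRecord]:
    """Simulate one synthetic study and (optionally) write its input files.

    Writes one FASTA per population plus ``population_map.tsv`` and
    ``truth.json`` under ``out_dir``. The same seed regenerates byte-identical
    files.
    """
    rng = np.random.default_rng(seed)
    draw, alignment = simulate_dataset(
        scenario, priors, sample_config, rng, length=length,
        mutation_priors=mutation_priors or DEFAULT_MUTATION_PRIORS,
    )
    truth = TruthRecord(
        scenario_id=scenario.id, parameters=draw, seed=seed,
        sample_sizes=dict(sample_config), length=length,
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for pop in sample_config:
            alignment.subset([pop]).write_fasta(out / f"{pop}.fasta")
        alignment.write_fasta(out / "all.fasta")
        alignment.write_population_map(out / "population_map.tsv")
        truth.to_json(out / "truth.json")
    return alignment, truth


def table1_like_counts(
    seed: int,
    native_totals: dict[str, int] | None = None,
    introduced_totals: dict[str, int] | None = None,
    n_pool: int = 40,
    dominant_share: float = 0.85,
    length: int = 685,
) -> HaplotypeTable:
    """A randomized count table with the survey's signature structure.

    Native populations draw from a long-tailed (geometric-ish) haplotype
    pool; each introduced population is dominated by one founder haplotype
    picked from its source's common types, with the remainder spread over a
    couple of rare types. Deterministic under ``seed``.
    """
    if native_totals is None:
        native_totals = {"native1": 158, "native2": 44, "native3": 12}
    if introduced_totals is None:
        introduced_totals = {"introduced1": 108, "introduced2": 139}
    rng = np.random.default_rng(seed)
    labels = [f"H{i+1}" for i in range(n_pool)]
    # long-tailed pool frequencies shared by the native range
    base = 0.6 ** np.arange(n_pool)
    rows = {}
    for pop, total in native_totals.items():
        w = base * rng.gamma(1.0, 1.0, size=n_pool)
        rows[pop] = rng.multinomial(total, w / w.sum())
    for pop, total in introduced_totals.items():
        founder = int(rng.integers(0, 5))  # founder drawn among common types
        probs = np.zeros(n_pool)
        probs[founder] = dominant_share
        n_rare = int(rng.integers(1, 4))
        rare = rng.choice(n_pool, size=n_rare, replace=False)
        probs[rare] += (1.0 - dominant_share) / n_rare
        rows[pop] = rng.multinomial(total, probs / probs.sum())
    counts = pd.DataFrame(rows).T
    counts.columns = labels
    counts = counts.loc[:, (counts.sum(axis=0) > 0)]
    return table_from_counts(counts, length=length)
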