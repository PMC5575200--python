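"""End-to-end scenario-choice experiments.

``run_experiment`` ties the stages together for one experiment config:
observed alignment -> summary statistics -> reference table -> rejection ->
posterior probabilities (with 95% CIs) -> PCA/prior pre-evaluation ->
posterior-based confidence, and writes a probability table shaped like the
published experiment tables (rows = scenarios; columns = Prob., CI low,
CI high; experiment-level Conf.) plus a JSON report recording the seed.

``run_elimination_round`` implements the two-round procedure: scenarios
whose posterior probability falls below a threshold (default 0.10) are
dropped and the analysis re-runs on the survivors.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .abc import (
    DEFAULT_TOLERANCE,
    ReferenceTable,
    ScenarioPosterior,
    build_reference_table,
    estimate_posteriors,
    prior_scenario_check,
    rejection_select,
    scenario_confidence,
)
from .alignment import Alignment, SequenceRecord, read_alignment
from .scenario import ExperimentSpec, load_experiment
from .sumstats import StatConfig, compute_summary_vector

logger = logging.getLogger(__name__)


@dataclass
class ExperimentReport:
    """Everything an experiment run produced, ready to serialize."""

    name: str
    seed: int
    posterior: ScenarioPosterior
    pre_evaluation: dict
    settings: dict
    table: ReferenceTable | None = None
    scenario_descriptions: dict[str, str] = field(default_factory=dict)

    def posterior_frame(self) -> pd.DataFrame:
        df = self.posterior.to_frame()
        df.insert(1, "description",
                  [self.scenario_descriptions.get(s, "") for s in df["scenario"]])
        return df

    def to_json_dict(self) -> dict:
        pre = dict(self.pre_evaluation)
        tails = pre.pop("tails", None)
        if tails is not None:
            pre["tails"] = {
                stat: {"q": float(row["q"]), "stars": row["stars"]}
                for stat, row in tails.iterrows()
            }
        return {
            "experiment": self.name,
            "version": __version__,
            "seed": self.seed,
            "settings": self.settings,
            "probabilities": self.posterior.probabilities,
            "intervals": {s: list(iv) for s, iv in self.posterior.intervals.items()},
            "selected": self.posterior.selected,
            "confidence": self.posterior.confidence,
            "method": self.posterior.method,
            "diagnostics": {
                k: v for k, v in self.posterior.diagnostics.items()
                if isinstance(v, (int, float, str, bool, list))
            },
            "pre_evaluation": pre,
        }

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.posterior_frame().to_csv(out / "posterior_table.csv", index=False)
        with open(out / "report.json", "w") as fh:
            json.dump(self.to_json_dict(), fh, indent=2, sort_keys=True)


def regroup_alignment(alignment: Alignment, groups: dict[str, list[str]]) -> Alignment:
    """Relabel observed populations onto the experiment's population names.

    ``groups`` maps an experiment population to the list of observed labels
    it pools (e.g. an eastern-US group pooling state-level collections).
    Records whose label matches no group are dropped.
    """
    reverse = {m: g for g, members in groups.items() for m in members}
    records = [
        SequenceRecord(id=r.id, population=reverse[r.population], sequence=r.sequence)
        for r in alignment.records
        if r.population in reverse
    ]
    if not records:
        raise ValueError("no observed records matched the experiment's groups")
    return Alignment(records)


def run_experiment(
    spec: ExperimentSpec | str | Path,
    observed: Alignment,
    seed: int,
    out_dir: str | Path | None = None,
    n_rows: int | None = None,
    tolerance: float | None = None,
    n_pods: int | None = None,
    length: int | None = None,
    method: str = "logistic",
    n_jobs: int = 1,
    compute_confidence: bool = True,
    keep_table: bool = False,
) -> ExperimentReport:
    """Run one scenario-choice experiment on an observed alignment.

    Sample sizes for the simulations default to the observed per-population
    sample sizes; base frequencies default to the observed composition.
    """
    if not isinstance(spec, ExperimentSpec):
        spec = load_experiment(spec)
    spec.validate()

    settings = dict(spec.abc_settings)
    n_rows = n_rows or int(settings.get("n_rows", 10_000))
    tolerance = tolerance or float(settings.get("tolerance", DEFAULT_TOLERANCE))
    n_pods = n_pods or int(settings.get("n_pods", 500))
    length = length or int(settings.get("length", 685))

    pops = [p for p in spec.scenarios[0].population_names
            if p in observed.populations]
    missing = set(spec.scenarios[0].population_names) - set(pops)
    if missing:
        raise ValueError(
            f"observed alignment lacks experiment population(s): {sorted(missing)}"
        )
    sample_config = {
        p: sum(r.population == p for r in observed.records) for p in pops
    }
    stat_config = StatConfig.all_pairs(pops)
    observed_vector = compute_summary_vector(observed, stat_config)
    # empirical composition, floored so a base absent from a small observed
    # sample cannot zero out the substitution model
    base_freqs = np.maximum(observed.base_frequencies(), 1e-3)
    base_freqs = base_freqs / base_freqs.sum()

    t0 = time.perf_counter()
    table = build_reference_table(
        spec.scenarios, spec.priors, sample_config, n_rows=n_rows, seed=seed,
        stat_config=stat_config, length=length, mutation_priors=spec.mutation,
        base_frequencies=base_freqs, n_jobs=n_jobs,
    )
    logger.info("reference table: %d rows in %.1fs (seed=%d)",
                n_rows, time.perf_counter() - t0, seed)

    pre = prior_scenario_check(table, observed_vector)
    rejection = rejection_select(table, observed_vector, tolerance)
    posterior = estimate_posteriors(rejection, table.scenario_set, method=method)

    if compute_confidence:
        selected_scenario = next(
            s for s in spec.scenarios if s.id == posterior.selected
        )
        t0 = time.perf_counter()
        posterior.confidence = scenario_confidence(
            selected_scenario, table, rejection, posterior.selected,
            sample_config, stat_config, tolerance, n_pods=n_pods,
            seed=seed + 1, length=length,
            p_invariant=spec.mutation.p_invariant,
            gamma_shape=spec.mutation.gamma_shape,
            base_frequencies=base_freqs, method=method,
        )
        logger.info("confidence: %d PODs in %.1fs",
                    n_pods, time.perf_counter() - t0)

    report = ExperimentReport(
        name=spec.name,
        seed=seed,
        posterior=posterior,
        pre_evaluation=pre,
        settings={
            "n_rows": n_rows, "tolerance": tolerance, "n_pods": n_pods,
            "length": length, "method": method,
            "sample_sizes": sample_config,
        },
        table=table if keep_table else None,
        scenario_descriptions={s.id: s.description for s in spec.scenarios},
    )
    if out_dir is not None:
        report.write(out_dir)
    return report


def run_elimination_round(
    spec: ExperimentSpec | str | Path,
    previous: ExperimentReport | dict | str | Path,
    observed: Alignment,
    seed: int,
    threshold: float = 0.10,
    out_dir: str | Path | None = None,
    **kwargs,
) -> ExperimentReport:
    """Re-run an experiment keeping only scenarios at or above ``threshold``.

    Raises if fewer than two scenarios survive.
    """
    if not isinstance(spec, ExperimentSpec):
        spec = load_experiment(spec)
    if isinstance(previous, (str, Path)):
        with open(previous) as fh:
            previous = json.load(fh)
    if isinstance(previous, ExperimentReport):
        probabilities = previous.posterior.probabilities
    else:
        probabilities = previous["probabilities"]
    survivors = [s for s in spec.scenarios
                 if probabilities.get(s.id, 0.0) >= threshold]
    if len(survivors) < 2:
        raise ValueError("nothing to compare: fewer than two scenarios survive")
    spec2 = ExperimentSpec(
        name=f"{spec.name}-round2",
        scenarios=survivors,
        priors=spec.priors,
        mutation=spec.mutation,
        sample_sizes=spec.sample_sizes,
        abc_settings=spec.abc_settings,
        description=spec.description,
    )
    return run_experiment(spec2, observed, seed, out_dir=out_dir, **kwargs)


def load_observed(
    fasta: str | Path, popmap: str | Path, groups: dict[str, list[str]] | None = None
) -> Alignment:
    """Read observed data and optionally pool labels into experiment groups."""
    alignment = read_alignment(fasta, popmap)
    if groups:
        alignment = regroup_alignment(alignment, groups)
    return alignment
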