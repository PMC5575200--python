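"""Haploid coalescent simulation under an invasion scenario, with HKY
mutations on the genealogy.

One simulated dataset is: (i) a backward-time genealogy of the sampled
lineages, with pairwise coalescence inside each population at rate
k(k-1)/(2N) for N the population's haploid effective size, lineage movement
at merge events, and probabilistic movement at admixture events; then (ii)
an HKY substitution process dropped onto the genealogy, with 10% invariant
sites and continuous Gamma(shape 2, mean 1) rate heterogeneity across the
remaining sites.

Substitutions are simulated exactly via uniformization: candidate events
form a Poisson process along each branch at the site's rate times the
maximum exit rate of the (mean-rate-one) HKY generator, and each candidate
either jumps according to the rate-matrix row or stays put, so multiple hits
are possible and the stationary base composition is exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alignment import Alignment, SequenceRecord, BASES
from .scenario import (
    MutationPriorConfig,
    PriorSpec,
    Scenario,
    ScenarioError,
    sample_parameters,
)


@dataclass
class Genealogy:
    """A binary coalescent tree over sampled lineages.

    Node arrays are indexed 0..2n-2; the first n nodes are leaves at time 0.
    ``parent[root] == -1``. Times are in generations before present and
    strictly increase root-ward.
    """

    parent: np.ndarray
    time: np.ndarray
    leaf_populations: list[str]
    leaf_ids: list[str]

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_populations)

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def root(self) -> int:
        return int(np.flatnonzero(self.parent == -1)[0])

    def tmrca(self) -> float:
        return float(self.time[self.root])

    def total_branch_length(self) -> float:
        has_parent = self.parent >= 0
        return float(
            np.sum(self.time[self.parent[has_parent]] - self.time[has_parent])
        )


def simulate_genealogy(
    scenario: Scenario,
    draw: dict[str, float],
    sample_config: dict[str, int],
    rng: np.random.Generator,
) -> Genealogy:
    """Simulate one genealogy under a scenario and parameter draw.

    ``sample_config`` maps population name -> number of sampled lineages
    (all sampled at time 0).
    """
    for pop, n in sample_config.items():
        if pop not in scenario.population_names:
            raise ScenarioError(f"sampled population {pop!r} not in scenario")
        if n < 1:
            raise ScenarioError(f"need >=1 lineage in population {pop!r}")

    leaf_pops = [p for p in sample_config for _ in range(sample_config[p])]
    n = len(leaf_pops)
    n_nodes = 2 * n - 1
    parent = np.full(n_nodes, -1, dtype=np.int64)
    time = np.zeros(n_nodes, dtype=float)
    leaf_ids = [f"{p}_{i}" for i, p in enumerate(leaf_pops)]

    # active lineages per population
    lineages: dict[str, list[int]] = {p: [] for p in scenario.population_names}
    for i, p in enumerate(leaf_pops):
        lineages[p].append(i)
    sizes = {p.name: float(draw[p.size_param]) for p in scenario.populations}

    events = sorted(
        scenario.events, key=lambda e: draw[e.time_param]
    )  # draws are strictly ordered already; sort is belt and braces
    next_node = n
    t = 0.0

    def n_active() -> int:
        return sum(len(v) for v in lineages.values())

    def coalesce(pop: str, at: float) -> None:
        nonlocal next_node
        group = lineages[pop]
        i, j = rng.choice(len(group), size=2, replace=False)
        a, b = group[int(i)], group[int(j)]
        parent[a] = parent[b] = next_node
        time[next_node] = at
        group.remove(a)
        group.remove(b)
        group.append(next_node)
        next_node += 1

    event_iter = iter(events)
    pending = next(event_iter, None)
    while n_active() > 1:
        # candidate coalescence: minimum of per-population exponentials
        best_pop, best_wait = None, np.inf
        for pop, group in lineages.items():
            k = len(group)
            if k >= 2:
                rate = k * (k - 1) / (2.0 * sizes[pop])
                w = rng.exponential(1.0 / rate)
                if w < best_wait:
                    best_pop, best_wait = pop, w
        t_event = draw[pending.time_param] if pending is not None else np.inf
        if t + best_wait < t_event:
            t = t + best_wait
            coalesce(best_pop, t)
            continue
        if pending is None:
            stranded = [p for p, g in lineages.items() if g]
            raise ScenarioError(
                f"lineages stranded in {stranded} with no remaining events"
            )
        # apply the demographic event
        t = t_event
        e = pending
        movers = lineages[e.child]
        lineages[e.child] = []
        if e.kind == "merge":
            lineages[e.parent].extend(movers)
        else:  # admixture, backward in time
            r = draw[e.rate_param]
            for node in movers:
                if rng.random() < r:
                    lineages[e.parent_a].append(node)
                else:
                    lineages[e.parent_b].append(node)
        pending = next(event_iter, None)

    return Genealogy(
        parent=parent, time=time, leaf_populations=leaf_pops, leaf_ids=leaf_ids
    )


# ---------------------------------------------------------------------------
# HKY mutation process
# ---------------------------------------------------------------------------

@dataclass
class MutationModel:
    """HKY substitution model with invariant sites and gamma site rates.

    Parameters
    ----------
    rate : float
        Locus substitution rate per site per generation (averaged over the
        variable sites' unit-mean gamma rates).
    kappa : float
        Transition/transversion rate coefficient (the C/T coefficient).
    base_frequencies : array-like of 4 floats (A, C, G, T)
        Stationary base frequencies; must be positive and sum to 1.
    p_invariant : float
        Fraction of sites with rate 0 (default 0.10).
    gamma_shape : float
        Shape of the unit-mean gamma distribution of per-site rates among
        variable sites (default 2).
    """

    rate: float
    kappa: float
    base_frequencies: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )
    p_invariant: float = 0.10
    gamma_shape: float = 2.0

    def __post_init__(self) -> None:
        self.base_frequencies = np.asarray(self.base_frequencies, dtype=float)
        if self.kappa <= 0:
            raise ValueError("kappa must be > 0")
        if (self.base_frequencies <= 0).any() or not np.isclose(
            self.base_frequencies.sum(), 1.0
        ):
            raise ValueError("base frequencies must be positive and sum to 1")
        if not 0.0 <= self.p_invariant < 1.0:
            raise ValueError("p_invariant must be in [0, 1)")

    def generator(self) -> np.ndarray:
        """HKY rate matrix normalized to one expected substitution per site
        per unit of mutation distance at stationarity."""
        pi = self.base_frequencies
        q = np.zeros((4, 4))
        transitions = {(0, 2), (2, 0), (1, 3), (3, 1)}  # A<->G, C<->T
        for i in range(4):
            for j in range(4):
                if i == j:
                    continue
                q[i, j] = pi[j] * (self.kappa if (i, j) in transitions else 1.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        mean_rate = float(-(pi * np.diag(q)).sum())
        return q / mean_rate

    def draw_site_rates(self, length: int, rng: np.random.Generator) -> np.ndarray:
        """Per-site relative rates: 0 with probability p_invariant, else
        Gamma(shape, mean 1)."""
        rates = rng.gamma(self.gamma_shape, 1.0 / self.gamma_shape, size=length)
        rates[rng.random(length) < self.p_invariant] = 0.0
        return rates


def mutate_alignment(
    genealogy: Genealogy,
    model: MutationModel,
    length: int,
    rng: np.random.Generator,
    stats_out: dict | None = None,
) -> Alignment:
    """Drop HKY mutations onto a genealogy, returning the leaf alignment.

    The ancestral sequence is drawn from the stationary base frequencies;
    each branch then evolves each site by a uniformized HKY jump process
    (multiple hits allowed). If ``stats_out`` is supplied, the number of
    realized substitutions is stored under ``"n_substitutions"``.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    pi = model.base_frequencies
    q = model.generator()
    exit_rates = -np.diag(q)
    q_max = float(exit_rates.max())
    # jump table: candidate event from state i goes to j with prob q[i,j]/q_max,
    # stays with prob 1 - exit_rates[i]/q_max
    jump_cdf = np.zeros((4, 4))
    for i in range(4):
        probs = q[i].copy()
        probs[i] = q_max - exit_rates[i]
        jump_cdf[i] = np.cumsum(probs / q_max)

    site_rates = model.draw_site_rates(length, rng)
    root_seq = rng.choice(4, size=length, p=pi).astype(np.uint8)

    # candidate-event counts for every (node, site) in one vectorized draw
    parent = genealogy.parent
    has_parent = parent >= 0
    branch_len = np.zeros(genealogy.n_nodes)
    branch_len[has_parent] = (
        genealogy.time[parent[has_parent]] - genealogy.time[has_parent]
    )
    lam = (model.rate * q_max) * branch_len[:, None] * site_rates[None, :]
    counts = rng.poisson(lam)

    children: dict[int, list[int]] = {}
    for node, par in enumerate(parent):
        if par >= 0:
            children.setdefault(int(par), []).append(node)

    seqs: dict[int, np.ndarray] = {genealogy.root: root_seq}
    n_subs = 0
    stack = [genealogy.root]
    while stack:
        node = stack.pop()
        node_seq = seqs[node]
        for child in children.get(node, []):
            child_seq = node_seq.copy()
            for s in np.flatnonzero(counts[child]):
                state = child_seq[s]
                for _ in range(int(counts[child, s])):
                    u = rng.random()
                    new_state = int(np.searchsorted(jump_cdf[state], u))
                    if new_state != state:
                        n_subs += 1
                        state = new_state
                child_seq[s] = state
            seqs[child] = child_seq
            stack.append(child)

    if stats_out is not None:
        stats_out["n_substitutions"] = n_subs
        stats_out["site_rates"] = site_rates
        stats_out["ancestral"] = root_seq

    base_bytes = np.frombuffer(BASES.encode("ascii"), dtype=np.uint8)
    records = []
    for i in range(genealogy.n_leaves):
        records.append(
            SequenceRecord(
                id=genealogy.leaf_ids[i],
                population=genealogy.leaf_populations[i],
                sequence=base_bytes[seqs[i]].tobytes().decode("ascii"),
            )
        )
    alignment = Alignment(records)
    # leaves are pure A/C/G/T: hand the encoder its matrix directly
    alignment._matrix = np.vstack([seqs[i] for i in range(genealogy.n_leaves)])
    return alignment


def simulate_dataset(
    scenario: Scenario,
    priors: dict[str, PriorSpec],
    sample_config: dict[str, int],
    rng: np.random.Generator,
    length: int = 685,
    mutation_priors: MutationPriorConfig | None = None,
    base_frequencies: np.ndarray | None = None,
) -> tuple[dict[str, float], Alignment]:
    """One prior draw -> one genealogy -> one alignment.

    Returns the full parameter draw (demographic and mutation parameters)
    plus the simulated alignment. Deterministic given the generator state.
    """
    from .scenario import DEFAULT_MUTATION_PRIORS

    mp = mutation_priors or DEFAULT_MUTATION_PRIORS
    draw = sample_parameters(scenario, priors, rng)
    mut = mp.sample(rng)
    draw = {**draw, **mut}
    genealogy = simulate_genealogy(scenario, draw, sample_config, rng)
    model = MutationModel(
        rate=mut["mu"],
        kappa=mut["kappa"],
        base_frequencies=(
            base_frequencies if base_frequencies is not None else np.full(4, 0.25)
        ),
        p_invariant=mp.p_invariant,
        gamma_shape=mp.gamma_shape,
    )
    alignment = mutate_alignment(genealogy, model, length, rng)
    return draw, alignment
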