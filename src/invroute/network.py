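"""Statistical-parsimony (TCS) haplotype networks.

Three stages: a pairwise mutational-step matrix (Hamming distance over
unambiguous sites), the 95% statistical-parsimony connection limit, and
minimum-spanning-network assembly in which multi-step connections receive
zero-frequency inferred intermediate nodes. Ties between equal-step
alternative connections are all retained, so reticulations (loops) survive
rather than being broken by a frequency criterion.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
from scipy.optimize import brentq

from .haplotypes import HaplotypeTable


@dataclass
class StepMatrix:
    """Symmetric matrix of mutational steps between haplotypes."""

    labels: list[str]
    steps: np.ndarray

    def __post_init__(self) -> None:
        s = np.asarray(self.steps)
        if s.shape != (len(self.labels), len(self.labels)):
            raise ValueError("step matrix shape does not match labels")
        if (s != s.T).any() or np.diag(s).any():
            raise ValueError("step matrix must be symmetric with zero diagonal")
        self.steps = s.astype(int)

    def get(self, a: str, b: str) -> int:
        i, j = self.labels.index(a), self.labels.index(b)
        return int(self.steps[i, j])


def _pairwise_steps(seq_a: str, seq_b: str) -> int:
    """Hamming distance skipping sites where either sequence is ambiguous."""
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences differ in length")
    n = 0
    for x, y in zip(seq_a, seq_b):
        if x in "ACGT" and y in "ACGT" and x != y:
            n += 1
    return n


def step_matrix(table: HaplotypeTable) -> StepMatrix:
    """Pairwise mutational steps between all haplotypes of a table.

    Sites where either sequence carries ``N`` or ``-`` are skipped for that
    pair (pairwise deletion).
    """
    labels = table.labels
    if not labels:
        raise ValueError("need at least one haplotype")
    n = len(labels)
    steps = np.zeros((n, n), dtype=int)
    seqs = [table.haplotypes[l] for l in labels]
    for i in range(n):
        for j in range(i + 1, n):
            steps[i, j] = steps[j, i] = _pairwise_steps(seqs[i], seqs[j])
    return StepMatrix(labels=labels, steps=steps)


# ---------------------------------------------------------------------------
# statistical-parsimony connection limit
# ---------------------------------------------------------------------------

def _prob_difference(lam: float) -> float:
    """P(a site shows a difference) when substitutions are Poisson(lam) with
    Jukes-Cantor jumps."""
    return 0.75 * (1.0 - math.exp(-4.0 * lam / 3.0))


def probability_of_parsimony(j: int, seq_length: int) -> float:
    """Probability that ``j`` observed differences over ``seq_length`` sites
    arose without any superimposed (homoplastic) change.

    The per-site number of substitutions on the path between two haplotypes
    is modelled as Poisson with mean ``lam``, calibrated so the expected
    number of differing sites equals ``j``. Parsimony holds when no site took
    more than one substitution: each observed difference must be a single
    hit, and each invariant site must hide no back-mutation.
    """
    if j <= 0:
        return 1.0
    m = seq_length
    if j >= 0.75 * m:  # more differences than the saturation expectation
        return 0.0
    f = lambda lam: m * _prob_difference(lam) - j
    hi = 1.0
    while f(hi) < 0:
        hi *= 2.0
    lam = brentq(f, 1e-15, hi, xtol=1e-14, rtol=1e-14)
    p_diff = _prob_difference(lam)
    per_differing = lam * math.exp(-lam) / p_diff
    per_matching = math.exp(-lam) / (1.0 - p_diff)
    return per_differing**j * per_matching ** (m - j)


def parsimony_limit(seq_length: int, confidence: float = 0.95) -> int:
    """Largest number of steps ``j`` whose probability of parsimony is still
    at or above ``confidence`` (the classic 95% connection limit)."""
    if seq_length < 1:
        raise ValueError("seq_length must be >= 1")
    if not 0.0 < confidence < 1.0:
        raise ValueError("confidence must be in (0, 1)")
    j = 0
    while probability_of_parsimony(j + 1, seq_length) >= confidence:
        j += 1
    return j


# ---------------------------------------------------------------------------
# network assembly
# ---------------------------------------------------------------------------

@dataclass
class HaplotypeNetwork:
    """A haplotype network: observed nodes with frequencies and population
    composition, zero-frequency inferred intermediates, and unit-step edges."""

    graph: nx.Graph
    limit: int

    @property
    def observed_nodes(self) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if not d["is_intermediate"]]

    @property
    def intermediate_nodes(self) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if d["is_intermediate"]]

    def total_frequency(self) -> int:
        return sum(d["frequency"] for _, d in self.graph.nodes(data=True))

    def connections(self) -> set[frozenset[str]]:
        """Observed-haplotype pairs joined by a direct (possibly multi-step,
        via intermediates) connection."""
        out = set()
        for u, v, d in self.graph.edges(data=True):
            pair = d.get("connection")
            if pair:
                out.add(frozenset(pair))
        return out

    def write_graphml(self, path: str | Path) -> None:
        g = self.graph.copy()
        for _, d in g.nodes(data=True):
            # GraphML holds scalars only; flatten the composition dict
            comp = d.pop("populations", {})
            d["populations"] = ";".join(f"{p}:{c}" for p, c in sorted(comp.items()))
        for _, _, d in g.edges(data=True):
            pair = d.pop("connection", None)
            if pair:
                d["connection"] = f"{pair[0]}|{pair[1]}"
        nx.write_graphml(g, str(path))

    def write_edge_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["source", "target", "step"])
            for u, v, d in self.graph.edges(data=True):
                w.writerow([u, v, d["step"]])


def _sorted_pair(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


def build_network(
    steps: StepMatrix, table: HaplotypeTable, limit: int
) -> HaplotypeNetwork:
    """Assemble the minimum-spanning haplotype network.

    Pairs are processed in increasing step order up to ``limit``. Within one
    step class, every pair whose endpoints lay in different components before
    the class is connected — retaining all equal-step alternatives, hence
    loops. A d-step connection inserts d-1 zero-frequency intermediates.
    Deterministic: ties inside a class are added in lexicographic label order.
    """
    if limit < 1:
        raise ValueError("limit must be >= 1")
    labels = steps.labels
    g = nx.Graph()
    pop_counts = table.counts
    for lab in labels:
        comp = {p: int(pop_counts.loc[p, lab]) for p in table.populations
                if pop_counts.loc[p, lab] > 0}
        g.add_node(lab, frequency=int(pop_counts[lab].sum()), is_intermediate=False,
                   populations=comp)

    # candidate pairs grouped by step value
    by_step: dict[int, list[tuple[str, str]]] = {}
    n = len(labels)
    for i in range(n):
        for j in range(i + 1, n):
            d = int(steps.steps[i, j])
            if 1 <= d <= limit:
                by_step.setdefault(d, []).append(_sorted_pair(labels[i], labels[j]))

    # union-find over observed labels
    parent = {l: l for l in labels}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for d in sorted(by_step):
        snapshot = {l: find(l) for l in labels}
        added: list[tuple[str, str]] = []
        for a, b in sorted(by_step[d]):
            if snapshot[a] != snapshot[b]:
                added.append((a, b))
                # lay the connection as a path with d-1 intermediates
                prev = a
                for k in range(1, d):
                    mid = f"{a}~{b}.{k}"
                    g.add_node(mid, frequency=0, is_intermediate=True, populations={})
                    g.add_edge(prev, mid, step=1, connection=(a, b))
                    prev = mid
                g.add_edge(prev, b, step=1, connection=(a, b))
        for a, b in added:
            parent[find(a)] = find(b)
    return HaplotypeNetwork(graph=g, limit=limit)
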