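"""Single-locus sequence summary statistics.

These are the coordinates of the Euclidean rejection space in the ABC
engine: per population — number of distinct haplotypes, segregating sites,
mean and variance of pairwise differences, private segregating sites; per
population pair — mean between-population pairwise differences, pooled
haplotype count, and Hudson's FST. Sites with ``N``/``-`` are excluded
pairwise, the same masking rule used for mutational steps in the network
module.

Statistics that are undefined on a dataset (FST with zero between-population
diversity, pairwise moments of a single sequence) are reported as NaN and
imputed with the reference-table column mean before standardization in the
ABC engine, so Euclidean distances stay well-defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alignment import Alignment

PER_POP_STATS = ("n_haplotypes", "segregating_sites", "mean_pairwise",
                 "var_pairwise", "private_segregating")
PER_PAIR_STATS = ("mean_between", "pooled_haplotypes", "fst")


class _Profile:
    """Cached per-alignment precomputation shared by all statistics.

    Only the overall-variable columns can ever contribute a pairwise
    difference or a segregating site, so everything is computed on that
    column subset; the full n x n difference matrix uses pairwise deletion
    of ambiguous sites.
    """

    def __init__(self, alignment: Alignment) -> None:
        mat = alignment.to_matrix()
        valid = mat < 4
        lo = np.where(valid, mat, 9).min(axis=0)
        hi = np.where(valid, mat, 0).max(axis=0)
        var_cols = np.flatnonzero((hi > lo) & (lo < 9))
        self.sub = mat[:, var_cols]
        self.vsub = valid[:, var_cols]
        diff = (self.sub[:, None, :] != self.sub[None, :, :])
        both = self.vsub[:, None, :] & self.vsub[None, :, :]
        self.dist = (diff & both).sum(axis=2).astype(float)
        self.seqs = [r.sequence for r in alignment.records]
        self.pop_index: dict[str, np.ndarray] = {}
        for i, r in enumerate(alignment.records):
            self.pop_index.setdefault(r.population, []).append(i)  # type: ignore
        self.pop_index = {p: np.asarray(v) for p, v in self.pop_index.items()}
        self._seg_cache: dict[str, np.ndarray] = {}
        self._within_cache: dict[str, np.ndarray] = {}

    def pop_segregating(self, pop: str) -> np.ndarray:
        if pop not in self._seg_cache:
            self._seg_cache[pop] = self.segregating(self.pop_index[pop])
        return self._seg_cache[pop]

    def pop_pair_diffs(self, pop: str) -> np.ndarray:
        if pop not in self._within_cache:
            self._within_cache[pop] = self.pair_diffs(self.pop_index[pop])
        return self._within_cache[pop]

    def segregating(self, idx: np.ndarray) -> np.ndarray:
        """Boolean mask (over variable columns) of sites segregating within
        the row subset ``idx``."""
        sub, vsub = self.sub[idx], self.vsub[idx]
        lo = np.where(vsub, sub, 9).min(axis=0)
        hi = np.where(vsub, sub, 0).max(axis=0)
        return (hi > lo) & (lo < 9)

    _triu_cache: dict[int, tuple[np.ndarray, np.ndarray]] = {}

    def pair_diffs(self, idx: np.ndarray) -> np.ndarray:
        n = len(idx)
        iu = self._triu_cache.get(n)
        if iu is None:
            iu = self._triu_cache[n] = np.triu_indices(n, k=1)
        return self.dist[np.ix_(idx, idx)][iu]

    def cross_diffs(self, idx_a: np.ndarray, idx_b: np.ndarray) -> np.ndarray:
        return self.dist[np.ix_(idx_a, idx_b)].ravel()

    def n_haplotypes(self, idx: np.ndarray) -> int:
        return len({self.seqs[i] for i in idx})


def _profile(alignment: Alignment) -> _Profile:
    prof = getattr(alignment, "_sumstat_profile", None)
    if prof is None:
        prof = _Profile(alignment)
        alignment._sumstat_profile = prof
    return prof


def per_population_stats(alignment: Alignment, population: str) -> dict[str, float]:
    """Within-population statistics; pairwise moments are NaN when n=1."""
    prof = _profile(alignment)
    if population not in prof.pop_index:
        raise KeyError(f"population {population!r} not present in alignment")
    idx = prof.pop_index[population]
    seg = prof.pop_segregating(population)
    stats: dict[str, float] = {
        "n_haplotypes": float(prof.n_haplotypes(idx)),
        "segregating_sites": float(seg.sum()),
    }
    if idx.size >= 2:
        diffs = prof.pop_pair_diffs(population)
        stats["mean_pairwise"] = float(diffs.mean())
        stats["var_pairwise"] = float(diffs.var(ddof=0))
    else:
        stats["mean_pairwise"] = np.nan
        stats["var_pairwise"] = np.nan
    # private segregating sites: polymorphic here, monomorphic in the rest
    other = np.asarray(sorted(set(range(len(prof.seqs))) - set(idx.tolist())))
    if other.size:
        stats["private_segregating"] = float((seg & ~prof.segregating(other)).sum())
    else:
        stats["private_segregating"] = float(seg.sum())
    return stats


def pairwise_population_stats(
    alignment: Alignment, pop_a: str, pop_b: str
) -> dict[str, float]:
    """Between-population statistics for one population pair.

    FST follows Hudson: 1 - (mean within)/(mean between), with the mean
    within averaged over the two populations. Undefined (NaN) when the mean
    between-population difference is zero.
    """
    prof = _profile(alignment)
    for p in (pop_a, pop_b):
        if p not in prof.pop_index:
            raise KeyError(f"population {p!r} not present in alignment")
    idx_a, idx_b = prof.pop_index[pop_a], prof.pop_index[pop_b]
    mean_between = float(prof.cross_diffs(idx_a, idx_b).mean())
    pooled = prof.n_haplotypes(np.concatenate([idx_a, idx_b]))
    within = [prof.pop_pair_diffs(p).mean() for p, idx in
              ((pop_a, idx_a), (pop_b, idx_b)) if idx.size >= 2]
    if mean_between > 0 and within:
        fst = 1.0 - float(np.mean(within)) / mean_between
    else:
        fst = np.nan
    return {
        "mean_between": mean_between,
        "pooled_haplotypes": float(pooled),
        "fst": fst,
    }


@dataclass
class StatConfig:
    """Which populations and pairs enter the summary vector, in fixed order."""

    populations: list[str]
    pairs: list[tuple[str, str]] = field(default_factory=list)

    @classmethod
    def all_pairs(cls, populations: list[str]) -> "StatConfig":
        pairs = [
            (a, b)
            for i, a in enumerate(populations)
            for b in populations[i + 1:]
        ]
        return cls(populations=list(populations), pairs=pairs)

    def names(self) -> list[str]:
        out = [f"{p}:{s}" for p in self.populations for s in PER_POP_STATS]
        out += [f"{a}|{b}:{s}" for a, b in self.pairs for s in PER_PAIR_STATS]
        return out


def compute_summary_vector(alignment: Alignment, config: StatConfig) -> pd.Series:
    """The full summary-statistic vector, as a named pandas Series.

    Order: per-population blocks (haplotypes, S, mean pi, var pi, private S)
    for each configured population, then per-pair blocks (mean between,
    pooled haplotypes, FST). Missing values are NaN here; imputation happens
    against the reference table.
    """
    values: list[float] = []
    for pop in config.populations:
        stats = per_population_stats(alignment, pop)
        values.extend(stats[s] for s in PER_POP_STATS)
    for a, b in config.pairs:
        stats = pairwise_population_stats(alignment, a, b)
        values.extend(stats[s] for s in PER_PAIR_STATS)
    return pd.Series(values, index=config.names(), dtype=float)
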