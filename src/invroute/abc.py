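"""ABC scenario choice: reference table, rejection, posterior estimation,
prior/scenario pre-evaluation, and posterior-based confidence.

The engine follows the classic rejection + local multinomial logistic
regression recipe for model choice. A reference table of pseudo-observed
datasets (PODs) is simulated with scenarios drawn with equal weight; every
summary statistic is standardized by its reference-table mean and standard
deviation; the PODs closest to the observed vector in Euclidean distance
are retained; scenario posterior probabilities come either from retained-set
proportions (direct) or from a multinomial logistic regression of scenario
identity on the (centered) statistics, evaluated at the observed point, with
95% confidence intervals by the delta method. Confidence in scenario choice
is the posterior-based reclassification rate: datasets re-simulated from the
chosen scenario's retained parameter draws are pushed through the same
classification, and confidence is the fraction assigned back to it.

Every stochastic stage derives per-row random streams by counter-based seed
splitting, so results are reproducible and independent of worker count.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from joblib import Parallel, delayed
from sklearn.decomposition import PCA
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression

from .alignment import Alignment
from .coalescent import MutationModel, mutate_alignment, simulate_genealogy
from .scenario import MutationPriorConfig, PriorSpec, Scenario, sample_parameters
from .sumstats import StatConfig, compute_summary_vector

logger = logging.getLogger(__name__)

Z95 = 1.959963984540054


@dataclass
class ReferenceTable:
    """Rows of (scenario id, parameter draw, summary-statistic vector)."""

    scenario_ids: np.ndarray           # (n,) str
    params: pd.DataFrame               # (n, n_params), NaN where not applicable
    stats: pd.DataFrame                # (n, n_stats)
    scenario_set: list[str]

    def __len__(self) -> int:
        return len(self.scenario_ids)

    def to_csv(self, path: str | Path) -> None:
        out = pd.concat(
            [pd.Series(self.scenario_ids, name="scenario"), self.params, self.stats],
            axis=1,
        )
        out.to_csv(path, index=False)

    def column_moments(self) -> tuple[pd.Series, pd.Series]:
        """NaN-aware mean and standard deviation of every statistic."""
        return self.stats.mean(skipna=True), self.stats.std(skipna=True, ddof=0)


def _row_rng(seed: int, row: int) -> np.random.Generator:
    """Counter-based stream split: row streams are independent of how rows
    are partitioned across workers."""
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(row,)))


def _simulate_row(
    row: int,
    seed: int,
    scenarios: list[Scenario],
    priors: dict[str, PriorSpec],
    sample_config: dict[str, int],
    stat_config: StatConfig,
    length: int,
    mutation_priors: MutationPriorConfig | None,
    base_frequencies: np.ndarray | None,
) -> tuple[str, dict[str, float], pd.Series]:
    from .coalescent import simulate_dataset

    rng = _row_rng(seed, row)
    k = int(rng.integers(len(scenarios)))
    scenario = scenarios[k]
    try:
        draw, alignment = simulate_dataset(
            scenario, priors, sample_config, rng, length=length,
            mutation_priors=mutation_priors, base_frequencies=base_frequencies,
        )
        stats = compute_summary_vector(alignment, stat_config)
    except Exception as exc:  # pragma: no cover - row context for debugging
        raise RuntimeError(f"reference-table row {row} (scenario {scenario.id}) "
                           f"failed: {exc}") from exc
    return scenario.id, draw, stats


#: reference-table size used in the full-scale analyses
DEFAULT_N_ROWS = 1_000_000
#: default fraction of closest PODs retained by rejection
DEFAULT_TOLERANCE = 0.01


def build_reference_table(
    scenarios: list[Scenario],
    priors: dict[str, PriorSpec],
    sample_config: dict[str, int],
    n_rows: int = DEFAULT_N_ROWS,
    seed: int = 0,
    stat_config: StatConfig | None = None,
    length: int = 685,
    mutation_priors: MutationPriorConfig | None = None,
    base_frequencies: np.ndarray | None = None,
    n_jobs: int = 1,
) -> ReferenceTable:
    """Simulate the reference table of PODs.

    Scenarios are drawn with equal weight for each row. Rows are seeded
    individually from ``seed`` and the row index, so serial and parallel
    runs produce identical tables.
    """
    if len(scenarios) < 2:
        raise ValueError("need at least two scenarios to compare")
    if n_rows < 1:
        raise ValueError("n_rows must be >= 1")
    if stat_config is None:
        stat_config = StatConfig.all_pairs(list(sample_config))

    args = (seed, scenarios, priors, sample_config, stat_config, length,
            mutation_priors, base_frequencies)
    if n_jobs == 1:
        rows = [_simulate_row(i, *args) for i in range(n_rows)]
    else:
        rows = Parallel(n_jobs=n_jobs, batch_size=256)(
            delayed(_simulate_row)(i, *args) for i in range(n_rows)
        )
    ids = np.asarray([r[0] for r in rows])
    params = pd.DataFrame([r[1] for r in rows])
    stats = pd.DataFrame([r[2] for r in rows])
    return ReferenceTable(
        scenario_ids=ids, params=params, stats=stats,
        scenario_set=[s.id for s in scenarios],
    )


# ---------------------------------------------------------------------------
# rejection
# ---------------------------------------------------------------------------

@dataclass
class RejectionResult:
    """Retained PODs with their distances and the standardized design."""

    indices: np.ndarray                # retained row indices, closest first
    distances: np.ndarray              # matching Euclidean distances
    retained_std: np.ndarray           # standardized stats of retained rows
    observed_std: np.ndarray           # standardized observed vector
    kept_columns: list[str]            # statistics that entered the distance
    scenario_ids: np.ndarray           # scenario id per retained row

    def __len__(self) -> int:
        return len(self.indices)


def standardize(
    table: ReferenceTable, observed: pd.Series
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Impute NaNs with reference-table column means, standardize by table
    mean/SD, and drop zero-variance statistics (logged)."""
    mean, sd = table.column_moments()
    stats = table.stats.reindex(columns=observed.index)
    mean = mean.reindex(observed.index)
    sd = sd.reindex(observed.index)
    keep = sd > 0
    dropped = list(observed.index[~keep])
    if dropped:
        logger.warning("dropping zero-variance statistics from distance: %s", dropped)
    cols = list(observed.index[keep])
    x = stats[cols].fillna(mean[cols]).to_numpy()
    x = (x - mean[cols].to_numpy()) / sd[cols].to_numpy()
    obs = observed[cols].fillna(mean[cols]).to_numpy()
    obs = (obs - mean[cols].to_numpy()) / sd[cols].to_numpy()
    return x, obs, cols


def rejection_select(
    table: ReferenceTable, observed: pd.Series, tolerance_fraction: float
) -> RejectionResult:
    """Retain the ceil(tolerance * n) PODs closest to the observed vector.

    Distance is Euclidean on standardized statistics; ties break
    deterministically by row index (stable sort).
    """
    if not 0.0 < tolerance_fraction <= 1.0:
        raise ValueError("tolerance_fraction must be in (0, 1]")
    x, obs, cols = standardize(table, observed)
    dist = np.sqrt(((x - obs) ** 2).sum(axis=1))
    n_keep = math.ceil(tolerance_fraction * len(table))
    order = np.argsort(dist, kind="stable")[:n_keep]
    return RejectionResult(
        indices=order,
        distances=dist[order],
        retained_std=x[order],
        observed_std=obs,
        kept_columns=cols,
        scenario_ids=table.scenario_ids[order],
    )


# ---------------------------------------------------------------------------
# posterior estimation
# ---------------------------------------------------------------------------

@dataclass
class ScenarioPosterior:
    """Per-scenario probabilities with 95% CIs and the chosen scenario."""

    probabilities: dict[str, float]
    intervals: dict[str, tuple[float, float]]
    selected: str
    method: str
    confidence: float | None = None
    diagnostics: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "scenario": s,
                "Prob.": self.probabilities[s],
                "CI low": self.intervals[s][0],
                "CI high": self.intervals[s][1],
            }
            for s in self.probabilities
        ]
        df = pd.DataFrame(rows)
        df["Conf."] = self.confidence
        return df


def _fit_multinomial(x: np.ndarray, y: np.ndarray, classes: list[str]):
    """Unpenalized multinomial logistic fit, with a ridge fallback when the
    unpenalized likelihood does not converge (separation)."""
    regularized = False
    clf = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=5000, tol=1e-10)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        clf.fit(x, y)
        bad = any(issubclass(w.category, ConvergenceWarning) for w in caught)
    if bad or not np.isfinite(clf.coef_).all() or np.abs(clf.coef_).max() > 30:
        regularized = True
        clf = LogisticRegression(C=1.0, solver="lbfgs", max_iter=5000)
        clf.fit(x, y)
    return clf, regularized


def _delta_method_intervals(
    x: np.ndarray, y: np.ndarray, clf, classes: list[str]
) -> dict[str, tuple[float, float]]:
    """95% CIs for the class probabilities at x=0 from the inverse observed
    information of the minimal (reference-class) parameterization."""
    k = len(classes)
    design = np.hstack([np.ones((len(x), 1)), x])
    d = design.shape[1]
    # coefficients in reference-class form: beta_k = theta_k - theta_0
    inter = clf.intercept_
    coef = clf.coef_
    if k == 2 and coef.shape[0] == 1:
        theta = np.vstack([np.zeros(d), np.concatenate([inter, coef[0]])])
    else:
        theta = np.hstack([inter[:, None], coef])
    beta = theta[1:] - theta[0]  # (k-1, d)
    eta = design @ np.vstack([np.zeros(d), beta]).T
    eta -= eta.max(axis=1, keepdims=True)
    p = np.exp(eta)
    p /= p.sum(axis=1, keepdims=True)  # (n, k) in `classes` order

    # observed information for beta (k-1 blocks of size d)
    kk = k - 1
    h = np.zeros((kk * d, kk * d))
    for a in range(kk):
        for b in range(kk):
            w = p[:, a + 1] * ((1.0 if a == b else 0.0) - p[:, b + 1])
            h[a * d:(a + 1) * d, b * d:(b + 1) * d] = design.T @ (w[:, None] * design)
    cov = np.linalg.pinv(h)

    # probabilities and gradients at the observed point x = 0
    x0 = np.zeros(d)
    x0[0] = 1.0
    eta0 = np.concatenate([[0.0], beta @ x0])
    eta0 -= eta0.max()
    p0 = np.exp(eta0)
    p0 /= p0.sum()
    intervals = {}
    for j, cls in enumerate(classes):
        g = np.zeros(kk * d)
        for l in range(kk):
            g[l * d:(l + 1) * d] = x0 * p0[j] * ((1.0 if j == l + 1 else 0.0) - p0[l + 1])
        var = float(g @ cov @ g)
        sd = math.sqrt(max(var, 0.0))
        lo = min(max(0.0, p0[j] - Z95 * sd), p0[j])
        hi = max(min(1.0, p0[j] + Z95 * sd), p0[j])
        intervals[cls] = (lo, hi)
    return intervals


def estimate_posteriors(
    rejection: RejectionResult,
    scenario_set: list[str],
    method: str = "logistic",
    compute_intervals: bool = True,
) -> ScenarioPosterior:
    """Scenario posterior probabilities from the retained PODs.

    ``direct``: retained-set proportions with normal-approximation binomial
    CIs. ``logistic``: multinomial logistic regression of scenario identity
    on (standardized stats - observed), evaluated at the observed point; CIs
    by the delta method on the fitted coefficients. Scenarios absent from
    the retained set receive probability 0.
    """
    y = rejection.scenario_ids
    n = len(y)
    present = [s for s in scenario_set if (y == s).any()]
    diagnostics: dict = {"n_retained": n, "present": present}

    if method == "direct" or len(present) == 1:
        probs = {s: float((y == s).mean()) for s in scenario_set}
        intervals = {}
        for s in scenario_set:
            p = probs[s]
            sd = math.sqrt(p * (1 - p) / n) if n else 0.0
            intervals[s] = (max(0.0, p - Z95 * sd), min(1.0, p + Z95 * sd))
        tag = "direct"
        if method != "direct":
            diagnostics["note"] = "single scenario retained; direct fallback"
    elif method == "logistic":
        x = rejection.retained_std - rejection.observed_std
        clf, regularized = _fit_multinomial(x, y, present)
        diagnostics["regularized"] = regularized
        classes = list(clf.classes_)
        p0 = clf.predict_proba(np.zeros((1, x.shape[1])))[0]
        probs = {s: 0.0 for s in scenario_set}
        for cls, p in zip(classes, p0):
            probs[cls] = float(p)
        if compute_intervals:
            ivs = _delta_method_intervals(x, y, clf, classes)
        else:
            ivs = {c: (probs[c], probs[c]) for c in classes}
        intervals = {s: ivs.get(s, (0.0, 0.0)) for s in scenario_set}
        tag = "logistic"
    else:
        raise ValueError(f"unknown method {method!r}")

    total = sum(probs.values())
    probs = {s: p / total for s, p in probs.items()}
    selected = max(probs, key=probs.get)
    return ScenarioPosterior(
        probabilities=probs, intervals=intervals, selected=selected,
        method=tag, diagnostics=diagnostics,
    )


# ---------------------------------------------------------------------------
# prior / scenario pre-evaluation
# ---------------------------------------------------------------------------

def prior_scenario_check(
    table: ReferenceTable, observed: pd.Series, n_pca: int = 2
) -> dict:
    """PCA + per-statistic tail check of the observed data against the PODs.

    The observed vector is projected into the PCA space of the standardized
    POD statistics; it should fall inside the empirical [0.5%, 99.5%] box of
    each retained component. Each statistic also gets a tail probability
    q = fraction of PODs below the observed value, starred at the two-sided
    5% (*), 1% (**) and 0.1% (***) levels.
    """
    x, obs, cols = standardize(table, observed)
    n_pca = min(n_pca, x.shape[1])
    pca = PCA(n_components=n_pca)
    coords = pca.fit_transform(x)
    obs_coords = pca.transform(obs[None, :])[0]
    lo = np.quantile(coords, 0.005, axis=0)
    hi = np.quantile(coords, 0.995, axis=0)
    within = (obs_coords >= lo) & (obs_coords <= hi)

    q = {}
    stars = {}
    for j, c in enumerate(cols):
        qq = float((x[:, j] < obs[j]).mean())
        q[c] = qq
        two_sided = 2.0 * min(qq, 1.0 - qq)
        stars[c] = ("***" if two_sided < 0.001 else
                    "**" if two_sided < 0.01 else
                    "*" if two_sided < 0.05 else "")
    tails = pd.DataFrame({"q": pd.Series(q), "stars": pd.Series(stars)})
    return {
        "pca_within_box": bool(within.all()),
        "pca_within_by_component": within.tolist(),
        "observed_coords": obs_coords.tolist(),
        "explained_variance_ratio": pca.explained_variance_ratio_.tolist(),
        "tails": tails,
        "n_three_star": int((tails["stars"] == "***").sum()),
    }


# ---------------------------------------------------------------------------
# posterior-based confidence
# ---------------------------------------------------------------------------

def classify_dataset(
    table: ReferenceTable,
    observed: pd.Series,
    tolerance_fraction: float,
    method: str = "logistic",
) -> ScenarioPosterior:
    """Rejection + posterior estimation for one observed vector (point
    estimates only; no interval computation)."""
    rej = rejection_select(table, observed, tolerance_fraction)
    return estimate_posteriors(
        rej, table.scenario_set, method=method, compute_intervals=False
    )


def scenario_confidence(
    scenario: Scenario,
    table: ReferenceTable,
    rejection: RejectionResult,
    selected: str,
    sample_config: dict[str, int],
    stat_config: StatConfig,
    tolerance_fraction: float,
    n_pods: int = 500,
    seed: int = 0,
    length: int = 685,
    p_invariant: float = 0.10,
    gamma_shape: float = 2.0,
    base_frequencies: np.ndarray | None = None,
    method: str = "logistic",
) -> float:
    """Posterior-based confidence in the scenario choice.

    Datasets are re-simulated from the selected scenario using parameter
    draws resampled (with replacement) from its retained rows, then pushed
    through the same rejection + posterior classification against the same
    reference table. Confidence is the fraction assigned back to the
    selected scenario.
    """
    if n_pods < 1:
        raise ValueError("n_pods must be >= 1")
    if scenario.id != selected:
        raise ValueError("scenario object must be the selected scenario")
    mask = rejection.scenario_ids == selected
    retained_rows = rejection.indices[mask]
    if retained_rows.size == 0:
        raise ValueError(f"no retained draws for scenario {selected!r}")
    posterior_draws = table.params.iloc[retained_rows]
    needed = scenario.parameter_names() + ["mu", "kappa"]

    hits = 0
    for i in range(n_pods):
        rng = _row_rng(seed, i)
        row = posterior_draws.iloc[int(rng.integers(len(posterior_draws)))]
        draw = {k: float(row[k]) for k in needed}
        genealogy = simulate_genealogy(scenario, draw, sample_config, rng)
        model = MutationModel(
            rate=draw["mu"], kappa=draw["kappa"],
            base_frequencies=(base_frequencies if base_frequencies is not None
                              else np.full(4, 0.25)),
            p_invariant=p_invariant, gamma_shape=gamma_shape,
        )
        alignment = mutate_alignment(genealogy, model, length, rng)
        stats = compute_summary_vector(alignment, stat_config)
        pod_posterior = classify_dataset(table, stats, tolerance_fraction, method)
        if pod_posterior.selected == selected:
            hits += 1
    return hits / n_pods
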