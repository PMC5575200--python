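"""The ABC engine: reference tables, rejection, posterior estimation,
pre-evaluation, and posterior-based confidence."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats as sps

import invroute.abc as abc
from invroute.abc import (
    DEFAULT_N_ROWS,
    RejectionResult,
    build_reference_table,
    classify_dataset,
    estimate_posteriors,
    prior_scenario_check,
    rejection_select,
    scenario_confidence,
)
from invroute.sumstats import StatConfig, compute_summary_vector

from conftest import source_choice_pair, tight_mutation_priors


SAMPLES = {"native1": 8, "native2": 8, "introduced": 8}


@pytest.fixture(scope="module")
def small_table():
    scenarios, priors = source_choice_pair()
    cfg = StatConfig.all_pairs(list(SAMPLES))
    return build_reference_table(
        scenarios, priors, SAMPLES, n_rows=600, seed=42, stat_config=cfg,
        length=150, mutation_priors=tight_mutation_priors(),
    )


@pytest.fixture(scope="module")
def observed_vector(small_table):
    # an observed vector that is itself a typical POD
    return small_table.stats.iloc[7].copy()


class TestReferenceTable:
    def test_equal_scenario_weighting(self, small_table):
        counts = pd.Series(small_table.scenario_ids).value_counts()
        chi2, p = sps.chisquare(counts.values)
        assert p > 0.001

    def test_identical_on_rerun_and_worker_independent(self):
        scenarios, priors = source_choice_pair()
        cfg = StatConfig.all_pairs(list(SAMPLES))
        kwargs = dict(n_rows=60, seed=9, stat_config=cfg, length=100,
                      mutation_priors=tight_mutation_priors())
        t1 = build_reference_table(scenarios, priors, SAMPLES, **kwargs)
        t2 = build_reference_table(scenarios, priors, SAMPLES, **kwargs)
        t3 = build_reference_table(scenarios, priors, SAMPLES, n_jobs=2, **kwargs)
        for other in (t2, t3):
            assert (t1.scenario_ids == other.scenario_ids).all()
            pd.testing.assert_frame_equal(t1.stats, other.stats)
            pd.testing.assert_frame_equal(t1.params, other.params)

    def test_default_row_count_is_one_million(self):
        assert DEFAULT_N_ROWS == 1_000_000

    def test_too_few_scenarios_rejected(self):
        scenarios, priors = source_choice_pair()
        with pytest.raises(ValueError):
            build_reference_table(scenarios[:1], priors, SAMPLES, n_rows=5)


class TestRejection:
    def test_tolerance_one_retains_everything(self, small_table, observed_vector):
        r = rejection_select(small_table, observed_vector, 1.0)
        assert len(r) == len(small_table)

    def test_observed_equal_to_a_row_has_distance_zero(self, small_table,
                                                       observed_vector):
        r = rejection_select(small_table, observed_vector, 0.05)
        assert r.indices[0] == 7
        assert r.distances[0] == pytest.approx(0.0, abs=1e-12)

    def test_matches_bruteforce_sort(self, small_table, observed_vector):
        tol = 0.1
        r = rejection_select(small_table, observed_vector, tol)
        # independent full sort: standardize by hand, sort all distances
        mean = small_table.stats.mean()
        sd = small_table.stats.std(ddof=0)
        keep = sd > 0
        x = small_table.stats.loc[:, keep].fillna(mean[keep])
        x = (x - mean[keep]) / sd[keep]
        obs = observed_vector[keep.index[keep]].fillna(mean[keep])
        obs = (obs - mean[keep]) / sd[keep]
        d = np.sqrt(((x - obs) ** 2).sum(axis=1).to_numpy())
        order = np.argsort(d, kind="stable")[: len(r)]
        assert list(order) == list(r.indices)

    def test_invalid_tolerance(self, small_table, observed_vector):
        with pytest.raises(ValueError):
            rejection_select(small_table, observed_vector, 0.0)


def multinomial_mle_oracle(x, y, classes):
    """Independent multinomial-likelihood maximization via scipy.optimize,
    returning class probabilities at x=0."""
    n, d = x.shape
    design = np.hstack([np.ones((n, 1)), x])
    k = len(classes)
    y_idx = np.array([classes.index(c) for c in y])

    def nll(theta):
        beta = theta.reshape(k - 1, d + 1)
        eta = np.hstack([np.zeros((n, 1)), design @ beta.T])
        eta -= eta.max(axis=1, keepdims=True)
        logp = eta - np.log(np.exp(eta).sum(axis=1, keepdims=True))
        return -logp[np.arange(n), y_idx].sum()

    res = optimize.minimize(nll, np.zeros((k - 1) * (d + 1)), method="BFGS",
                            options={"gtol": 1e-10, "maxiter": 5000})
    beta = res.x.reshape(k - 1, d + 1)
    eta0 = np.concatenate([[0.0], beta[:, 0]])
    p = np.exp(eta0 - eta0.max())
    return p / p.sum()


class TestPosteriors:
    def test_single_scenario_retained_gets_probability_one(self):
        r = RejectionResult(
            indices=np.arange(10), distances=np.zeros(10),
            retained_std=np.zeros((10, 2)), observed_std=np.zeros(2),
            kept_columns=["a", "b"], scenario_ids=np.array(["s1"] * 10),
        )
        post = estimate_posteriors(r, ["s1", "s2"], method="direct")
        assert post.probabilities == {"s1": 1.0, "s2": 0.0}
        assert post.selected == "s1"

    def test_symmetry_of_identical_scenarios(self):
        # duplicated scenario ids on exchangeable rows: probabilities ~ 0.5
        scenarios, priors = source_choice_pair()
        dup = [scenarios[0],
               type(scenarios[0])("copy", scenarios[0].populations,
                                  scenarios[0].events, scenarios[0].conditions)]
        cfg = StatConfig.all_pairs(list(SAMPLES))
        table = build_reference_table(
            dup, priors, SAMPLES, n_rows=800, seed=3, stat_config=cfg,
            length=150, mutation_priors=tight_mutation_priors(),
        )
        obs = table.stats.mean()
        r = rejection_select(table, obs, 0.25)
        for method in ("direct", "logistic"):
            post = estimate_posteriors(r, table.scenario_set, method=method)
            assert post.probabilities["from_native1"] == pytest.approx(0.5, abs=0.15)
            lo, hi = post.intervals["from_native1"]
            assert lo <= 0.65 and hi >= 0.35

    def test_logistic_matches_independent_mle(self, rng):
        # synthetic retained set with mild class structure, no separation
        n, d = 120, 3
        x = rng.normal(size=(n, d))
        logits = np.stack([0.3 * x[:, 0], -0.2 * x[:, 1], 0.1 * x[:, 2]], axis=1)
        p = np.exp(logits) / np.exp(logits).sum(1, keepdims=True)
        classes = ["a", "b", "c"]
        y = np.array([classes[rng.choice(3, p=pi)] for pi in p])
        r = RejectionResult(
            indices=np.arange(n), distances=np.zeros(n), retained_std=x,
            observed_std=np.zeros(d), kept_columns=list("xyz"), scenario_ids=y,
        )
        post = estimate_posteriors(r, classes, method="logistic")
        oracle = multinomial_mle_oracle(x, y, classes)
        for cls, p_hat in zip(classes, oracle):
            assert post.probabilities[cls] == pytest.approx(p_hat, abs=1e-4)

    def test_probabilities_sum_to_one_and_cis_contain_points(
        self, small_table, observed_vector
    ):
        r = rejection_select(small_table, observed_vector, 0.2)
        for method in ("direct", "logistic"):
            post = estimate_posteriors(r, small_table.scenario_set, method=method)
            assert sum(post.probabilities.values()) == pytest.approx(1.0, abs=1e-9)
            for s, p in post.probabilities.items():
                lo, hi = post.intervals[s]
                assert 0.0 <= lo <= p <= hi <= 1.0


class TestPreEvaluation:
    def test_mean_observed_is_inside_cloud(self, small_table):
        obs = small_table.stats.mean()
        res = prior_scenario_check(small_table, obs)
        assert res["pca_within_box"]
        assert (res["tails"]["stars"] == "").all()

    def test_extreme_observed_is_three_starred(self, small_table):
        obs = small_table.stats.mean()
        col = "introduced:mean_pairwise"
        obs[col] = small_table.stats[col].max() * 10 + 100
        res = prior_scenario_check(small_table, obs)
        assert res["tails"].loc[col, "stars"] == "***"
        assert res["n_three_star"] >= 1

    def test_tail_probabilities_are_probabilities(self, small_table,
                                                  observed_vector):
        res = prior_scenario_check(small_table, observed_vector)
        q = res["tails"]["q"]
        assert ((q >= 0) & (q <= 1)).all()


class TestConfidence:
    def test_confidence_high_for_separable_scenarios(self):
        scenarios, priors = source_choice_pair()
        cfg = StatConfig.all_pairs(list(SAMPLES))
        mp = tight_mutation_priors()
        table = build_reference_table(
            scenarios, priors, SAMPLES, n_rows=3000, seed=11, stat_config=cfg,
            length=250, mutation_priors=mp,
        )
        # an observed dataset truly from scenario "from_native1"
        from invroute.coalescent import simulate_dataset

        rng = np.random.default_rng(77)
        _, aln = simulate_dataset(scenarios[0], priors, SAMPLES, rng,
                                  length=250, mutation_priors=mp)
        obs = compute_summary_vector(aln, cfg)
        rej = rejection_select(table, obs, 0.05)
        post = estimate_posteriors(rej, table.scenario_set)
        assert post.selected == "from_native1"
        conf = scenario_confidence(
            scenarios[0], table, rej, "from_native1", SAMPLES, cfg,
            tolerance_fraction=0.05, n_pods=60, seed=5, length=250,
        )
        assert 0.0 <= conf <= 1.0
        assert conf > 0.9

    def test_confidence_near_half_for_identical_scenarios(self):
        scenarios, priors = source_choice_pair()
        twin = type(scenarios[0])("twin", scenarios[0].populations,
                                  scenarios[0].events, scenarios[0].conditions)
        pair = [scenarios[0], twin]
        cfg = StatConfig.all_pairs(list(SAMPLES))
        mp = tight_mutation_priors()
        table = build_reference_table(
            pair, priors, SAMPLES, n_rows=1500, seed=21, stat_config=cfg,
            length=150, mutation_priors=mp,
        )
        obs = table.stats.iloc[3]
        rej = rejection_select(table, obs, 0.1)
        post = estimate_posteriors(rej, table.scenario_set)
        sel = post.selected
        sel_scenario = pair[0] if sel == pair[0].id else pair[1]
        conf = scenario_confidence(
            sel_scenario, table, rej, sel, SAMPLES, cfg,
            tolerance_fraction=0.1, n_pods=80, seed=6, length=150,
        )
        assert conf == pytest.approx(0.5, abs=0.2)


class TestClassify:
    def test_classify_matches_manual_pipeline(self, small_table, observed_vector):
        post = classify_dataset(small_table, observed_vector, 0.1)
        rej = rejection_select(small_table, observed_vector, 0.1)
        manual = estimate_posteriors(rej, small_table.scenario_set,
                                     compute_intervals=False)
        assert post.probabilities == manual.probabilities
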