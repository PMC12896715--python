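"""Survival engine: hand-worked oracles, lifelines cross-checks, the
brute-force cutpoint oracle, permutation adjustment, coherence rules."""

import numpy as np
import pandas as pd
import pytest
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as lifelines_logrank

import emtsig as es
from emtsig.errors import ParameterError, SampleSizeError, ScanEmptyError

from conftest import make_survival_cohort


def brute_force_best_cutoff(time, event, expr, min_group_size):
    """Exhaustive dichotomization oracle, independent of the scan engine.

    Enumerates every distinct expression value within [Q1, Q3], splits
    low (<= cutoff) / high (> cutoff), scores each split with the
    lifelines log-rank test, and keeps the smallest p (ties -> smaller
    cutoff).
    """
    time, event, expr = map(np.asarray, (time, event, expr))
    q1, q3 = np.quantile(expr, [0.25, 0.75])
    best = None
    n_eval = 0
    for c in np.unique(expr):
        if not q1 <= c <= q3:
            continue
        low = expr <= c
        if low.sum() < min_group_size or (~low).sum() < min_group_size:
            continue
        n_eval += 1
        res = lifelines_logrank(time[low], time[~low], event[low], event[~low])
        p = res.p_value if np.isfinite(res.p_value) else 1.0
        if best is None or p < best[1] - 1e-12:
            best = (c, p)
    return best, n_eval


class TestKaplanMeier:
    def test_all_events_hand_values(self):
        km = es.km_estimate([1, 2, 3], [1, 1, 1])
        np.testing.assert_allclose(km.survival, [2 / 3, 1 / 3, 0.0])
        np.testing.assert_array_equal(km.at_risk, [3, 2, 1])

    def test_censoring_shrinks_risk_set_without_step(self):
        km = es.km_estimate([1, 2, 3], [1, 0, 1])
        np.testing.assert_allclose(km.event_times, [1, 3])
        np.testing.assert_allclose(km.survival, [2 / 3, 0.0])

    def test_all_censored_flat_at_one(self):
        km = es.km_estimate([5, 6, 7], [0, 0, 0])
        assert km.event_times.size == 0

    def test_invariant_to_record_order(self):
        rng = np.random.default_rng(1)
        t = rng.exponential(5, 40)
        e = (rng.random(40) < 0.6).astype(int)
        perm = rng.permutation(40)
        a, b = es.km_estimate(t, e), es.km_estimate(t[perm], e[perm])
        np.testing.assert_allclose(a.survival, b.survival)

    def test_matches_lifelines_on_random_cohort(self):
        rng = np.random.default_rng(2)
        t = np.ceil(rng.exponential(5, 80))  # ties on purpose
        e = (rng.random(80) < 0.7).astype(int)
        km = es.km_estimate(t, e)
        kmf = KaplanMeierFitter().fit(t, e)
        theirs = kmf.survival_function_at_times(km.event_times).to_numpy()
        np.testing.assert_allclose(km.survival, theirs, atol=1e-10)

    def test_empty_input_rejected(self):
        with pytest.raises(SampleSizeError):
            es.km_estimate([], [])


class TestLogrank:
    def test_identical_groups_give_zero_statistic(self):
        t, e = [1, 2, 3, 4], [1, 1, 0, 1]
        res = es.logrank_test(t, e, t, e)
        assert res.chi_square == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_hand_worked_toy_tables(self):
        # A: events at 1, 2; B: events at 3, 4. Hand 2x2 tables give
        # O_A = 2, E_A = 1/2 + 1/3 = 5/6, V = 1/4 + 2/9 = 17/36,
        # chi2 = (7/6)^2 / (17/36) = 49/17.
        res = es.logrank_test([1, 2], [1, 1], [3, 4], [1, 1])
        assert res.chi_square == pytest.approx(49 / 17, abs=1e-10)

    def test_symmetric_in_group_labels(self):
        rng = np.random.default_rng(3)
        tA, tB = rng.exponential(4, 30), rng.exponential(8, 25)
        eA, eB = np.ones(30, int), (rng.random(25) < 0.5).astype(int)
        r1 = es.logrank_test(tA, eA, tB, eB)
        r2 = es.logrank_test(tB, eB, tA, eA)
        assert r1.chi_square == pytest.approx(r2.chi_square)
        assert r1.p_value == pytest.approx(r2.p_value)

    def test_matches_lifelines_on_random_cohorts(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            nA, nB = rng.integers(10, 40, 2)
            tA = np.ceil(rng.exponential(5, nA))
            tB = np.ceil(rng.exponential(3, nB))
            eA = (rng.random(nA) < 0.7).astype(int)
            eB = (rng.random(nB) < 0.7).astype(int)
            if eA.sum() + eB.sum() == 0:
                continue
            mine = es.logrank_test(tA, eA, tB, eB)
            theirs = lifelines_logrank(tA, tB, eA, eB)
            assert mine.chi_square == pytest.approx(theirs.test_statistic, abs=1e-8)

    def test_zero_variance_flagged_degenerate(self):
        # single pooled event at the very first time in a 1-patient riskset
        res = es.logrank_test([5], [1], [1, 2], [0, 0])
        assert res.degenerate and res.p_value == 1.0

    def test_empty_group_rejected(self):
        with pytest.raises(SampleSizeError):
            es.logrank_test([], [], [1], [1])


class TestHazardRatio:
    def test_identical_groups_give_unit_hr(self):
        t, e = [1, 2, 3, 4, 5], [1, 1, 1, 0, 1]
        res = es.hazard_ratio_oe(t, e, t, e)
        assert res.hr == pytest.approx(1.0)
        assert res.ci_low < 1.0 < res.ci_high

    def test_no_events_in_one_group_is_boundary(self):
        res = es.hazard_ratio_oe([5, 6, 7], [0, 0, 0], [1, 2, 3], [1, 1, 1])
        assert res.boundary and res.hr == 0.0

    def test_recovers_true_hazard_ratio_two(self):
        # binary expression at +/-1 SD with beta = ln(2)/2 makes the true
        # between-group hazard ratio exactly 2
        hits = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            expr = pd.DataFrame({"g": rng.integers(0, 2, 500).astype(float)})
            params = es.SurvivalSimParams(
                n_patients=500, log_hr_per_sd={"g": np.log(2) / 2},
                censor_rate=0.3, max_follow_up=40.0, rng_seed=seed + 1,
            )
            cohort = es.simulate_survival_cohort(params, expr)
            high = cohort.expression["g"].to_numpy() == 1
            res = es.hazard_ratio_oe(
                cohort.time[high], cohort.event[high],
                cohort.time[~high], cohort.event[~high],
            )
            hits += 1.6 <= res.hr <= 2.5
        assert hits >= 45  # >= 90% of seeds


class TestBestCutoffScan:
    def test_toy_cohort_matches_brute_force(self, small_config):
        rng = np.random.default_rng(5)
        t = np.ceil(rng.exponential(5, 8))
        e = np.ones(8, int)
        expr = rng.normal(size=8)
        cohort = es.SurvivalCohort("OS", t, e, pd.DataFrame({"g": expr}))
        res = es.best_cutoff_scan("g", cohort, small_config, adjust=False)
        (oracle_cut, oracle_p), n_eval = brute_force_best_cutoff(
            t, e, expr, small_config.min_group_size
        )
        assert res.best_cutoff == pytest.approx(oracle_cut)
        assert res.logrank_p_min == pytest.approx(oracle_p, abs=1e-9)
        assert res.candidates_evaluated == n_eval

    def test_random_small_cohorts_match_brute_force(self, small_config):
        rng = np.random.default_rng(6)
        checked = 0
        for _ in range(30):
            n = int(rng.integers(6, 13))
            t = np.ceil(rng.exponential(5, n))
            e = (rng.random(n) < 0.8).astype(int)
            if e.sum() == 0:
                continue
            expr = np.round(rng.normal(size=n), 1)  # ties on purpose
            cohort = es.SurvivalCohort("OS", t, e, pd.DataFrame({"g": expr}))
            oracle, n_eval = brute_force_best_cutoff(
                t, e, expr, small_config.min_group_size
            )
            if oracle is None:
                with pytest.raises(ScanEmptyError):
                    es.best_cutoff_scan("g", cohort, small_config, adjust=False)
                continue
            res = es.best_cutoff_scan("g", cohort, small_config, adjust=False)
            assert res.best_cutoff == pytest.approx(oracle[0])
            assert res.logrank_p_min == pytest.approx(oracle[1], abs=1e-9)
            checked += 1
        assert checked >= 20

    def test_constant_expression_is_scan_empty(self, small_config):
        cohort = es.SurvivalCohort(
            "OS", np.arange(1.0, 21.0), np.ones(20, int),
            pd.DataFrame({"g": np.ones(20)}),
        )
        with pytest.raises(ScanEmptyError):
            es.best_cutoff_scan("g", cohort, small_config, adjust=False)

    def test_minimum_beats_median_split_under_monotone_hazard(self):
        cohort = make_survival_cohort(n=400, beta=0.8, seed=7)
        res = es.best_cutoff_scan("g", cohort, adjust=False)
        expr = cohort.expression["g"].to_numpy()
        high = expr > np.median(expr)
        median_p = es.logrank_test(
            cohort.time[high], cohort.event[high],
            cohort.time[~high], cohort.event[~high],
        ).p_value
        assert res.logrank_p_min <= median_p
        q1, q3 = np.quantile(expr, [0.25, 0.75])
        assert q1 <= res.best_cutoff <= q3

    def test_unknown_gene_is_key_error(self):
        cohort = make_survival_cohort(n=30, seed=8)
        with pytest.raises(KeyError):
            es.best_cutoff_scan("nope", cohort, adjust=False)


class TestMinPAdjustment:
    def test_adjusted_never_below_permutation_floor(self):
        cohort = make_survival_cohort(n=60, beta=1.5, seed=9)
        cfg = es.AnalysisConfig(n_permutations=999, rng_seed=9)
        res = es.best_cutoff_scan("g", cohort, cfg)
        # strong planted effect: observed min-p beats every permutation
        assert res.adjusted_p == pytest.approx(1 / 1000)

    def test_adjusted_at_least_nominal_minimum(self):
        for seed in range(5):
            cohort = make_survival_cohort(n=60, beta=0.0, seed=20 + seed)
            cfg = es.AnalysisConfig(n_permutations=199, rng_seed=seed)
            res = es.best_cutoff_scan("g", cohort, cfg)
            assert res.adjusted_p >= res.logrank_p_min

    def test_too_few_permutations_rejected(self):
        with pytest.raises(ParameterError):
            es.AnalysisConfig(n_permutations=50)

    def test_adjust_min_p_matches_scan(self):
        cohort = make_survival_cohort(n=60, beta=1.0, seed=10)
        cfg = es.AnalysisConfig(n_permutations=199, rng_seed=10)
        rng1 = np.random.default_rng(42)
        rng2 = np.random.default_rng(42)
        direct = es.adjust_min_p("g", cohort, cfg, rng=rng1)
        via_scan = es.best_cutoff_scan("g", cohort, cfg, rng=rng2).adjusted_p
        assert direct == via_scan


class TestClassifyPrognosis:
    def _cohorts(self, betas, n=200, seed=0):
        return {
            ep: make_survival_cohort(n=n, beta=b, seed=seed + i, endpoint=ep)
            for i, (ep, b) in enumerate(zip(es.ENDPOINTS, betas))
        }

    def test_hazardous_gene_called_coherent_worse(self):
        cfg = es.AnalysisConfig(n_permutations=199, rng_seed=1)
        call = es.classify_prognosis("g", self._cohorts([1.2, 1.2, 1.2], seed=30), cfg)
        assert call.coherent and call.direction == "worse"
        assert all(hr > 1 for _, hr in call.per_endpoint.values())

    def test_protective_gene_called_coherent_better(self):
        cfg = es.AnalysisConfig(n_permutations=199, rng_seed=2)
        call = es.classify_prognosis("g", self._cohorts([-1.2, -1.2, -1.2], seed=40), cfg)
        assert call.coherent and call.direction == "better"

    def test_direction_conflict_voids_the_call(self):
        cfg = es.AnalysisConfig(n_permutations=199, rng_seed=3)
        call = es.classify_prognosis("g", self._cohorts([1.2, 1.2, -1.2], seed=50), cfg)
        assert not call.coherent and call.direction == "none"

    def test_one_null_endpoint_voids_the_call(self):
        cfg = es.AnalysisConfig(n_permutations=199, rng_seed=4)
        call = es.classify_prognosis("g", self._cohorts([1.2, 1.2, 0.0], seed=60), cfg)
        assert not call.coherent and call.direction == "none"

    def test_missing_endpoint_rejected(self):
        cohorts = self._cohorts([1.0, 1.0, 1.0], seed=70)
        del cohorts["OS"]
        with pytest.raises(ParameterError):
            es.classify_prognosis("g", cohorts)
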