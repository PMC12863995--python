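import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from clonecomp.stats import (
    ContingencyTable,
    CoxFit,
    SurvivalSample,
    _enumerate_tables,
    _table_logp,
    compare_groups,
    cox_fit,
    fisher_exact,
    km_estimate,
    kruskal_wallis,
    logrank,
    mann_whitney,
    min_detectable_hr,
    pearson_r,
    summarize_counts,
)


from oracles import fisher_2x2_oracle as _fisher_2x2_oracle


class TestFisher:
    @pytest.mark.parametrize(
        "table,printed",
        [
            ([[1, 14], [2, 57]], 0.499),   # EBV status
            ([[14, 1], [49, 10]], 0.443),  # performance status
            ([[9, 6], [31, 28]], 0.773),   # extranodal sites
            ([[4, 11], [16, 43]], 1.00),   # stage III vs IV
        ],
    )
    def test_two_by_two_matches_printed_values(self, table, printed):
        assert round(fisher_exact(table), 3) == pytest.approx(printed, abs=5e-4)

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            t = rng.integers(0, 11, size=(2, 2))
            if (t.sum(0) == 0).any() or (t.sum(1) == 0).any():
                continue
            assert fisher_exact(t) == pytest.approx(_fisher_2x2_oracle(t), abs=1e-10)

    def test_freeman_halton_3x2_matches_printed_value(self):
        # first-line therapy: R-CHOP / R-THPCOP / R-CVP by Mono/Poly
        assert round(fisher_exact([[11, 41], [3, 18], [1, 0]]), 3) == 0.192

    def test_label_permutation_invariance(self):
        t = np.array([[11, 41], [3, 18], [1, 0]])
        p = fisher_exact(t)
        assert fisher_exact(t[::-1]) == pytest.approx(p, rel=1e-9)
        assert fisher_exact(t[:, ::-1]) == pytest.approx(p, rel=1e-9)

    def test_enumeration_support_probabilities_sum_to_one(self):
        t = np.array([[11, 41], [3, 18], [1, 0]])
        total = sum(
            math.exp(_table_logp(x))
            for x in _enumerate_tables(list(t.sum(1)), list(t.sum(0)))
        )
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_empty_margin_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact([[0, 0], [1, 2]])


class TestSummaries:
    def test_cc_histograms_match_printed_means(self):
        overall = summarize_counts({0: 15, 1: 46, 2: 11, 3: 1, 4: 1})
        assert round(overall.mean, 2) == 1.01
        assert overall.median == 1 and (overall.min, overall.max) == (0, 4)
        poly = summarize_counts({1: 46, 2: 11, 3: 1, 4: 1})
        assert round(poly.mean, 2) == 1.27
        abc_poly = summarize_counts({1: 21, 2: 7, 4: 1})
        assert round(abc_poly.mean, 2) == 1.34

    def test_degenerate_distribution(self):
        s = summarize_counts({5: 3})
        assert (s.mean, s.sd_sample, s.sd_population) == (5.0, 0.0, 0.0)

    def test_both_sd_conventions_reported(self):
        s = summarize_counts({0: 15, 1: 46, 2: 11, 3: 1, 4: 1})
        assert s.sd_sample == pytest.approx(0.7308, abs=1e-4)
        assert s.sd_population == pytest.approx(0.7258, abs=1e-4)


class TestRankTests:
    def test_identical_groups_near_null(self):
        x = [1, 2, 3, 4, 5, 6]
        assert mann_whitney(x, x) == pytest.approx(1.0)

    def test_exact_small_sample_matches_enumeration(self):
        x = [1.2, 3.4, 0.8, 5.1, 2.2, 9.0]
        y = [4.4, 6.1, 7.2, 8.0, 3.9, 5.5]
        # independent oracle: scipy's exact distribution (tie-free data)
        expected = sps.mannwhitneyu(x, y, method="exact", alternative="two-sided").pvalue
        assert mann_whitney(x, y) == pytest.approx(expected, abs=1e-12)

    def test_large_sample_with_ties_matches_scipy_asymptotic(self):
        rng = np.random.default_rng(3)
        x = rng.integers(0, 6, size=40).astype(float)
        y = rng.integers(1, 7, size=35).astype(float)
        expected = sps.mannwhitneyu(
            x, y, method="asymptotic", use_continuity=True, alternative="two-sided"
        ).pvalue
        assert mann_whitney(x, y) == pytest.approx(expected, rel=1e-9)

    def test_kruskal_and_pearson_basics(self):
        assert kruskal_wallis([[1, 2, 3], [1, 2, 3]]) == pytest.approx(1.0, abs=0.05)
        r, _ = pearson_r([1, 2, 3, 4], [1, 2, 3, 4])
        assert r == pytest.approx(1.0)
        with pytest.raises(ValueError):
            pearson_r([1, 1, 1], [1, 2, 3])


# hand-computed product-limit table for 8 subjects
KM_TIMES = [5, 8, 8, 12, 15, 20, 22, 30]
KM_EVENTS = [1, 1, 1, 0, 1, 0, 1, 1]
KM_EXPECTED = {5: 0.875, 8: 0.625, 15: 0.46875, 22: 0.234375, 30: 0.0}


class TestSurvival:
    def test_km_matches_hand_computed_table(self):
        curve = km_estimate(SurvivalSample(KM_TIMES, KM_EVENTS))
        for t, s in KM_EXPECTED.items():
            assert curve.survival_at(t) == pytest.approx(s, abs=1e-12)
        assert curve.survival_at(0) == 1.0

    def test_km_no_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(11)
        times = rng.exponential(100, size=50)
        curve = km_estimate(SurvivalSample(times, np.ones(50)))
        for t in (20, 80, 200):
            assert curve.survival_at(t) == pytest.approx((times > t).mean(), abs=1e-12)

    def test_km_all_events_no_ties_drops_by_one_nth(self):
        times = np.arange(1.0, 11.0)
        curve = km_estimate(SurvivalSample(times, np.ones(10)))
        drops = np.diff(np.concatenate([[1.0], curve.survival]))
        assert np.allclose(drops, -0.1)

    def test_logrank_identical_groups_p_one(self):
        t = np.tile(KM_TIMES, 2)
        e = np.tile(KM_EVENTS, 2)
        g = np.repeat(["a", "b"], len(KM_TIMES))
        assert logrank(SurvivalSample(t, e, g)) == pytest.approx(1.0)

    def test_logrank_label_swap_invariance(self):
        rng = np.random.default_rng(2)
        t = rng.exponential(100, size=60)
        e = rng.integers(0, 2, size=60)
        e[0] = 1
        g = np.repeat(["x", "y"], 30)
        p1 = logrank(SurvivalSample(t, e, g))
        p2 = logrank(SurvivalSample(t, e, np.where(g == "x", "y", "x")))
        assert p1 == pytest.approx(p2, rel=1e-12)

    def test_logrank_empty_group_rejected(self):
        with pytest.raises(ValueError):
            logrank(SurvivalSample([1, 2], [1, 1], ["a", "a"]))


def _cox_newton_oracle(times, events, x, iters=60):
    """Exact Newton iteration on the partial likelihood, binary covariate,
    no tied event times."""
    order = np.argsort(times)
    times, events, x = np.asarray(times)[order], np.asarray(events)[order], np.asarray(x)[order]
    beta = 0.0
    for _ in range(iters):
        u = h = 0.0
        for i in np.nonzero(events)[0]:
            risk = times >= times[i]
            w = np.exp(beta * x[risk])
            xbar = (w * x[risk]).sum() / w.sum()
            x2bar = (w * x[risk] ** 2).sum() / w.sum()
            u += x[i] - xbar
            h += x2bar - xbar**2
        beta += u / h
    return beta


class TestCox:
    def test_six_subject_fixture_matches_newton_oracle(self):
        times = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        events = [1, 1, 1, 1, 1, 1]
        x = [1, 0, 1, 0, 1, 0]
        df = pd.DataFrame({"t": times, "e": events, "x": x})
        fit = cox_fit(df, "t", "e", ["x"])
        assert fit.converged
        assert fit.log_hr[0] == pytest.approx(_cox_newton_oracle(times, events, x), abs=1e-6)

    def test_null_simulation_ci_contains_one(self):
        rng = np.random.default_rng(5)
        n = 600
        df = pd.DataFrame(
            {
                "t": rng.exponential(100, size=n),
                "e": 1,
                "x": rng.integers(0, 2, size=n),
            }
        )
        fit = cox_fit(df, "t", "e", ["x"])
        assert fit.ci_low[0] < 1.0 < fit.ci_high[0]

    def test_ci_must_bracket_estimate(self):
        with pytest.raises(ValueError):
            CoxFit(
                covariates=["x"], log_hr=np.array([0.5]), hr=np.array([1.65]),
                ci_low=np.array([1.7]), ci_high=np.array([2.0]), p=np.array([0.01]),
            )


class TestPower:
    def test_doubling_events_scales_log_hr_by_inv_sqrt2(self):
        h1 = math.log(min_detectable_hr(15, 59, 40))
        h2 = math.log(min_detectable_hr(15, 59, 80))
        assert h2 == pytest.approx(h1 / math.sqrt(2), rel=1e-12)

    def test_monotone_decreasing_in_events(self):
        hrs = [min_detectable_hr(15, 59, d) for d in (10, 30, 100, 1000)]
        assert hrs == sorted(hrs, reverse=True)
        assert hrs[-1] > 1.0  # approaches but never reaches the null

    def test_study_allocation_formula_evaluation(self):
        # Mono n=15 vs Poly n=59 at 80% power, alpha 0.05: ~2.3 needs ~70 events
        assert min_detectable_hr(15, 59, 70) == pytest.approx(2.30, abs=0.01)


class TestCompareGroups:
    def test_table_one_style_report(self):
        rng = np.random.default_rng(1)
        n = 74
        df = pd.DataFrame(
            {
                "patient_id": [f"p{i}" for i in range(n)],
                "efs_days": rng.exponential(1000, n),
                "efs_event": rng.integers(0, 2, n),
                "os_days": rng.exponential(1500, n),
                "os_event": rng.integers(0, 2, n),
                "cc_class": np.where(rng.random(n) < 0.2, "Mono", "Poly"),
                "stage": rng.choice(["III", "IV"], n),
                "ki67": rng.uniform(0.2, 0.95, n),
            }
        )
        from clonecomp.datatypes import CohortTable

        out = compare_groups(CohortTable(df), categorical=["stage"], numeric=["ki67"])
        assert set(out["test"]) == {"fisher", "kruskal"}
        assert ((out["p"] > 0) & (out["p"] <= 1)).all()
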