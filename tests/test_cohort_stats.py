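"""Statistical operations against independent oracles and reference libraries.

Each implemented route is cross-checked against a second, independent route:
closed-form enumeration (Fisher, Mann-Whitney), brute-force likelihood
maximisation (Cox), known estimator identities (KM with no censoring,
log-rank as Cox score test, Spearman as Pearson-on-ranks) and the lifelines
reference implementations.
"""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as ss

from fmfct.cohort_simulator import SimulationConfig, simulate_cohort
from fmfct.cohort_stats import (
    TestResult as StatResult,
)
from fmfct.cohort_stats import (
    chi_square_2x2,
    cox_fit,
    cox_partial_loglik,
    cox_score_test,
    fisher_exact_2x2,
    km_estimate,
    km_mortality_at,
    log_rank_test,
    mann_whitney_u,
    shapiro_wilk,
    spearman,
    t_from_summary,
    t_test_two_sample,
    table_one,
)

# ---------------------------------------------------------------------------
# contingency tables


class TestChiSquare:
    @pytest.mark.parametrize(
        "table,expected",
        [
            ((25, 19, 33, 10), 3.886),  # male/not-male by FMF group
            ((20, 24, 30, 13), 5.259),  # weaned/not by FMF group
            ((27, 17, 26, 17), 0.007),  # pulmonary/extrapulmonary ARDS
        ],
    )
    def test_published_statistics_from_counts(self, table, expected):
        assert chi_square_2x2(*table).statistic == pytest.approx(expected, abs=5e-4)

    def test_no_association(self):
        res = chi_square_2x2(10, 10, 10, 10)
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_transposition_and_swap_invariance(self):
        base = chi_square_2x2(12, 5, 7, 20).statistic
        assert chi_square_2x2(12, 7, 5, 20).statistic == pytest.approx(base)
        assert chi_square_2x2(20, 7, 5, 12).statistic == pytest.approx(base)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            chi_square_2x2(0, 0, 5, 5)


def _fisher_oracle(a, b, c, d):
    """Two-sided Fisher p by full enumeration of tables with fixed margins."""
    r1, c1, n = a + b, a + c, a + b + c + d
    rv = ss.hypergeom(n, c1, r1)
    p_obs = rv.pmf(a)
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    return sum(rv.pmf(x) for x in range(lo, hi + 1) if rv.pmf(x) <= p_obs * (1 + 1e-9))


class TestFisher:
    @pytest.mark.parametrize(
        "table,expected",
        [((1, 9, 11, 3), 0.002759), ((5, 0, 0, 5), 2 / 252), ((2, 2, 2, 2), 1.0)],
    )
    def test_known_values(self, table, expected):
        assert fisher_exact_2x2(*table).p_value == pytest.approx(expected, rel=1e-3)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a, b, c, d = rng.integers(0, 11, size=4)
        assert fisher_exact_2x2(a, b, c, d).p_value == pytest.approx(
            _fisher_oracle(a, b, c, d), rel=1e-9
        )


# ---------------------------------------------------------------------------
# t and Mann-Whitney


class TestTTest:
    def test_published_muscle_area_t_from_printed_summaries(self):
        res = t_from_summary(43.3, 11.3, 44, 44.9, 12.4, 43)
        assert res.statistic == pytest.approx(0.630, abs=0.005)
        assert res.df == 85

    def test_identical_groups(self):
        res = t_test_two_sample([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_summary_path_equals_raw_path(self, rng):
        a = rng.normal(10, 2, 30)
        b = rng.normal(11, 3, 25)
        raw = t_test_two_sample(a, b)
        summ = t_from_summary(a.mean(), a.std(ddof=1), 30, b.mean(), b.std(ddof=1), 25)
        assert raw.statistic == pytest.approx(summ.statistic, rel=1e-12)
        assert raw.p_value == pytest.approx(summ.p_value, rel=1e-12)

    def test_two_sided_p_is_twice_one_sided_tail(self):
        res = t_from_summary(12.0, 2.0, 20, 10.0, 2.5, 18)
        one_sided = float(ss.t.sf(res.statistic, res.df))
        assert res.p_value == pytest.approx(2 * one_sided, rel=1e-12)

    def test_zero_variance_unequal_means_is_an_error(self):
        with pytest.raises(ZeroDivisionError):
            t_from_summary(1.0, 0.0, 5, 2.0, 0.0, 5)


def _mw_brute_force(a, b):
    """Permutation p via pairwise-comparison U on every group assignment."""
    pooled = list(a) + list(b)
    n_a = len(a)

    def u_min(sample_a, sample_b):
        u = sum(
            1.0 if x > y else 0.5 if x == y else 0.0
            for x in sample_a
            for y in sample_b
        )
        return min(u, len(sample_a) * len(sample_b) - u)

    observed = u_min(a, b)
    hits = total = 0
    for idx in itertools.combinations(range(len(pooled)), n_a):
        sa = [pooled[i] for i in idx]
        sb = [pooled[i] for i in range(len(pooled)) if i not in idx]
        if u_min(sa, sb) <= observed + 1e-9:
            hits += 1
        total += 1
    return observed, hits / total


class TestMannWhitney:
    def test_complete_separation(self):
        assert mann_whitney_u([1, 2, 3], [4, 5, 6]).statistic == 0.0

    def test_identical_multisets(self):
        res = mann_whitney_u([1, 2, 3, 4], [1, 2, 3, 4])
        assert res.statistic == 16 / 2
        assert res.p_value == 1.0

    @pytest.mark.parametrize("seed", range(6))
    def test_exact_path_matches_brute_force_permutation(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.integers(0, 6, size=5).astype(float)  # ties likely
        b = rng.integers(0, 6, size=6).astype(float)
        u_oracle, p_oracle = _mw_brute_force(a, b)
        res = mann_whitney_u(a, b)
        assert res.statistic == pytest.approx(u_oracle)
        assert res.p_value == pytest.approx(p_oracle, rel=1e-12)

    def test_asymptotic_close_to_scipy(self, rng):
        a = rng.normal(0, 1, 40)
        b = rng.normal(0.5, 1, 35)
        res = mann_whitney_u(a, b)
        ref = ss.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic",
                              use_continuity=False)
        assert res.p_value == pytest.approx(float(ref.pvalue), rel=1e-9)


class TestShapiro:
    def test_calibration_on_normal_draws(self):
        rng = np.random.default_rng(77)
        passes = sum(
            shapiro_wilk(rng.normal(0, 1, 500)).p_value > 0.05 for _ in range(50)
        )
        assert passes >= 45

    def test_power_on_exponential_draws(self):
        rng = np.random.default_rng(78)
        rejections = sum(
            shapiro_wilk(rng.exponential(1, 500)).p_value < 0.05 for _ in range(50)
        )
        assert rejections >= 45

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            shapiro_wilk([2.0] * 10)


class TestSpearman:
    def test_monotone_transform_gives_one(self):
        x = np.array([1.0, 2.0, 5.0, 9.0, 12.0])
        assert spearman(x, x**3).statistic == pytest.approx(1.0)

    def test_reversed_gives_minus_one(self):
        x = np.arange(10.0)
        assert spearman(x, x[::-1]).statistic == pytest.approx(-1.0)

    def test_equals_pearson_on_ranks(self, rng):
        x = rng.normal(size=60)
        y = rng.normal(size=60) + 0.3 * x
        rho = np.corrcoef(ss.rankdata(x), ss.rankdata(y))[0, 1]
        assert spearman(x, y).statistic == pytest.approx(rho, abs=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


# ---------------------------------------------------------------------------
# survival


class TestKaplanMeier:
    def test_no_censoring_equals_empirical_mortality(self, rng):
        # 32 deaths among 44 subjects, all before day 365
        times = np.concatenate([rng.uniform(1, 360, 32), np.full(12, 365.0)])
        events = np.concatenate([np.ones(32, bool), np.zeros(12, bool)])
        curve = km_estimate(times, events)
        assert km_mortality_at(curve, 365.0) == pytest.approx(100 * 32 / 44)

    def test_no_censoring_equals_empirical_at_every_time(self, rng):
        times = rng.uniform(1, 100, 50)
        events = np.ones(50, bool)
        curve = km_estimate(times, events)
        for t in [5.0, 25.0, 50.0, 99.0]:
            assert curve.survival_at(t) == pytest.approx((times > t).mean())

    def test_all_censored_flat_curve(self):
        curve = km_estimate([10.0, 20.0, 30.0], [False, False, False])
        assert curve.survival_at(25.0) == 1.0
        assert curve.event_times.size == 0

    def test_single_death_step(self):
        curve = km_estimate([10.0], [True])
        assert curve.survival_at(9.99) == 1.0
        assert curve.survival_at(10.0) == 0.0

    def test_monotone_and_bounded(self, rng):
        times = rng.exponential(100, 80)
        events = rng.random(80) < 0.7
        s = km_estimate(times, events).survival_probabilities
        assert np.all(np.diff(s) <= 1e-15)
        assert np.all((s >= 0) & (s <= 1))

    def test_matches_lifelines(self, rng):
        from lifelines import KaplanMeierFitter

        times = rng.exponential(200, 100)
        events = rng.random(100) < 0.6
        if not events.any():
            events[0] = True
        curve = km_estimate(times, events)
        kmf = KaplanMeierFitter().fit(times, events)
        for t in [10.0, 50.0, 150.0]:
            assert curve.survival_at(t) == pytest.approx(
                float(kmf.predict(t)), abs=1e-10
            )


class TestLogRank:
    def test_identical_groups_give_zero(self):
        t = [5.0, 10.0, 15.0, 20.0]
        e = [True, True, False, True]
        res = log_rank_test(t, e, t, e)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_symmetry_in_group_order(self, rng):
        ta, tb = rng.exponential(100, 60), rng.exponential(150, 70)
        ea, eb = np.ones(60, bool), np.ones(70, bool)
        r1 = log_rank_test(ta, ea, tb, eb)
        r2 = log_rank_test(tb, eb, ta, ea)
        assert r1.statistic == pytest.approx(r2.statistic, rel=1e-12)

    def test_detects_threefold_rate_ratio(self):
        rng = np.random.default_rng(101)
        ta = rng.exponential(100, 200)
        tb = rng.exponential(300, 200)
        res = log_rank_test(ta, np.ones(200, bool), tb, np.ones(200, bool))
        assert res.p_value < 0.001

    def test_no_events_rejected(self):
        with pytest.raises(ValueError):
            log_rank_test([5.0], [False], [6.0], [False])

    def test_equals_cox_score_test_on_group_indicator(self, rng):
        ta = rng.exponential(80, 40)
        tb = rng.exponential(160, 45)
        times = np.concatenate([ta, tb])
        events = np.ones(85, bool)
        group = np.concatenate([np.ones(40), np.zeros(45)])
        lr = log_rank_test(ta, np.ones(40, bool), tb, np.ones(45, bool))
        score = cox_score_test(times, events, group)
        assert lr.statistic == pytest.approx(score.statistic, abs=1e-8)

    def test_matches_lifelines(self, rng):
        from lifelines.statistics import logrank_test as ll_logrank

        ta, tb = rng.exponential(100, 50), rng.exponential(200, 55)
        ea = rng.random(50) < 0.8
        eb = rng.random(55) < 0.8
        mine = log_rank_test(ta, ea, tb, eb)
        ref = ll_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
        assert mine.statistic == pytest.approx(float(ref.test_statistic), rel=1e-9)
        assert mine.p_value == pytest.approx(float(ref.p_value), rel=1e-9)


# ---------------------------------------------------------------------------
# Cox proportional hazards


def _naive_loglik(times, events, x, beta):
    """Risk-set-by-risk-set partial log likelihood (no ties in the data)."""
    ll = 0.0
    for i in range(len(times)):
        if events[i]:
            risk = times >= times[i]
            ll += beta * x[i] - math.log(np.sum(np.exp(beta * x[risk])))
    return ll


class TestCoxFit:
    def _binary_cohort(self, seed=13, n=30):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 2, n).astype(float)
        times = rng.exponential(100 * np.exp(-0.8 * x))
        return pd.DataFrame(
            {"time_days": times, "event": np.ones(n, bool), "x": x}
        )

    def test_single_covariate_matches_brute_force_maximum(self):
        from scipy.optimize import minimize_scalar

        df = self._binary_cohort()
        res = cox_fit(df, ["x"])
        opt = minimize_scalar(
            lambda b: -_naive_loglik(
                df["time_days"].to_numpy(), df["event"].to_numpy(), df["x"].to_numpy(), b
            ),
            bounds=(-5, 5),
            method="bounded",
            options={"xatol": 1e-10},
        )
        assert float(res.summary.loc["x", "coef"]) == pytest.approx(opt.x, abs=1e-6)

    def test_partial_loglik_agrees_with_naive(self):
        df = self._binary_cohort(seed=5)
        for beta in [-1.0, 0.0, 0.7]:
            mine = cox_partial_loglik(
                df["time_days"], df["event"], df["x"].to_numpy(), beta
            )
            ref = _naive_loglik(
                df["time_days"].to_numpy(), df["event"].to_numpy(), df["x"].to_numpy(), beta
            )
            assert mine == pytest.approx(ref, abs=1e-10)

    def test_hr_ci_contains_hr_and_exp_coef(self):
        df = self._binary_cohort(seed=21, n=60)
        res = cox_fit(df, ["x"])
        row = res.summary.loc["x"]
        assert row["hazard_ratio"] == pytest.approx(math.exp(row["coef"]))
        assert row["ci_low"] <= row["hazard_ratio"] <= row["ci_high"]
        assert res.converged

    def test_matches_lifelines_multivariable(self):
        from lifelines import CoxPHFitter

        cfg = SimulationConfig(n_subjects=400, seed=8)
        df = simulate_cohort(cfg)
        covs = ["age", "bmi", "fmf", "saps2"]
        mine = cox_fit(df, covs)
        cph = CoxPHFitter()
        cph.fit(
            df[["time_days", "event", *covs]],
            duration_col="time_days",
            event_col="event",
        )
        for c in covs:
            assert float(mine.summary.loc[c, "coef"]) == pytest.approx(
                float(cph.params_[c]), abs=1e-5
            )

    def test_efron_and_breslow_agree_without_ties(self):
        df = self._binary_cohort(seed=31, n=50)
        b = cox_fit(df, ["x"], ties="breslow")
        e = cox_fit(df, ["x"], ties="efron")
        assert float(b.summary.loc["x", "coef"]) == pytest.approx(
            float(e.summary.loc["x", "coef"]), abs=1e-10
        )

    def test_efron_with_ties_matches_lifelines(self):
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(3)
        x = rng.normal(size=80)
        times = np.ceil(rng.exponential(20 * np.exp(-0.5 * x)))  # heavy ties
        df = pd.DataFrame({"time_days": times, "event": np.ones(80, bool), "x": x})
        mine = cox_fit(df, ["x"], ties="efron")
        cph = CoxPHFitter().fit(df, "time_days", "event")
        assert float(mine.summary.loc["x", "coef"]) == pytest.approx(
            float(cph.params_["x"]), abs=1e-5
        )

    def test_sex_coding_female_is_one(self):
        df = self._binary_cohort(seed=17, n=40)
        df["sex"] = np.where(df["x"] > 0, "female", "male")
        res_sex = cox_fit(df, ["sex"])
        res_x = cox_fit(df, ["x"])
        assert float(res_sex.summary.loc["sex", "coef"]) == pytest.approx(
            float(res_x.summary.loc["x", "coef"]), abs=1e-10
        )

    def test_constant_covariate_rejected(self):
        df = self._binary_cohort()
        df["const"] = 1.0
        with pytest.raises(ValueError, match="constant"):
            cox_fit(df, ["const"])

    def test_missing_values_rejected(self):
        df = self._binary_cohort()
        df.loc[0, "x"] = np.nan
        with pytest.raises(ValueError, match="missing"):
            cox_fit(df, ["x"])

    def test_too_few_events_rejected(self):
        df = self._binary_cohort(n=10)
        df["event"] = False
        with pytest.raises(ValueError, match="events"):
            cox_fit(df, ["x"])


# ---------------------------------------------------------------------------
# table one


def _ideal_normal(n, loc, scale):
    """Deterministic, perfectly normal-looking sample (normal quantiles)."""
    p = (np.arange(1, n + 1) - 0.375) / (n + 0.25)
    return loc + scale * ss.norm.ppf(p)


def _ideal_skewed(n, scale):
    p = (np.arange(1, n + 1) - 0.375) / (n + 0.25)
    return scale * ss.expon.ppf(p)


def _toy_cohort(continuous_factory):
    rows = []
    for g, fmf in (("high", 60.0), ("low", 20.0)):
        n = 40
        for i, (age, bmi) in enumerate(
            zip(continuous_factory(n, 55 if g == "high" else 50, 10),
                continuous_factory(n, 29, 4))
        ):
            rows.append(
                {
                    "age": age,
                    "bmi": bmi,
                    "sex": "male" if i % 3 else "female",
                    "renal_failure": i % 2 == 0,
                    "weaned": i % 4 == 0,
                    "fmf": fmf,
                    "time_days": 100.0 + i,
                    "event": True,
                }
            )
    return pd.DataFrame(rows)


class TestTableOne:
    def test_contains_expected_row_labels(self):
        df = simulate_cohort(SimulationConfig(n_subjects=87, seed=1))
        report = table_one(df)
        labels = {r["variable"] for r in report["rows"]}
        for expected in (
            "Age (years)",
            "Sex (male)",
            "Body Mass Index (kg/m^2)",
            "Skeletal muscle area (cm^2)",
            "Skeletal muscle index (cm^2/m^2)",
            "Muscle mean attenuation (HU)",
            "Charlson comorbidity index",
            "Simplified acute physiology score II",
            "Respiratory ECMO survival prediction (RESP) score (%)",
            "Duration of ECMO support (days)",
            "Pre-ECMO renal failure (CRRT)",
            "Weaning from ECMO",
        ):
            assert expected in labels
        assert report["n_high"] + report["n_low"] == 87

    def test_identical_variable_gives_p_one(self):
        df = _toy_cohort(_ideal_normal)
        df["bmi"] = 25.0
        report = table_one(df, cutoff=44.0)
        row = next(r for r in report["rows"] if r["column"] == "bmi")
        assert row["p_value"] == 1.0

    def test_all_normal_data_uses_t_tests(self):
        report = table_one(_toy_cohort(_ideal_normal), cutoff=44.0)
        for r in report["rows"]:
            if r["column"] in ("age", "bmi"):
                assert r["test"] == "t"

    def test_skewed_data_uses_mann_whitney(self):
        def skewed(n, loc, scale):
            return loc + _ideal_skewed(n, scale)

        report = table_one(_toy_cohort(skewed), cutoff=44.0)
        for r in report["rows"]:
            if r["column"] in ("age", "bmi"):
                assert r["test"] == "mann_whitney_u"

    def test_small_group_rejected(self):
        df = _toy_cohort(_ideal_normal)
        df.loc[df["fmf"] > 44.0, "fmf"] = [60.0] + [20.0] * 39  # leave 1 high subject
        with pytest.raises(ValueError):
            table_one(df, cutoff=44.0)


class TestResultInvariants:
    def test_p_value_bounds_enforced(self):
        with pytest.raises(ValueError):
            StatResult("t", 1.0, 1.5)
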