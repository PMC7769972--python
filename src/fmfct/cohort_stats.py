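"""Cohort statistics: group comparisons, survival curves, and Cox modelling.

Everything the outcome analysis needs on a subject table binarised by FMF:

* 2x2 chi-square (no continuity correction) and Fisher's exact test;
* pooled-variance Student t (raw values or printed mean/SD/n summaries) and
  the Mann-Whitney U test (exact enumeration for small samples, tie-corrected
  normal approximation otherwise);
* Shapiro-Wilk normality gate and Spearman rank correlation;
* Kaplan-Meier product-limit estimation and the two-group log-rank test;
* a multivariable Cox proportional-hazards fit by Newton-Raphson on the
  partial likelihood (Breslow ties by default, Efron behind a flag), with
  Wald 95% confidence intervals and p-values;
* a "table one" builder that applies the normality gate / expected-count
  rules to pick the right test per variable.

Conventions follow the source analysis: t and chi-square statistics are
reported unsigned, U is min(U_a, U_b), sex is coded female = 1, the FMF
dichotomy is strict ('high' iff FMF > cutoff), and no multiple-testing
correction is applied (every p is raw).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TestResult",
    "KMCurve",
    "CoxModelResult",
    "chi_square_2x2",
    "fisher_exact_2x2",
    "t_test_two_sample",
    "t_from_summary",
    "mann_whitney_u",
    "shapiro_wilk",
    "spearman",
    "km_estimate",
    "km_mortality_at",
    "log_rank_test",
    "cox_fit",
    "cox_score_test",
    "cox_partial_loglik",
    "table_one",
]

WALD_Z = 1.96  # 95% two-sided


@dataclass(frozen=True)
class TestResult:
    statistic_name: str
    statistic: float
    p_value: float
    df: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p_value outside [0, 1]")


# ---------------------------------------------------------------------------
# contingency tables


def chi_square_2x2(a: int, b: int, c: int, d: int) -> TestResult:
    """Pearson chi-square for a 2x2 table, no continuity correction.

    statistic = n (ad - bc)^2 / [(a+b)(c+d)(a+c)(b+d)]; p from chi2, df = 1.
    """
    for v in (a, b, c, d):
        if v < 0:
            raise ValueError("counts must be nonnegative")
    n = a + b + c + d
    margins = [(a + b), (c + d), (a + c), (b + d)]
    if any(m == 0 for m in margins):
        raise ValueError("chi-square undefined with a zero margin")
    stat = n * (a * d - b * c) ** 2 / math.prod(margins)
    return TestResult("chi_square", stat, float(stats.chi2.sf(stat, df=1)), df=1)


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> TestResult:
    """Fisher's exact test, two-sided (sum of tables no more probable than observed)."""
    for v in (a, b, c, d):
        if v < 0:
            raise ValueError("counts must be nonnegative")
    res = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return TestResult("fisher", float(res.statistic), float(res.pvalue))


# ---------------------------------------------------------------------------
# continuous two-sample tests


def t_from_summary(
    mean_a: float, sd_a: float, n_a: int, mean_b: float, sd_b: float, n_b: int
) -> TestResult:
    """Pooled-variance Student t from printed group summaries; |t| is reported."""
    if n_a < 2 or n_b < 2:
        raise ValueError("need n >= 2 per group")
    if sd_a < 0 or sd_b < 0:
        raise ValueError("standard deviations must be nonnegative")
    df = n_a + n_b - 2
    pooled_var = ((n_a - 1) * sd_a**2 + (n_b - 1) * sd_b**2) / df
    if pooled_var == 0:
        if mean_a == mean_b:
            return TestResult("t", 0.0, 1.0, df=df)
        raise ZeroDivisionError("zero pooled variance with unequal means: t infinite")
    t = abs(mean_a - mean_b) / math.sqrt(pooled_var * (1 / n_a + 1 / n_b))
    return TestResult("t", t, float(2 * stats.t.sf(t, df)), df=df)


def t_test_two_sample(values_a, values_b) -> TestResult:
    """Unpaired pooled-variance t-test on raw values."""
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    return t_from_summary(
        a.mean(), a.std(ddof=1), len(a), b.mean(), b.std(ddof=1), len(b)
    )


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """U for sample a against b with midrank ties."""
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    r_a = ranks[: len(a)].sum()
    return r_a - len(a) * (len(a) + 1) / 2


def mann_whitney_u(values_a, values_b) -> TestResult:
    """Mann-Whitney U with midrank ties; U = min(U_a, U_b).

    Exact permutation enumeration of the rank assignments when
    n_a + n_b <= 12 (p = share of assignments with min-U at most the
    observed one); otherwise normal approximation with tie correction,
    no continuity correction.
    """
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    if len(a) < 1 or len(b) < 1:
        raise ValueError("need at least one value per group")
    n_a, n_b = len(a), len(b)
    u_a = _u_statistic(a, b)
    u_min = min(u_a, n_a * n_b - u_a)

    total = n_a + n_b
    if total <= 12:
        pooled = np.concatenate([a, b])
        ranks = stats.rankdata(pooled)
        count = 0
        n_assign = 0
        offset = n_a * (n_a + 1) / 2
        for idx in itertools.combinations(range(total), n_a):
            u = ranks[list(idx)].sum() - offset
            if min(u, n_a * n_b - u) <= u_min + 1e-9:
                count += 1
            n_assign += 1
        return TestResult("mann_whitney_u", u_min, count / n_assign)

    pooled = np.concatenate([a, b])
    _, tie_counts = np.unique(pooled, return_counts=True)
    mu = n_a * n_b / 2
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (total * (total - 1))
    var = n_a * n_b / 12 * ((total + 1) - tie_term)
    if var == 0:  # all values identical
        return TestResult("mann_whitney_u", u_min, 1.0)
    z = (u_a - mu) / math.sqrt(var)
    return TestResult(
        "mann_whitney_u", u_min, float(min(1.0, 2 * stats.norm.sf(abs(z))))
    )


def shapiro_wilk(values) -> TestResult:
    """Shapiro-Wilk W (Royston approximation via the vetted scipy routine)."""
    x = np.asarray(values, float)
    if not (3 <= len(x) <= 5000):
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.ptp(x) == 0:
        raise ValueError("Shapiro-Wilk undefined for constant input")
    res = stats.shapiro(x)
    return TestResult("shapiro_w", float(res.statistic), float(res.pvalue))


def spearman(x, y) -> TestResult:
    """Spearman rank correlation: Pearson on midranks, t-approximation p."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Spearman undefined for a constant vector")
    res = stats.spearmanr(x, y)
    return TestResult("spearman_rho", float(res.statistic), float(res.pvalue))


# ---------------------------------------------------------------------------
# survival curves


@dataclass(frozen=True)
class KMCurve:
    """Kaplan-Meier product-limit curve evaluated at the event times."""

    event_times: np.ndarray  # sorted, times with >= 1 death
    survival_probabilities: np.ndarray
    at_risk: np.ndarray
    deaths: np.ndarray

    def survival_at(self, t: float) -> float:
        """Right-continuous step function; 1 before the first event."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival_probabilities[idx])


def km_estimate(times, events) -> KMCurve:
    """Product-limit estimator S(t) = prod_{t_i <= t} (1 - d_i / n_i)."""
    t = np.asarray(times, float)
    e = np.asarray(events, bool)
    if t.size == 0:
        raise ValueError("empty survival input")
    if np.any(t <= 0):
        raise ValueError("times must be positive")
    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]
    uniq, start = np.unique(t, return_index=True)
    n_total = len(t)
    at_risk_all = n_total - start
    deaths_all = np.add.reduceat(e.astype(int), start)
    has_death = deaths_all > 0
    ev_times = uniq[has_death]
    n_i = at_risk_all[has_death]
    d_i = deaths_all[has_death]
    surv = np.cumprod(1.0 - d_i / n_i)
    return KMCurve(ev_times, surv, n_i, d_i)


def km_mortality_at(curve: KMCurve, horizon_days: float) -> float:
    """Percent cumulative mortality 100 * (1 - S(horizon))."""
    return 100.0 * (1.0 - curve.survival_at(horizon_days))


def log_rank_test(times_a, events_a, times_b, events_b) -> TestResult:
    """Two-group log-rank chi-square (O - E)^2 / V, df = 1.

    At each pooled event time the group-A death count is compared with its
    hypergeometric expectation given the risk sets.
    """
    ta = np.asarray(times_a, float)
    ea = np.asarray(events_a, bool)
    tb = np.asarray(times_b, float)
    eb = np.asarray(events_b, bool)
    if ta.size == 0 or tb.size == 0:
        raise ValueError("both groups must be non-empty")
    if not (ea.any() or eb.any()):
        raise ValueError("log-rank undefined with no events in either group")

    t_all = np.concatenate([ta, tb])
    e_all = np.concatenate([ea, eb])
    grp_a = np.concatenate([np.ones(len(ta), bool), np.zeros(len(tb), bool)])
    ev_times = np.unique(t_all[e_all])

    O = E = V = 0.0
    for t in ev_times:
        at_risk = t_all >= t
        n_j = at_risk.sum()
        n1_j = (at_risk & grp_a).sum()
        dead = e_all & (t_all == t)
        d_j = dead.sum()
        d1_j = (dead & grp_a).sum()
        O += d1_j
        E += n1_j * d_j / n_j
        if n_j > 1:
            V += d_j * (n1_j / n_j) * (1 - n1_j / n_j) * (n_j - d_j) / (n_j - 1)
    if V == 0:
        return TestResult("log_rank_chi2", 0.0, 1.0, df=1)
    stat = (O - E) ** 2 / V
    return TestResult("log_rank_chi2", stat, float(stats.chi2.sf(stat, df=1)), df=1)


# ---------------------------------------------------------------------------
# Cox proportional hazards


@dataclass(frozen=True)
class CoxModelResult:
    """Per-covariate hazard ratios with Wald 95% CIs plus fit diagnostics."""

    summary: pd.DataFrame  # index: covariate; columns: coef, se, hazard_ratio, ci_low, ci_high, p_value
    log_likelihood: float
    iterations: int
    converged: bool
    ties: str

    def hazard_ratio(self, name: str) -> float:
        return float(self.summary.loc[name, "hazard_ratio"])

    def ci(self, name: str) -> tuple[float, float]:
        row = self.summary.loc[name]
        return float(row["ci_low"]), float(row["ci_high"])


class _CoxData:
    """Pre-sorted arrays and tie-group bookkeeping, computed once per fit."""

    def __init__(self, times, events, X):
        t = np.asarray(times, float)
        e = np.asarray(events, bool)
        X = np.asarray(X, float)
        if X.ndim == 1:
            X = X[:, None]
        order = np.argsort(-t, kind="stable")  # descending: cumsums = risk sets
        self.t = t[order]
        self.e = e[order].astype(float)
        self.X = X[order]
        self.n, self.p = self.X.shape
        starts = np.flatnonzero(np.r_[True, self.t[1:] != self.t[:-1]])
        ends = np.r_[starts[1:], self.n] - 1
        d = np.add.reduceat(self.e, starts)
        keep = d > 0
        self.starts = starts[keep]
        self.ends = ends[keep]
        self.d = d[keep]
        self.group_slices = [
            slice(s, e + 1) for s, e in zip(starts[keep], ends[keep])
        ]

    def derivatives(self, beta: np.ndarray, ties: str = "breslow"):
        """(log partial likelihood, gradient, observed information) at beta."""
        if ties not in ("breslow", "efron"):
            raise ValueError(f"unknown tie handling '{ties}'")
        X, e = self.X, self.e
        eta = X @ beta
        c = float(eta.max()) if self.n else 0.0  # shift for overflow safety
        w = np.exp(eta - c)
        wX = w[:, None] * X
        S0c = np.cumsum(w)
        S1c = np.cumsum(wX, axis=0)
        S2c = np.cumsum(wX[:, :, None] * X[:, None, :], axis=0)

        ev = e.astype(bool)
        ll = float(eta[ev].sum())
        grad = X[ev].sum(axis=0)

        S0 = S0c[self.ends]  # (G,)
        S1 = S1c[self.ends]  # (G, p)
        S2 = S2c[self.ends]  # (G, p, p)
        d = self.d

        # vectorized Breslow terms for every event-time group
        m = S1 / S0[:, None]
        ll -= float((d * (np.log(S0) + c)).sum())
        grad -= (d[:, None] * m).sum(axis=0)
        info = (
            d[:, None, None]
            * (S2 / S0[:, None, None] - m[:, :, None] * m[:, None, :])
        ).sum(axis=0)

        if ties == "efron":
            # replace the Breslow contribution of tied groups by Efron's
            for g in np.flatnonzero(d > 1):
                sl = self.group_slices[g]
                ev_g = ev[sl]
                dg = int(d[g])
                wsum = w[sl][ev_g].sum()
                w1 = wX[sl][ev_g].sum(axis=0)
                w2 = (wX[sl][ev_g][:, :, None] * X[sl][ev_g][:, None, :]).sum(axis=0)
                mg = S1[g] / S0[g]
                ll += dg * (math.log(S0[g]) + c)
                grad += dg * mg
                info -= dg * (S2[g] / S0[g] - np.outer(mg, mg))
                for l in range(dg):
                    f = l / dg
                    S0l = S0[g] - f * wsum
                    S1l = S1[g] - f * w1
                    S2l = S2[g] - f * w2
                    ml = S1l / S0l
                    ll -= math.log(S0l) + c
                    grad -= ml
                    info += S2l / S0l - np.outer(ml, ml)
        return ll, grad, info


def cox_partial_loglik(times, events, X, beta, ties: str = "breslow") -> float:
    """Log partial likelihood at an arbitrary beta (for external checks)."""
    beta = np.atleast_1d(np.asarray(beta, float))
    return _CoxData(times, events, X).derivatives(beta, ties)[0]


def cox_score_test(times, events, X, ties: str = "breslow") -> TestResult:
    """Score (Rao) test of beta = 0: U' I^-1 U ~ chi2(p)."""
    data = _CoxData(times, events, X)
    _, g, info = data.derivatives(np.zeros(data.p), ties)
    stat = float(g @ np.linalg.solve(info, g))
    return TestResult(
        "cox_score_chi2", stat, float(stats.chi2.sf(stat, df=data.p)), df=data.p
    )


class CoxConvergenceError(RuntimeError):
    """Newton iteration failed (e.g. monotone likelihood)."""


def _cox_newton(data: _CoxData, ties: str, tol: float = 1e-8, max_iter: int = 100):
    beta = np.zeros(data.p)
    ll, grad, info = data.derivatives(beta, ties)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError as exc:
            raise CoxConvergenceError("singular information matrix") from exc
        # step-halving to guarantee likelihood ascent
        factor = 1.0
        for _ in range(40):
            beta_new = beta + factor * step
            ll_new, grad_new, info_new = data.derivatives(beta_new, ties)
            if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                break
            factor /= 2
        delta = np.max(np.abs(beta_new - beta))
        beta, ll, grad, info = beta_new, ll_new, grad_new, info_new
        if delta < tol:
            converged = True
            break
    return beta, ll, info, it, converged


def cox_fit(
    cohort: pd.DataFrame,
    covariates: list[str],
    ties: str = "breslow",
    tol: float = 1e-8,
    max_iter: int = 100,
) -> CoxModelResult:
    """Fit the multivariable Cox proportional-hazards model.

    ``cohort`` needs ``time_days``/``event`` plus every covariate column on
    every row (complete cases required).  ``sex`` is coded female = 1,
    male = 0; boolean covariates become 0/1.  Wald 95% CIs use
    exp(coef +/- 1.96 * SE).  Non-convergence is reported via the
    ``converged`` flag, never silently.
    """
    if len(covariates) != len(set(covariates)):
        raise ValueError("covariate names must be unique")
    for col in ("time_days", "event", *covariates):
        if col not in cohort.columns:
            raise KeyError(f"cohort missing column '{col}'")
    cols = []
    for name in covariates:
        col = cohort[name]
        if name == "sex":
            values = (col == "female").astype(float)
        else:
            values = pd.to_numeric(col).astype(float)
        if values.isna().any():
            raise ValueError(f"covariate '{name}' has missing values (complete cases required)")
        if values.nunique() <= 1:
            raise ValueError(f"covariate '{name}' is constant")
        cols.append(np.asarray(values))
    X = np.column_stack(cols)
    events = np.asarray(cohort["event"], bool)
    if events.sum() < 2:
        raise ValueError("need at least 2 events to fit a Cox model")
    data = _CoxData(cohort["time_days"], events, X)
    beta, ll, info, iterations, converged = _cox_newton(data, ties, tol, max_iter)
    se = np.sqrt(np.diag(np.linalg.inv(info)))
    z = beta / se
    summary = pd.DataFrame(
        {
            "coef": beta,
            "se": se,
            "hazard_ratio": np.exp(beta),
            "ci_low": np.exp(beta - WALD_Z * se),
            "ci_high": np.exp(beta + WALD_Z * se),
            "p_value": 2 * stats.norm.sf(np.abs(z)),
        },
        index=pd.Index(covariates, name="covariate"),
    )
    return CoxModelResult(summary, ll, iterations, converged, ties)


# ---------------------------------------------------------------------------
# table one

_CONTINUOUS_VARS = [
    ("age", "Age (years)"),
    ("bmi", "Body Mass Index (kg/m^2)"),
    ("muscle_area", "Skeletal muscle area (cm^2)"),
    ("smi", "Skeletal muscle index (cm^2/m^2)"),
    ("mean_attenuation", "Muscle mean attenuation (HU)"),
    ("cci", "Charlson comorbidity index"),
    ("saps2", "Simplified acute physiology score II"),
    ("resp_score", "Respiratory ECMO survival prediction (RESP) score (%)"),
    ("ecmo_days", "Duration of ECMO support (days)"),
]

_CATEGORICAL_VARS = [
    ("sex", "Sex (male)", lambda s: s == "male"),
    ("renal_failure", "Pre-ECMO renal failure (CRRT)", lambda s: s.astype(bool)),
    ("weaned", "Weaning from ECMO", lambda s: s.astype(bool)),
]


def _summarise(values: np.ndarray, parametric: bool) -> str:
    if parametric:
        return f"{values.mean():.1f} +/- {values.std(ddof=1):.1f}"
    q25, q50, q75 = np.percentile(values, [25, 50, 75])
    return f"{q50:.1f} ({q25:.1f}-{q75:.1f})"


def table_one(cohort: pd.DataFrame, cutoff: float | None = None) -> dict:
    """Group-comparison table for the FMF dichotomy.

    Continuous variables: Shapiro-Wilk on both groups; if both pass at 0.05
    use the pooled t-test and report mean +/- SD, else Mann-Whitney and
    median (IQR).  Categorical variables: chi-square when all expected cell
    counts are >= 5, else Fisher's exact test.  The cutoff defaults to the
    sample median FMF (ties go to 'low').
    """
    if "fmf" not in cohort.columns:
        raise KeyError("cohort missing 'fmf'")
    if cutoff is None:
        cutoff = float(np.median(cohort["fmf"]))
    high = cohort[cohort["fmf"] > cutoff]
    low = cohort[cohort["fmf"] <= cutoff]
    if len(high) < 2 or len(low) < 2:
        raise ValueError("each FMF group needs at least 2 subjects")

    rows = []
    for col, label in _CONTINUOUS_VARS:
        if col not in cohort.columns:
            continue
        va = np.asarray(high[col], float)
        vb = np.asarray(low[col], float)
        normal = True
        for v in (va, vb):
            if len(v) < 3 or np.ptp(v) == 0:
                normal = False
            else:
                normal = normal and shapiro_wilk(v).p_value > 0.05
        if np.ptp(va) == 0 and np.ptp(vb) == 0 and va[0] == vb[0]:
            res = TestResult("t", 0.0, 1.0)  # identical constant variable
            normal = True
        elif normal:
            res = t_test_two_sample(va, vb)
        else:
            res = mann_whitney_u(va, vb)
        rows.append(
            {
                "variable": label,
                "column": col,
                "kind": "continuous",
                "high": _summarise(va, normal),
                "low": _summarise(vb, normal),
                "test": res.statistic_name,
                "statistic": res.statistic,
                "p_value": res.p_value,
            }
        )

    for col, label, as_bool in _CATEGORICAL_VARS:
        if col not in cohort.columns:
            continue
        ya = int(as_bool(high[col]).sum())
        yb = int(as_bool(low[col]).sum())
        a, b_, c, d = ya, len(high) - ya, yb, len(low) - yb
        n = a + b_ + c + d
        expected_ok = all(
            rm * cm / n >= 5
            for rm in (a + b_, c + d)
            for cm in (a + c, b_ + d)
        )
        res = chi_square_2x2(a, b_, c, d) if expected_ok else fisher_exact_2x2(a, b_, c, d)
        rows.append(
            {
                "variable": label,
                "column": col,
                "kind": "categorical",
                "high": f"{ya} ({100 * ya / len(high):.0f}%)",
                "low": f"{yb} ({100 * yb / len(low):.0f}%)",
                "test": res.statistic_name,
                "statistic": res.statistic,
                "p_value": res.p_value,
            }
        )

    return {
        "cutoff": cutoff,
        "n_high": int(len(high)),
        "n_low": int(len(low)),
        "rows": rows,
    }
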