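"""Survival, discrimination and regression statistics for score validation.

Conventions, chosen once and documented so every p-value is reproducible:

* Kaplan–Meier median: smallest time with S(t) <= 0.5; when the curve sits
  exactly at 0.5 over a flat stretch, the median is the midpoint between
  the time it reaches 0.5 and the next drop below it.
* Cox proportional hazards: Efron tie handling, Wald inference (lifelines).
* Fisher's exact test: two-sided by summing hypergeometric probabilities
  <= the observed table's (not by doubling).
* Mann–Whitney: tie-corrected normal approximation; exact enumeration of
  all group assignments for combined n <= 12.
* Log-rank: hypergeometric expected counts at each distinct event time;
  an exact mode enumerates all group relabelings.
* ROC: higher score predicts the positive class (enforced, not
  auto-detected); AUC via the tie-corrected rank (Mann–Whitney) statistic.
* No multiple-testing adjustment anywhere: p-values are reported raw.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from scipy import stats as sps

from .errors import StatisticalError

# ---------------------------------------------------------------------------
# ROC / correlation


@dataclass(frozen=True)
class ROCResult:
    auc: float
    thresholds: pd.DataFrame        # cutoff, sensitivity, specificity
    operating_point: dict           # Youden-J maximizer
    p_value: float                  # vs AUC = 0.5, normal approx to U
    n_pos: int
    n_neg: int


def roc(scores, outcome) -> ROCResult:
    """Empirical ROC of a numeric score against a binary outcome.

    Higher scores must indicate the positive class.  AUC is the normalized
    Mann–Whitney U with tie correction (ties count 1/2); the operating
    point maximizes Youden's J = sensitivity + specificity - 1.
    """
    scores = np.asarray(scores, dtype=float)
    outcome = np.asarray(outcome, dtype=bool)
    pos, neg = scores[outcome], scores[~outcome]
    if len(pos) == 0 or len(neg) == 0:
        raise StatisticalError("ROC needs both outcome classes non-empty")

    ranks = sps.rankdata(scores)
    u_pos = ranks[outcome].sum() - len(pos) * (len(pos) + 1) / 2
    auc = u_pos / (len(pos) * len(neg))

    rows = []
    # classify positive when score >= cutoff; sweep all distinct values
    for cutoff in np.unique(scores):
        sens = float((pos >= cutoff).mean())
        spec = float((neg < cutoff).mean())
        rows.append({"cutoff": float(cutoff), "sensitivity": sens,
                     "specificity": spec})
    table = pd.DataFrame(rows)
    j = table["sensitivity"] + table["specificity"] - 1
    best = table.iloc[int(j.idxmax())].to_dict()

    p = sps.mannwhitneyu(pos, neg, alternative="two-sided",
                         method="asymptotic").pvalue
    return ROCResult(auc=float(auc), thresholds=table, operating_point=best,
                     p_value=float(p), n_pos=len(pos), n_neg=len(neg))


def spearman(x, y) -> tuple[float, float, float]:
    """Spearman rank correlation plus the OLS slope of y on x.

    Returns ``(r, p, slope)``.  The slope comes from an ordinary linear
    fit on the raw scales (the rank correlation and the regression line are
    reported side by side, as is usual for score-vs-duration plots).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise StatisticalError("spearman needs paired data with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise StatisticalError("spearman undefined for constant input")
    r, p = sps.spearmanr(x, y)
    slope = float(np.polyfit(x, y, 1)[0])
    return float(r), float(p), slope


# ---------------------------------------------------------------------------
# Kaplan–Meier / log-rank


@dataclass(frozen=True)
class SurvivalCurve:
    times: np.ndarray
    survival: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    at_risk: np.ndarray
    median: float                  # np.inf when not reached
    median_ci: tuple[float, float]
    n: int
    n_events: int

    @property
    def median_reached(self) -> bool:
        return np.isfinite(self.median)

    def at(self, t: float) -> float:
        """S(t): right-continuous step-function evaluation."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def _median_with_midpoint(times: np.ndarray, surv: np.ndarray) -> float:
    """Smallest t with S(t) <= 0.5; midpoint convention at an exact 0.5 flat."""
    hit = np.where(surv <= 0.5 + 1e-12)[0]
    if len(hit) == 0:
        return np.inf
    i = hit[0]
    if abs(surv[i] - 0.5) < 1e-12:
        below = np.where(surv < 0.5 - 1e-12)[0]
        if len(below):
            return float((times[i] + times[below[0]]) / 2.0)
    return float(times[i])


def km_fit(times, events) -> SurvivalCurve:
    """Product-limit estimator with Greenwood-type confidence intervals."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if len(times) == 0:
        raise StatisticalError("km_fit: empty group")
    if (times < 0).any():
        raise StatisticalError("km_fit: negative times")

    kmf = KaplanMeierFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        kmf.fit(times, events)
    grid = kmf.survival_function_.index.values
    surv = kmf.survival_function_.iloc[:, 0].values
    ci = kmf.confidence_interval_
    at_risk = np.array([int((times >= t).sum()) for t in grid])

    median = _median_with_midpoint(grid, surv)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        from lifelines.utils import median_survival_times
        ci_med = median_survival_times(kmf.confidence_interval_)
        lo = float(ci_med.iloc[0, 0])
        hi = float(ci_med.iloc[0, 1])
    return SurvivalCurve(
        times=grid, survival=surv,
        ci_lower=ci.iloc[:, 0].values, ci_upper=ci.iloc[:, 1].values,
        at_risk=at_risk, median=median, median_ci=(lo, hi),
        n=len(times), n_events=int(events.sum()),
    )


def _logrank_statistic(times, events, groups) -> float:
    """Two-group log-rank chi-square via hypergeometric expected counts."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups, dtype=int)
    obs_minus_exp = 0.0
    var = 0.0
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & (groups == 1)).sum()
        d = ((times == t) & (events == 1)).sum()
        d1 = ((times == t) & (events == 1) & (groups == 1)).sum()
        obs_minus_exp += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var == 0:
        return 0.0
    return obs_minus_exp ** 2 / var


def logrank(times_a, events_a, times_b, events_b,
            method: str = "asymptotic") -> tuple[float, float]:
    """Two-group log-rank test; returns ``(chi2, p)``.

    ``method="exact"`` enumerates every assignment of the pooled patients
    into groups of the observed sizes and reports the fraction with a
    statistic at least as large (feasible for pooled n up to ~12).
    """
    times_a, times_b = np.asarray(times_a, float), np.asarray(times_b, float)
    events_a, events_b = np.asarray(events_a, int), np.asarray(events_b, int)
    if len(times_a) == 0 or len(times_b) == 0:
        raise StatisticalError("logrank: empty group")
    times = np.concatenate([times_a, times_b])
    events = np.concatenate([events_a, events_b])
    groups = np.concatenate([np.zeros(len(times_a), int),
                             np.ones(len(times_b), int)])
    chi2 = _logrank_statistic(times, events, groups)
    if method == "asymptotic":
        p = float(sps.chi2.sf(chi2, df=1)) if chi2 > 0 else 1.0
        return float(chi2), p
    if method != "exact":
        raise ValueError(f"unknown method {method!r}")
    n = len(times)
    n_b = int(groups.sum())
    count = total = 0
    for combo in itertools.combinations(range(n), n_b):
        g = np.zeros(n, int)
        g[list(combo)] = 1
        stat = _logrank_statistic(times, events, g)
        total += 1
        if stat >= chi2 - 1e-12:
            count += 1
    return float(chi2), count / total


# ---------------------------------------------------------------------------
# Competing risks (Aalen–Johansen)


@dataclass(frozen=True)
class CumulativeIncidenceCurve:
    times: np.ndarray
    incidence: dict                 # cause -> nondecreasing array
    event_free: np.ndarray
    at_risk: np.ndarray
    n: int

    def at(self, cause: str, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 0.0 if idx < 0 else float(self.incidence[cause][idx])


def aalen_johansen(times, causes, cause_labels=None) -> CumulativeIncidenceCurve:
    """Aalen–Johansen cumulative incidence for competing events.

    ``causes`` holds a label per subject, with ``None``/""/"censored" for
    censoring.  At every time, event-free probability plus the summed
    cause-specific incidences equals 1.
    """
    times = np.asarray(times, dtype=float)
    causes = np.asarray([c if c not in (None, "", "censored") else None
                         for c in causes], dtype=object)
    if len(times) == 0:
        raise StatisticalError("aalen_johansen: empty data")
    labels = cause_labels or sorted({c for c in causes if c is not None})

    event_times = np.unique(times[causes != None])  # noqa: E711
    surv = 1.0
    cif = {c: [] for c in labels}
    ef, at_risk = [], []
    cum = {c: 0.0 for c in labels}
    for t in event_times:
        n = int((times >= t).sum())
        for c in labels:
            d_c = int(((times == t) & (causes == c)).sum())
            cum[c] += surv * d_c / n
        d_all = int(((times == t) & (causes != None)).sum())  # noqa: E711
        surv *= 1 - d_all / n
        for c in labels:
            cif[c].append(cum[c])
        ef.append(surv)
        at_risk.append(n)
    return CumulativeIncidenceCurve(
        times=event_times,
        incidence={c: np.asarray(v) for c, v in cif.items()},
        event_free=np.asarray(ef),
        at_risk=np.asarray(at_risk, dtype=int),
        n=len(times),
    )


def nrm_cuminc(records, horizon_months: float = 12.0,
               groups: dict | None = None):
    """Non-relapse-mortality cumulative incidence with progression-related
    death as the competing cause.

    NRM is death after infusion without progression/relapse.  Deaths after
    a progression event count as the competing cause; event-free patients
    are censored at last follow-up.  Returns the overall curve, or
    ``{group: curve}`` plus a cause-specific log-rank comparison when
    ``groups`` maps patient_id -> group label.

    The 1-year NRM estimate is ``curve.at("NRM", 12)``.
    """
    times, causes, ids = [], [], []
    for r in records:
        o = r.outcome
        if o is None:
            continue
        if o.os_event == 1 and o.death_cause == "none":
            raise StatisticalError(f"{r.patient_id}: death with cause 'none'")
        times.append(o.os_time)
        if o.os_event == 0:
            causes.append(None)
        elif o.nrm_event:
            causes.append("NRM")
        else:
            causes.append("progression_death")
        ids.append(r.patient_id)
    labels = ["NRM", "progression_death"]
    if groups is None:
        return aalen_johansen(times, causes, labels)
    out = {}
    by_group = {}
    for t, c, pid in zip(times, causes, ids):
        g = groups[pid]
        by_group.setdefault(g, []).append((t, c))
    for g, pairs in by_group.items():
        out[g] = aalen_johansen([t for t, _ in pairs], [c for _, c in pairs], labels)
    # cause-specific log-rank on NRM (competing deaths treated as censoring)
    gl = sorted(by_group)
    if len(gl) == 2:
        ta = [t for t, c in by_group[gl[0]]]
        ea = [1 if c == "NRM" else 0 for _, c in by_group[gl[0]]]
        tb = [t for t, c in by_group[gl[1]]]
        eb = [1 if c == "NRM" else 0 for _, c in by_group[gl[1]]]
        chi2, p = logrank(ta, ea, tb, eb)
    else:
        chi2, p = np.nan, np.nan
    return out, (chi2, p)


# ---------------------------------------------------------------------------
# Regression


@dataclass(frozen=True)
class RegressionResult:
    table: pd.DataFrame  # index covariate: coef, ratio, ci_lower, ci_upper, p
    n: int
    n_events: int
    model: str           # "cox" | "logistic"
    tie_handling: str | None = None

    def ratio(self, covariate: str) -> float:
        return float(self.table.loc[covariate, "ratio"])


def cox_fit(df: pd.DataFrame, covariates: list[str], time_col: str,
            event_col: str) -> RegressionResult:
    """Cox proportional-hazards fit (Efron ties, Wald CIs) via lifelines.

    ``df`` holds one row per patient.  Raises :class:`StatisticalError` on
    constant covariates, collinearity or non-convergence.
    """
    data = df[covariates + [time_col, event_col]].astype(float)
    if data[event_col].sum() < 1:
        raise StatisticalError("cox_fit: no events")
    for c in covariates:
        if data[c].nunique() < 2:
            raise StatisticalError(f"cox_fit: covariate {c!r} is constant")
    if len(covariates) > 1:
        rank = np.linalg.matrix_rank(np.column_stack(
            [np.ones(len(data))] + [data[c].values for c in covariates]))
        if rank < len(covariates) + 1:
            raise StatisticalError("cox_fit: collinear covariates")
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(data, duration_col=time_col, event_col=event_col)
    except (ConvergenceError, np.linalg.LinAlgError, ValueError) as e:
        raise StatisticalError(f"cox_fit did not converge: {e}") from e
    s = cph.summary
    table = pd.DataFrame({
        "coef": s["coef"],
        "ratio": np.exp(s["coef"]),
        "ci_lower": np.exp(s["coef lower 95%"]),
        "ci_upper": np.exp(s["coef upper 95%"]),
        "p": s["p"],
    })
    return RegressionResult(table=table, n=len(data),
                            n_events=int(data[event_col].sum()),
                            model="cox", tie_handling="efron")


def logistic_fit(df: pd.DataFrame, covariates: list[str],
                 outcome_col: str) -> RegressionResult:
    """Maximum-likelihood logistic regression (Wald CIs) via statsmodels."""
    import statsmodels.api as sm

    data = df[covariates + [outcome_col]].astype(float)
    y = data[outcome_col]
    if y.nunique() < 2:
        raise StatisticalError("logistic_fit: one-class outcome")
    X = sm.add_constant(data[covariates])
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            fit = sm.Logit(y, X).fit(disp=0)
    except Exception as e:  # separation, singular matrix, non-convergence
        raise StatisticalError(f"logistic_fit failed: {e}") from e
    if not fit.mle_retvals.get("converged", True):
        raise StatisticalError("logistic_fit did not converge")
    params = fit.params.drop("const")
    conf = fit.conf_int().drop(index="const")
    table = pd.DataFrame({
        "coef": params,
        "ratio": np.exp(params),
        "ci_lower": np.exp(conf[0]),
        "ci_upper": np.exp(conf[1]),
        "p": fit.pvalues.drop("const"),
    })
    return RegressionResult(table=table, n=len(data),
                            n_events=int(y.sum()), model="logistic")


# ---------------------------------------------------------------------------
# Group comparison


@dataclass(frozen=True)
class GroupTestResult:
    test: str
    statistic: float
    p_value: float
    method: str


def _mannwhitney_u(x: np.ndarray, y: np.ndarray) -> float:
    ranks = sps.rankdata(np.concatenate([x, y]))
    return float(ranks[: len(x)].sum() - len(x) * (len(x) + 1) / 2)


def mann_whitney(x, y, method: str = "auto") -> GroupTestResult:
    """Two-sided Mann–Whitney test.

    ``method="exact"`` (automatic for combined n <= 12) enumerates all
    group assignments of the pooled values and reports the fraction whose
    ``|U - n1*n2/2|`` is at least the observed one — a convention that
    handles ties without a correction formula.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise StatisticalError("mann_whitney: empty group")
    if method == "auto":
        method = "exact" if len(x) + len(y) <= 12 else "asymptotic"
    u = _mannwhitney_u(x, y)
    if method == "asymptotic":
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        return GroupTestResult("mann_whitney", float(res.statistic),
                               float(res.pvalue), "asymptotic")
    pooled = np.concatenate([x, y])
    n, n1 = len(pooled), len(x)
    mu = n1 * len(y) / 2
    obs = abs(u - mu)
    count = total = 0
    for combo in itertools.combinations(range(n), n1):
        mask = np.zeros(n, bool)
        mask[list(combo)] = True
        u_p = _mannwhitney_u(pooled[mask], pooled[~mask])
        total += 1
        if abs(u_p - mu) >= obs - 1e-9:
            count += 1
    return GroupTestResult("mann_whitney", u, count / total, "exact")


def fisher_exact(table) -> GroupTestResult:
    """Two-sided Fisher exact test on a 2x2 table, by summing the
    probabilities of all tables no more likely than the observed one."""
    table = np.asarray(table, dtype=int)
    if table.shape != (2, 2):
        raise StatisticalError("fisher_exact needs a 2x2 table")
    _, p = sps.fisher_exact(table, alternative="two-sided")
    odds = np.inf
    if table[0, 1] * table[1, 0] > 0:
        odds = table[0, 0] * table[1, 1] / (table[0, 1] * table[1, 0])
    return GroupTestResult("fisher_exact", float(odds), float(p), "exact")


def group_compare(values_or_table, groups=None) -> GroupTestResult:
    """Dispatch: continuous values + group labels -> Mann–Whitney;
    a 2x2 count table -> Fisher exact."""
    if groups is None:
        return fisher_exact(values_or_table)
    values = np.asarray(values_or_table, dtype=float)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if len(labels) != 2:
        raise StatisticalError("group_compare needs exactly two groups")
    return mann_whitney(values[groups == labels[0]], values[groups == labels[1]])
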