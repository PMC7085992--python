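"""Survival stratification of per-subject PET/CT indices.

Each candidate prognostic variable (age, ALSFRS-R, spinal-cord N-SUV,
psoas volume, psoas N-SUV, psoas VC-SUV, motor-cortex SUV) is median-split
into a low and a high group; the groups are compared with Kaplan-Meier
curves and the log-rank test, and modelled with univariate Cox
proportional-hazards fits on the split indicator. A multivariate Cox model
is then reduced by backward elimination on the likelihood-ratio test,
removing variables while their p exceeds 0.1.

Kaplan-Meier curves and the log-rank test are delegated to lifelines; Cox
fits use statsmodels' PHReg with Breslow tie handling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

#: The seven stratification variables, as cohort-table column names.
SEVEN_VARIABLES = (
    "age_years",
    "alsfrs_r",
    "spinal_cord_n_suv",
    "psoas_volume_mL_per_kg",
    "psoas_n_suv",
    "psoas_vc_suv_pct",
    "ba4_suv",
)

REQUIRED_COLUMNS = ("subject_id",) + SEVEN_VARIABLES + ("followup_months", "event")


class SurvivalInputError(ValueError):
    """Degenerate or invalid survival input."""


def validate_cohort(records: pd.DataFrame) -> pd.DataFrame:
    """Check SubjectRecord invariants; returns the frame unchanged."""
    missing = [c for c in REQUIRED_COLUMNS if c not in records.columns]
    if missing:
        raise SurvivalInputError(f"cohort table missing columns {missing}")
    if (records["followup_months"] < 0).any():
        raise SurvivalInputError("negative follow-up times")
    if not records["event"].isin([0, 1]).all():
        raise SurvivalInputError("event flags must be 0/1")
    if not records["alsfrs_r"].between(0, 48).all():
        raise SurvivalInputError("ALSFRS-R outside [0, 48]")
    return records


# ---------------------------------------------------------------------------
# Stratification arithmetic
# ---------------------------------------------------------------------------

def median_split(records: pd.DataFrame, variable: str) -> tuple[pd.DataFrame, pd.DataFrame, float]:
    """Split a cohort at the median of one variable.

    The median is the midpoint of the central order statistics for even n;
    ties at the median go to the low group (low: value <= median, high:
    value > median).
    """
    vals = records[variable].to_numpy(dtype=float)
    if len(vals) < 2 or not np.isfinite(vals).all():
        raise SurvivalInputError(f"{variable}: need >= 2 finite values")
    med = float(np.median(vals))
    low = records[records[variable] <= med]
    high = records[records[variable] > med]
    if len(high) == 0:
        raise SurvivalInputError(f"{variable}: degenerate split (all values <= median {med})")
    if len(low) != len(high):
        log.info("%s: tied median %.6g gives groups %d | %d", variable, med, len(low), len(high))
    return low, high, med


def mortality_rate(n_patients: int, n_deaths: int) -> int:
    """Mortality rate as a whole percent: nearest integer, halves down.

    21 deaths in 56 patients is 37.5% and reports as 37%.
    """
    if n_patients <= 0:
        raise SurvivalInputError(f"n_patients must be > 0, got {n_patients}")
    if not 0 <= n_deaths <= n_patients:
        raise SurvivalInputError(f"n_deaths {n_deaths} outside [0, {n_patients}]")
    import math

    return int(math.ceil(100.0 * n_deaths / n_patients - 0.5))


# ---------------------------------------------------------------------------
# Kaplan-Meier / log-rank
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KMCurve:
    """Product-limit survival estimate."""

    event_times: np.ndarray          # distinct event times with >= 1 death
    survival_probabilities: np.ndarray
    n_at_risk: np.ndarray            # risk-set size just before each event time

    def survival_at(self, t: float) -> float:
        """Step-function value S(t)."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival_probabilities[idx])


def km_estimate(times, events) -> KMCurve:
    """Kaplan-Meier estimate; censored subjects leave the risk set silently."""
    from lifelines import KaplanMeierFitter

    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise SurvivalInputError("empty survival input")
    if (times < 0).any():
        raise SurvivalInputError("negative times")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    tab = kmf.event_table
    tab = tab[tab["observed"] > 0]
    event_times = tab.index.to_numpy(dtype=float)
    surv = np.array([kmf.predict(t) for t in event_times], dtype=float)
    return KMCurve(
        event_times=event_times,
        survival_probabilities=surv,
        n_at_risk=tab["at_risk"].to_numpy(dtype=float),
    )


def logrank_test(group1, group2) -> tuple[float, float]:
    """Two-sample log-rank test.

    Each group is ``(times, events)``; returns the chi-square statistic on
    one degree of freedom and its p-value.
    """
    from lifelines.statistics import logrank_test as _ll_logrank

    t1, e1 = (np.asarray(a, dtype=float) for a in group1)
    t2, e2 = (np.asarray(a, dtype=float) for a in group2)
    if t1.size == 0 or t2.size == 0:
        raise SurvivalInputError("both groups must be nonempty")
    if int(e1.sum() + e2.sum()) == 0:
        raise SurvivalInputError("log-rank undefined with zero events")
    res = _ll_logrank(t1, t2, event_observed_A=e1, event_observed_B=e2)
    return float(res.test_statistic), float(res.p_value)


# ---------------------------------------------------------------------------
# Cox proportional hazards
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CoxResult:
    """One covariate's hazard ratio with Wald CI and p."""

    covariate: str
    hazard_ratio: float
    ci95_low: float
    ci95_high: float
    p_value: float
    log_likelihood: float
    converged: bool = True
    note: str = ""


def _phreg_fit(times, events, X: pd.DataFrame):
    from statsmodels.duration.hazard_regression import PHReg

    model = PHReg(np.asarray(times, float), X.to_numpy(float),
                  status=np.asarray(events, int), ties="breslow")
    return model.fit(method="newton", disp=False)


def cox_fit(records: pd.DataFrame, covariates: list[str]) -> list[CoxResult]:
    """Breslow-ties Cox fit; one CoxResult per covariate (shared model llf)."""
    if int(records["event"].sum()) < 1:
        raise SurvivalInputError("Cox fit needs >= 1 event")
    X = records[covariates]
    for c in covariates:
        if X[c].nunique() < 2:
            raise SurvivalInputError(f"covariate {c} is constant")
    try:
        res = _phreg_fit(records["followup_months"], records["event"], X)
    except Exception as e:  # non-convergence / separation
        return [
            CoxResult(c, np.nan, np.nan, np.nan, np.nan, np.nan,
                      converged=False, note=f"fit failed: {e}")
            for c in covariates
        ]
    llf = float(res.llf)
    out = []
    z975 = stats.norm.ppf(0.975)
    for i, c in enumerate(covariates):
        b, se = float(res.params[i]), float(res.bse[i])
        note = ""
        ok = np.isfinite(b) and np.isfinite(se) and se < 50
        if not ok:
            note = "unstable estimate (possible separation)"
        out.append(
            CoxResult(
                covariate=c,
                hazard_ratio=float(np.exp(b)),
                ci95_low=float(np.exp(b - z975 * se)),
                ci95_high=float(np.exp(b + z975 * se)),
                p_value=float(2 * stats.norm.sf(abs(b / se))) if se > 0 else np.nan,
                log_likelihood=llf,
                converged=ok,
                note=note,
            )
        )
    return out


def cox_univariate(
    records: pd.DataFrame, variable: str, split: bool = True
) -> tuple[CoxResult, float | None]:
    """Univariate Cox fit on one variable.

    With ``split=True`` (the default, matching the stratified analysis) the
    covariate is the median-split indicator (1 = above the median); the low
    group is the reference. ``split=False`` uses the continuous value.

    Returns the fit and the median used (None when continuous).
    """
    df = records.copy()
    if split:
        _, _, med = median_split(df, variable)
        df["_x"] = (df[variable] > med).astype(float)
        name = f"{variable} > {med:g}"
    else:
        df["_x"] = df[variable].astype(float)
        med = None
        name = variable
    if df["_x"].nunique() < 2:
        raise SurvivalInputError(f"{variable}: group indicator is constant")
    low_events = int(df.loc[df["_x"] == 0, "event"].sum()) if split else 1
    res = cox_fit(df, ["_x"])[0]
    if split and (low_events == 0 or int(df.loc[df["_x"] == 1, "event"].sum()) == 0):
        res = CoxResult(
            name, res.hazard_ratio, res.ci95_low, res.ci95_high, res.p_value,
            res.log_likelihood, converged=False,
            note="one group has no events: monotone likelihood / separation",
        )
    else:
        res = CoxResult(name, res.hazard_ratio, res.ci95_low, res.ci95_high,
                        res.p_value, res.log_likelihood, converged=res.converged,
                        note=res.note)
    return res, med


@dataclass(frozen=True)
class BackwardEliminationResult:
    """Final model of the step-down procedure, with the removal trail."""

    retained: tuple[CoxResult, ...]
    removed: tuple[tuple[str, float], ...]   # (variable, LRT p at removal)
    removal_p: float


def lrt_pvalue(llf_full: float, llf_reduced: float, df: int = 1) -> float:
    """Likelihood-ratio-test p-value for nested Cox models."""
    chi2 = max(2.0 * (llf_full - llf_reduced), 0.0)
    return float(stats.chi2.sf(chi2, df))


def cox_backward(
    records: pd.DataFrame,
    variables: list[str] | tuple[str, ...] = SEVEN_VARIABLES,
    removal_p: float = 0.1,
) -> BackwardEliminationResult:
    """Backward elimination of a multivariate Cox model by the LRT.

    At each step every remaining variable is dropped in turn and its
    likelihood-ratio p computed against the current model; the variable
    with the largest p is removed while that p exceeds ``removal_p``. An
    empty final model is a legitimate outcome.
    """
    current = list(variables)
    removed: list[tuple[str, float]] = []
    while current:
        full = cox_fit(records, current)
        if not full[0].converged and np.isnan(full[0].hazard_ratio):
            raise SurvivalInputError(f"multivariate fit failed on {current}")
        llf_full = full[0].log_likelihood
        pvals = {}
        for v in current:
            rest = [c for c in current if c != v]
            if rest:
                llf_red = cox_fit(records, rest)[0].log_likelihood
            else:
                llf_red = _null_llf(records)
            pvals[v] = lrt_pvalue(llf_full, llf_red)
        worst = max(pvals, key=pvals.get)
        if pvals[worst] <= removal_p:
            return BackwardEliminationResult(tuple(full), tuple(removed), removal_p)
        removed.append((worst, pvals[worst]))
        current.remove(worst)
    return BackwardEliminationResult((), tuple(removed), removal_p)


def _null_llf(records: pd.DataFrame) -> float:
    """Log partial likelihood of the covariate-free (null) Cox model."""
    from statsmodels.duration.hazard_regression import PHReg

    model = PHReg(records["followup_months"].to_numpy(float),
                  np.zeros((len(records), 1)),
                  status=records["event"].to_numpy(int), ties="breslow")
    return float(model.loglike(np.zeros(1)))


# ---------------------------------------------------------------------------
# Group comparisons / regression
# ---------------------------------------------------------------------------

def compare_groups(values1, values2, paired: bool = False, welch: bool = False) -> tuple[float, float]:
    """Student (or Welch) t test between two groups; paired when requested."""
    a = np.asarray(values1, dtype=float)
    b = np.asarray(values2, dtype=float)
    if a.size < 2 or b.size < 2:
        raise SurvivalInputError("need >= 2 values per group")
    if paired:
        if a.size != b.size:
            raise SurvivalInputError("paired test needs equal lengths")
        if np.ptp(a - b) == 0 and np.all(a == b):
            return 0.0, 1.0
        res = stats.ttest_rel(a, b)
    else:
        if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
            if a.mean() == b.mean():
                return 0.0, 1.0
            raise SurvivalInputError("zero variance in both groups")
        res = stats.ttest_ind(a, b, equal_var=not welch)
    return float(res.statistic), float(res.pvalue)


def linfit(x, y) -> tuple[float, float, float, float]:
    """Ordinary least-squares line: (slope, intercept, Pearson r, p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or x.size != y.size:
        raise SurvivalInputError("need two equal-length arrays of >= 2 points")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue), float(res.pvalue)


# ---------------------------------------------------------------------------
# Stratification report (group sizes / deaths / mortality % / HR table)
# ---------------------------------------------------------------------------

def stratification_table(
    records: pd.DataFrame,
    variables: list[str] | tuple[str, ...] = SEVEN_VARIABLES,
    removal_p: float = 0.1,
) -> pd.DataFrame:
    """Per-variable median-split outcome and Cox summary table.

    One row per (variable, group): group sizes, deaths, whole-percent
    mortality rate, the univariate hazard ratio of the high group with its
    Wald 95% CI and p, the log-rank p, and — for variables surviving
    backward elimination — the multivariate hazard ratio.
    """
    validate_cohort(records)
    multi = cox_backward(records, list(variables), removal_p=removal_p)
    multi_by_var = {r.covariate: r for r in multi.retained}
    rows = []
    for var in variables:
        low, high, med = median_split(records, var)
        uni, _ = cox_univariate(records, var, split=True)
        lr_stat, lr_p = logrank_test(
            (low["followup_months"], low["event"]),
            (high["followup_months"], high["event"]),
        )
        m = multi_by_var.get(var)
        for name, grp in (("low", low), ("high", high)):
            d = int(grp["event"].sum())
            rows.append(
                {
                    "variable": var,
                    "group": f"{'<=' if name == 'low' else '>'} {med:g}",
                    "n_patients": len(grp),
                    "n_deaths": d,
                    "mortality_rate_pct": mortality_rate(len(grp), d),
                    "hazard_ratio": 1.0 if name == "low" else uni.hazard_ratio,
                    "ci95_low": np.nan if name == "low" else uni.ci95_low,
                    "ci95_high": np.nan if name == "low" else uni.ci95_high,
                    "univariate_p": uni.p_value,
                    "logrank_p": lr_p,
                    "multivariate_hazard_ratio": (
                        np.nan if (m is None or name == "low") else m.hazard_ratio
                    ),
                    "multivariate_p": np.nan if (m is None or name == "low") else m.p_value,
                }
            )
    return pd.DataFrame(rows)


def schoenfeld_residuals(records: pd.DataFrame, covariates: list[str]):
    """Hook for proportional-hazards diagnostics (not part of the pipeline)."""
    X = records[covariates]
    res = _phreg_fit(records["followup_months"], records["event"], X)
    return res.schoenfeld_residuals
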