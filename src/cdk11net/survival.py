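"""Tissue-microarray staining scores and cohort survival statistics.

Staining is scored by the percentage of positively stained nuclei into
six ordinal categories (0, 1+ ... 5+) and dichotomized at category 2
(<=2 low, >=3 high). Cohort machinery covers the stratified summary
table, the chi-square association test, Spearman rank correlation of
two markers, Kaplan-Meier curves, the log-rank test, Cox proportional
hazards (Newton-Raphson on the partial likelihood, Breslow or Efron
ties), and forward/backward stepwise covariate selection on Wald
p-values.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

from .errors import AnalysisError, InputError

N_CATEGORIES = 6
DEFAULT_HIGH_CUTOFF = 2  # category <= 2 -> "low", >= 3 -> "high"


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal round-half-up, the convention of printed clinical tables."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def categorize_staining(percent_positive: float, any_nuclear: bool = True) -> int:
    """Ordinal staining category 0-5 from percent positive nuclei.

    0: no nuclear staining; 1+: <10%; 2+: 10-25%; 3+: >25-50%;
    4+: >50-75%; 5+: >75%. Non-integer boundary percentages resolve
    upper-inclusive (25.0 -> 2+, 25.5 -> 3+).
    """
    if not 0 <= percent_positive <= 100:
        raise InputError(f"percent_positive {percent_positive} outside [0, 100]")
    if not any_nuclear:
        return 0
    if percent_positive < 10:
        return 1
    if percent_positive <= 25:
        return 2
    if percent_positive <= 50:
        return 3
    if percent_positive <= 75:
        return 4
    return 5


def dichotomize(category: int, cutoff: int = DEFAULT_HIGH_CUTOFF) -> str:
    """'low' for category <= cutoff, else 'high'."""
    if not 0 <= category < N_CATEGORIES:
        raise InputError(f"staining category {category} outside 0..{N_CATEGORIES - 1}")
    return "low" if category <= cutoff else "high"


def staining_distribution(
    counts: list[int] | np.ndarray, cutoff: int = DEFAULT_HIGH_CUTOFF
) -> pd.DataFrame:
    """Percentage breakdown of the six staining categories.

    Returns one row per category with n and percent of evaluable cores,
    plus a ``group`` column marking each category low or high at the
    dichotomization cutoff.
    """
    counts = np.asarray(counts, dtype=int)
    if counts.shape != (N_CATEGORIES,) or (counts < 0).any():
        raise InputError(f"counts must be {N_CATEGORIES} nonnegative category counts")
    total = counts.sum()
    if total == 0:
        raise InputError("no evaluable cores")
    out = pd.DataFrame(
        {
            "category": range(N_CATEGORIES),
            "n": counts,
            "percent": [round_half_up(100.0 * c / total) for c in counts],
            "group": [dichotomize(c, cutoff) for c in range(N_CATEGORIES)],
        }
    )
    return out


def low_high_shares(
    counts: list[int] | np.ndarray, cutoff: int = DEFAULT_HIGH_CUTOFF
) -> dict[str, float]:
    """Percent of evaluable cores scored low vs high."""
    dist = staining_distribution(counts, cutoff)
    total = dist["n"].sum()
    low = dist.loc[dist["group"] == "low", "n"].sum()
    return {
        "low": round_half_up(100.0 * low / total),
        "high": round_half_up(100.0 * (total - low) / total),
    }


# ---------------------------------------------------------------------------
# stratified cohort summary
# ---------------------------------------------------------------------------

SUMMARY_FEATURES: dict[str, str] = {
    "age_group": "Age",
    "gender": "Gender",
    "grade": "Grade",
    "metastasis": "Metastasis",
    "recurrence": "Recurrence",
    "chemo_response": "Response to preoperative chemotherapy",
}


def cohort_summary(
    cohort: pd.DataFrame, cutoff: int = DEFAULT_HIGH_CUTOFF
) -> pd.DataFrame:
    """Clinicopathological strata with counts, column % and AR high/low split.

    For every stratum of every feature: n, percent of patients with that
    feature recorded (column percent), and the AR-high / AR-low counts
    with within-row percentages. Percentages are round-half-up to one
    decimal.
    """
    if cohort.empty:
        raise InputError("cohort is empty")
    df = cohort.copy()
    df["ar_group"] = [dichotomize(int(c), cutoff) for c in df["ar_category"]]
    if "age_group" not in df.columns and "age_years" in df.columns:
        df["age_group"] = np.where(df["age_years"] <= 24, "<=24", ">24")

    rows = []
    for col, label in SUMMARY_FEATURES.items():
        if col not in df.columns:
            continue
        sub = df[df[col].notna()]
        total = len(sub)
        for stratum, grp in sub.groupby(col, sort=True):
            n = len(grp)
            high = int((grp["ar_group"] == "high").sum())
            low = n - high
            rows.append(
                {
                    "feature": label,
                    "stratum": str(stratum),
                    "n": n,
                    "percent": round_half_up(100.0 * n / total),
                    "ar_high_n": high,
                    "ar_high_percent": round_half_up(100.0 * high / n) if n else 0.0,
                    "ar_low_n": low,
                    "ar_low_percent": round_half_up(100.0 * low / n) if n else 0.0,
                }
            )
    n_all = len(df)
    n_high = int((df["ar_group"] == "high").sum())
    rows.append(
        {
            "feature": "AR expression",
            "stratum": "high",
            "n": n_high,
            "percent": round_half_up(100.0 * n_high / n_all),
            "ar_high_n": n_high,
            "ar_high_percent": 100.0,
            "ar_low_n": 0,
            "ar_low_percent": 0.0,
        }
    )
    rows.append(
        {
            "feature": "AR expression",
            "stratum": "low",
            "n": n_all - n_high,
            "percent": round_half_up(100.0 * (n_all - n_high) / n_all),
            "ar_high_n": 0,
            "ar_high_percent": 0.0,
            "ar_low_n": n_all - n_high,
            "ar_low_percent": 100.0,
        }
    )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# association statistics
# ---------------------------------------------------------------------------


def chi_square(
    table: np.ndarray | list[list[float]], yates: bool = False
) -> tuple[float, int, float]:
    """Pearson chi-square test of independence on an r x c count table."""
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or (t < 0).any():
        raise InputError("table must be a 2-D nonnegative count matrix")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise InputError("table has a zero row or column margin")
    res = stats.chi2_contingency(t, correction=yates)
    return float(res.statistic), int(res.dof), float(res.pvalue)


def spearman(x, y) -> tuple[float, float]:
    """Tie-corrected Spearman rank correlation (rho, p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise InputError("spearman needs two equal-length vectors with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise AnalysisError("spearman undefined for a zero-variance vector")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


# ---------------------------------------------------------------------------
# survival curves and tests
# ---------------------------------------------------------------------------


@dataclass
class SurvivalCurve:
    """Product-limit survival estimate as a right-continuous step function."""

    times: np.ndarray  # distinct observed times, ascending
    at_risk: np.ndarray
    survival: np.ndarray

    def validate(self) -> "SurvivalCurve":
        s = self.survival
        if (np.diff(s) > 1e-12).any() or (s < -1e-12).any() or (s > 1 + 1e-12).any():
            raise AnalysisError("survival probabilities must be non-increasing in [0, 1]")
        return self

    def at(self, t: float) -> float:
        """S(t) of the step function."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def kaplan_meier(times, events) -> SurvivalCurve:
    """Kaplan-Meier product-limit estimator.

    At tied times, events precede censorings (the censored subject is
    still at risk for the tied event).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if (times < 0).any():
        raise InputError("survival times must be >= 0")
    if times.shape != events.shape:
        raise InputError("times and events must have equal length")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    ts = np.unique(times)
    at_risk = np.array([(times >= t).sum() for t in ts])
    surv = kmf.survival_function_at_times(ts).to_numpy(dtype=float)
    return SurvivalCurve(times=ts, at_risk=at_risk, survival=surv).validate()


def log_rank(groups, times, events) -> tuple[float, int, float]:
    """K-sample log-rank test; returns (statistic, df, p)."""
    groups = np.asarray(groups)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    labels, counts = np.unique(groups, return_counts=True)
    if len(labels) < 2:
        raise InputError("log-rank needs at least 2 non-empty groups")
    res = multivariate_logrank_test(times, groups, events)
    df = len(labels) - 1
    stat = float(res.test_statistic)
    return stat, df, float(stats.chi2.sf(stat, df))


# ---------------------------------------------------------------------------
# Cox proportional hazards
# ---------------------------------------------------------------------------


@dataclass
class CoxModel:
    """Fitted proportional-hazards model.

    ``summary`` has one row per covariate: coef, se, hr, hr_ci_low,
    hr_ci_high, p (Wald).
    """

    summary: pd.DataFrame
    loglik: float
    ties: str
    n: int
    n_events: int

    @property
    def covariates(self) -> list[str]:
        return list(self.summary.index)

    def hazard_ratio(self, covariate: str) -> float:
        return float(self.summary.at[covariate, "hr"])


def _cox_loglik_derivs(beta, x, times, events, ties):
    """Partial log-likelihood, gradient and information (Breslow/Efron)."""
    order = np.argsort(-times, kind="stable")  # descending: risk sets by cumsum
    x = x[order]
    t = times[order]
    e = events[order]
    n, p = x.shape
    eta = x @ beta
    eta -= eta.max()  # overflow guard; the shift cancels identically in
    theta = np.exp(eta)  # the partial likelihood and its derivatives
    wx = x * theta[:, None]
    wxx = x[:, :, None] * x[:, None, :] * theta[:, None, None]

    ll = 0.0
    grad = np.zeros(p)
    info = np.zeros((p, p))
    s0 = 0.0
    s1 = np.zeros(p)
    s2 = np.zeros((p, p))
    i = 0
    while i < n:
        j = i
        while j < n and t[j] == t[i]:
            j += 1
        s0 += theta[i:j].sum()
        s1 += wx[i:j].sum(axis=0)
        s2 += wxx[i:j].sum(axis=0)
        ev = np.flatnonzero(e[i:j]) + i
        d = len(ev)
        if d:
            ll += float(eta[ev].sum())
            if ties == "breslow":
                ll -= d * np.log(s0)
                m1 = s1 / s0
                grad += x[ev].sum(axis=0) - d * m1
                info += d * (s2 / s0 - np.outer(m1, m1))
            else:  # efron
                d0 = theta[ev].sum()
                d1 = wx[ev].sum(axis=0)
                d2 = wxx[ev].sum(axis=0)
                for l in range(d):
                    f = l / d
                    denom = s0 - f * d0
                    m1 = (s1 - f * d1) / denom
                    ll -= np.log(denom)
                    grad -= m1
                    info += (s2 - f * d2) / denom - np.outer(m1, m1)
                grad += x[ev].sum(axis=0)
        i = j
    return ll, grad, info


def cox_fit(
    covariates: pd.DataFrame,
    times,
    events,
    ties: str = "breslow",
    tol: float = 1e-8,
    max_iter: int = 50,
) -> CoxModel:
    """Newton-Raphson maximization of the Cox partial likelihood.

    Breslow tie handling by default, Efron via ``ties='efron'``.
    Standard errors come from the observed information at the optimum;
    confidence intervals are 95% Wald intervals on the log scale.
    """
    if ties not in ("breslow", "efron"):
        raise InputError("ties must be 'breslow' or 'efron'")
    if isinstance(covariates, pd.Series):
        covariates = covariates.to_frame()
    names = list(covariates.columns)
    x = covariates.to_numpy(dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if x.ndim != 2 or len(x) != len(times) or len(times) != len(events):
        raise InputError("covariates, times and events must have matching lengths")
    if events.sum() < 1:
        raise InputError("at least one event is required")
    sds = x.std(axis=0)
    if (sds == 0).any():
        bad = [names[i] for i in np.flatnonzero(sds == 0)]
        raise InputError(f"constant covariates cannot be fit: {bad}")

    beta = np.zeros(x.shape[1])
    ll, grad, info = _cox_loglik_derivs(beta, x, times, events, ties)
    for _ in range(max_iter):
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError as err:
            raise AnalysisError(f"singular information matrix: {err}") from err
        # step halving keeps the likelihood ascending
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * step
            ll_new, grad_new, info_new = _cox_loglik_derivs(cand, x, times, events, ties)
            if ll_new >= ll - 1e-12:
                break
            scale /= 2.0
        beta, ll, grad, info = cand, ll_new, grad_new, info_new
        if np.abs(beta).max() > 100:
            raise AnalysisError(
                "coefficient diverging (monotone likelihood / perfect separation)"
            )
        if np.abs(scale * step).max() < tol:
            break
    else:
        raise AnalysisError(f"Cox fit did not converge in {max_iter} iterations")

    cov = np.linalg.inv(info)
    se = np.sqrt(np.diag(cov))
    zstat = beta / se
    pvals = stats.chi2.sf(zstat**2, df=1)
    zcrit = stats.norm.ppf(0.975)
    summary = pd.DataFrame(
        {
            "coef": beta,
            "se": se,
            "hr": np.exp(beta),
            "hr_ci_low": np.exp(beta - zcrit * se),
            "hr_ci_high": np.exp(beta + zcrit * se),
            "p": pvals,
        },
        index=pd.Index(names, name="covariate"),
    )
    return CoxModel(
        summary=summary,
        loglik=float(ll),
        ties=ties,
        n=len(times),
        n_events=int(events.sum()),
    )


def stepwise_cox(
    covariates: pd.DataFrame,
    times,
    events,
    p_enter: float = 0.05,
    p_remove: float = 0.10,
    ties: str = "breslow",
) -> CoxModel:
    """Forward selection with backward pruning on Wald p-values.

    At each forward step the candidate with the smallest Wald p below
    ``p_enter`` enters (ties broken lexicographically by name); after
    each entry, covariates whose p rises above ``p_remove`` are dropped,
    worst first. Deterministic given the input.
    """
    if covariates.shape[1] < 1:
        raise InputError("stepwise selection needs at least one candidate covariate")
    selected: list[str] = []
    while True:
        changed = False
        best: tuple[float, str] | None = None
        for name in covariates.columns:
            if name in selected:
                continue
            try:
                model = cox_fit(covariates[selected + [name]], times, events, ties=ties)
            except (AnalysisError, InputError):
                continue
            p = float(model.summary.at[name, "p"])
            if p < p_enter and (best is None or (p, name) < best):
                best = (p, name)
        if best is not None:
            selected.append(best[1])
            changed = True
        # backward pruning
        while selected:
            model = cox_fit(covariates[selected], times, events, ties=ties)
            worst = model.summary["p"].sort_values(ascending=False)
            if worst.iloc[0] > p_remove:
                # drop the worst; lexicographic among exact ties
                wp = worst.iloc[0]
                name = sorted(worst.index[worst == wp])[0]
                selected.remove(name)
                changed = True
            else:
                break
        if not changed:
            break
    if not selected:
        empty = pd.DataFrame(
            columns=["coef", "se", "hr", "hr_ci_low", "hr_ci_high", "p"],
            index=pd.Index([], name="covariate"),
        )
        return CoxModel(
            summary=empty,
            loglik=float("nan"),
            ties=ties,
            n=len(np.asarray(times)),
            n_events=int(np.asarray(events, dtype=bool).sum()),
        )
    return cox_fit(covariates[selected], times, events, ties=ties)
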