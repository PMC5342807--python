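"""Patient-level aggregation, cutpoint discovery, and survival statistics.

The clinical question is whether high stromal collagen alignment predicts
poor overall survival after resection.  The machinery here mirrors the
standard workflow: average per-ROI alignment to a patient value, find an
optimal dichotomizing cutoff on a training cohort by scanning the log-rank
statistic over candidate thresholds, then validate with Kaplan-Meier /
log-rank and multivariable Cox regression (Efron ties, backward selection
with forced clinical covariates), plus the usual association tests.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats

from .synthetic import TUMOR_REGIONS

__all__ = [
    "aggregate_patient_alignment",
    "dichotomize",
    "CutoffResult",
    "find_cutoff",
    "KMEstimate",
    "km_estimate",
    "LogrankResult",
    "logrank_test",
    "CoxModelFit",
    "cox_fit",
    "select_candidates",
    "backward_select",
    "fisher_exact",
    "spearman",
    "GroupComparison",
    "group_compare",
]


def aggregate_patient_alignment(
    rois: pd.DataFrame,
    *,
    min_tumor_cores: int = 2,
    tumor_regions: tuple[str, ...] = TUMOR_REGIONS,
) -> pd.DataFrame:
    """Average tumor-region ROI alignment values to one value per patient.

    ``rois`` needs columns ``patient_id``, ``core_id``, ``region``, ``R``.
    Normal-region ROIs never enter the average.  Patients represented by
    fewer than ``min_tumor_cores`` distinct tumor cores are excluded with a
    reason, mirroring the inclusion rule that guards against sampling bias.

    Returns one row per patient: ``patient_id``, ``alignment``,
    ``n_tumor_cores``, ``n_rois``, ``included``, ``reason``.
    """
    required = {"patient_id", "core_id", "region", "R"}
    if missing := required - set(rois.columns):
        raise ValueError(f"ROI table missing columns: {sorted(missing)}")
    rows = []
    for pid, grp in rois.groupby("patient_id", sort=True):
        tumor = grp[grp["region"].isin(tumor_regions)]
        n_cores = tumor["core_id"].nunique()
        if n_cores < min_tumor_cores:
            rows.append(
                {
                    "patient_id": pid,
                    "alignment": float("nan"),
                    "n_tumor_cores": n_cores,
                    "n_rois": len(tumor),
                    "included": False,
                    "reason": f"cores<{min_tumor_cores}",
                }
            )
            continue
        rows.append(
            {
                "patient_id": pid,
                "alignment": float(tumor["R"].mean()),
                "n_tumor_cores": n_cores,
                "n_rois": len(tumor),
                "included": True,
                "reason": "",
            }
        )
    return pd.DataFrame(rows)


def dichotomize(values, cutoff: float = 0.60) -> np.ndarray:
    """Label each value ``'high'`` when >= cutoff, else ``'low'``."""
    v = np.asarray(values, dtype=float)
    return np.where(v >= cutoff, "high", "low")


def _logrank_chi2(times: np.ndarray, events: np.ndarray, group: np.ndarray) -> float:
    """Two-group log-rank chi-square via the O-E / hypergeometric-variance sum."""
    order = np.argsort(times, kind="stable")
    t, e, g = times[order], events[order], group[order].astype(bool)
    event_times = np.unique(t[e.astype(bool)])
    o = ex = v = 0.0
    for tj in event_times:
        at_risk = t >= tj
        nj = at_risk.sum()
        n1j = (at_risk & g).sum()
        died = (t == tj) & e.astype(bool)
        dj = died.sum()
        d1j = (died & g).sum()
        o += d1j
        ex += dj * n1j / nj
        if nj > 1:
            v += dj * (n1j / nj) * (1 - n1j / nj) * (nj - dj) / (nj - 1)
    if v <= 0:
        return 0.0
    return float((o - ex) ** 2 / v)


def _logrank_chi2_profile(
    times: np.ndarray, events: np.ndarray, values: np.ndarray, candidates: np.ndarray
) -> np.ndarray:
    """Log-rank chi-square at every candidate cutoff, fully vectorized.

    Shares the risk-set matrices across candidates: for event time j and
    cutoff k, ``n1[j, k]`` and ``d1[j, k]`` come from one matrix product
    with the (n x K) group-indicator matrix.
    """
    e_bool = events.astype(bool)
    tj = np.unique(times[e_bool])
    if tj.size == 0:
        return np.zeros(candidates.size)
    risk = times[None, :] >= tj[:, None]  # (m, n)
    died = (times[None, :] == tj[:, None]) & e_bool[None, :]
    high = (values[:, None] >= candidates[None, :]).astype(float)  # (n, K)
    nj = risk.sum(axis=1).astype(float)
    dj = died.sum(axis=1).astype(float)
    n1 = risk.astype(float) @ high  # (m, K)
    d1 = died.astype(float) @ high
    frac = n1 / nj[:, None]
    o_minus_e = (d1 - dj[:, None] * frac).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        vj = (dj * (nj - dj) / np.maximum(nj - 1, 1))[:, None] * frac * (1 - frac)
    v = vj.sum(axis=0)
    chi2 = np.zeros(candidates.size)
    ok = v > 0
    chi2[ok] = o_minus_e[ok] ** 2 / v[ok]
    return chi2


@dataclass
class CutoffResult:
    """Result of the exhaustive log-rank cutoff scan."""

    cutoff: float
    chi2: float
    p: float
    n_low: int
    n_high: int
    candidates: np.ndarray
    chi2_profile: np.ndarray
    permutation_p: float | None = None
    significant: bool = True


def find_cutoff(
    values,
    times,
    events,
    *,
    min_group_frac: float = 0.10,
    min_group_size: int | None = None,
    percentile_window: tuple[float, float] = (10.0, 90.0),
    n_permutations: int = 0,
    seed: int = 0,
) -> CutoffResult:
    """Scan candidate alignment cutoffs for the maximal log-rank separation.

    Candidates are the unique observed patient values inside the given
    percentile window; a candidate is admissible only when both resulting
    groups hold at least ``max(5, min_group_frac * n)`` patients (or
    ``min_group_size`` if given).  The returned cutoff maximizes the
    log-rank chi-square.  Because scanning optimizes the statistic, the
    nominal p at the maximum is optimistic; ``n_permutations > 0`` adds a
    permutation-adjusted p (distribution of the maximal statistic under
    label permutation).  ``significant`` is False when even the best
    cutpoint has p > 0.05 (using the permutation p when available).
    """
    v = np.asarray(values, dtype=float)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    n = v.size
    if n == 0 or np.unique(v).size < 2:
        raise ValueError("degenerate cutoff grid: need at least two distinct values")
    gmin = min_group_size if min_group_size is not None else max(5, int(math.ceil(min_group_frac * n)))
    lo, hi = np.percentile(v, percentile_window)
    candidates = np.unique(v)
    candidates = candidates[(candidates >= lo) & (candidates <= hi)]
    n_high = (v[:, None] >= candidates[None, :]).sum(axis=0)
    ok = (n_high >= gmin) & (n_high <= n - gmin)
    admissible = candidates[ok]
    if admissible.size == 0:
        raise ValueError("no candidate cutoff satisfies the group-size constraint")
    chi2s = _logrank_chi2_profile(t, e, v, admissible)
    best = int(np.argmax(chi2s))
    cutoff, chi2 = float(admissible[best]), float(chi2s[best])
    p = float(stats.chi2.sf(chi2, df=1))
    perm_p = None
    if n_permutations > 0:
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_permutations):
            perm = rng.permutation(n)
            mx = _logrank_chi2_profile(t[perm], e[perm], v, admissible).max()
            if mx >= chi2:
                count += 1
        perm_p = (count + 1) / (n_permutations + 1)
    effective_p = perm_p if perm_p is not None else p
    high = v >= cutoff
    return CutoffResult(
        cutoff=cutoff,
        chi2=chi2,
        p=p,
        n_low=int((~high).sum()),
        n_high=int(high.sum()),
        candidates=admissible,
        chi2_profile=chi2s,
        permutation_p=perm_p,
        significant=effective_p <= 0.05,
    )


@dataclass
class KMEstimate:
    """Product-limit survival curve with its median."""

    times: np.ndarray
    survival: np.ndarray
    median: float  # nan when S never reaches 0.5
    n: int
    n_events: int

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_estimate(times, events) -> KMEstimate:
    """Kaplan-Meier estimate; median is the smallest t with S(t) <= 0.5."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    kmf = KaplanMeierFitter()
    kmf.fit(t, e)
    sf = kmf.survival_function_
    med = kmf.median_survival_time_
    return KMEstimate(
        times=sf.index.to_numpy(dtype=float),
        survival=sf.iloc[:, 0].to_numpy(dtype=float),
        median=float(med) if np.isfinite(med) else float("nan"),
        n=t.size,
        n_events=int(e.sum()),
    )


@dataclass
class LogrankResult:
    chi2: float
    p: float


def logrank_test(times_a, events_a, times_b, events_b) -> LogrankResult:
    """Two-sided log-rank test between two samples."""
    res = _ll_logrank(
        np.asarray(times_a, float), np.asarray(times_b, float),
        event_observed_A=np.asarray(events_a, int),
        event_observed_B=np.asarray(events_b, int),
    )
    return LogrankResult(chi2=float(res.test_statistic), p=float(res.p_value))


@dataclass
class CoxModelFit:
    """Cox proportional-hazards fit: per-covariate effects and model info."""

    summary: pd.DataFrame  # index: covariate; columns: log_hr, hr, ci_lower, ci_upper, p
    log_likelihood: float
    n: int
    n_events: int
    ties: str = "efron"

    def hr(self, covariate: str) -> float:
        return float(self.summary.loc[covariate, "hr"])

    def p(self, covariate: str) -> float:
        return float(self.summary.loc[covariate, "p"])

    def ci(self, covariate: str) -> tuple[float, float]:
        row = self.summary.loc[covariate]
        return float(row["ci_lower"]), float(row["ci_upper"])


def cox_fit(
    data: pd.DataFrame,
    duration_col: str = "os_months",
    event_col: str = "event",
    covariates: list[str] | None = None,
) -> CoxModelFit:
    """Fit a Cox model by partial-likelihood maximization (Efron ties).

    Rows with missing values in the model columns are dropped
    (complete-case analysis).  Constant covariates or zero events raise.
    """
    cols = covariates if covariates is not None else [
        c for c in data.columns if c not in (duration_col, event_col)
    ]
    df = data[[duration_col, event_col, *cols]].dropna()
    if df[event_col].sum() < 1:
        raise ValueError("no events in data")
    for c in cols:
        if df[c].nunique() < 2:
            raise ValueError(f"covariate {c!r} is constant")
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(df, duration_col=duration_col, event_col=event_col)
    s = cph.summary
    summary = pd.DataFrame(
        {
            "log_hr": s["coef"],
            "hr": s["exp(coef)"],
            "ci_lower": np.exp(s["coef lower 95%"]),
            "ci_upper": np.exp(s["coef upper 95%"]),
            "p": s["p"],
        }
    )
    return CoxModelFit(
        summary=summary,
        log_likelihood=float(cph.log_likelihood_),
        n=len(df),
        n_events=int(df[event_col].sum()),
    )


def select_candidates(univariate_p: dict[str, float], threshold: float = 0.25) -> list[str]:
    """Covariates passing the univariate screen (p < threshold)."""
    return [name for name, p in univariate_p.items() if p < threshold]


def backward_select(
    data: pd.DataFrame,
    candidates: list[str],
    forced: list[str],
    *,
    duration_col: str = "os_months",
    event_col: str = "event",
    threshold: float = 0.25,
    univariate_p: dict[str, float] | None = None,
) -> CoxModelFit:
    """Backward elimination around a forced clinical-covariate core.

    The initial model holds the forced covariates plus every candidate
    whose univariate p (supplied, or computed here from single-covariate
    Cox fits) is below ``threshold``.  The highest-p non-forced covariate
    at or above ``threshold`` is dropped and the model refit until all
    remaining non-forced covariates fall below the threshold.  Forced
    covariates are never dropped.
    """
    if univariate_p is None:
        univariate_p = {}
        for c in candidates:
            try:
                univariate_p[c] = cox_fit(
                    data, duration_col, event_col, covariates=[c]
                ).p(c)
            except ValueError:
                univariate_p[c] = 1.0
    current = list(dict.fromkeys(select_candidates(univariate_p, threshold) + list(forced)))
    if not current:
        raise ValueError("no covariates to fit (empty initial model)")
    while True:
        fit = cox_fit(data, duration_col, event_col, covariates=current)
        droppable = {
            c: fit.p(c) for c in current if c not in forced and fit.p(c) >= threshold
        }
        if not droppable:
            return fit
        worst = max(droppable, key=droppable.get)
        current.remove(worst)
        if not current:
            return fit


def fisher_exact(table) -> float:
    """Two-sided Fisher exact p for a 2x2 count table.

    Sums hypergeometric probabilities of all tables (fixed margins) no more
    probable than the observed one.  Rows with unknown category membership
    must be excluded before tabulation.
    """
    tab = np.asarray(table, dtype=int)
    if tab.shape != (2, 2) or (tab < 0).any():
        raise ValueError("expected a non-negative 2x2 table")
    return float(stats.fisher_exact(tab, alternative="two-sided")[1])


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation (midranks for ties) with two-sided p."""
    rho, p = stats.spearmanr(np.asarray(x, float), np.asarray(y, float))
    return float(rho), float(p)


@dataclass
class GroupComparison:
    """Nonparametric group comparison with recorded normality screens."""

    test: str
    statistic: float
    p: float
    shapiro_p: list[float] = field(default_factory=list)


def group_compare(groups: list) -> GroupComparison:
    """Mann-Whitney U for two groups, Kruskal-Wallis for three or more.

    Shapiro-Wilk normality p-values per group are recorded alongside the
    result (the screen that motivates the nonparametric choice); groups
    too small for Shapiro-Wilk record NaN.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    shapiro_p = []
    for a in arrays:
        if a.size >= 3 and np.ptp(a) > 0:
            shapiro_p.append(float(stats.shapiro(a).pvalue))
        else:
            shapiro_p.append(float("nan"))
    if len(arrays) == 2:
        if np.array_equal(arrays[0], arrays[1]):
            return GroupComparison("mann-whitney-u", float(arrays[0].size ** 2 / 2), 1.0, shapiro_p)
        stat, p = stats.mannwhitneyu(arrays[0], arrays[1], alternative="two-sided")
        return GroupComparison("mann-whitney-u", float(stat), float(p), shapiro_p)
    stat, p = stats.kruskal(*arrays)
    return GroupComparison("kruskal-wallis", float(stat), float(p), shapiro_p)
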