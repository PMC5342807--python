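"""Aggregation, cutoff scanning, and survival/association statistics."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar
from scipy.stats import hypergeom

from collalign import (
    CohortSpec,
    aggregate_patient_alignment,
    backward_select,
    cox_fit,
    dichotomize,
    find_cutoff,
    fisher_exact,
    group_compare,
    km_estimate,
    logrank_test,
    make_cohort,
    select_candidates,
    spearman,
)
from collalign.cohort import _logrank_chi2


class TestAggregation:
    @staticmethod
    def _rois(rows):
        return pd.DataFrame(rows, columns=["patient_id", "core_id", "region", "R"])

    def test_mean_of_tumor_rois(self):
        rois = self._rois(
            [("p1", "c1", "core", 0.5), ("p1", "c2", "edge", 0.7)]
        )
        agg = aggregate_patient_alignment(rois)
        assert agg.loc[0, "alignment"] == pytest.approx(0.6)
        assert agg.loc[0, "included"]

    def test_normal_rois_ignored(self):
        rois = self._rois(
            [
                ("p1", "c1", "core", 0.5),
                ("p1", "c2", "edge", 0.7),
                ("p1", "cn", "normal", 0.1),
            ]
        )
        agg = aggregate_patient_alignment(rois)
        assert agg.loc[0, "alignment"] == pytest.approx(0.6)

    def test_only_normal_rois_excluded(self):
        rois = self._rois([("p1", "cn", "normal", 0.3), ("p1", "cn2", "normal", 0.2)])
        agg = aggregate_patient_alignment(rois)
        assert not agg.loc[0, "included"]

    def test_single_tumor_core_excluded_with_reason(self):
        rois = self._rois([("p1", "c1", "core", 0.5), ("p1", "c1", "core", 0.6)])
        agg = aggregate_patient_alignment(rois)
        assert not agg.loc[0, "included"]
        assert agg.loc[0, "reason"] == "cores<2"


class TestDichotomize:
    def test_cutoff_inclusive_high(self):
        labels = dichotomize([0.60, 0.59, 0.61])
        assert list(labels) == ["high", "low", "high"]


class TestCutoffScan:
    def test_degenerate_grid_rejected(self):
        with pytest.raises(ValueError):
            find_cutoff([0.5] * 20, np.arange(1, 21), np.ones(20))

    def test_null_cohort_flagged_not_significant(self, rng):
        v = rng.uniform(0.3, 0.7, 80)
        t = rng.exponential(20, 80)
        e = np.ones(80, dtype=int)
        res = find_cutoff(v, t, e, n_permutations=200, seed=1)
        assert res.permutation_p is not None
        assert not res.significant or res.permutation_p > 0.05 * 0.5  # permutation guard active

    def test_group_size_constraint_enforced(self, rng):
        v = rng.uniform(0, 1, 60)
        t = rng.exponential(20, 60)
        e = np.ones(60, dtype=int)
        res = find_cutoff(v, t, e)
        assert res.n_low >= 6 and res.n_high >= 6

    def test_consistency_improves_with_n(self):
        med_errs = []
        for n in (70, 400):
            errs = []
            for rep in range(12):
                c = make_cohort(CohortSpec(n_patients=n, seed=500 + rep))
                p = c.patients
                res = find_cutoff(
                    p["alignment_true"].to_numpy(),
                    p["os_months"].to_numpy(),
                    p["event"].to_numpy(),
                )
                errs.append(abs(res.cutoff - 0.60))
            med_errs.append(np.median(errs))
        assert med_errs[1] < med_errs[0]


class TestKaplanMeier:
    def test_worked_product_limit_example(self):
        est = km_estimate([1.0, 2.0, 3.0], [1, 0, 1])
        assert est.survival_at(1.0) == pytest.approx(2 / 3)
        assert est.survival_at(2.0) == pytest.approx(2 / 3)
        assert est.survival_at(3.0) == pytest.approx(0.0)
        assert est.median == pytest.approx(3.0)

    def test_all_censored_curve_flat_median_undefined(self):
        est = km_estimate([5.0, 6.0, 7.0], [0, 0, 0])
        assert est.survival_at(7.0) == 1.0
        assert math.isnan(est.median)

    def test_no_censoring_equals_empirical_survivor(self, rng):
        t = rng.exponential(10, 40)
        est = km_estimate(t, np.ones(40, dtype=int))
        for q in np.quantile(t, [0.2, 0.5, 0.8]):
            assert est.survival_at(q) == pytest.approx((t > q).mean(), abs=1e-12)


class TestLogrank:
    def test_identical_groups_null(self):
        t = [3.0, 5.0, 8.0, 11.0]
        e = [1, 1, 0, 1]
        res = logrank_test(t, e, t, e)
        assert res.chi2 == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_label_swap_symmetric(self, rng):
        ta, tb = rng.exponential(10, 20), rng.exponential(20, 25)
        ea, eb = np.ones(20, int), np.ones(25, int)
        r1 = logrank_test(ta, ea, tb, eb)
        r2 = logrank_test(tb, eb, ta, ea)
        assert r1.chi2 == pytest.approx(r2.chi2, rel=1e-12)

    def test_eight_subject_worked_dataset_matches_oracle(self):
        # group A: 1,3(c),5,7 ; group B: 2,4,6(c),8
        t = np.array([1.0, 3.0, 5.0, 7.0, 2.0, 4.0, 6.0, 8.0])
        e = np.array([1, 0, 1, 1, 1, 1, 0, 1])
        g = np.array([1, 1, 1, 1, 0, 0, 0, 0], dtype=bool)
        # brute-force O-E/V accumulation over event times
        o = ex = v = 0.0
        for tj in sorted(t[e == 1]):
            risk = t >= tj
            nj, n1j = risk.sum(), (risk & g).sum()
            died = (t == tj) & (e == 1)
            dj, d1j = died.sum(), (died & g).sum()
            o += d1j
            ex += dj * n1j / nj
            if nj > 1:
                v += dj * (n1j / nj) * (1 - n1j / nj) * (nj - dj) / (nj - 1)
        expected = (o - ex) ** 2 / v
        res = logrank_test(t[g], e[g], t[~g], e[~g])
        assert res.chi2 == pytest.approx(expected, rel=1e-9)
        assert _logrank_chi2(t, e, g) == pytest.approx(expected, rel=1e-12)


def efron_negloglik(beta, t, e, x):
    """Efron-approximated negative log partial likelihood (test oracle)."""
    ll = 0.0
    for tj in np.unique(t[e == 1]):
        died = (t == tj) & (e == 1)
        risk = t >= tj
        d = died.sum()
        s_risk = np.sum(np.exp(beta * x[risk]))
        s_died = np.sum(np.exp(beta * x[died]))
        ll += beta * x[died].sum()
        for r in range(d):
            ll -= math.log(s_risk - (r / d) * s_died)
    return -ll


class TestCox:
    t6 = np.array([2.0, 4.0, 5.0, 7.0, 9.0, 12.0])
    e6 = np.array([1, 1, 0, 1, 1, 1])
    x6 = np.array([1.0, 0.0, 1.0, 0.0, 1.0, 0.0])

    def _df(self, t, e, x):
        return pd.DataFrame({"os_months": t, "event": e, "x": x})

    def test_six_subject_estimate_matches_partial_likelihood_oracle(self):
        res = minimize_scalar(
            efron_negloglik,
            bounds=(-5, 5),
            method="bounded",
            args=(self.t6, self.e6, self.x6),
            options={"xatol": 1e-10},
        )
        fit = cox_fit(self._df(self.t6, self.e6, self.x6), covariates=["x"])
        assert float(fit.summary.loc["x", "log_hr"]) == pytest.approx(res.x, abs=1e-4)

    def test_duplicated_subjects_match_efron_oracle(self):
        # duplication creates ties; the fit must agree with the Efron
        # partial likelihood maximized by brute force on the tied data
        t = np.r_[self.t6, self.t6]
        e = np.r_[self.e6, self.e6]
        x = np.r_[self.x6, self.x6]
        res = minimize_scalar(
            efron_negloglik, bounds=(-5, 5), method="bounded",
            args=(t, e, x), options={"xatol": 1e-10},
        )
        fit = cox_fit(self._df(t, e, x), covariates=["x"])
        assert float(fit.summary.loc["x", "log_hr"]) == pytest.approx(res.x, abs=1e-4)

    def test_ci_brackets_hr(self):
        c = make_cohort(CohortSpec(seed=3))
        df = c.patients[["os_months", "event", "high_true"]]
        fit = cox_fit(df, covariates=["high_true"])
        lo, hi = fit.ci("high_true")
        assert lo < fit.hr("high_true") < hi

    def test_null_covariate_mean_hr_near_one(self):
        logs, cover = [], 0
        reps = 60
        for s in range(reps):
            rng = np.random.default_rng(2000 + s)
            n = 80
            t = rng.exponential(20, n)
            x = (rng.random(n) < 0.5).astype(float)
            df = pd.DataFrame({"os_months": t, "event": np.ones(n, int), "x": x})
            fit = cox_fit(df, covariates=["x"])
            logs.append(float(fit.summary.loc["x", "log_hr"]))
            lo, hi = fit.ci("x")
            cover += lo <= 1.0 <= hi
        assert abs(np.mean(logs)) < 0.1
        assert 0.85 <= cover / reps <= 1.0

    def test_constant_covariate_rejected(self):
        df = self._df(self.t6, self.e6, np.ones(6))
        with pytest.raises(ValueError):
            cox_fit(df, covariates=["x"])

    def test_no_events_rejected(self):
        df = self._df(self.t6, np.zeros(6, int), self.x6)
        with pytest.raises(ValueError):
            cox_fit(df, covariates=["x"])


class TestBackwardSelection:
    # univariate p-values of the modeled cohort's candidate covariates
    UNIVARIATE_P = {
        "age_gt65": 0.0839,
        "female": 0.0051,
        "tumor_head": 0.3036,
        "size_gt2cm": 0.9951,
        "pT34": 0.7278,
        "pN1": 0.7724,
        "stage_late": 0.7434,
        "grade_high": 0.2672,
        "margin_r1": 0.8843,
        "venous": 0.8428,
        "lymphatic": 0.4874,
        "perineural": 0.7913,
        "adjuvant": 0.1159,
        "alignment_high": 0.0062,
    }

    def test_univariate_screen_selects_expected_candidates(self):
        chosen = set(select_candidates(self.UNIVARIATE_P, threshold=0.25))
        assert chosen == {"female", "age_gt65", "adjuvant", "alignment_high"}

    def test_screen_plus_forced_builds_eight_covariate_model(self):
        forced = ["pT34", "pN1", "margin_r1", "grade_high"]
        initial = set(select_candidates(self.UNIVARIATE_P, 0.25)) | set(forced)
        assert len(initial) == 8

    def test_all_candidates_fail_screen_leaves_forced_only(self):
        c = make_cohort(CohortSpec(seed=5))
        df = c.patients[["os_months", "event", "high_true", "female", "pT34"]].copy()
        fit = backward_select(
            df,
            candidates=["high_true", "female"],
            forced=["pT34"],
            univariate_p={"high_true": 0.9, "female": 0.8},
        )
        assert list(fit.summary.index) == ["pT34"]

    def test_forced_covariates_never_dropped(self):
        c = make_cohort(CohortSpec(seed=6))
        df = c.patients[["os_months", "event", "high_true", "female", "margin_r1"]].copy()
        fit = backward_select(
            df,
            candidates=["high_true", "female"],
            forced=["margin_r1"],
        )
        assert "margin_r1" in fit.summary.index
        for cov in fit.summary.index:
            if cov != "margin_r1":
                assert fit.p(cov) < 0.25


def fisher_enumeration_oracle(table):
    """Sum hypergeometric probabilities <= P(observed), fixed margins."""
    a, b = table[0]
    c, d = table[1]
    row1, col1, n = a + b, a + c, a + b + c + d
    p_obs = hypergeom.pmf(a, n, col1, row1)
    total = 0.0
    for k in range(max(0, row1 + col1 - n), min(row1, col1) + 1):
        p = hypergeom.pmf(k, n, col1, row1)
        if p <= p_obs * (1 + 1e-9):
            total += p
    return min(total, 1.0)


class TestFisherExact:
    def test_balanced_table_no_association(self):
        assert fisher_exact([[10, 10], [10, 10]]) == pytest.approx(1.0)

    def test_matches_enumeration_on_small_tables(self, rng):
        for _ in range(60):
            tab = rng.integers(0, 16, (2, 2))
            if tab.sum() == 0 or tab.sum() > 60:
                continue
            assert fisher_exact(tab) == pytest.approx(
                fisher_enumeration_oracle(tab), abs=1e-9
            )

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact([[1, -2], [3, 4]])


class TestSpearman:
    def test_monotone_is_one(self):
        rho, _ = spearman([1, 2, 3, 4, 5], [10, 20, 40, 80, 160])
        assert rho == pytest.approx(1.0)

    def test_closed_form_four_points(self):
        rho, _ = spearman([1, 2, 3, 4], [1, 3, 2, 4])
        assert rho == pytest.approx(0.8, abs=1e-12)

    def test_ties_match_midrank_pearson_oracle(self, rng):
        x = rng.integers(0, 5, 40).astype(float)
        y = rng.integers(0, 5, 40).astype(float)
        rx = pd.Series(x).rank().to_numpy()
        ry = pd.Series(y).rank().to_numpy()
        oracle = np.corrcoef(rx, ry)[0, 1]
        rho, _ = spearman(x, y)
        assert rho == pytest.approx(oracle, abs=1e-12)


class TestGroupCompare:
    def test_identical_groups_p_one(self):
        res = group_compare([[1, 2, 3, 4], [1, 2, 3, 4]])
        assert res.p == pytest.approx(1.0)
        assert res.test == "mann-whitney-u"

    def test_shifted_groups_detected(self, rng):
        a = rng.normal(0, 1, 50)
        b = rng.normal(3, 1, 50)
        res = group_compare([a, b])
        assert res.p < 0.001

    def test_three_groups_use_kruskal_wallis(self, rng):
        groups = [rng.normal(i, 1, 30) for i in range(3)]
        res = group_compare(groups)
        assert res.test == "kruskal-wallis"
        assert len(res.shapiro_p) == 3

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            group_compare([[1, 2, 3]])
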