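import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gsas import (
    ClinicalTable,
    bh_fdr,
    binarize_grade,
    cluster_gsas,
    cox_score_test,
    fit_cox,
    km_logrank,
    robust_intersection,
    screen_collection,
)
from gsas.survival import SurvivalScreenResult


def make_clinical(times, events, **extra):
    samples = [f"s{i}" for i in range(len(times))]
    return ClinicalTable(
        pd.DataFrame(
            {"time": list(map(float, times)), "event": list(map(float, events)), **extra},
            index=pd.Index(samples, name="sample"),
        )
    ), samples


class TestFitCox:
    def test_grade_binarization_rule(self):
        grade = pd.Series([1.0, 2.0, 3.0, 2.0])
        assert list(binarize_grade(grade)) == [0.0, 1.0, 1.0, 1.0]

    def test_grade_binarization_missing_preserved(self):
        out = binarize_grade(pd.Series([1.0, np.nan, 3.0]))
        assert out.iloc[0] == 0.0 and np.isnan(out.iloc[1]) and out.iloc[2] == 1.0

    def test_constant_score_degenerate(self):
        clin, samples = make_clinical(range(1, 11), [1] * 10)
        res = fit_cox(pd.Series(0.7, index=samples), clin)
        assert res.coefficient == 0.0
        assert res.hazard_ratio == 1.0
        assert res.wald_p == 1.0
        assert res.converged

    def test_hr_equals_exp_coef(self):
        rng = np.random.default_rng(4)
        clin, samples = make_clinical(
            rng.uniform(1, 50, 30).round(3), (rng.random(30) < 0.8).astype(int)
        )
        res = fit_cox(pd.Series(rng.normal(size=30), index=samples), clin)
        assert res.hazard_ratio == pytest.approx(np.exp(res.coefficient), abs=1e-12)
        assert 0 < res.wald_p <= 1

    def test_missing_covariate_rows_dropped_and_counted(self):
        clin, samples = make_clinical(
            range(1, 9), [1] * 8, age=[50, 60, np.nan, 55, 58, 62, np.nan, 70]
        )
        rng = np.random.default_rng(0)
        res = fit_cox(pd.Series(rng.normal(size=8), index=samples), clin, covariates=("age",))
        assert res.n == 6
        assert res.n_dropped == 2

    def test_no_events_error(self):
        clin, samples = make_clinical([1, 2, 3], [0, 0, 0])
        with pytest.raises(ValueError, match="event"):
            fit_cox(pd.Series([1.0, 2.0, 3.0], index=samples), clin)

    def test_unknown_covariate_error(self):
        clin, samples = make_clinical(range(1, 6), [1] * 5)
        with pytest.raises(ValueError, match="unknown covariates"):
            fit_cox(pd.Series(1.0 * np.arange(5), index=samples), clin, covariates=("bmi",))

    def test_multivariate_adjustment_runs(self):
        rng = np.random.default_rng(2)
        n = 60
        clin, samples = make_clinical(
            rng.uniform(1, 80, n).round(2),
            (rng.random(n) < 0.7).astype(int),
            age=rng.normal(60, 8, n),
            grade=rng.choice([1.0, 2.0, 3.0], n),
        )
        res = fit_cox(
            pd.Series(rng.normal(size=n), index=samples),
            clin,
            covariates=("age", "grade_binary"),
        )
        assert set(res.effects) == {"score", "age", "grade_binary"}
        assert res.converged


class TestScoreTest:
    def test_score_test_equals_logrank_tie_free(self):
        rng = np.random.default_rng(3)
        n = 20
        times = rng.permutation(np.arange(1, n + 1)).astype(float)
        events = (rng.random(n) < 0.8).astype(float)
        events[:3] = 1.0
        x = (rng.random(n) < 0.5).astype(float)
        clin, samples = make_clinical(times, events)
        stat, p = cox_score_test(pd.Series(x, index=samples), clin)
        km = km_logrank(pd.Series(np.where(x > 0, 1.0, -1.0), index=samples), clin)
        assert stat == pytest.approx(km.chi_square, abs=1e-6)
        assert p == pytest.approx(km.p_value, abs=1e-6)


class TestKmLogrank:
    def test_dichotomization_about_zero(self):
        clin, samples = make_clinical([5, 10, 15], [1, 1, 1])
        km = km_logrank(pd.Series([-6.0, 1.0, 8.0], index=samples), clin)
        assert list(km.groups) == ["low", "high", "high"]

    def test_zero_goes_to_low_group(self):
        clin, samples = make_clinical([5, 10, 15, 20], [1, 1, 1, 1])
        km = km_logrank(pd.Series([0.0, -1.0, 2.0, 3.0], index=samples), clin)
        assert km.groups.iloc[0] == "low"

    def test_identical_groups_chi_square_zero(self):
        times = [3, 6, 9, 12, 3, 6, 9, 12]
        events = [1, 1, 0, 1, 1, 1, 0, 1]
        clin, samples = make_clinical(times, events)
        scores = pd.Series([1, 1, 1, 1, -1, -1, -1, -1], index=samples, dtype=float)
        km = km_logrank(scores, clin)
        assert km.chi_square == pytest.approx(0.0, abs=1e-12)
        assert km.p_value == pytest.approx(1.0, abs=1e-12)

    def test_hand_enumerated_logrank(self):
        # 8 samples, all events, no ties: observed-expected by hand.
        times = [1, 2, 3, 4, 5, 6, 7, 8]
        events = [1] * 8
        x = [1, 0, 1, 0, 1, 0, 1, 0]  # group of each sample (1 = high)
        # hand enumeration of the log-rank statistic
        o_minus_e = 0.0
        var = 0.0
        n1, n = 4, 8
        remaining = list(zip(times, x))
        for t, g in sorted(remaining):
            at_risk = [item for item in remaining if item[0] >= t]
            nr = len(at_risk)
            nr1 = sum(1 for item in at_risk if item[1] == 1)
            e = nr1 / nr
            o_minus_e += g - e
            var += e * (1 - e)
        expected_chi2 = o_minus_e**2 / var
        clin, samples = make_clinical(times, events)
        km = km_logrank(pd.Series(np.where(np.array(x) == 1, 2.0, -2.0), index=samples), clin)
        assert km.chi_square == pytest.approx(expected_chi2, rel=1e-9)

    def test_one_group_empty_error(self):
        clin, samples = make_clinical([1, 2, 3], [1, 1, 1])
        with pytest.raises(ValueError, match="Cox"):
            km_logrank(pd.Series([1.0, 2.0, 3.0], index=samples), clin)

    def test_km_no_censoring_is_empirical_survival(self):
        times = [2, 4, 6, 8]
        clin, samples = make_clinical(times * 2, [1] * 8)
        scores = pd.Series([1] * 4 + [-1] * 4, index=samples, dtype=float)
        km = km_logrank(scores, clin)
        high = km.curves["high"]
        surv = dict(zip(high["time"], high["survival"]))
        # empirical survival: S(t) = #{T > t} / n
        for t, expected in [(2, 0.75), (4, 0.5), (6, 0.25), (8, 0.0)]:
            assert surv[t] == pytest.approx(expected, abs=1e-12)

    def test_km_curves_monotone_from_one(self):
        rng = np.random.default_rng(9)
        clin, samples = make_clinical(
            rng.uniform(1, 60, 30).round(1), (rng.random(30) < 0.6).astype(int)
        )
        km = km_logrank(pd.Series(rng.normal(size=30), index=samples), clin)
        for curve in km.curves.values():
            s = curve["survival"].to_numpy()
            assert s[0] == 1.0
            assert (np.diff(s) <= 1e-12).all()


class TestBhFdr:
    def test_hand_computation(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p(self):
        assert bh_fdr([0.2])[0] == pytest.approx(0.2)

    def test_all_ones(self):
        np.testing.assert_array_equal(bh_fdr([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])
        with pytest.raises(ValueError):
            bh_fdr([-0.1])

    def test_order_preserving(self):
        p = [0.04, 0.001, 0.3, 0.02]
        q = bh_fdr(p)
        assert q[1] == min(q)
        # q-values monotone in p
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=40))
    @settings(max_examples=50, deadline=None)
    def test_properties(self, p):
        q = bh_fdr(p)
        assert ((q >= np.asarray(p) - 1e-15) | np.isclose(q, p)).all()
        assert (q <= 1.0 + 1e-15).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()


def make_screen(dataset, names, pvals, hrs=None):
    hrs = hrs if hrs is not None else [1.5] * len(names)
    table = pd.DataFrame(
        {"coef": np.log(hrs), "hr": hrs, "p": pvals, "q": bh_fdr(pvals)},
        index=pd.Index(names, name="set"),
    )
    return SurvivalScreenResult(dataset=dataset, table=table)


class TestRobustIntersection:
    def test_significant_in_all_but_one_excluded(self):
        names = ["A", "B"]
        screens = [make_screen(f"d{i}", names, [0.01, 0.01]) for i in range(6)]
        screens.append(make_screen("d6", names, [0.01, 0.2]))
        robust, report = robust_intersection(screens, alpha=0.05)
        assert robust == ["A"]
        assert "p_d6" in report.columns

    def test_alpha_one_returns_all_common(self):
        screens = [
            make_screen("d0", ["A", "B", "C"], [0.5, 0.9, 0.99]),
            make_screen("d1", ["B", "C", "D"], [0.5, 0.9, 0.99]),
        ]
        robust, _ = robust_intersection(screens, alpha=1.01)
        assert robust == ["B", "C"]

    def test_disjoint_collections_error(self):
        screens = [make_screen("d0", ["A"], [0.01]), make_screen("d1", ["B"], [0.01])]
        with pytest.raises(ValueError, match="share no"):
            robust_intersection(screens)

    def test_needs_two_screens(self):
        with pytest.raises(ValueError):
            robust_intersection([make_screen("d0", ["A"], [0.01])])

    def test_matches_brute_force_on_benchmark(self, small_benchmark, small_scored):
        screens = [screen for _, screen in small_scored]
        robust, _ = robust_intersection(screens, alpha=0.05)
        brute = set(screens[0].table.index)
        for s in screens:
            brute &= {n for n in s.table.index if s.table.loc[n, "p"] < 0.05}
        assert set(robust) == brute
        # output size bounded by per-screen significant counts
        assert len(robust) <= min(len(s.significant(0.05)) for s in screens)


class TestScreenCollection:
    def test_screen_shape_and_q(self, small_scored):
        _, screen = small_scored[0]
        assert {"coef", "hr", "p", "q"} <= set(screen.table.columns)
        assert (screen.table["q"] >= screen.table["p"] - 1e-12).all()

    def test_planted_sets_deleterious(self, small_benchmark, small_scored):
        prog = small_benchmark.cohorts[0][2].program_set_names
        _, screen = small_scored[0]
        tab = screen.table.loc[prog]
        assert (tab["hr"] > 1).mean() >= 0.9
        assert (tab["p"] < 0.05).mean() >= 0.9


class TestClusterGsas:
    def test_identical_samples_merge_at_zero(self, small_scored):
        gsas, _ = small_scored[0]
        sub = gsas.data.iloc[:, :3].copy()
        sub["dup"] = sub.iloc[:, 0]
        from gsas.engine import GsasMatrix

        dup = GsasMatrix(data=sub, n_perm=gsas.n_perm, seed=gsas.seed)
        result = cluster_gsas(dup, gsas.set_names[:5])
        assert result.linkage_matrix[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_capping_rule(self, small_scored):
        gsas, _ = small_scored[0]
        result = cluster_gsas(gsas, gsas.set_names[:5])
        assert result.ordered_matrix.to_numpy().max() <= 3.0
        assert result.ordered_matrix.to_numpy().min() >= -3.0
        raw = gsas.data.loc[gsas.set_names[:5]].T
        big = raw[raw > 3.0]
        if big.notna().any().any():
            # a capped cell really was > 3 before capping
            r, c = np.argwhere(raw.to_numpy() > 3.0)[0]
            assert result.ordered_matrix.loc[raw.index[r], raw.columns[c]] == 3.0

    def test_two_latent_modes_recovered(self, small_benchmark, small_scored):
        expr, clinical, truth = small_benchmark.cohorts[0]
        gsas, screen = small_scored[0]
        prog = truth.program_set_names
        result = cluster_gsas(gsas, prog)
        modes = (truth.latent_activity > 0).astype(int)
        labels = result.labels.loc[modes.index]
        agree = max(
            (labels - 1 == modes).mean(),
            (2 - labels == modes).mean(),
        )
        assert agree >= 0.9

    def test_empty_subset_error(self, small_scored):
        gsas, _ = small_scored[0]
        with pytest.raises(ValueError):
            cluster_gsas(gsas, [])
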