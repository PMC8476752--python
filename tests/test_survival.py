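import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from icpscore.survival import (
    cox_fit,
    harrell_c,
    logrank,
    km_curve,
    max_sel_cutpoint,
    roc_auc,
    auc_at_horizon,
    correlate,
    group_compare,
    read_clinical,
    _cox_ll_grad_hess,
)

from conftest import make_clinical, random_survival


# ---------------------------------------------------------------------------
# independent oracles

def breslow_loglik(beta, x, time, event):
    """Literal Breslow partial log-likelihood, pure loops."""
    ll = 0.0
    for tk in sorted({t for t, e in zip(time, event) if e}):
        deaths = [i for i in range(len(time)) if time[i] == tk and event[i]]
        risk = [i for i in range(len(time)) if time[i] >= tk]
        denom = sum(np.exp(beta * x[i]) for i in risk)
        for i in deaths:
            ll += beta * x[i] - np.log(denom)
    return ll


def harrell_oracle(risk, time, event):
    """Exhaustive enumeration of comparable pairs."""
    num = den = 0.0
    n = len(risk)
    for i, j in itertools.permutations(range(n), 2):
        usable = event[i] == 1 and (
            time[i] < time[j] or (time[i] == time[j] and event[j] == 0)
        )
        if not usable:
            continue
        den += 1
        if risk[i] > risk[j]:
            num += 1
        elif risk[i] == risk[j]:
            num += 0.5
    return num / den


def auc_oracle(score, label):
    num = den = 0.0
    for i in range(len(score)):
        for j in range(len(score)):
            if label[i] == 1 and label[j] == 0:
                den += 1
                if score[i] > score[j]:
                    num += 1
                elif score[i] == score[j]:
                    num += 0.5
    return num / den


# ---------------------------------------------------------------------------
# Cox regression

class TestCoxFit:
    def test_breslow_matches_grid_search_oracle(self):
        x = np.array([1.0, 0, 1, 0, 1, 0])
        clin = make_clinical([1, 2, 3, 4, 5, 6], [1] * 6)
        fit = cox_fit(x, clin, ties="breslow")
        grid = np.arange(-5, 5, 1e-4)
        lls = [breslow_loglik(b, x, clin["time"].to_numpy(),
                              clin["event"].to_numpy()) for b in grid]
        assert fit.beta[0] == pytest.approx(grid[int(np.argmax(lls))], abs=1e-3)

    def test_breslow_grid_oracle_on_random_small_instances(self):
        rng = np.random.default_rng(77)
        grid = np.arange(-5, 5, 1e-3)
        checked = 0
        while checked < 10:
            x = rng.integers(0, 2, 8).astype(float)
            if x.sum() in (0, 8):
                continue
            t = rng.exponential(1.0, 8)
            clin = make_clinical(t, np.ones(8))
            fit = cox_fit(x, clin, ties="breslow")
            if not fit.converged:
                continue  # separated draw
            lls = [breslow_loglik(b, x, t, np.ones(8, dtype=int)) for b in grid]
            assert fit.beta[0] == pytest.approx(grid[int(np.argmax(lls))], abs=2e-3)
            checked += 1

    def test_covariate_negation_flips_beta_and_inverts_hr(self):
        rng = np.random.default_rng(11)
        x, clin = random_survival(rng, 60, beta=0.8, censor_scale=2.0)
        f1 = cox_fit(x, clin)
        f2 = cox_fit(-x, clin)
        assert f2.beta[0] == pytest.approx(-f1.beta[0], abs=1e-8)
        assert f2.hr[0] == pytest.approx(1 / f1.hr[0], rel=1e-8)

    def test_agrees_with_lifelines_efron(self):
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(0)
        x, clin = random_survival(rng, 150, beta=0.7, censor_scale=2.0)
        mine = cox_fit(x, clin, ties="efron")
        df = pd.DataFrame({"T": clin["time"], "E": clin["event"], "x": x})
        ref = lifelines.CoxPHFitter().fit(df, "T", "E")
        assert mine.beta[0] == pytest.approx(ref.params_["x"], abs=1e-4)
        assert mine.se[0] == pytest.approx(ref.standard_errors_["x"], abs=1e-4)

    def test_null_wald_p_is_calibrated(self):
        rng = np.random.default_rng(2024)
        rejections = 0
        reps = 400
        for _ in range(reps):
            x, clin = random_survival(rng, 200, beta=0.0)
            rejections += cox_fit(x, clin).wald_p[0] < 0.05
        assert 0.02 <= rejections / reps <= 0.09

    def test_multivariate_recovers_both_effects(self):
        rng = np.random.default_rng(5)
        n = 400
        X = rng.standard_normal((n, 2))
        t = rng.exponential(1 / np.exp(0.8 * X[:, 0] - 0.5 * X[:, 1]))
        clin = make_clinical(t, np.ones(n))
        fit = cox_fit(X, clin)
        assert fit.beta == pytest.approx([0.8, -0.5], abs=3 * fit.se.max())

    def test_zero_events_rejected(self):
        clin = make_clinical([1, 2, 3], [0, 0, 0])
        with pytest.raises(ValueError, match="events"):
            cox_fit(np.array([1.0, 2, 3]), clin)

    def test_constant_covariate_rejected(self):
        clin = make_clinical([1, 2, 3], [1, 1, 1])
        with pytest.raises(ValueError, match="constant"):
            cox_fit(np.ones(3), clin)

    def test_perfect_separation_flagged_not_silent(self):
        # covariate perfectly orders survival: monotone likelihood
        x = np.arange(20.0)
        clin = make_clinical(20.0 - np.arange(20.0), np.ones(20))
        fit = cox_fit(x, clin)
        assert not fit.converged

    def test_group_dying_strictly_first_is_separated(self):
        # the binary group whose members all fail first is also monotone
        x = np.array([1.0, 1, 1, 0, 0, 0])
        clin = make_clinical([1, 2, 3, 4, 5, 6], [1] * 6)
        assert not cox_fit(x, clin, ties="breslow").converged


class TestHarrellC:
    def test_perfect_concordance(self):
        clin = make_clinical([1, 2, 3], [1, 1, 1])
        assert harrell_c([3, 2, 1], clin) == 1.0
        assert harrell_c([1, 2, 3], clin) == 0.0

    def test_matches_exhaustive_pair_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(25):
            n = 8
            risk = rng.integers(0, 5, n).astype(float)  # ties likely
            t = rng.integers(1, 6, n).astype(float)
            e = (rng.random(n) > 0.3).astype(int)
            if e.sum() == 0:
                continue
            clin = make_clinical(t, e)
            try:
                mine = harrell_c(risk, clin)
            except ValueError:
                continue
            assert mine == harrell_oracle(risk, t, e)

    def test_complement_sums_to_one_on_tiefree_risks(self):
        rng = np.random.default_rng(4)
        risk = rng.permutation(np.arange(10.0))
        _, clin = random_survival(rng, 10, censor_scale=2.0)
        if clin["event"].sum() == 0:
            pytest.skip("no events drawn")
        assert harrell_c(risk, clin) + harrell_c(-risk, clin) == pytest.approx(1.0)


class TestLogrank:
    def test_identical_groups_give_null_statistic(self):
        clin = make_clinical([1, 2, 3, 1, 2, 3], [1, 0, 1, 1, 0, 1])
        chi2, p = logrank([0, 0, 0, 1, 1, 1], clin)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_equals_cox_breslow_score_test_on_tiefree_data(self):
        rng = np.random.default_rng(21)
        for _ in range(20):
            n = 40
            g = rng.random(n) > 0.5
            t = rng.exponential(1 / np.exp(0.5 * g))
            e = (rng.random(n) > 0.3).astype(int)
            if e.sum() == 0 or g.all() or (~g).all():
                continue
            clin = make_clinical(t, e)
            chi2, _ = logrank(g, clin)
            x = (g.astype(float) - g.mean())[:, None]
            o = np.argsort(t)
            _, grad, info = _cox_ll_grad_hess(
                np.zeros(1), x[o], t[o], e[o].astype(int), "breslow")
            assert chi2 == pytest.approx(grad[0] ** 2 / info[0, 0], abs=1e-8)

    def test_agrees_with_lifelines_under_ties(self):
        lifelines_stats = pytest.importorskip("lifelines.statistics")
        rng = np.random.default_rng(3)
        t = rng.integers(1, 8, 60).astype(float)
        e = (rng.random(60) > 0.25).astype(int)
        g = rng.random(60) > 0.5
        chi2, p = logrank(g, make_clinical(t, e))
        ref = lifelines_stats.logrank_test(t[g], t[~g], e[g], e[~g])
        assert chi2 == pytest.approx(ref.test_statistic, abs=1e-10)
        assert p == pytest.approx(ref.p_value, abs=1e-10)

    def test_permutation_null_mean_is_one(self):
        rng = np.random.default_rng(8)
        _, clin = random_survival(rng, 50, censor_scale=2.0)
        g = np.array([True] * 25 + [False] * 25)
        chis = []
        for _ in range(1000):
            chis.append(logrank(rng.permutation(g), clin)[0])
        # chi-square(1): mean 1, var 2
        se = np.sqrt(2 / len(chis))
        assert abs(np.mean(chis) - 1.0) < 3 * se

    def test_single_group_rejected(self):
        clin = make_clinical([1, 2], [1, 1])
        with pytest.raises(ValueError):
            logrank([1, 1], clin)


class TestKaplanMeier:
    def test_all_events_distinct_times(self):
        clin = make_clinical([1, 2, 3, 4], [1, 1, 1, 1])
        curve = km_curve(clin)
        np.testing.assert_allclose(curve.survival, [0.75, 0.5, 0.25, 0.0])
        np.testing.assert_array_equal(curve.at_risk, [4, 3, 2, 1])

    def test_no_censoring_matches_empirical_survival(self):
        rng = np.random.default_rng(12)
        t = rng.exponential(1.0, 30)
        clin = make_clinical(t, np.ones(30))
        curve = km_curve(clin)
        for tk, s in zip(curve.event_times, curve.survival):
            assert s == pytest.approx((t > tk).mean())

    def test_hand_computed_product_limit_with_heavy_censoring(self):
        # times 1+ 2 3+ 4 5+ 6 ; events at 2 (5 at risk), 4 (3), 6 (1)
        clin = make_clinical([1, 2, 3, 4, 5, 6], [0, 1, 0, 1, 0, 1])
        curve = km_curve(clin)
        np.testing.assert_allclose(
            curve.survival, [4 / 5, 4 / 5 * 2 / 3, 0.0])
        np.testing.assert_array_equal(curve.at_risk, [5, 3, 1])

    def test_matches_lifelines(self):
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(6)
        t = rng.integers(1, 10, 40).astype(float)
        e = (rng.random(40) > 0.4).astype(int)
        curve = km_curve(make_clinical(t, e))
        kmf = lifelines.KaplanMeierFitter().fit(t, e)
        ref = kmf.survival_function_at_times(curve.event_times).to_numpy()
        np.testing.assert_allclose(curve.survival, ref, atol=1e-12)

    def test_no_events_rejected(self):
        with pytest.raises(ValueError):
            km_curve(make_clinical([1, 2], [0, 0]))


class TestMaxSelCutpoint:
    def test_two_distinct_values_single_candidate(self):
        clin = make_clinical([1, 2, 3, 4], [1, 1, 1, 1])
        res = max_sel_cutpoint([0, 0, 1, 1], clin, minprop=0.2)
        assert res.cutoff == 0.5
        assert len(res.candidates) == 1

    def test_recovers_true_hazard_jump(self):
        rng = np.random.default_rng(17)
        n = 200
        score = rng.integers(1, 11, n).astype(float)
        rate = np.where(score > 5, 1.0, 0.1)
        clin = make_clinical(rng.exponential(1 / rate), np.ones(n))
        res = max_sel_cutpoint(score, clin)
        assert 5 < res.cutoff < 6

    def test_matches_exhaustive_scan_with_lifelines_statistic(self):
        lifelines_stats = pytest.importorskip("lifelines.statistics")
        rng = np.random.default_rng(23)
        n = 60
        score = rng.integers(0, 6, n).astype(float)
        _, clin = random_survival(rng, n, censor_scale=2.0)
        res = max_sel_cutpoint(score, clin, minprop=0.1)
        t, e = clin["time"].to_numpy(), clin["event"].to_numpy()
        best_cut, best_stat = None, -1.0
        for c in res.candidates:
            hi = score > c
            ref = lifelines_stats.logrank_test(t[hi], t[~hi], e[hi], e[~hi])
            z = np.sqrt(ref.test_statistic)
            if z > best_stat + 1e-12:
                best_cut, best_stat = c, z
        assert res.cutoff == best_cut
        assert res.max_stat == pytest.approx(best_stat, abs=1e-10)

    def test_minprop_excludes_extreme_candidates(self):
        clin = make_clinical(np.arange(1.0, 11), np.ones(10))
        # only 1 of 10 samples below/above either split: no valid candidate
        with pytest.raises(ValueError, match="candidate"):
            max_sel_cutpoint([1] + [2] * 9, clin, minprop=0.15)

    def test_constant_scores_rejected(self):
        clin = make_clinical([1, 2, 3], [1, 1, 1])
        with pytest.raises(ValueError):
            max_sel_cutpoint([2, 2, 2], clin)


class TestRocAuc:
    def test_perfect_and_constant_scores(self):
        y = [0, 0, 1, 1]
        assert roc_auc([0.1, 0.2, 0.8, 0.9], y) == 1.0
        assert roc_auc([1, 1, 1, 1], y) == 0.5

    def test_matches_pair_counting_oracle_with_ties(self):
        rng = np.random.default_rng(31)
        for _ in range(10):
            s = rng.integers(0, 4, 10).astype(float)
            y = rng.integers(0, 2, 10)
            if y.sum() in (0, 10):
                continue
            assert roc_auc(s, y) == pytest.approx(auc_oracle(s, y), abs=1e-12)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(32)
        s = rng.standard_normal(50)
        y = rng.integers(0, 2, 50)
        assert roc_auc(np.exp(s), y) == roc_auc(s, y)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1, 2], [1, 1])


class TestAucAtHorizon:
    def test_no_censoring_collapses_to_plain_auc(self):
        rng = np.random.default_rng(41)
        n = 80
        s = rng.standard_normal(n)
        t = rng.exponential(1 / np.exp(s))
        clin = make_clinical(t, np.ones(n))
        tau = float(np.median(t))
        label = ((t <= tau)).astype(int)
        assert auc_at_horizon(s, clin, tau) == pytest.approx(
            roc_auc(s, label), abs=1e-12)

    def test_oracle_risk_scores_give_auc_one(self):
        clin = make_clinical([1, 2, 3, 4, 5], np.ones(5))
        assert auc_at_horizon([-1, -2, -3, -4, -5], clin, 2.5) == 1.0

    def test_matches_scikit_survival_under_censoring(self):
        metrics = pytest.importorskip("sksurv.metrics")
        util = pytest.importorskip("sksurv.util")
        rng = np.random.default_rng(13)
        n = 150
        s = rng.standard_normal(n)
        t = rng.exponential(1 / np.exp(0.8 * s))
        c = rng.exponential(2.0, n)
        time, ev = np.minimum(t, c), (t <= c).astype(int)
        clin = make_clinical(time, ev)
        tau = float(np.quantile(time, 0.5))
        y = util.Surv.from_arrays(ev.astype(bool), time)
        ref = metrics.cumulative_dynamic_auc(y, y, s, [tau])[0][0]
        assert auc_at_horizon(s, clin, tau) == pytest.approx(ref, abs=1e-10)

    def test_bad_horizon_named_in_error(self):
        clin = make_clinical([5, 6, 7], [1, 1, 1])
        with pytest.raises(ValueError, match="t=1"):
            auc_at_horizon([1, 2, 3], clin, 1)


class TestAssociation:
    def test_correlate_exact_cases_and_hand_value(self):
        x = np.array([1.0, 2, 3, 4, 5])
        assert correlate(x, 2 * x + 1)[0] == pytest.approx(1.0)
        assert correlate(x, -x)[0] == pytest.approx(-1.0)
        y = np.array([2.0, 1, 4, 3, 5])
        # hand computation: r = cov(x,y)/(sd_x sd_y) = 0.8
        r, p = correlate(x, y)
        assert r == pytest.approx(0.8)
        assert 0 < p < 1

    def test_correlate_rejects_constant(self):
        with pytest.raises(ValueError):
            correlate([1, 1, 1], [1, 2, 3])

    def test_group_compare_null_and_separated(self):
        v = np.array([1.0, 2, 3, 4, 1, 2, 3, 4])
        g = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        assert group_compare(v, g, "wilcoxon") > 0.9
        v2 = np.concatenate([np.arange(10.0), np.arange(10.0) + 100])
        g2 = np.repeat([0, 1], 10)
        assert group_compare(v2, g2, "wilcoxon") < 0.01
        assert group_compare(v2, g2, "kruskal") < 0.01

    def test_wilcoxon_orders_like_exact_permutation_test(self):
        # p-values must rank datasets the same way the exact test does
        rng = np.random.default_rng(55)
        datasets = []
        for shift in (0.0, 0.5, 1.0, 2.0, 4.0):
            v = np.round(np.concatenate(
                [rng.normal(0, 1, 6), rng.normal(shift, 1, 6)]), 1)
            datasets.append(v)
        g = np.repeat([0, 1], 6)

        def exact_p(v):
            obs = stats.rankdata(v)[g == 1].sum()
            null = []
            for comb in itertools.combinations(range(12), 6):
                mask = np.zeros(12, bool)
                mask[list(comb)] = True
                null.append(stats.rankdata(v)[mask].sum())
            null = np.asarray(null)
            centre = null.mean()
            return np.mean(np.abs(null - centre) >= abs(obs - centre) - 1e-12)

        approx = [group_compare(v, g, "wilcoxon") for v in datasets]
        exact = [exact_p(v) for v in datasets]
        assert np.argsort(approx).tolist() == np.argsort(exact).tolist()

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            group_compare([1, 2, 3], [0, 0, 0], "wilcoxon")


class TestClinicalIO:
    def test_round_trip_with_annotations(self, tmp_path):
        path = tmp_path / "clin.tsv"
        path.write_text(
            "sample\ttime\tevent\tgrade\n"
            "p1\t10.5\t1\tII\n"
            "p2\t3.2\t0\tIV\n"
        )
        clin = read_clinical(path)
        assert clin.loc["p1", "time"] == 10.5
        assert clin["grade"].tolist() == ["II", "IV"]

    def test_invalid_times_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("sample\ttime\tevent\np1\t-1\t1\n")
        with pytest.raises(ValueError, match="positive"):
            read_clinical(path)
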