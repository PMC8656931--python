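import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from ccfrisk.exceptions import ValidationError
from ccfrisk.survival import (cox_fit, cox_loglik_grad_hess, compare_auc_z,
                              cv_choose_lambda, fit_scad_cox, km_estimate,
                              lambda_grid, logrank_test, logrank_z_at_cuts,
                              partition_risk, ph_test,
                              reverse_km_median_followup, scad_derivative,
                              scad_penalty, stability_selection, stepwise_bic,
                              td_auc)
from conftest import exp_surv


def grid_search_cox(x, time, event, lo=-4, hi=4, n=80001):
    """Brute-force partial-likelihood maximization over a fine beta grid."""
    grid = np.linspace(lo, hi, n)
    lls = [cox_loglik_grad_hess(np.array([b]), x[:, None], time, event)[0]
           for b in grid]
    i = int(np.argmax(lls))
    return grid[i], lls[i]


class TestCoxFit:
    def test_matches_grid_search_oracle(self, surv6):
        x, time, event = surv6
        fit = cox_fit(pd.DataFrame({"x": x}), time, event)
        b_star, ll_star = grid_search_cox(x, time, event)
        assert fit.params["x"] == pytest.approx(b_star, abs=1e-4)
        assert fit.loglik == pytest.approx(ll_star, abs=1e-4)

    def test_identical_groups_give_zero_coefficient(self):
        time = np.r_[1.0:9.0, 1.0:9.0]
        event = np.r_[np.ones(8), np.ones(8)].astype(int)
        x = np.r_[np.zeros(8), np.ones(8)]
        fit = cox_fit(pd.DataFrame({"x": x}), time, event)
        assert abs(fit.params["x"]) < 1e-8

    def test_matches_lifelines_with_ties(self):
        from lifelines import CoxPHFitter
        rng = np.random.default_rng(2)
        n, p = 150, 4
        X = pd.DataFrame(rng.normal(size=(n, p)),
                         columns=[f"x{i}" for i in range(p)])
        time, event = exp_surv(rng, X.to_numpy() @ [0.5, -0.5, 0.0, 0.3])
        time = np.ceil(time)  # force ties to exercise the Efron path
        fit = cox_fit(X, time, event)
        cph = CoxPHFitter().fit(X.assign(t=time, e=event), "t", "e")
        assert np.allclose(fit.params.to_numpy(), cph.params_.to_numpy(),
                           atol=1e-4)
        assert np.allclose(fit.bse.to_numpy(),
                           cph.standard_errors_.to_numpy(), atol=1e-4)

    def test_planted_effect_recovered(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            x = rng.normal(size=500)
            time, event = exp_surv(rng, 0.7 * x)
            fit = cox_fit(pd.DataFrame({"x": x}), time, event)
            hits += abs(fit.params["x"] - 0.7) <= 0.15
        assert hits >= 9

    def test_constant_covariate_dropped(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame({"c": np.ones(50), "x": rng.normal(size=50)})
        time, event = exp_surv(rng, np.zeros(50))
        fit = cox_fit(X, time, event)
        assert fit.dropped == ["c"] and list(fit.params.index) == ["x"]

    def test_separation_detected_and_flagged(self):
        time = np.array([1.0, 2, 3, 4, 5, 6])
        event = np.array([1, 1, 1, 1, 0, 0])
        x = np.array([0.0, 0, 0, 1, 1, 1])  # mutants all survive longest
        fit = cox_fit(pd.DataFrame({"x": x}), time, event)
        assert fit.separated == ["x"]


class TestScadPenalty:
    @pytest.mark.parametrize("beta,expected", [
        (0.0, 0.0),
        (0.5, 0.5),                      # linear region
        (2.0, 1.8148148148148149),       # quadratic clipping region
        (5.0, 2.35),                     # constant region (a+1)*lam^2/2
    ])
    def test_closed_forms(self, beta, expected):
        assert scad_penalty(beta, lam=1.0, a=3.7) == pytest.approx(expected,
                                                                   abs=1e-9)

    def test_continuity_at_region_boundaries(self):
        lam, a, eps = 0.7, 3.7, 1e-7
        for b in (lam, a * lam):
            below = scad_penalty(b - eps, lam, a)
            above = scad_penalty(b + eps, lam, a)
            assert abs(above - below) < 1e-6
            dbelow = scad_derivative(b - eps, lam, a)
            dabove = scad_derivative(b + eps, lam, a)
            assert abs(dabove - dbelow) < 1e-6

    def test_invalid_shape_rejected(self):
        with pytest.raises(ValidationError):
            scad_penalty(1.0, 1.0, a=2.0)


@pytest.fixture(scope="module")
def cox_data():
    rng = np.random.default_rng(11)
    n, p = 200, 8
    X = pd.DataFrame(rng.normal(size=(n, p)),
                     columns=[f"g{i}" for i in range(p)])
    beta = np.zeros(p)
    beta[:2] = [0.9, -1.0]
    time, event = exp_surv(rng, X.to_numpy() @ beta)
    return X, time, event


class TestScadCox:
    def test_zero_penalty_equals_unpenalized(self, cox_data):
        X, time, event = cox_data
        f0 = cox_fit(X, time, event)
        fs = fit_scad_cox(X, time, event, lam=0.0)
        assert np.max(np.abs(f0.params - fs.params)) < 1e-4

    def test_lambda_max_zeroes_everything(self, cox_data):
        X, time, event = cox_data
        lam_max = lambda_grid(X, time, event, n_lambda=2)[0]
        fs = fit_scad_cox(X, time, event, lam=lam_max)
        assert (fs.params == 0).all()

    def test_unbiasedness_region_single_covariate(self):
        # SCAD leaves large coefficients unshrunk: |beta| > a*lam
        rng = np.random.default_rng(4)
        x = rng.normal(size=400)
        time, event = exp_surv(rng, 1.2 * x)
        X = pd.DataFrame({"x": x})
        f0 = cox_fit(X, time, event)
        lam = abs(f0.params["x"]) / 3.7 * 0.8
        fs = fit_scad_cox(X, time, event, lam=lam)
        assert abs(fs.params["x"] - f0.params["x"]) < 1e-3

    def test_nonzero_count_monotone_along_path(self, cox_data):
        X, time, event = cox_data
        path = cv_choose_lambda(X, time, event, k=5, seed=3, n_lambda=15)
        nnz = path.n_nonzero()   # ordered from largest to smallest lambda
        assert all(b >= a - 1 for a, b in zip(nnz, nnz[1:]))

    def test_cv_deterministic_and_finite(self, cox_data):
        X, time, event = cox_data
        p1 = cv_choose_lambda(X, time, event, k=5, seed=7, n_lambda=10)
        p2 = cv_choose_lambda(X, time, event, k=5, seed=7, n_lambda=10)
        assert p1.chosen_lambda == p2.chosen_lambda
        pd.testing.assert_frame_equal(p1.coefs, p2.coefs)
        assert np.isfinite(p1.cv_deviance).all()

    def test_cv_requires_enough_events(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame({"x": rng.normal(size=30)})
        time = rng.exponential(10, 30)
        event = np.zeros(30, dtype=int)
        event[:3] = 1
        with pytest.raises(ValidationError, match="events"):
            cv_choose_lambda(X, time, event, k=10)

    def test_pure_noise_selects_near_empty(self):
        near_empty = 0
        for seed in range(6):
            rng = np.random.default_rng(500 + seed)
            X = pd.DataFrame(rng.normal(size=(250, 20)),
                             columns=[f"n{i}" for i in range(20)])
            time, event = exp_surv(rng, np.zeros(250))
            path = cv_choose_lambda(X, time, event, k=10, seed=seed,
                                    n_lambda=20)
            near_empty += len(path.selected) <= 2
        assert near_empty >= 5


class TestStepwiseBic:
    def test_bic_arithmetic_matches_hand_formula(self, surv6):
        x, time, event = surv6
        X = pd.DataFrame({"x": x})
        genes, fit, bic = stepwise_bic(["x"], X, time, event)
        if genes:  # formula check regardless of which model wins
            assert bic == pytest.approx(-2 * fit.loglik
                                        + len(genes) * np.log(event.sum()),
                                        abs=1e-10)

    def test_noise_covariate_removed(self):
        removed = 0
        for seed in range(10):
            rng = np.random.default_rng(900 + seed)
            X = pd.DataFrame({"signal": rng.normal(size=400),
                              "noise": rng.normal(size=400)})
            time, event = exp_surv(rng, 1.0 * X["signal"].to_numpy())
            genes, _, _ = stepwise_bic(["signal", "noise"], X, time, event)
            removed += genes == ["signal"]
        assert removed >= 9

    def test_strong_covariate_retained(self):
        rng = np.random.default_rng(21)
        X = pd.DataFrame({"x": rng.normal(size=300)})
        time, event = exp_surv(rng, 1.5 * X["x"].to_numpy())
        genes, fit, _ = stepwise_bic(["x"], X, time, event)
        assert genes == ["x"] and fit is not None

    def test_empty_candidates_give_empty_model(self):
        time = np.array([1.0, 2, 3])
        event = np.array([1, 1, 0])
        genes, fit, _ = stepwise_bic([], pd.DataFrame(index=range(3)),
                                     time, event)
        assert genes == [] and fit is None


class TestKaplanMeier:
    def test_hand_product_limit(self):
        curve = km_estimate(np.array([1.0, 2.0, 3.0]), np.array([1, 1, 1]))
        for t, s in [(1, 2 / 3), (2, 1 / 3), (3, 0.0)]:
            assert curve.survival_at(t) == pytest.approx(s)

    def test_all_censored_is_flat_one(self):
        curve = km_estimate(np.array([5.0, 7.0, 9.0]), np.zeros(3, int))
        assert curve.survival_at(100) == 1.0

    def test_matches_brute_force_risk_sets(self):
        rng = np.random.default_rng(8)
        time = np.round(rng.exponential(10, 40), 1) + 0.1
        event = rng.integers(0, 2, 40)
        curve = km_estimate(time, event)
        s = 1.0
        for t in np.unique(time[event == 1]):
            d = int(((time == t) & (event == 1)).sum())
            n_at = int((time >= t).sum())
            s *= 1 - d / n_at
            assert curve.survival_at(t) == pytest.approx(s, abs=1e-12)

    def test_reverse_km_followup(self):
        # all censored at 49.1 months: median follow-up is 49.1
        t = np.full(30, 49.1)
        med, lo, hi = reverse_km_median_followup(t, np.zeros(30, int))
        assert med == pytest.approx(49.1)
        # all events: undefined
        med, _, _ = reverse_km_median_followup(t, np.ones(30, int))
        assert np.isnan(med)

    def test_reverse_km_equals_flipped_indicator(self):
        rng = np.random.default_rng(9)
        time = rng.exponential(30, 80)
        event = rng.integers(0, 2, 80)
        med, _, _ = reverse_km_median_followup(time, event)
        curve = km_estimate(time, 1 - event)
        crossing = curve.times[np.flatnonzero(curve.survival <= 0.5)[0]]
        assert med == pytest.approx(crossing)


class TestLogrank:
    def test_identical_groups_statistic_zero(self):
        time = np.r_[1.0:9.0, 1.0:9.0]
        event = np.ones(16, int)
        groups = np.r_[np.zeros(8), np.ones(8)]
        stat, p, df = logrank_test(groups, time, event)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert df == 1

    def test_matches_observed_minus_expected_oracle(self):
        rng = np.random.default_rng(12)
        n = 30
        time = rng.exponential(10, n)
        event = rng.integers(0, 2, n)
        event[:5] = 1
        groups = rng.integers(0, 2, n)
        stat, _, _ = logrank_test(groups, time, event)
        # independent route: hypergeometric O-E over the risk sets
        oe, var = 0.0, 0.0
        for t in np.unique(time[event == 1]):
            at = time >= t
            d = int(((time == t) & (event == 1)).sum())
            d1 = int(((time == t) & (event == 1) & (groups == 1)).sum())
            n_at, n1 = int(at.sum()), int((at & (groups == 1)).sum())
            oe += d1 - d * n1 / n_at
            if n_at > 1:
                var += (d * (n1 / n_at) * (1 - n1 / n_at)
                        * (n_at - d) / (n_at - 1))
        assert stat == pytest.approx(oe ** 2 / var, rel=1e-9)

    def test_single_group_rejected(self):
        with pytest.raises(ValidationError):
            logrank_test(np.zeros(5), np.arange(1.0, 6.0), np.ones(5, int))

    def test_type_one_error_near_nominal(self):
        rng = np.random.default_rng(77)
        rejections = 0
        n_rep = 300
        for _ in range(n_rep):
            time = rng.exponential(10, 60)
            event = (rng.random(60) < 0.8).astype(int)
            groups = rng.integers(0, 2, 60)
            _, p, _ = logrank_test(groups, time, event)
            rejections += p < 0.05
        assert 0.025 <= rejections / n_rep <= 0.08


class TestPartition:
    def test_constant_scores_single_group(self):
        time = np.arange(1.0, 61.0)
        event = np.ones(60, int)
        cuts, strat = partition_risk(np.zeros(60), time, event)
        assert cuts == [] and strat.flagged
        assert (strat.groups == "low").all()

    def test_first_split_matches_exhaustive_scan(self):
        rng = np.random.default_rng(31)
        scores = rng.normal(size=20)
        time, event = exp_surv(rng, 1.5 * (scores > 0))
        cuts, _ = partition_risk(scores, time, event, max_groups=2,
                                 min_leaf=5)
        # independent route: scan every admissible midpoint with lifelines
        from lifelines.statistics import logrank_test as ll_logrank
        uniq = np.unique(scores)
        best, best_stat = None, -1
        for cut in (uniq[:-1] + uniq[1:]) / 2:
            g = scores > cut
            if g.sum() < 5 or (~g).sum() < 5:
                continue
            res = ll_logrank(time[g], time[~g], event[g], event[~g])
            if res.test_statistic > best_stat:
                best, best_stat = cut, res.test_statistic
        assert cuts[0] == pytest.approx(best)

    def test_three_planted_strata_recovered(self):
        hits = 0
        for seed in range(5):
            rng = np.random.default_rng(700 + seed)
            scores = rng.uniform(-1, 2, 240)
            lp = 1.3 * (scores > 0) + 1.3 * (scores > 1)
            time, event = exp_surv(rng, lp, baseline=0.02)
            cuts, strat = partition_risk(scores, time, event)
            if (len(cuts) == 2 and -0.5 < cuts[0] < 0.5
                    and 0.5 < cuts[1] < 1.5):
                hits += 1
        assert hits >= 4

    def test_group_km_curves_ordered(self):
        rng = np.random.default_rng(41)
        scores = rng.normal(size=300)
        time, event = exp_surv(rng, 1.2 * scores)
        _, strat = partition_risk(scores, time, event)
        for t in (12, 24, 36):
            s = [strat.km_curves[g].survival_at(t)
                 for g in ("low", "intermediate", "high")]
            assert s[0] >= s[1] >= s[2]

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValidationError):
            partition_risk(np.arange(10.0), np.arange(1.0, 11.0),
                           np.ones(10, int))


class TestTdAuc:
    def test_perfect_score_reaches_one(self):
        time = np.arange(1.0, 101.0)
        event = np.ones(100, int)
        scores = -time  # exact event-time rank
        res = td_auc(scores, time, event, horizon=36, n_boot=20, seed=0)
        assert res.auc == pytest.approx(1.0)

    def test_independent_score_near_half(self):
        rng = np.random.default_rng(55)
        time = rng.exponential(30, 2000)
        event = np.ones(2000, int)
        scores = rng.normal(size=2000)
        res = td_auc(scores, time, event, horizon=36, n_boot=20, seed=0)
        assert abs(res.auc - 0.5) < 0.03

    def test_censoring_free_equals_mann_whitney(self):
        rng = np.random.default_rng(66)
        time = rng.exponential(40, 300)
        event = np.ones(300, int)
        scores = -time + rng.normal(0, 20, 300)
        res = td_auc(scores, time, event, horizon=36, n_boot=20, seed=0)
        cases, ctrl = scores[time <= 36], scores[time > 36]
        mw = ((cases[:, None] > ctrl[None, :]).sum()
              + 0.5 * (cases[:, None] == ctrl[None, :]).sum())
        assert res.auc == pytest.approx(mw / (len(cases) * len(ctrl)),
                                        abs=1e-10)

    def test_no_events_before_horizon_rejected(self):
        with pytest.raises(ValidationError):
            td_auc(np.arange(5.0), np.full(5, 50.0), np.ones(5, int),
                   horizon=36)


class TestCompareAuc:
    @staticmethod
    def _cohort():
        rng = np.random.default_rng(13)
        n = 400
        signal = rng.normal(size=n)
        time, event = exp_surv(rng, 1.0 * signal, baseline=0.02)
        noise = rng.normal(size=n)
        return time, event, signal, noise

    def test_identical_scores_give_null_result(self):
        time, event, signal, _ = self._cohort()
        a = td_auc(signal, time, event, n_boot=50, seed=5)
        b = td_auc(signal.copy(), time, event, n_boot=50, seed=5)
        z, p = compare_auc_z(a, b)
        assert z == 0.0 and p == 1.0

    def test_antisymmetric_in_arguments(self):
        time, event, signal, noise = self._cohort()
        a = td_auc(signal, time, event, n_boot=50, seed=5)
        b = td_auc(noise, time, event, n_boot=50, seed=5)
        z_ab, p_ab = compare_auc_z(a, b)
        z_ba, p_ba = compare_auc_z(b, a)
        assert z_ab == pytest.approx(-z_ba)
        assert p_ab == pytest.approx(p_ba)

    def test_informative_beats_noise(self):
        time, event, signal, noise = self._cohort()
        a = td_auc(signal, time, event, n_boot=100, seed=5)
        b = td_auc(noise, time, event, n_boot=100, seed=5)
        z, p = compare_auc_z(a, b)
        assert z > 0 and p < 0.05

    def test_mismatched_resamples_rejected(self):
        time, event, signal, noise = self._cohort()
        a = td_auc(signal, time, event, n_boot=50, seed=5)
        b = td_auc(noise, time, event, n_boot=50, seed=6)
        with pytest.raises(ValidationError):
            compare_auc_z(a, b)


class TestPhTest:
    def test_single_covariate_matches_lifelines_oracle(self):
        from lifelines import CoxPHFitter
        from lifelines.statistics import proportional_hazard_test

        rng = np.random.default_rng(23)
        X = pd.DataFrame({"x": rng.normal(size=250)})
        time, event = exp_surv(rng, 0.6 * X["x"].to_numpy())
        fit = cox_fit(X, time, event)
        stat, p = ph_test(fit, X, time, event)
        cph = CoxPHFitter().fit(X.assign(t=time, e=event), "t", "e")
        res = proportional_hazard_test(cph, X.assign(t=time, e=event),
                                       time_transform="km")
        assert stat == pytest.approx(
            float(res.summary["test_statistic"].iloc[0]), rel=1e-3)
        assert p == pytest.approx(float(res.summary["p"].iloc[0]), rel=1e-2)

    def test_time_varying_effect_detected(self):
        detected = 0
        for seed in range(5):
            rng = np.random.default_rng(300 + seed)
            n = 400
            x = rng.integers(0, 2, n).astype(float)
            # effect reverses at t=15: clear proportional-hazards violation
            h0 = 0.05
            t1 = rng.exponential(1 / (h0 * np.exp(-1.0 * x)))
            t2 = 15 + rng.exponential(1 / (h0 * np.exp(1.5 * x)))
            t = np.where(t1 < 15, t1, t2)
            c = np.full(n, 60.0)
            time = np.minimum(t, c)
            event = (t <= c).astype(int)
            fit = cox_fit(pd.DataFrame({"x": x}), time, event)
            _, p = ph_test(fit, pd.DataFrame({"x": x}), time, event)
            detected += p < 0.05
        assert detected >= 4


class TestStability:
    def test_reproducible_and_signal_ranks_higher(self):
        rng = np.random.default_rng(99)
        n, p = 120, 10
        X = pd.DataFrame(rng.normal(size=(n, p)),
                         columns=[f"g{i}" for i in range(p)])
        time, event = exp_surv(rng, 1.2 * X["g0"].to_numpy())
        kwargs = dict(n_subsamples=15, seed=5, k=5, n_lambda=10)
        f1 = stability_selection(X, time, event, **kwargs)
        f2 = stability_selection(X, time, event, **kwargs)
        pd.testing.assert_series_equal(f1, f2)
        assert f1["g0"] > f1.drop("g0").median()
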