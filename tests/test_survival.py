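"""Survival statistics against hand computations and brute-force oracles."""

import numpy as np
import pandas as pd
import pytest

from confluencemorph.phantom import cohort_truth_frame, make_synthetic_cohort
from confluencemorph.survival import (
    SurvivalSample,
    backward_select,
    cox_fit,
    km_estimate,
    logrank_test,
    pearson_r,
    rcs_basis,
    rcs_hazard_curve,
    schoenfeld_check,
    td_roc,
)


def _sample(time, event, **cov):
    n = len(time)
    return SurvivalSample(
        np.asarray(time, float),
        np.asarray(event, bool),
        pd.DataFrame(cov) if cov else pd.DataFrame(index=range(n)),
    )


class TestKaplanMeier:
    def test_all_censored_curve_stays_at_one(self):
        km = km_estimate(_sample([1, 2, 3], [False, False, False]))
        assert km(0.0) == 1.0 and km(10.0) == 1.0

    def test_hand_product_limit(self):
        # event at 1 (risk 3), censored at 2, event at 3 (risk 1):
        # S(1) = 2/3, S(3) = 2/3 * 0 = 0
        km = km_estimate(_sample([1, 2, 3], [True, False, True]))
        assert km(1.0) == pytest.approx(2 / 3)
        assert km(2.5) == pytest.approx(2 / 3)
        assert km(3.0) == pytest.approx(0.0)

    def test_single_subject_step(self):
        km = km_estimate(_sample([5.0], [True]))
        assert km(4.99) == 1.0 and km(5.0) == 0.0

    def test_no_censoring_equals_empirical_survival(self, rng):
        t = rng.exponential(5.0, 60)
        km = km_estimate(_sample(t, np.ones(60, bool)))
        grid = np.quantile(t, [0.1, 0.4, 0.8])
        emp = np.array([(t > g).mean() for g in grid])
        assert np.allclose(km(grid), emp)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            _sample([-1.0], [True])


class TestLogrank:
    def test_identical_groups_null(self):
        g = _sample([1, 2, 3, 4], [True, True, False, True])
        stat, p = logrank_test(g, g)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_hand_computed_statistic(self):
        # A events at 1, 2; B events at 10, 11; no censoring.
        # Observed A = 2; E and V accumulated over the four event times:
        # t=1: n=4, nA=2, E=1/2, V=(2*2*3)/(16*3)=1/4
        # t=2: n=3, nA=1, E=1/3, V=(1*2*2)/(9*2)=2/9
        # t=10: n=2, nA=0 -> 0; t=11: n=1 -> 0
        # chi2 = (2 - 5/6)^2 / (1/4 + 2/9) = (7/6)^2 / (17/36)
        expected = (7 / 6) ** 2 / (17 / 36)
        stat, p = logrank_test(
            _sample([1, 2], [True, True]), _sample([10, 11], [True, True])
        )
        assert stat == pytest.approx(expected, rel=1e-9)

    def test_no_events_rejected(self):
        a = _sample([1, 2], [False, False])
        b = _sample([3, 4], [False, False])
        with pytest.raises(ValueError, match="event"):
            logrank_test(a, b)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            logrank_test(_sample([], []), _sample([1.0], [True]))


def _grid_search_beta(x, time, event, lo=-5.0, hi=5.0, num=200001):
    """Brute-force maximizer of the Breslow partial likelihood (1 covariate)."""
    betas = np.linspace(lo, hi, num)
    order = np.argsort(-time)
    xs, es = x[order], event[order]
    eta = np.outer(betas, xs)                       # (B, n)
    w = np.exp(eta)
    log_s0 = np.log(np.cumsum(w, axis=1))
    ll = np.where(es[None, :], eta - log_s0, 0.0).sum(axis=1)
    return betas[np.argmax(ll)]


TOY_TIME = np.array([1.0, 2.0, 3.5, 4.0, 5.5, 7.0, 8.0, 10.0])
TOY_EVENT = np.array([1, 1, 0, 1, 1, 0, 1, 1], dtype=bool)
TOY_X = np.array([1.0, 1.0, 0.0, 1.0, 0.0, 1.0, 0.0, 0.0])


class TestCox:
    def test_toy_fit_matches_grid_search(self):
        fit = cox_fit(_sample(TOY_TIME, TOY_EVENT, x=TOY_X))
        beta_grid = _grid_search_beta(TOY_X, TOY_TIME, TOY_EVENT)
        assert fit.coef("x") == pytest.approx(beta_grid, abs=1e-4)

    def test_exchangeable_groups_give_zero_coefficient(self):
        time = np.array([1.0, 2.0, 3.0, 4.0, 1.0, 2.0, 3.0, 4.0])
        event = np.array([1, 1, 0, 1, 1, 1, 0, 1], dtype=bool)
        x = np.array([0.0, 0, 0, 0, 1, 1, 1, 1])
        fit = cox_fit(_sample(time, event, x=x))
        assert abs(fit.coef("x")) < 1e-6

    def test_score_vanishes_at_maximizer(self, rng):
        n = 80
        x = rng.binomial(1, 0.5, n).astype(float)
        t = rng.exponential(1 / (0.2 * np.exp(0.6 * x)))
        sample = _sample(t, np.ones(n, bool), x=x)
        fit = cox_fit(sample)
        from confluencemorph.survival import _partial_loglik

        _, grad, _ = _partial_loglik(
            fit.beta, sample.covariates.to_numpy(), sample.time, sample.event
        )
        assert np.abs(grad).max() < 1e-8

    def test_matches_lifelines_without_ties(self, rng):
        # Breslow and Efron coincide on tie-free data
        from lifelines import CoxPHFitter

        n = 120
        x1, x2 = rng.normal(0, 1, n), rng.normal(0, 1, n)
        t = rng.exponential(1 / (0.1 * np.exp(0.4 * x1 - 0.3 * x2)))
        c = rng.exponential(15.0, n)
        time, event = np.minimum(t, c), t <= c
        fit = cox_fit(_sample(time, event, x1=x1, x2=x2))
        df = pd.DataFrame({"t": time, "e": event.astype(int), "x1": x1, "x2": x2})
        ll = CoxPHFitter().fit(df, "t", "e")
        assert np.allclose(fit.beta, ll.params_.to_numpy(), atol=1e-5)
        assert np.allclose(fit.se, ll.standard_errors_.to_numpy(), atol=1e-5)

    def test_hr_equals_exp_beta_and_ci_brackets(self):
        fit = cox_fit(_sample(TOY_TIME, TOY_EVENT, x=TOY_X))
        assert fit.hr[0] == np.exp(fit.beta[0])
        assert fit.ci_lower[0] <= fit.hr[0] <= fit.ci_upper[0]

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            cox_fit(_sample(TOY_TIME, TOY_EVENT, x=np.ones(8)))

    def test_too_few_events_rejected(self):
        with pytest.raises(ValueError, match="events"):
            cox_fit(_sample([1.0, 2.0, 3.0], [True, False, False], x=[0.0, 1.0, 2.0]))

    def test_simulated_cohort_recovery(self):
        # protective iTVLC effect recovered without material bias
        ests = []
        for seed in range(20):
            coh = make_synthetic_cohort(
                400, effect_itvlc=-0.15, effect_ratio=0.0, seed=3000 + seed
            )
            df = cohort_truth_frame(coh)
            fit = cox_fit(
                SurvivalSample(
                    df["time_months"].to_numpy(),
                    df["event"].to_numpy(),
                    df[["itvlc", "ratio"]],
                )
            )
            ests.append(fit.coef("itvlc"))
        assert np.mean(ests) == pytest.approx(-0.15, abs=0.03)


class TestBackwardSelection:
    def test_noise_covariate_dropped(self, rng):
        n = 300
        x = rng.normal(0, 1, n)
        noise = rng.normal(0, 1, n)
        t = rng.exponential(1 / (0.1 * np.exp(0.8 * x)))
        sample = _sample(t, np.ones(n, bool), x=x, noise=noise)
        fit = backward_select(sample, ["x", "noise"])
        assert fit.names == ["x"]


class TestSchoenfeld:
    def test_too_few_events_rejected(self):
        s = _sample([1.0, 2.0, 3.0, 4.0], [True, True, False, False], x=[0, 1, 2, 3.0])
        fit = cox_fit(s)
        with pytest.raises(ValueError, match="3 events"):
            schoenfeld_check(fit, s)

    def test_time_varying_effect_detected(self):
        # effect flips sign mid-study: the rank test must reject
        rejections = 0
        for seed in range(20):
            rng = np.random.default_rng(4200 + seed)
            n = 300
            x = rng.normal(0, 1, n)
            h0, t0 = 0.08, 6.0
            hazard_early = h0 * np.exp(0.8 * x)
            hazard_late = h0 * np.exp(-0.8 * x)
            cum = -np.log(rng.random(n))
            t = np.where(
                cum <= hazard_early * t0,
                cum / hazard_early,
                t0 + (cum - hazard_early * t0) / hazard_late,
            )
            c = rng.uniform(0, 30, n)
            sample = _sample(np.minimum(t, c), t <= c, x=x)
            fit = cox_fit(sample)
            p = schoenfeld_check(fit, sample)["p"].iloc[0]
            rejections += p < 0.05
        assert rejections >= 10   # >= 50% power

    def test_proportional_data_mostly_accepted(self):
        rejections = 0
        for seed in range(30):
            rng = np.random.default_rng(6100 + seed)
            n = 150
            x = rng.normal(0, 1, n)
            t = rng.exponential(1 / (0.08 * np.exp(0.4 * x)))
            c = rng.uniform(0, 30, n)
            sample = _sample(np.minimum(t, c), t <= c, x=x)
            fit = cox_fit(sample)
            rejections += schoenfeld_check(fit, sample)["p"].iloc[0] < 0.05
        assert rejections <= 6


def _pair_count_auc(marker, positive):
    """Exhaustive concordant-pair AUC with half-credit for ties."""
    pos, neg = marker[positive], marker[~positive]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestTdRoc:
    def test_perfect_marker_gives_auc_one(self):
        time = np.array([1.0, 2.0, 3.0, 10.0, 11.0, 12.0])
        event = np.array([1, 1, 1, 0, 0, 0], dtype=bool)
        marker = np.array([10.0, 9.0, 8.0, 1.0, 2.0, 3.0])
        res = td_roc(_sample(time, event), marker, horizon=5.0, n_bootstrap=20)
        assert res.auc == pytest.approx(1.0)
        assert 0.0 <= res.ci_lower <= res.ci_upper <= 1.0

    def test_no_censoring_equals_pair_counting(self, rng):
        n = 120
        t = rng.exponential(8.0, n)
        marker = -t + rng.normal(0, 2.0, n)       # tie-free informative marker
        s = _sample(t, np.ones(n, bool))
        horizon = float(np.median(t))
        res = td_roc(s, marker, horizon=horizon, n_bootstrap=0)
        assert res.auc == pytest.approx(_pair_count_auc(marker, t <= horizon), abs=1e-12)

    def test_monotone_marker_transform_invariance(self, rng):
        n = 100
        t = rng.exponential(8.0, n)
        c = rng.uniform(0, 25, n)
        time, event = np.minimum(t, c), t <= c
        marker = rng.normal(0, 1, n)
        s = _sample(time, event)
        a1 = td_roc(s, marker, horizon=6.0, n_bootstrap=0).auc
        a2 = td_roc(s, np.exp(3.0 * marker) + 7.0, horizon=6.0, n_bootstrap=0).auc
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_null_marker_auc_near_half(self):
        aucs = []
        for seed in range(30):
            rng = np.random.default_rng(7100 + seed)
            n = 500
            t = rng.exponential(10.0, n)
            c = rng.uniform(0, 30, n)
            s = _sample(np.minimum(t, c), t <= c)
            aucs.append(td_roc(s, rng.normal(0, 1, n), horizon=8.0, n_bootstrap=0).auc)
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.03)

    def test_no_events_by_horizon_rejected(self):
        s = _sample([10.0, 11.0, 12.0], [True, True, False])
        with pytest.raises(ValueError, match="horizon"):
            td_roc(s, np.array([1.0, 2.0, 3.0]), horizon=5.0)

    def test_bootstrap_seeded(self):
        rng = np.random.default_rng(3)
        n = 80
        t = rng.exponential(8.0, n)
        s = _sample(t, np.ones(n, bool))
        m = -t + rng.normal(0, 2, n)
        r1 = td_roc(s, m, horizon=5.0, n_bootstrap=50, seed=11)
        r2 = td_roc(s, m, horizon=5.0, n_bootstrap=50, seed=11)
        assert (r1.ci_lower, r1.ci_upper) == (r2.ci_lower, r2.ci_upper)


class TestSpline:
    def test_knots_at_stated_percentiles(self):
        marker = np.arange(1.0, 101.0)
        assert np.allclose(
            np.percentile(marker, [5, 35, 65, 95]), [5.95, 35.65, 65.35, 95.05]
        )

    def test_curve_normalized_at_reference(self, rng):
        n = 200
        marker = rng.uniform(10, 30, n)
        t = rng.exponential(1 / (0.05 * np.exp(-0.1 * (marker - 20))))
        curve = rcs_hazard_curve(_sample(t, np.ones(n, bool)), marker)
        assert curve.hr_at(curve.reference) == pytest.approx(1.0)
        assert len(curve.knots) == 4

    def test_basis_linear_beyond_boundary_knots(self):
        knots = np.array([1.0, 2.0, 3.0, 4.0])
        x = np.array([5.0, 6.0, 7.0])
        b = rcs_basis(x, knots)
        # second differences vanish in the linear tail
        second = np.diff(b, n=2, axis=0)
        assert np.abs(second).max() < 1e-9

    def test_protective_log_linear_effect_yields_decreasing_curve(self):
        rng = np.random.default_rng(77)
        n = 400
        marker = rng.uniform(10, 30, n)
        t = rng.exponential(1 / (0.05 * np.exp(-0.15 * (marker - 20))))
        c = rng.uniform(0, 60, n)
        curve = rcs_hazard_curve(_sample(np.minimum(t, c), t <= c), marker)
        lo, hi = np.percentile(marker, [5, 95])
        central = (curve.grid >= lo) & (curve.grid <= hi)
        assert (np.diff(curve.hr[central]) < 0).all()

    def test_constant_marker_rejected(self):
        s = _sample(np.arange(1.0, 31.0), np.ones(30, bool))
        with pytest.raises(ValueError, match="constant"):
            rcs_hazard_curve(s, np.full(30, 5.0))


class TestPearson:
    def test_exact_linear(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert pearson_r(x, 2 * x)[0] == pytest.approx(1.0)
        assert pearson_r(x, -x + 5)[0] == pytest.approx(-1.0)

    def test_hand_formula(self):
        r, _ = pearson_r(np.array([1, 2, 3, 4.0]), np.array([2, 1, 4, 3.0]))
        assert r == pytest.approx(0.6)

    def test_constant_rejected(self):
        with pytest.raises(ValueError):
            pearson_r(np.array([1.0, 1.0, 1.0]), np.array([1.0, 2.0, 3.0]))
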