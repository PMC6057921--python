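"""Dwell-time MLE, survival curves, bootstrap and model comparison."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tirfkin.dwell import (
    DwellSample,
    Exp2Fit,
    ExpFit,
    ExponentialDwellModel,
    TwoExponentialDwellModel,
    bootstrap_se,
    compare_models,
    exponential_loglik,
    fit_exponential,
    fit_two_exponential,
    mean_lifetime,
    survival_curve,
    two_exponential_loglik,
)
from tirfkin.synthetic import simulate_dwell_sample


# ----------------------------------------------------------------------
# single-exponential MLE
# ----------------------------------------------------------------------
class TestFitExponential:
    def test_naive_is_sample_mean(self):
        # dwells 1, 2, 3 s at dt = 1
        fit = fit_exponential(DwellSample([1, 2, 3], 1.0), estimator="naive")
        assert fit.tau == pytest.approx(2.0)

    def test_phase_marginalized_closed_form(self):
        # geometric MLE: tau = dt / ln(kbar / (kbar - 1))
        fit = fit_exponential(DwellSample([1, 1, 2, 3], 0.25))
        assert fit.tau == pytest.approx(0.25 / np.log(1.75 / 0.75), rel=1e-12)
        assert fit.tau == pytest.approx(0.2951, abs=1e-4)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_mle_equals_grid_search(self, seed):
        """Closed-form MLE matches a dense grid maximizer to 1e-4 relative."""
        rng = np.random.default_rng(seed)
        k = rng.geometric(0.4, 40)
        cens = rng.random(40) < 0.1
        sample = DwellSample(k, 0.25, cens)
        fit = fit_exponential(sample)
        taus = np.geomspace(fit.tau / 5, fit.tau * 5, 100001)
        # independent likelihood evaluation on the grid
        S = float((k - 1).sum())
        n_u = int((~cens).sum())
        q = np.exp(-0.25 / taus)
        ll = S * np.log(q) + n_u * np.log1p(-q)
        tau_grid = taus[np.argmax(ll)]
        assert fit.tau == pytest.approx(tau_grid, rel=1e-4)
        assert exponential_loglik(sample, fit.tau) >= ll.max() - 1e-9

    @pytest.mark.parametrize(
        "tau,dt",
        [(0.37, 0.15), (0.46, 0.25), (2.0, 1.0), (0.2, 0.15), (40.0, 1.0)],
    )
    def test_parameter_recovery_bias(self, tau, dt):
        """Bias of the phase-marginalized estimator is < 2% at n = 10,000."""
        errs = []
        for seed in range(8):
            s = simulate_dwell_sample({"tau": tau}, dt, seed=1000 + seed, n_events=10000)
            errs.append(fit_exponential(s).tau / tau - 1.0)
        assert abs(np.mean(errs)) < 0.02

    def test_censored_events_enter_as_survival_terms(self):
        # heavy right censoring must not bias tau upward or downward
        rng = np.random.default_rng(7)
        tau, dt, window = 5.0, 0.5, 10.0
        durs = rng.exponential(tau, 20000)
        phases = rng.uniform(0, dt, durs.size)
        kend = np.ceil((phases + durs) / dt - 1e-9).astype(int) - 1
        n_inst = int(window / dt) + 1
        cens = kend > n_inst - 1
        k = np.minimum(kend, n_inst)
        keep = k >= 1
        fit = fit_exponential(DwellSample(k[keep], dt, cens[keep]))
        assert fit.tau == pytest.approx(tau, rel=0.05)

    def test_all_single_frame_hits_boundary(self):
        with pytest.warns(RuntimeWarning, match="boundary"):
            fit = fit_exponential(DwellSample([1, 1, 1, 1], 0.25))
        assert fit.boundary
        assert fit.tau > 0

    def test_naive_overestimates_and_grows_with_dt(self):
        """Frame censoring inflates the naive estimate, worse at longer dt."""
        tau = 0.46
        naive = []
        for dt in (0.15, 0.25, 1.0):
            s = simulate_dwell_sample({"tau": tau}, dt, seed=42, n_events=40000)
            naive.append(fit_exponential(s, estimator="naive").tau)
        assert all(v > tau for v in naive)
        assert naive[0] < naive[1] < naive[2]
        # the phase-marginalized fit stays unbiased at the same dt
        s = simulate_dwell_sample({"tau": tau}, 1.0, seed=42, n_events=40000)
        assert fit_exponential(s).tau == pytest.approx(tau, rel=0.1)


# ----------------------------------------------------------------------
# two-exponential MLE
# ----------------------------------------------------------------------
class TestFitTwoExponential:
    def test_loglik_matches_grid_search(self):
        """Optimized loglik beats a brute-force grid on a 20-event sample."""
        s = simulate_dwell_sample(
            {"t_short": 0.5, "t_long": 4.0, "frac_long": 0.3}, 0.25, seed=5, n_events=25
        )
        fit = fit_two_exponential(s, seed=0)
        grid_best = -np.inf
        for ts in np.geomspace(0.05, 10, 25):
            for tl in np.geomspace(0.05, 50, 25):
                if tl <= ts:
                    continue
                for a in np.linspace(0.02, 0.98, 13):
                    grid_best = max(grid_best, two_exponential_loglik(s, ts, tl, a))
        assert fit.loglik >= grid_best - 1e-3

    def test_nesting_on_single_exponential_data(self):
        s = simulate_dwell_sample({"tau": 1.0}, 0.25, seed=3, n_detected=500)
        fit1 = fit_exponential(s)
        fit2 = fit_two_exponential(s, seed=0)
        assert fit2.loglik >= fit1.loglik - 1e-9
        assert fit2.loglik - fit1.loglik < 2.0  # degenerate ridge, no real gain

    def test_canonical_ordering(self):
        s = simulate_dwell_sample(
            {"t_short": 1.0, "t_long": 20.0, "frac_long": 0.3}, 1.0, seed=9, n_detected=2000
        )
        fit = fit_two_exponential(s, seed=0)
        assert fit.t_short < fit.t_long

    def test_mixture_recovery(self):
        s = simulate_dwell_sample(
            {"t_short": 2.0, "t_long": 28.0, "frac_long": 0.10}, 1.0, seed=77, n_detected=8000
        )
        fit = fit_two_exponential(s, seed=0)
        assert fit.t_short == pytest.approx(2.0, rel=0.1)
        assert fit.t_long == pytest.approx(28.0, rel=0.15)
        assert fit.frac_long == pytest.approx(0.10, abs=0.02)

    def test_needs_ten_events(self):
        with pytest.raises(ValueError):
            fit_two_exponential(DwellSample([1, 2, 3], 0.25))


# ----------------------------------------------------------------------
# survival curves
# ----------------------------------------------------------------------
class TestSurvivalCurve:
    def test_two_identical_dwells(self):
        # dwells of 2 s each: S = 1 on [0, 2], 0 after
        curve = survival_curve(DwellSample([2, 2], 1.0))
        assert curve.survival[curve.times <= 2.0] == pytest.approx(1.0)
        assert curve.survival[curve.times > 2.0] == pytest.approx(0.0)

    def test_single_event_is_step_function(self):
        curve = survival_curve(DwellSample([3], 0.5))
        drops = np.flatnonzero(np.diff(curve.survival) < 0)
        assert drops.size == 1

    def test_kaplan_meier_hand_table(self):
        """Product-limit on a 5-event mixed-censoring sample, hand computed."""
        sample = DwellSample([1, 2, 3, 3, 4], 1.0, [False, True, False, False, True])
        curve = survival_curve(sample)
        # deaths: t=1 (1 of 5), t=3 (2 of 3) -> S = 1, 4/5, 4/5, 4/15 ...
        expected = {0: 1.0, 1: 1.0, 2: 4 / 5, 3: 4 / 5, 4: 4 / 15, 5: 4 / 15}
        for t, s_exp in expected.items():
            assert curve.survival[curve.times == float(t)][0] == pytest.approx(s_exp)

    def test_kaplan_meier_matches_lifelines(self):
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(4)
        k = rng.geometric(0.3, 60)
        cens = rng.random(60) < 0.25
        sample = DwellSample(k, 0.25, cens)
        curve = survival_curve(sample)
        km = lifelines.KaplanMeierFitter().fit(sample.dwell_s, ~cens)
        for t, s in zip(curve.times[1:], curve.survival[1:]):
            # our S(t) = P(T >= t) equals the KM function just below t
            assert s == pytest.approx(
                float(km.survival_function_at_times(t - 0.125).iloc[0]), abs=1e-9
            )

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=25, deadline=None)
    def test_monotone_and_starts_at_one(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 40))
        sample = DwellSample(rng.geometric(0.3, n), 0.25, rng.random(n) < 0.3)
        curve = survival_curve(sample)
        assert curve.survival[0] == 1.0
        assert np.all(np.diff(curve.survival) <= 1e-12)


# ----------------------------------------------------------------------
# bootstrap
# ----------------------------------------------------------------------
class TestBootstrap:
    def test_degenerate_sample_has_zero_se(self):
        boot = bootstrap_se(DwellSample([4] * 20, 1.0), fit_exponential, n_boot=50, seed=0)
        assert boot["se"]["tau"] == pytest.approx(0.0)

    def test_se_matches_fisher_information(self):
        """Uncensored exponential: SE(tau) ~ tau / sqrt(n)."""
        rng = np.random.default_rng(12)
        # tau = 1 s sampled at a fine interval so quantization is negligible
        k = np.maximum(1, np.round(rng.exponential(1.0, 400) / 0.01).astype(int))
        sample = DwellSample(k, 0.01)
        boot = bootstrap_se(
            sample, lambda s: fit_exponential(s, "naive"), n_boot=2000, seed=1
        )
        assert boot["se"]["tau"] == pytest.approx(1.0 / np.sqrt(400), rel=0.15)

    def test_same_seed_reproduces(self):
        sample = simulate_dwell_sample({"tau": 0.5}, 0.25, seed=6, n_detected=100)
        b1 = bootstrap_se(sample, fit_exponential, n_boot=200, seed=11)
        b2 = bootstrap_se(sample, fit_exponential, n_boot=200, seed=11)
        assert b1["se"] == b2["se"]

    def test_mixture_label_switching_resolved(self):
        s = simulate_dwell_sample(
            {"t_short": 1.0, "t_long": 15.0, "frac_long": 0.3}, 1.0, seed=8, n_detected=400
        )
        fit = fit_two_exponential(s, seed=0)
        init = (fit.t_short, fit.t_long, fit.frac_long)
        boot = bootstrap_se(
            s,
            lambda r: fit_two_exponential(r, n_starts=1, seed=0, init=init),
            n_boot=100,
            seed=2,
        )
        reps = boot["replicates"]
        names = boot["param_names"]
        assert np.all(reps[:, names.index("t_short")] <= reps[:, names.index("t_long")])


# ----------------------------------------------------------------------
# model comparison, summaries, estimator front ends
# ----------------------------------------------------------------------
class TestComparisonAndSummaries:
    def test_equal_logliks_prefer_single(self):
        f1 = ExpFit(tau=1.0, loglik=-50.0, n=100, estimator="phase_marginalized")
        f2 = Exp2Fit(t_short=1.0, t_long=1.0, frac_long=0.5, loglik=-50.0, n=100,
                     estimator="phase_marginalized")
        assert compare_models(f1, f2)["preferred"] == "1exp"

    def test_strong_mixture_prefers_two_exponential(self):
        s = simulate_dwell_sample(
            {"t_short": 0.5, "t_long": 20.0, "frac_long": 0.3}, 0.25, seed=13, n_detected=3000
        )
        rep = compare_models(fit_exponential(s), fit_two_exponential(s, seed=0))
        assert rep["preferred"] == "2exp"
        assert rep["delta_loglik"] >= 0.0

    def test_mean_lifetime(self):
        assert mean_lifetime(ExpFit(0.46, 0.0, 10, "naive")) == pytest.approx(0.46)
        assert mean_lifetime(Exp2Fit(2.0, 28.0, 0.0, 0.0, 10, "naive")) == pytest.approx(2.0)
        assert mean_lifetime(Exp2Fit(2.0, 28.0, 0.5, 0.0, 10, "naive")) == pytest.approx(15.0)

    def test_estimator_front_ends(self):
        s = simulate_dwell_sample({"tau": 0.5}, 0.25, seed=21, n_detected=800)
        m = ExponentialDwellModel(frame_interval_s=0.25).fit(s.frame_counts)
        assert m.tau_ == pytest.approx(0.5, rel=0.1)
        assert m.get_params()["estimator"] == "phase_marginalized"
        s2 = simulate_dwell_sample(
            {"t_short": 1.0, "t_long": 10.0, "frac_long": 0.3}, 0.5, seed=22, n_detected=1500
        )
        m2 = TwoExponentialDwellModel(frame_interval_s=0.5).fit(s2.frame_counts)
        assert m2.t_short_ < m2.t_long_
        assert m2.score(s2.frame_counts) <= 0.0
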