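import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import cropshift.quantile_trend as qt
from cropshift import (
    TrendObservation,
    fit_pair,
    fit_weighted_quantile,
    period_change,
    pinball_objective,
)

TAUS = (0.05, 0.5, 0.9, 0.93, 0.95, 0.97)


def brute_force_minimum(t, y, w, tau):
    """Minimum weighted check loss over all lines through observation pairs."""
    best = np.inf
    for i in range(len(t)):
        for j in range(i + 1, len(t)):
            if t[i] == t[j]:
                continue
            b = (y[i] - y[j]) / (t[i] - t[j])
            a = y[i] - b * t[i]
            best = min(best, pinball_objective(t, y, w, tau, a, b))
    return best


def random_instance(rng, n_max=10):
    while True:
        n = int(rng.integers(2, n_max + 1))
        t = rng.integers(0, 6, n).astype(float)
        if np.unique(t).size >= 2:
            break
    y = np.round(rng.normal(0, 3, n), 2)
    w = rng.uniform(0.01, 2.0, n)
    return t, y, w


class TestFitExamples:
    @pytest.mark.parametrize("tau", TAUS)
    def test_exact_line_is_interpolated(self, tau):
        t = np.array([0.0, 1.0, 2.0, 5.0])
        y = 2.0 + 0.5 * t
        fit = fit_weighted_quantile(year=t, temperature=y, weight=[1, 3, 2, 0.5], tau=tau)
        assert fit.intercept == pytest.approx(2.0, abs=1e-9)
        assert fit.slope == pytest.approx(0.5, abs=1e-9)
        assert fit.objective == pytest.approx(0.0, abs=1e-12)

    def test_two_point_identity(self):
        fit = fit_weighted_quantile(year=[1.0, 3.0], temperature=[4.0, 10.0], weight=[2.0, 5.0], tau=0.9)
        assert fit.slope == pytest.approx(3.0)
        assert fit.intercept == pytest.approx(1.0)

    def test_three_point_weighted_example(self):
        # brute force over point-pair lines: the optimum passes through
        # (2, 3) and (3, 2) with objective 0.3
        fit = fit_weighted_quantile(
            [TrendObservation(1, 1, 1), TrendObservation(2, 3, 1), TrendObservation(3, 2, 2)],
            tau=0.9,
        )
        assert fit.slope == pytest.approx(-1.0)
        assert fit.intercept == pytest.approx(5.0)
        assert fit.objective == pytest.approx(0.3)

    def test_errors(self):
        with pytest.raises(ValueError, match="all weights zero"):
            fit_weighted_quantile(year=[1, 2], temperature=[1, 2], weight=[0, 0], tau=0.5)
        with pytest.raises(ValueError, match="single distinct year"):
            fit_weighted_quantile(year=[2, 2], temperature=[1, 2], weight=[1, 1], tau=0.5)
        with pytest.raises(ValueError, match="tau"):
            fit_weighted_quantile(year=[1, 2], temperature=[1, 2], weight=[1, 1], tau=1.2)


class TestOracleEquivalence:
    def test_matches_brute_force_on_small_instances(self):
        rng = np.random.default_rng(2024)
        checked = 0
        for _ in range(60):
            t, y, w = random_instance(rng)
            tau = float(rng.choice(TAUS))
            fit = fit_weighted_quantile(year=t, temperature=y, weight=w, tau=tau)
            assert fit.objective <= brute_force_minimum(t, y, w, tau) + 1e-8
            checked += 1
        assert checked == 60

    def test_numpy_fallback_agrees_with_jit_path(self, monkeypatch):
        rng = np.random.default_rng(7)
        n = 800
        t = np.repeat(np.arange(20), 40).astype(float)
        y = 10 + 0.1 * t + rng.normal(0, 1, n)
        w = rng.uniform(0.1, 2, n)
        fit_jit = fit_weighted_quantile(year=t, temperature=y, weight=w, tau=0.9)
        monkeypatch.setattr(qt, "_HAVE_NUMBA", False)
        fit_np = fit_weighted_quantile(year=t, temperature=y, weight=w, tau=0.9)
        assert fit_np.slope == pytest.approx(fit_jit.slope, abs=1e-9)
        assert fit_np.objective == pytest.approx(fit_jit.objective, abs=1e-9)

    def test_independent_library_cross_check(self):
        # statsmodels QuantReg on row-scaled data solves the same objective
        import statsmodels.api as sm

        rng = np.random.default_rng(3)
        n = 2000
        t = np.repeat(np.arange(40), 50).astype(float)
        y = 20 + 0.03 * t + rng.normal(0, 0.5, n)
        w = rng.uniform(0.01, 2, n)
        for tau in (0.05, 0.95):
            fit = fit_weighted_quantile(year=t, temperature=y, weight=w, tau=tau)
            tc = t - np.average(t, weights=w)
            res = sm.QuantReg(w * y, np.column_stack([w, w * tc])).fit(q=tau, max_iter=5000)
            obj_sm = pinball_objective(tc, y, w, tau, *res.params)
            assert fit.objective <= obj_sm + 1e-6
            assert fit.slope == pytest.approx(res.params[1], abs=5e-4)


class TestInvariants:
    def test_weight_splitting_leaves_objective_unchanged(self):
        rng = np.random.default_rng(5)
        for _ in range(25):
            t, y, w = random_instance(rng, n_max=8)
            tau = float(rng.choice(TAUS))
            base = fit_weighted_quantile(year=t, temperature=y, weight=w, tau=tau)
            t2 = np.concatenate([t, [t[0]]])
            y2 = np.concatenate([y, [y[0]]])
            w2 = np.concatenate([w, [w[0] / 2]])
            w2[0] /= 2
            split = fit_weighted_quantile(year=t2, temperature=y2, weight=w2, tau=tau)
            assert split.objective == pytest.approx(base.objective, abs=1e-10)

    def test_weight_scale_invariance(self):
        rng = np.random.default_rng(6)
        t, y, w = random_instance(rng, n_max=9)
        fit = fit_weighted_quantile(year=t, temperature=y, weight=w, tau=0.9)
        scaled = fit_weighted_quantile(year=t, temperature=y, weight=123.0 * w, tau=0.9)
        assert scaled.slope == pytest.approx(fit.slope, abs=1e-12)
        assert scaled.intercept == pytest.approx(fit.intercept, abs=1e-12)
        assert scaled.objective == pytest.approx(123.0 * fit.objective, rel=1e-9)

    def test_quantile_coverage_subgradient_bound(self):
        # at the optimum the weighted mass strictly below the line lies in
        # [tau - Z/W, tau], Z = combined weight of the interpolated points
        rng = np.random.default_rng(8)
        for _ in range(40):
            n = int(rng.integers(20, 200))
            t = rng.integers(0, 40, n).astype(float)
            if np.unique(t).size < 2:
                continue
            y = rng.normal(0, 2, n)
            w = rng.uniform(0.01, 2, n)
            tau = float(rng.choice(TAUS))
            fit = fit_weighted_quantile(year=t, temperature=y, weight=w, tau=tau)
            resid = y - fit.intercept - fit.slope * t
            W = w.sum()
            on = np.abs(resid) <= 1e-9 * max(1.0, np.abs(y).max())
            below = w[(resid < 0) & ~on].sum() / W
            z = w[on].sum() / W
            assert tau - z - 1e-9 <= below <= tau + 1e-9

    def test_vertex_property_on_noisy_data(self):
        rng = np.random.default_rng(9)
        n = 3000
        t = np.repeat(np.arange(30), 100).astype(float)
        y = 5 + 0.02 * t + rng.normal(0, 1, n)
        w = rng.uniform(0.5, 1.5, n)
        fit = fit_weighted_quantile(year=t, temperature=y, weight=w, tau=0.93)
        resid = np.abs(y - fit.intercept - fit.slope * t)
        assert (resid <= 1e-8 * max(1.0, np.abs(y).max())).sum() >= 2

    @settings(max_examples=40, deadline=None)
    @given(
        data=st.lists(
            st.tuples(
                st.integers(0, 5),
                st.floats(-5, 5, allow_nan=False),
                st.floats(0.05, 2.0, allow_nan=False),
            ),
            min_size=2,
            max_size=8,
        ),
        tau=st.sampled_from(TAUS),
    )
    def test_objective_is_brute_force_minimum(self, data, tau):
        t = np.array([d[0] for d in data], dtype=float)
        y = np.array([d[1] for d in data])
        w = np.array([d[2] for d in data])
        if np.unique(t).size < 2:
            return
        fit = fit_weighted_quantile(year=t, temperature=y, weight=w, tau=tau)
        assert fit.objective <= brute_force_minimum(t, y, w, tau) + 1e-8
        assert fit.objective >= -1e-12


class TestPeriodChange:
    def test_default_span_is_39_years(self):
        fit = fit_weighted_quantile(year=[1973, 2012], temperature=[10.0, 10.78], weight=[1, 1], tau=0.5)
        assert period_change(fit) == pytest.approx(0.78)

    @pytest.mark.parametrize("slope,expected", [(0.02, 0.78), (0.0, 0.0), (-0.04, -1.56)])
    def test_arithmetic(self, slope, expected):
        fit = qt.QuantileFit(tau=0.95, intercept=0.0, slope=slope, objective=0.0, n_obs=2)
        assert period_change(fit, 1973, 2012) == pytest.approx(expected)

    def test_bad_span_rejected(self):
        fit = qt.QuantileFit(tau=0.95, intercept=0.0, slope=1.0, objective=0.0, n_obs=2)
        with pytest.raises(ValueError):
            period_change(fit, 2012, 1973)


class TestFitPair:
    def test_identical_weights_give_identical_fits(self, small_setup):
        obs, cf = fit_pair(
            small_setup["season"], small_setup["dynamic"], small_setup["static"], 0.95
        )
        # the static scenario has areas constant in time: weights coincide
        assert obs.slope == pytest.approx(cf.slope, abs=1e-12)
        assert obs.intercept == pytest.approx(cf.intercept, abs=1e-12)

    def test_global_weight_scaling_does_not_change_fit(self, small_setup):
        from cropshift.area_weights import WeightSet

        dynamic = small_setup["dynamic"]
        scaled = WeightSet(mode="dynamic", weights=dynamic.weights * 7.5)
        a, _ = fit_pair(small_setup["season"], dynamic, small_setup["static"], 0.9)
        b, _ = fit_pair(small_setup["season"], scaled, small_setup["static"], 0.9)
        assert a.slope == pytest.approx(b.slope, abs=1e-10)
        assert a.intercept == pytest.approx(b.intercept, abs=1e-10)
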