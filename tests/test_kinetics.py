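"""First-order model evaluation, fitting, and goodness of fit."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from releasekit import (
    FirstOrderParams,
    ReleaseCurve,
    UnfittableInputError,
    eval_first_order,
    fit_first_order,
    goodness_of_fit,
    generate_release_curve,
    NoiseModel,
)


class TestEvalFirstOrder:
    @pytest.mark.parametrize(
        "a,b,t,expected",
        [
            (100.0, 0.1, 0.0, 0.0),  # initial condition Cr(0)=0
            (100.0, np.log(2) / 24, 24.0, 50.0),  # half-life construction
            (80.0, 0.05, 1e7, 80.0),  # asymptote
        ],
    )
    def test_known_values(self, a, b, t, expected):
        assert eval_first_order(FirstOrderParams(a, b), t) == pytest.approx(expected, abs=1e-9)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            eval_first_order(FirstOrderParams(100, 0.1), -1.0)

    @given(
        a=st.floats(1.0, 500.0),
        b=st.floats(1e-3, 0.4),
        t1=st.floats(0.0, 40.0),
        dt=st.floats(1e-3, 20.0),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_monotone_increasing_and_bounded(self, a, b, t1, dt):
        """Cr is strictly increasing in t and bounded by the asymptote a.

        Exponents are kept below the float64 saturation point so the strict
        inequalities are representable.
        """
        p = FirstOrderParams(a, b)
        y1, y2 = eval_first_order(p, t1), eval_first_order(p, t1 + dt)
        assert 0.0 <= y1 < a
        assert y2 > y1

    def test_monotone_in_asymptote(self):
        t = np.array([1.0, 10.0, 50.0])
        lo = eval_first_order(FirstOrderParams(80, 0.1), t)
        hi = eval_first_order(FirstOrderParams(90, 0.1), t)
        assert np.all(hi > lo)

    @pytest.mark.parametrize("a,b", [(0.0, 0.1), (-5.0, 0.1), (100.0, 0.0), (100.0, -1.0)])
    def test_invalid_params_rejected(self, a, b):
        with pytest.raises(ValueError):
            FirstOrderParams(a, b)


class TestReleaseCurve:
    @pytest.mark.parametrize(
        "times,values",
        [
            ([2.0, 1.0, 3.0], [1.0, 2.0, 3.0]),  # not increasing
            ([1.0, 1.0, 2.0], [1.0, 2.0, 3.0]),  # duplicate time
            ([1.0, 2.0], [-1.0, 2.0]),  # negative value
            ([0.0, 1.0], [5.0, 10.0]),  # nonzero at t=0
            ([-1.0, 1.0], [0.0, 1.0]),  # negative time
        ],
    )
    def test_invariant_violations_rejected(self, times, values):
        with pytest.raises(ValueError):
            ReleaseCurve(np.asarray(times), np.asarray(values))

    def test_zero_at_origin_accepted(self):
        c = ReleaseCurve(np.array([0.0, 1.0]), np.array([0.0, 10.0]))
        assert len(c) == 2


class TestFitFirstOrder:
    @pytest.mark.parametrize(
        "a,b",
        [(90.0, 0.05), (105.0, 0.3), (42.0, 0.02), (300.0, 1.5)],
    )
    def test_noiseless_recovery(self, a, b, times):
        """Exact model data returns the generating parameters to 1e-6 relative."""
        curve = ReleaseCurve(times, eval_first_order(FirstOrderParams(a, b), times))
        fr = fit_first_order(curve)
        assert fr.converged
        assert fr.params.a == pytest.approx(a, rel=1e-6)
        assert fr.params.b == pytest.approx(b, rel=1e-6)
        assert fr.rss == pytest.approx(0.0, abs=1e-12)
        assert fr.n_obs == len(curve)

    def test_fit_idempotence(self, times):
        """Refitting a curve synthesized from a fit's own params returns them."""
        noisy = generate_release_curve(
            FirstOrderParams(90, 0.05), times, NoiseModel("additive_gaussian", 2.0, seed=7)
        )
        fr1 = fit_first_order(noisy)
        clean = ReleaseCurve(times, eval_first_order(fr1.params, times))
        fr2 = fit_first_order(clean)
        assert fr2.params.a == pytest.approx(fr1.params.a, rel=1e-6)
        assert fr2.params.b == pytest.approx(fr1.params.b, rel=1e-6)

    def test_noisy_fit_beats_grid_oracle(self, times):
        """Optimised RSS never exceeds the best of a 200x200 log-spaced grid."""
        curve = generate_release_curve(
            FirstOrderParams(90, 0.05), times, NoiseModel("additive_gaussian", 2.0, seed=11)
        )
        fr = fit_first_order(curve)
        a_grid = np.geomspace(10, 500, 200)
        b_grid = np.geomspace(1e-3, 10, 200)
        model = a_grid[:, None, None] * -np.expm1(
            -b_grid[None, :, None] * curve.times[None, None, :]
        )
        grid_rss = ((model - curve.values[None, None, :]) ** 2).sum(axis=2)
        assert fr.rss <= grid_rss.min() + 1e-9

    def test_recovery_error_shrinks_with_noise(self, times):
        """Median parameter error decreases as measurement noise decreases."""
        true = FirstOrderParams(90, 0.05)

        def median_err(sigma, base_seed):
            errs = []
            for i in range(50):
                c = generate_release_curve(
                    true, times, NoiseModel("proportional_gaussian", sigma, seed=base_seed + i)
                )
                fr = fit_first_order(c)
                errs.append(max(abs(fr.params.a - 90) / 90, abs(fr.params.b - 0.05) / 0.05))
            return np.median(errs)

        assert median_err(0.01, 100) < median_err(0.08, 100)

    @pytest.mark.parametrize(
        "values",
        [
            np.zeros(5),  # all zero
            np.array([0.0, 0.0, 5.0, 5.0, 5.0]),  # single nonzero level
            np.array([1.0, np.nan, 3.0, 4.0, 5.0]),  # non-finite
        ],
    )
    def test_unfittable_inputs_rejected(self, values):
        curve = ReleaseCurve(np.arange(1.0, 6.0), values)
        with pytest.raises(UnfittableInputError):
            fit_first_order(curve)

    def test_too_few_points_rejected(self):
        curve = ReleaseCurve(np.array([1.0, 2.0]), np.array([10.0, 20.0]))
        with pytest.raises(UnfittableInputError):
            fit_first_order(curve)


class TestGoodnessOfFit:
    def test_perfect_fit_gives_unity(self, times, slow_params):
        curve = ReleaseCurve(times, eval_first_order(slow_params, times))
        r2, r2_adj = goodness_of_fit(curve, slow_params)
        assert r2 == pytest.approx(1.0, abs=1e-12)
        assert r2_adj == pytest.approx(1.0, abs=1e-12)

    def test_mean_predictor_gives_zero(self):
        """Predictions equal to the observed mean at every point give R²=0."""
        times = np.array([5.0, 10.0, 20.0, 40.0])
        values = np.array([40.0, 48.0, 52.0, 60.0])  # mean 50
        # b so large the model is flat at its asymptote over these times
        params = FirstOrderParams(a=50.0, b=100.0)
        r2, _ = goodness_of_fit(curve := ReleaseCurve(times, values), params)
        assert r2 == pytest.approx(0.0, abs=1e-9)

    def test_matches_hand_formula_on_noisy_fixture(self, times):
        """R² equals 1 - RSS/TSS computed by independent arithmetic."""
        curve = generate_release_curve(
            FirstOrderParams(90, 0.05), times, NoiseModel("additive_gaussian", 3.0, seed=3)
        )
        params = FirstOrderParams(88.0, 0.06)
        r2, r2_adj = goodness_of_fit(curve, params)
        pred = params.a * (1 - np.exp(-params.b * curve.times))
        rss = float(np.sum((curve.values - pred) ** 2))
        tss = float(np.sum((curve.values - curve.values.mean()) ** 2))
        n = len(curve)
        assert r2 == pytest.approx(1 - rss / tss, rel=1e-12)
        assert r2_adj == pytest.approx(1 - (1 - r2) * (n - 1) / (n - 3), rel=1e-12)
        assert r2_adj <= r2

    def test_constant_observations_rejected(self):
        curve = ReleaseCurve(np.array([1.0, 2.0, 3.0, 4.0]), np.full(4, 5.0))
        with pytest.raises(ZeroDivisionError):
            goodness_of_fit(curve, FirstOrderParams(5, 0.1))

    def test_too_few_points_for_adjustment_rejected(self):
        curve = ReleaseCurve(np.array([1.0, 2.0, 3.0]), np.array([1.0, 2.0, 3.0]))
        with pytest.raises(ValueError):
            goodness_of_fit(curve, FirstOrderParams(5, 0.1))
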