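import numpy as np
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st

from fapsense import (
    DiscreteARX,
    REFERENCE_MODEL2,
    TransferModelParams,
    bilinear_discretize,
    compare_orders,
    continuous_from_discrete,
    fit_discrete,
    identify,
    simulate_discrete_arx,
)
from fapsense.errors import IdentifiabilityError, InvalidParameterError, MappingError

tau_strategy = st.floats(8.0, 600.0)


class TestFitDiscrete:
    def test_exact_recovery_of_known_coefficients(self, model2, logistic_input):
        truth = bilinear_discretize(model2, ts=12.0)
        r = simulate_discrete_arx(truth, logistic_input)
        fitted, diag = fit_discrete(r, logistic_input, order=2, ts=12.0)
        np.testing.assert_allclose(fitted.a, truth.a, rtol=1e-8)
        np.testing.assert_allclose(fitted.b, truth.b, rtol=1e-8)
        assert diag.residual_variance < 1e-12

    def test_zero_output_gives_zero_coefficients(self, logistic_input):
        model, diag = fit_discrete(np.zeros_like(logistic_input), logistic_input, 2, 12.0)
        assert model.a == (0.0, 0.0) and model.b == (0.0, 0.0, 0.0)
        assert diag.residual_variance == 0.0

    def test_constant_input_is_unidentifiable(self, model2):
        truth = bilinear_discretize(model2, ts=12.0)
        x = np.ones(100)
        r = simulate_discrete_arx(truth, x)
        with pytest.raises(IdentifiabilityError, match="constant input"):
            fit_discrete(r, x, order=2, ts=12.0)

    def test_noise_consistency(self, model2, logistic_input, rng):
        # OLS coefficient error shrinks with the noise level, in expectation
        truth = bilinear_discretize(model2, ts=12.0)
        clean = simulate_discrete_arx(truth, logistic_input)
        errs = []
        for sigma in (1e-2, 1e-4):
            level = []
            for _ in range(5):
                noisy = clean * (1 + sigma * rng.standard_normal(clean.size))
                fitted, _ = fit_discrete(noisy, logistic_input, order=2, ts=12.0)
                level.append(np.linalg.norm(np.subtract(fitted.a, truth.a)))
            errs.append(np.mean(level))
        assert errs[1] < errs[0]

    def test_too_short_series_rejected(self):
        with pytest.raises(InvalidParameterError, match="samples"):
            fit_discrete(np.ones(9), np.ones(9), order=2, ts=12.0)


class TestContinuousFromDiscrete:
    def test_inverse_of_hand_expanded_example(self):
        params, validity = continuous_from_discrete(DiscreteARX(a=(0.0,), b=(0.5, 0.5), ts=2.0))
        assert validity.ok
        assert params.k == pytest.approx(1.0, rel=1e-12)
        assert params.tau_p == pytest.approx((1.0,), rel=1e-12)
        assert params.tau_z == pytest.approx(0.0, abs=1e-12)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(k=st.floats(0.5, 400), tz=st.floats(0, 20), t1=tau_strategy, t2=tau_strategy)
    def test_roundtrip_identity(self, k, tz, t1, t2):
        # distinct poles: root extraction at a double pole is sqrt(eps)
        # sensitive, covered separately below
        assume(abs(t1 - t2) > 1e-3 * max(t1, t2))
        p = TransferModelParams(k=k, tau_z=tz, tau_p=(t1, t2))
        q, validity = continuous_from_discrete(bilinear_discretize(p, ts=12.0))
        assert validity.ok
        assert q.k == pytest.approx(p.k, rel=1e-9)
        assert q.tau_p == pytest.approx(p.tau_p, rel=1e-9)
        assert q.tau_z == pytest.approx(p.tau_z, rel=1e-6, abs=1e-9)

    def test_roundtrip_with_coincident_poles(self):
        p = TransferModelParams(k=10.0, tau_z=2.0, tau_p=(40.0, 40.0))
        q, validity = continuous_from_discrete(bilinear_discretize(p, ts=4.0))
        assert validity.ok
        assert q.tau_p == pytest.approx(p.tau_p, rel=1e-6)

    def test_roundtrip_identity_orders_1_and_3(self):
        for taus in [(200.0,), (300.0, 40.0, 6.5)]:
            p = TransferModelParams(k=5.0, tau_z=3.0, tau_p=taus)
            q, validity = continuous_from_discrete(bilinear_discretize(p, ts=3.0))
            assert validity.ok
            assert q.tau_p == pytest.approx(p.tau_p, rel=1e-9)

    def test_complex_poles_flagged_without_time_constants(self):
        # AR polynomial z^2 - z + 0.5 has complex roots
        params, validity = continuous_from_discrete(
            DiscreteARX(a=(1.0, -0.5), b=(0.1, 0.1, 0.0), ts=12.0)
        )
        assert params is None
        assert not validity.real_poles

    def test_unstable_poles_flagged(self):
        params, validity = continuous_from_discrete(
            DiscreteARX(a=(1.05,), b=(1.0, 0.0), ts=12.0)
        )
        assert params is None
        assert not validity.stable and validity.real_poles

    def test_nyquist_pole_raises(self):
        with pytest.raises(MappingError, match="z = -1"):
            continuous_from_discrete(DiscreteARX(a=(-1.0,), b=(1.0, 0.0), ts=12.0))

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(pole=st.floats(-0.95, 0.95), ts=st.floats(1.0, 24.0))
    def test_stability_preserved_backwards(self, pole, ts):
        # a pole inside the unit circle (and off z=-1) maps into the left
        # half plane: a positive time constant
        params, validity = continuous_from_discrete(
            DiscreteARX(a=(pole,), b=(0.5, 0.5), ts=ts)
        )
        if abs(1 - pole) < 1e-9:
            return
        assert validity.stable
        assert params.tau_p[0] > 0


class TestIdentify:
    @pytest.mark.parametrize("construct", ["matCmatB", "matCatoDA"])
    def test_reference_row_roundtrip(self, construct, logistic_input):
        ref = REFERENCE_MODEL2[construct]
        r = simulate_discrete_arx(bilinear_discretize(ref, ts=12.0), logistic_input)
        fit = identify(r, logistic_input, order=2, ts=12.0)
        assert fit.validity.ok
        assert fit.continuous.k == pytest.approx(ref.k, rel=1e-8)
        assert fit.continuous.tau_p == pytest.approx(ref.tau_p, rel=1e-8)

    def test_bilinear_error_shrinks_with_sampling_period(self, model2):
        from fapsense import GrowthParams, logistic_growth, simulate_continuous

        g = GrowthParams(x0=0.05, xmax=1.2, mu=0.01, lag=0.0)
        tfine = np.arange(0, 2880.0001, 0.25)
        xf = logistic_growth(g, tfine)
        rf = simulate_continuous(model2, xf, tfine)
        errors = []
        for ts in (12.0, 1.0):
            step = int(ts / 0.25)
            fit = identify(rf[::step], xf[::step], order=2, ts=ts)
            c = fit.continuous
            errors.append(
                max(
                    abs(c.tau_p[0] - model2.tau_p[0]) / model2.tau_p[0],
                    abs(c.tau_p[1] - model2.tau_p[1]) / model2.tau_p[1],
                )
            )
        assert errors[1] < errors[0]


class TestCompareOrders:
    def test_true_order2_system(self, model2, logistic_input):
        r = simulate_discrete_arx(bilinear_discretize(model2, ts=12.0), logistic_input)
        results, errors = compare_orders(r, logistic_input, ts=12.0)
        assert not errors
        assert results[2].residual_variance < 1e-12
        assert results[3].residual_variance < 1e-12
        assert results[1].residual_variance > 1e-6

    def test_residual_variance_nonincreasing_with_order(self, small_plate):
        w = small_plate.wells[0]
        results, _ = compare_orders(w.rfp, w.od, ts=small_plate.ts)
        rv = [results[o].residual_variance for o in sorted(results)]
        assert all(rv[i + 1] <= rv[i] + 1e-12 for i in range(len(rv) - 1))

    def test_order1_truth_fit_by_all_orders(self, logistic_input):
        truth = bilinear_discretize(
            TransferModelParams(k=10.0, tau_z=0.0, tau_p=(200.0,)), ts=12.0
        )
        r = simulate_discrete_arx(truth, logistic_input)
        results, _ = compare_orders(r, logistic_input, ts=12.0)
        for o in results:
            assert results[o].residual_variance < 1e-10

    def test_white_noise_output_has_no_fit(self, logistic_input, rng):
        r = rng.standard_normal(logistic_input.size)
        results, _ = compare_orders(r, logistic_input, ts=12.0)
        for o in results:
            assert results[o].r_squared < 0.15
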