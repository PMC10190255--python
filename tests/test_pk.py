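import numpy as np
import pytest
from scipy.integrate import solve_ivp

from meropk import DoseEvent, predict_concentration, simulate_observations
from meropk.pkcore import predict_concentration_matrix


def ode_profile(params, dose, times):
    """Independent stiff-ODE oracle for a single zero-order infusion."""
    k10 = params["CL"] / params["V1"]
    two = "Q" in params

    def rhs(t, x):
        r = dose.rate if t < dose.duration else 0.0
        if two:
            k12, k21 = params["Q"] / params["V1"], params["Q"] / params["V2"]
            return [r - (k10 + k12) * x[0] + k21 * x[1], k12 * x[0] - k21 * x[1]]
        return [r - k10 * x[0]]

    y0 = [0.0, 0.0] if two else [0.0]
    sol = solve_ivp(
        rhs, [0, times[-1]], y0, t_eval=times, method="LSODA",
        rtol=1e-10, atol=1e-12,
    )
    return sol.y[0] / params["V1"]


class TestClosedForm:
    def test_continuous_infusion_steady_state_1cmt(self):
        # Css = R0 / CL: 125 mg/h over 5 L/h -> 25 mg/L
        prof = predict_concentration(
            {"CL": 5.0, "V1": 30.0}, [DoseEvent(0.0, 125_000.0, 1000.0)], [900.0]
        )
        assert prof.concentrations[0] == pytest.approx(25.0, rel=1e-9)

    def test_continuous_infusion_steady_state_2cmt(self):
        prof = predict_concentration(
            {"CL": 4.0, "V1": 15.0, "Q": 6.0, "V2": 20.0},
            [DoseEvent(0.0, 100_000.0, 1000.0)],
            [990.0],
        )
        assert prof.concentrations[0] == pytest.approx(100.0 / 4.0, rel=1e-6)

    def test_no_doses_gives_zero_profile(self):
        prof = predict_concentration({"CL": 5.0, "V1": 30.0}, [], [1.0, 2.0, 3.0])
        assert np.all(prof.concentrations == 0.0)

    def test_agrees_with_ode_oracle(self):
        rng = np.random.default_rng(4)
        times = np.linspace(0.1, 24.0, 50)
        for _ in range(10):
            params = {
                "CL": rng.uniform(1, 15),
                "V1": rng.uniform(5, 40),
                "Q": rng.uniform(1, 12),
                "V2": rng.uniform(5, 50),
            }
            dose = DoseEvent(0.0, 1000.0, rng.uniform(0.25, 4.0))
            analytic = predict_concentration(params, [dose], times).concentrations
            oracle = ode_profile(params, dose, times)
            np.testing.assert_allclose(analytic, oracle, rtol=1e-6)

    def test_dose_linearity(self):
        params = {"CL": 4.0, "V1": 15.0, "Q": 6.0, "V2": 20.0}
        doses1 = [DoseEvent(0, 500, 0.5), DoseEvent(8, 500, 0.5)]
        doses2 = [DoseEvent(0, 1000, 0.5), DoseEvent(8, 1000, 0.5)]
        t = np.linspace(0.5, 20, 30)
        c1 = predict_concentration(params, doses1, t).concentrations
        c2 = predict_concentration(params, doses2, t).concentrations
        np.testing.assert_allclose(c2, 2.0 * c1, rtol=1e-12)

    def test_superposition_of_doses(self):
        params = {"CL": 4.0, "V1": 15.0, "Q": 6.0, "V2": 20.0}
        d1, d2 = DoseEvent(0, 800, 0.5), DoseEvent(6, 1200, 1.0)
        t = np.linspace(0.5, 24, 40)
        both = predict_concentration(params, [d1, d2], t).concentrations
        split = (
            predict_concentration(params, [d1], t).concentrations
            + predict_concentration(params, [d2], t).concentrations
        )
        np.testing.assert_allclose(both, split, rtol=1e-12)

    def test_degenerate_eigenvalues_fall_back(self):
        # k12 -> 0 with k10 == k21 makes alpha == beta within tolerance; the
        # engine perturbs k21 instead of dividing by (alpha - beta) ~ 0, and
        # the result collapses to the one-compartment profile
        params = {"CL": 4.0, "V1": 10.0, "Q": 1e-9, "V2": 2.5e-9}
        prof = predict_concentration(params, [DoseEvent(0, 1000, 0.5)], [1.0, 4.0])
        assert np.all(np.isfinite(prof.concentrations))
        assert np.all(prof.concentrations > 0)
        one_cmt = predict_concentration(
            {"CL": 4.0, "V1": 10.0}, [DoseEvent(0, 1000, 0.5)], [1.0, 4.0]
        )
        np.testing.assert_allclose(
            prof.concentrations, one_cmt.concentrations, rtol=1e-3
        )

    def test_batch_matches_scalar_engine(self):
        rng = np.random.default_rng(9)
        doses = [DoseEvent(0, 1000, 0.5), DoseEvent(8, 1000, 0.5)]
        t = np.array([1.0, 7.75, 9.0, 15.5])
        arrays = {
            "CL": rng.uniform(2, 10, 20),
            "V1": rng.uniform(8, 30, 20),
            "Q": rng.uniform(2, 10, 20),
            "V2": rng.uniform(10, 40, 20),
        }
        batch = predict_concentration_matrix(arrays, doses, t)
        for k in range(20):
            single = predict_concentration(
                {p: arrays[p][k] for p in arrays}, doses, t
            ).concentrations
            np.testing.assert_allclose(batch[k], single, rtol=1e-12)


class TestSimulateObservations:
    def test_fixed_seed_reproducible(self, minimal_spec):
        args = (
            minimal_spec,
            minimal_spec.thetas,
            [DoseEvent(0, 1000, 0.5)],
            [1.0, 4.0, 7.75],
        )
        y1 = simulate_observations(*args, rng=123)
        y2 = simulate_observations(*args, rng=123)
        np.testing.assert_array_equal(y1, y2)

    def test_proportional_sd_scales_with_prediction(self, minimal_spec):
        """At f = 10 mg/L a 20% proportional error gives sample SD ~= 2."""
        params = {"CL": 5.0, "V1": 30.0}
        doses = [DoseEvent(0.0, 300_000.0, 1000.0)]  # Css = 300/5... scaled below
        f = predict_concentration(params, doses, [900.0]).concentrations[0]
        scale = 10.0 / f
        doses = [DoseEvent(0.0, 300_000.0 * scale, 1000.0)]
        rng = np.random.default_rng(5)
        ys = simulate_observations(
            minimal_spec, params, doses, [900.0] * 1, rng=rng
        )
        draws = np.array(
            [
                simulate_observations(minimal_spec, params, doses, [900.0], rng=rng)[0]
                for _ in range(10_000)
            ]
        )
        assert draws.std() == pytest.approx(2.0, rel=0.05)

    def test_unknown_variant_lists_available(self, minimal_spec):
        with pytest.raises(KeyError, match="default"):
            simulate_observations(
                minimal_spec,
                minimal_spec.thetas,
                [DoseEvent(0, 1000, 0.5)],
                [1.0],
                error_variant="bogus",
            )

    def test_negative_draws_truncated_at_zero(self, minimal_spec):
        spec = minimal_spec.model_copy(deep=True)
        spec.residual_error[0].sd_additive = 50.0
        spec.residual_error[0].sd_proportional = 0.0
        object.__setattr__(spec.residual_error[0], "kind", "additive")
        y = simulate_observations(
            spec, spec.thetas, [DoseEvent(0, 100, 0.5)], np.linspace(1, 24, 200),
            rng=0,
        )
        assert np.all(y >= 0.0)
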