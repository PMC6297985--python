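import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vocscreen.cuvette import (
    ConcentrationSeries,
    CuvetteConfig,
    CuvetteRole,
    EmissionProfile,
    dynamic_emission,
    exchange_fraction,
    simulate_concentration,
    steady_state_emission,
    time_constant,
)
from vocscreen.errors import (
    InputError,
    InsufficientDataError,
    InvalidParameterError,
)


class TestCuvetteConfig:
    def test_valid_plant(self):
        cfg = CuvetteConfig("c01", 40.0, 10.0, CuvetteRole.PLANT, 0.1)
        assert cfg.tau_s == pytest.approx(240.0)

    def test_role_coercion_from_string(self):
        cfg = CuvetteConfig("c01", 40.0, 10.0, "empty_background", 0.0)
        assert cfg.role is CuvetteRole.EMPTY_BACKGROUND

    @pytest.mark.parametrize("kwargs", [
        dict(volume_l=0.0, inlet_flow_lpm=10.0, leaf_area_m2=0.1),
        dict(volume_l=40.0, inlet_flow_lpm=-1.0, leaf_area_m2=0.1),
        dict(volume_l=40.0, inlet_flow_lpm=10.0, leaf_area_m2=-0.1),
        dict(volume_l=40.0, inlet_flow_lpm=10.0, leaf_area_m2=0.0),  # plant
    ])
    def test_invalid(self, kwargs):
        with pytest.raises(InvalidParameterError):
            CuvetteConfig("c01", role=CuvetteRole.PLANT, **kwargs)

    def test_nonplant_with_leaf_area_rejected(self):
        with pytest.raises(InvalidParameterError):
            CuvetteConfig("c01", 40.0, 10.0, CuvetteRole.SOIL_REFERENCE, 0.1)


class TestTimeConstant:
    def test_40l_at_10lpm_gives_20min_for_5tau(self):
        tau = time_constant(40.0, 10.0)
        assert tau == pytest.approx(4.0)
        assert 5 * tau == pytest.approx(20.0)

    def test_40l_at_15lpm_gives_13p3min_for_5tau(self):
        tau = time_constant(40.0, 15.0)
        assert tau == pytest.approx(8.0 / 3.0)
        assert round(5 * tau, 1) == 13.3

    def test_identity(self):
        assert time_constant(1.0, 1.0) == 1.0

    @pytest.mark.parametrize("v,f", [(0, 1), (1, 0), (-1, 1), (1, -1)])
    def test_invalid(self, v, f):
        with pytest.raises(InvalidParameterError):
            time_constant(v, f)


class TestExchangeFraction:
    def test_zero_elapsed(self):
        assert exchange_fraction(0.0, 123.0) == 0.0

    def test_five_tau_exceeds_99_percent(self):
        frac = exchange_fraction(5.0, 1.0)
        assert frac == pytest.approx(1.0 - math.exp(-5.0))
        assert frac > 0.99

    def test_one_tau(self):
        assert exchange_fraction(1.0, 1.0) == pytest.approx(1.0 - math.exp(-1.0))

    def test_negative_elapsed_rejected(self):
        with pytest.raises(InvalidParameterError):
            exchange_fraction(-1.0, 1.0)

    @given(st.floats(0.0, 36.0), st.floats(1e-3, 1e6))
    def test_in_unit_interval(self, ratio, tau):
        # ratio capped where 1 - exp(-ratio) is still representably < 1
        assert 0.0 <= exchange_fraction(ratio * tau, tau) < 1.0


def _grid(t_end, n):
    return np.linspace(0.0, t_end, n)


class TestSimulateConcentration:
    def test_equilibrium_stays_constant(self, plant_config):
        emission = EmissionProfile.constant("voc1", 0.0)
        grid = _grid(1000.0, 101)
        out = simulate_concentration(plant_config, emission, 5.0, grid,
                                     initial_concentration=5.0)
        assert out.values == pytest.approx(np.full(101, 5.0), abs=1e-8)

    def test_washout_matches_exponential(self, plant_config):
        # closed form: c(t) = c0 exp(-t/tau) for E=0, c_in=0
        tau = plant_config.tau_s
        grid = _grid(5 * tau, 201)
        out = simulate_concentration(plant_config,
                                     EmissionProfile.constant("voc1", 0.0),
                                     0.0, grid, initial_concentration=100.0)
        expected = 100.0 * np.exp(-grid / tau)
        np.testing.assert_allclose(out.values, expected, rtol=1e-6, atol=1e-9)
        at_tau = np.interp(tau, grid, out.values)
        assert at_tau == pytest.approx(100.0 / math.e, rel=1e-6)

    def test_plateau_reaches_steady_state_after_5tau(self, plant_config):
        tau = plant_config.tau_s
        grid = _grid(6 * tau, 301)
        out = simulate_concentration(plant_config,
                                     EmissionProfile.constant("voc1", 2.0),
                                     0.0, grid)
        # steady state E*A/F
        plateau = (2.0 * plant_config.leaf_area_m2
                   / (plant_config.inlet_flow_lpm / 60e3))
        at_5tau = np.interp(5 * tau, grid, out.values)
        assert abs(at_5tau - plateau) / plateau < 0.01
        assert out.values[-1] == pytest.approx(plateau, rel=5e-3)

    def test_non_increasing_grid_rejected(self, plant_config):
        with pytest.raises(InputError):
            simulate_concentration(plant_config,
                                   EmissionProfile.constant("voc1", 0.0),
                                   0.0, np.array([0.0, 10.0, 10.0]))

    def test_inlet_not_covering_grid_rejected(self, plant_config):
        inlet = ConcentrationSeries("in", "voc1", [0.0, 50.0], [1.0, 1.0])
        with pytest.raises(InputError):
            simulate_concentration(plant_config,
                                   EmissionProfile.constant("voc1", 0.0),
                                   inlet, _grid(100.0, 11))


class TestSteadyStateEmission:
    def test_no_gradient(self):
        assert steady_state_emission(10.0, 0.1, 5.0, 5.0) == 0.0

    def test_worked_numbers(self):
        # 6 L/min = 1e-4 m3/s; x 1 nmol/m3 / 0.1 m2 = 1e-3 nmol/m2/s
        assert steady_state_emission(6.0, 0.1, 1.0, 0.0) == pytest.approx(1.0e-3)

    def test_negative_signals_uptake(self):
        assert steady_state_emission(6.0, 0.1, 0.0, 1.0) < 0

    def test_zero_leaf_area_names_nonplant(self):
        with pytest.raises(InvalidParameterError, match="non-plant"):
            steady_state_emission(6.0, 0.0, 1.0, 0.0)

    def test_inverts_simulated_plateau(self, plant_config):
        tau = plant_config.tau_s
        grid = _grid(12 * tau, 601)
        true_e = 3.7
        out = simulate_concentration(plant_config,
                                     EmissionProfile.constant("voc1", true_e),
                                     0.0, grid, rtol=1e-10)
        recovered = steady_state_emission(plant_config.inlet_flow_lpm,
                                          plant_config.leaf_area_m2,
                                          out.values[-1], 0.0)
        assert abs(recovered - true_e) / true_e < 1e-3


class TestDynamicEmission:
    def test_constant_series_equals_steady_state_exactly(self, plant_config):
        t = np.linspace(0, 1000, 11)
        outlet = ConcentrationSeries("c01", "voc1", t, np.full(11, 7.0))
        dyn = dynamic_emission(outlet, 2.0, plant_config)
        ss = steady_state_emission(plant_config.inlet_flow_lpm,
                                   plant_config.leaf_area_m2, 7.0, 2.0)
        np.testing.assert_array_equal(dyn.values, np.full(11, ss))

    def test_step_round_trip(self, plant_config):
        tau = plant_config.tau_s
        grid = np.linspace(0, 10 * tau, 2001)
        amp = 5.0
        profile = EmissionProfile.step("voc1", amp, t_on=2 * tau)
        out = simulate_concentration(plant_config, profile, 0.0, grid,
                                     rtol=1e-10)
        dyn = dynamic_emission(out, 0.0, plant_config)
        # away from the step and the grid boundaries
        mask = grid > 2 * tau + 5 * (grid[1] - grid[0])
        mask[-5:] = False
        assert np.max(np.abs(dyn.values[mask] - amp)) / amp < 0.02

    def test_diurnal_round_trip_dense_grid(self, plant_config):
        tau = plant_config.tau_s
        profile = EmissionProfile.diurnal_sine("voc1", 4.0, 0.0, 43200.0)
        grid = np.arange(0.0, 43200.0, tau / 20)
        out = simulate_concentration(plant_config, profile, 0.0, grid)
        dyn = dynamic_emission(out, 0.0, plant_config)
        truth = profile.evaluate(grid)
        mid = slice(len(grid) // 4, 3 * len(grid) // 4)
        rel = np.abs(dyn.values[mid] - truth[mid]) / truth[mid]
        assert np.max(rel) < 0.02

    def test_too_few_samples(self, plant_config):
        outlet = ConcentrationSeries("c01", "voc1", [0.0, 1.0], [1.0, 1.0])
        with pytest.raises(InsufficientDataError):
            dynamic_emission(outlet, 0.0, plant_config)


class TestModelProperties:
    def test_washout_monotone_without_overshoot(self, plant_config):
        # E=0, constant inlet: c(t) moves monotonically toward c_in
        grid = _grid(10 * plant_config.tau_s, 401)
        out = simulate_concentration(plant_config,
                                     EmissionProfile.constant("voc1", 0.0),
                                     10.0, grid, initial_concentration=2.0)
        assert np.all(np.diff(out.values) >= -1e-9)
        assert np.all(out.values <= 10.0 + 1e-8)

    def test_linearity_of_superposition(self, plant_config):
        grid = _grid(2000.0, 201)
        e1 = EmissionProfile.constant("voc1", 1.0)
        e2 = EmissionProfile.diurnal_sine("voc1", 2.0, 0.0, 4000.0)
        alpha, beta = 2.5, -0.5
        combo = EmissionProfile(
            "voc1", lambda t: alpha * e1.evaluate(t) + beta * e2.evaluate(t))
        kw = dict(rtol=1e-12, atol=1e-14)
        direct = simulate_concentration(plant_config, combo, 0.0, grid, **kw)
        parts = (alpha * simulate_concentration(plant_config, e1, 0.0, grid,
                                                **kw).values
                 + beta * simulate_concentration(plant_config, e2, 0.0, grid,
                                                 **kw).values)
        scale = np.max(np.abs(direct.values))
        assert np.max(np.abs(direct.values - parts)) / scale < 1e-9

    def test_low_pass_amplitude_attenuation(self, plant_config):
        # sinusoidal E at angular frequency w: gain = 1/sqrt(1+(w tau)^2)
        tau = plant_config.tau_s
        for omega_tau in (0.3, 1.0, 3.0):
            omega = omega_tau / tau
            period = 2 * math.pi / omega
            profile = EmissionProfile(
                "voc1", lambda t, w=omega: 1.0 * np.sin(w * np.asarray(t)))
            t_end = 12 * tau + 2 * period
            grid = np.arange(0.0, t_end, period / 400)
            out = simulate_concentration(plant_config, profile, 0.0, grid)
            tail = grid >= t_end - period
            amplitude = 0.5 * np.ptp(out.values[tail])
            quasi_static = (1.0 * plant_config.leaf_area_m2
                            / (plant_config.inlet_flow_lpm / 60e3))
            gain = amplitude / quasi_static
            expected = 1.0 / math.sqrt(1.0 + omega_tau ** 2)
            assert abs(gain - expected) / expected < 0.03


class TestConcentrationSeries:
    def test_length_mismatch(self):
        with pytest.raises(InputError):
            ConcentrationSeries("c", "v", [0.0, 1.0], [1.0])

    def test_non_increasing_rejected(self):
        with pytest.raises(InputError):
            ConcentrationSeries("c", "v", [0.0, 0.0], [1.0, 1.0])

    def test_non_finite_rejected(self):
        with pytest.raises(InputError):
            ConcentrationSeries("c", "v", [0.0, 1.0], [1.0, np.nan])
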