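"""Field physics: calibration, diffusion, ambient exchange, water ledger."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.signal import convolve2d

from conftest import make_system, open_geometry
from humibuild.conditions import Condition, ConditionKind, FanSide
from humibuild.physics import (
    RH_SAT,
    HumidityField,
    PhysicsParams,
    SubstrateMoisture,
    calibrate_evaporation,
    deposit_water,
    sample_humidity,
    step_field,
)

STILL = Condition(ConditionKind.STILL_WET)


def hourly_loss(rate: float, ambient: float, dt: float = 0.0625) -> float:
    """Integrate the evaporation law on one saturated cell with local RH
    clamped to ambient for one simulated hour; independent of step_field."""
    k = calibrate_evaporation(rate, ambient)
    n = int(round(3600.0 / dt))
    lost = 0.0
    mass = 10.0
    for _ in range(n):
        dm = min(mass, k * (RH_SAT - ambient) * dt)
        mass -= dm
        lost += dm
    return lost


class TestCalibration:
    @pytest.mark.parametrize("rate", [0.1, 0.6, 0.75, 2.0])
    def test_round_trip_recovers_rate(self, rate):
        assert hourly_loss(rate, 40.0) == pytest.approx(rate, rel=1e-3)

    def test_zero_target_means_no_loss(self):
        assert calibrate_evaporation(0.0, 40.0) == 0.0
        assert hourly_loss(0.0, 40.0) == 0.0

    def test_saturated_ambient_is_uncalibratable(self):
        with pytest.raises(ValueError, match="uncalibratable"):
            calibrate_evaporation(0.75, 100.0)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            calibrate_evaporation(-1.0, 40.0)


class TestStepField:
    def test_uniform_ambient_field_is_fixed_point(self):
        geom, field, moisture, params = make_system(value=params_ambient())
        before = field.values.copy()
        for _ in range(50):
            step_field(field, moisture, geom, params, STILL)
        np.testing.assert_allclose(field.values, before, atol=1e-12)

    def test_pulse_matches_discrete_diffusion_kernel(self):
        params = PhysicsParams(lambda_open=0.0, lambda_fan=0.0, evap_rate=0.0)
        geom, field, moisture, _ = make_system(nx=41, ny=41, value=40.0, params=params)
        field.values[20, 20] = 90.0
        alpha = params.diffusivity * field.dt / field.cell_size**2
        kernel = np.array([[0, alpha, 0], [alpha, 1 - 4 * alpha, alpha], [0, alpha, 0]])
        expected = field.values.copy()
        nsteps = 25  # influence stays far from the boundary
        for _ in range(nsteps):
            expected = convolve2d(expected, kernel, mode="same", boundary="fill", fillvalue=40.0)
        for _ in range(nsteps):
            step_field(field, moisture, geom, params, STILL)
        assert np.linalg.norm(field.values - expected) < 1e-6

    def test_diffusion_conserves_total_rh_on_closed_domain(self):
        params = PhysicsParams(lambda_open=0.0, lambda_fan=0.0, evap_rate=0.0)
        geom, field, moisture, _ = make_system(nx=15, ny=12, value=40.0, params=params)
        field.values[3:6, 4:8] = 95.0
        total0 = field.values.sum()
        for _ in range(1000):
            step_field(field, moisture, geom, params, STILL)
        assert abs(field.values.sum() - total0) / total0 < 1e-9

    def test_lid_suppresses_relaxation_toward_ambient(self):
        # identical wet cells; one sits under the lid, the other in open air
        params = PhysicsParams()
        results = {}
        for lid in (0.0, 50.0):
            geom = open_geometry(9, 9, lid_extent_y=lid, corridor=(0, 8))
            field = HumidityField.uniform(9, 9, params.ambient_rh, 1.0, params)
            moisture = SubstrateMoisture(np.zeros((9, 9)), params.capacity)
            moisture.mass[4, 4] = params.capacity
            field.values[4, 4] = 95.0
            for _ in range(200):
                step_field(field, moisture, geom, params, STILL)
            results[lid] = field.values[4, 4]
        assert abs(results[0.0] - params.ambient_rh) < abs(results[50.0] - params.ambient_rh)

    def test_exterior_humidity_nonincreasing_in_fan_strength(self):
        cumulative = []
        for lam_fan in (0.05, 0.2, 1.0):
            params = PhysicsParams(lambda_open=0.01, lambda_fan=lam_fan)
            geom, field, moisture, _ = make_system(nx=20, ny=30, value=40.0, params=params)
            moisture.mass[8:12, 0:10] = params.capacity
            field.values[8:12, 0:10] = 95.0
            fan = Condition(ConditionKind.FAN, FanSide.RIGHT)
            for _ in range(400):
                step_field(field, moisture, geom, params, fan)
            cumulative.append(field.values[:, 10:].sum())
        assert cumulative[0] >= cumulative[1] >= cumulative[2]

    def test_dimension_mismatch_rejected(self):
        geom, field, _, params = make_system(nx=10, ny=10)
        wrong = SubstrateMoisture(np.zeros((5, 5)), 0.15)
        with pytest.raises(ValueError, match="dimension"):
            step_field(field, wrong, geom, params, STILL)


def params_ambient() -> float:
    return PhysicsParams().ambient_rh


class TestWaterLedger:
    def test_mass_conserved_without_ambient_exchange(self):
        params = PhysicsParams(lambda_open=0.0, lambda_fan=0.0)
        geom, field, moisture, _ = make_system(nx=12, ny=12, value=40.0, params=params)
        rng = np.random.default_rng(7)
        rh0 = field.values.sum()
        added = 0.0
        for i in range(2000):
            if i % 10 == 0:
                cell = (int(rng.integers(12)), int(rng.integers(12)))
                _, runoff = deposit_water(moisture, cell, 0.01)
                added += 0.01 - runoff
            step_field(field, moisture, geom, params, STILL)
        held_in_field = (field.values.sum() - rh0) / params.gamma
        assert added == pytest.approx(moisture.total() + held_in_field, rel=1e-6)

    def test_ledger_closes_with_ambient_exchange(self):
        params = PhysicsParams(lambda_open=0.01)
        geom, field, moisture, _ = make_system(nx=12, ny=12, value=40.0, params=params)
        rh0 = field.values.sum()
        added, lost = 0.0, 0.0
        for i in range(2000):
            if i % 5 == 0:
                _, runoff = deposit_water(moisture, (6, 6), 0.02)
                added += 0.02 - runoff
            _, _, out = step_field(field, moisture, geom, params, STILL)
            lost += out
        held = (field.values.sum() - rh0) / params.gamma
        assert added == pytest.approx(moisture.total() + held + lost, rel=1e-6)


class TestDepositWater:
    def test_dry_cell_takes_full_drop(self):
        m = SubstrateMoisture(np.zeros((4, 4)), capacity=0.15)
        _, runoff = deposit_water(m, (1, 2), 0.1)
        assert m.mass[1, 2] == pytest.approx(0.1) and runoff == 0.0

    def test_saturated_cell_sheds_runoff(self):
        m = SubstrateMoisture(np.full((2, 2), 0.15), capacity=0.15)
        _, runoff = deposit_water(m, (0, 0), 0.1)
        assert m.mass[0, 0] == pytest.approx(0.15) and runoff == pytest.approx(0.1)

    def test_zero_amount_is_identity(self):
        m = SubstrateMoisture(np.zeros((2, 2)), capacity=0.15)
        _, runoff = deposit_water(m, (1, 1), 0.0)
        assert m.mass.sum() == 0.0 and runoff == 0.0

    def test_out_of_grid_rejected(self):
        m = SubstrateMoisture(np.zeros((2, 2)), capacity=0.15)
        with pytest.raises(IndexError):
            deposit_water(m, (5, 0), 0.1)

    @settings(derandomize=True, max_examples=30)
    @given(amount=st.floats(0, 1), frac=st.floats(0, 1))
    def test_absorbed_plus_runoff_equals_drop(self, amount, frac):
        m = SubstrateMoisture(np.array([[0.15 * frac]]), capacity=0.15)
        before = m.total()
        _, runoff = deposit_water(m, (0, 0), amount)
        assert m.total() - before + runoff == pytest.approx(amount, abs=1e-12)
        assert m.mass.max() <= 0.15 + 1e-12


class TestSampleHumidity:
    def test_uniform_field_everywhere(self):
        _, field, _, _ = make_system(value=40.0)
        for pos in [(0.1, 0.1), (10.0, 7.3), (19.9, 19.9)]:
            assert sample_humidity(field, pos) == pytest.approx(40.0)

    def test_cell_center_returns_cell_value(self):
        _, field, _, _ = make_system(value=40.0)
        field.values[3, 4] = 88.0
        assert sample_humidity(field, (3.5, 4.5)) == pytest.approx(88.0)

    def test_midpoint_of_two_cells_averages(self):
        _, field, _, _ = make_system(value=70.0)
        field.values[5, 5] = 80.0
        assert sample_humidity(field, (5.5 + 0.5, 5.5)) == pytest.approx(75.0)

    def test_out_of_bounds_rejected(self):
        _, field, _, _ = make_system()
        with pytest.raises(ValueError, match="outside"):
            sample_humidity(field, (-1.0, 5.0))

    def test_structure_cells_masked_out(self):
        geom, field, _, _ = make_system(value=90.0)
        geom.occupancy[5, 5] = 1
        field.values[5, 5] = 0.0  # stale value inside a wall
        assert sample_humidity(field, (6.0, 5.5), geom) == pytest.approx(90.0)


class TestConstruction:
    def test_stability_bound_enforced(self):
        params = PhysicsParams(diffusivity=2.0)
        with pytest.raises(ValueError, match="stability"):
            HumidityField(np.full((4, 4), 40.0), 1.0, dt=0.5).check_stability(params)

    def test_rh_range_enforced(self):
        with pytest.raises(ValueError):
            HumidityField(np.full((4, 4), 120.0), 1.0, 0.01)

    def test_fan_weaker_than_open_rejected(self):
        with pytest.raises(ValueError):
            PhysicsParams(lambda_open=0.5, lambda_fan=0.1)
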