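"""Integration, steady states, Jacobian and stability."""

import numpy as np
import pytest

from hptaxis import (
    HormoneState,
    ModelParameters,
    dstate_dt,
    get_preset,
    is_stable,
    jacobian,
    simulate,
    steady_state,
)

BASAL = HormoneState(1.0, 1.0, 15.0)


class TestSimulate:
    def test_steady_state_is_invariant_under_the_flow(self, design_a):
        traj = simulate(design_a, BASAL, t_end=1000.0, n_out=50)
        assert traj.final_state.as_array() == pytest.approx(BASAL.as_array(), rel=1e-6)

    @pytest.mark.parametrize("preset", ["design_A", "design_B"])
    def test_converges_to_basal_from_displaced_start(self, preset):
        params = get_preset(preset)
        traj = simulate(params, HormoneState(0.5, 0.5, 5.0), t_end=5000.0, n_out=50)
        assert traj.final_state.as_array() == pytest.approx(BASAL.as_array(), rel=1e-5)

    def test_short_integration_stays_near_start(self, design_a):
        init = HormoneState(0.0, 0.0, 0.0)
        traj = simulate(design_a, init, t_end=1e-9, n_out=2)
        assert traj.final_state.as_array() == pytest.approx(init.as_array(), abs=1e-6)

    def test_trajectories_stay_nonnegative(self, design_a):
        rng = np.random.default_rng(11)
        for _ in range(5):
            factors = rng.lognormal(0.0, 0.5, size=14)
            d = design_a.as_dict()
            params = ModelParameters.from_constants(
                **{k: v * f for (k, v), f in zip(d.items(), factors)}
            )
            init = HormoneState(*rng.uniform(0.0, 20.0, size=3))
            traj = simulate(params, init, t_end=200.0, n_out=40)
            assert np.all(traj.states >= 0.0)

    def test_trajectory_frame_columns(self, design_a):
        frame = simulate(design_a, BASAL, t_end=1.0, n_out=5).to_frame()
        assert list(frame.columns) == ["time_h", "TRH", "TSH", "TH"]
        assert len(frame) == 5

    def test_invalid_horizon_rejected(self, design_a):
        with pytest.raises(ValueError):
            simulate(design_a, BASAL, t_end=-1.0)


class TestSteadyState:
    @pytest.mark.parametrize("preset", ["design_A", "design_B"])
    def test_presets_reach_the_calibration_target(self, preset):
        ss = steady_state(get_preset(preset), HormoneState(0.5, 0.5, 5.0))
        assert ss.as_array() == pytest.approx(BASAL.as_array(), rel=1e-9)

    @pytest.mark.parametrize("preset", ["design_A_printed", "design_B_printed"])
    def test_printed_presets_land_within_rounding_of_target(self, preset):
        ss = steady_state(get_preset(preset))
        assert ss.as_array() == pytest.approx(BASAL.as_array(), rel=1e-2)

    def test_result_independent_of_start(self, design_a):
        starts = [
            HormoneState(0.1, 0.1, 0.1),
            HormoneState(10.0, 10.0, 100.0),
            HormoneState(0.01, 5.0, 50.0),
        ]
        states = [steady_state(design_a, s).as_array() for s in starts]
        for y in states[1:]:
            assert y == pytest.approx(states[0], rel=1e-8)

    def test_agrees_with_long_integration_under_random_perturbation(self, design_a):
        rng = np.random.default_rng(3)
        for _ in range(10):
            d = design_a.as_dict()
            params = ModelParameters.from_constants(
                **{k: v * rng.lognormal(0.0, 0.1) for k, v in d.items()}
            )
            root_ss = steady_state(params).as_array()
            flow_ss = simulate(
                params, BASAL, t_end=30 * np.log(2) / params.k2, n_out=20
            ).final_state.as_array()
            assert flow_ss == pytest.approx(root_ss, rel=1e-6)

    def test_severed_cascade_collapses_to_origin(self, design_a):
        # Without TRH production the whole axis shuts down.
        params = design_a.with_value("k5", 1e-300)
        ss = steady_state(params, HormoneState(0.5, 0.5, 5.0)).as_array()
        assert ss == pytest.approx(np.zeros(3), abs=1e-6)

    def test_monotone_comparative_statics(self, design_a):
        # Steady-state TH rises with the TH production capacity and falls
        # with its clearance.
        th0 = steady_state(design_a).th
        th_hi_k1 = steady_state(design_a.with_value("k1", design_a.k1 * 1.2)).th
        th_hi_k2 = steady_state(design_a.with_value("k2", design_a.k2 * 1.2)).th
        assert th_hi_k1 > th0 > th_hi_k2


class TestJacobianAndStability:
    def test_diagonal_is_pure_clearance(self, design_a):
        j = jacobian(design_a, BASAL)
        assert np.diag(j) == pytest.approx([-design_a.k6, -design_a.k4, -design_a.k2])

    def test_regulation_sign_pattern(self, design_a):
        j = jacobian(design_a, BASAL)
        assert j[1, 0] > 0   # TRH stimulates TSH
        assert j[1, 2] < 0   # TH inhibits TSH
        assert j[0, 2] < 0   # TH inhibits TRH
        assert j[2, 1] > 0   # TSH stimulates TH
        assert j[0, 1] == 0 and j[2, 0] == 0

    def test_matches_finite_differences_on_random_states(self, design_a):
        rng = np.random.default_rng(5)
        for _ in range(10):
            y = rng.uniform(0.5, 20.0, size=3)
            state = HormoneState(*y)
            j = jacobian(design_a, state)
            num = np.zeros((3, 3))
            h = 1e-7
            for col in range(3):
                up, dn = y.copy(), y.copy()
                up[col] += h * y[col]
                dn[col] -= h * y[col]
                num[:, col] = (
                    dstate_dt(up, design_a) - dstate_dt(dn, design_a)
                ) / (2 * h * y[col])
            scale = np.abs(j) + 1e-9
            assert np.max(np.abs(j - num) / scale) < 1e-5

    def test_jacobian_rejects_zero_components(self, design_a):
        with pytest.raises(ValueError):
            jacobian(design_a, HormoneState(0.0, 1.0, 15.0))

    @pytest.mark.parametrize("preset", ["design_A", "design_B"])
    def test_presets_are_linearly_stable(self, preset):
        params = get_preset(preset)
        ss = steady_state(params)
        stable, real_parts = is_stable(params, ss)
        assert stable
        assert np.all(real_parts < 0)

    @pytest.mark.parametrize("preset", ["design_A", "design_B"])
    def test_timescale_separation_makes_system_stiff(self, preset):
        params = get_preset(preset)
        _, real_parts = is_stable(params, steady_state(params))
        assert np.max(np.abs(real_parts)) / np.min(np.abs(real_parts)) > 100

    def test_is_stable_refuses_non_steady_state(self, design_a):
        with pytest.raises(ValueError):
            is_stable(design_a, HormoneState(2.0, 2.0, 2.0))
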