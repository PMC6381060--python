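"""Recurrent circuit: kernels, drives, equilibria, integration, readout."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from skewadapt import circuit, protocols, stimgen
from skewadapt.circuit import (
    CircuitState,
    VariantParams,
    adaptation_response,
    compute_drives,
    count_modes,
    direction_kernel,
    peak_location,
    probe_tuning,
    readout,
    readout_weights,
    run_segment,
    steady_state_membrane,
    steady_state_synapse,
    step,
)
from skewadapt.grid import DirectionGrid, DirectionSignal


def params_nosyn(lam=0.0, **kw):
    """Parameters with frozen efficacies (alpha = beta = 0)."""
    defaults = dict(lam=lam, alpha_ff=0.0, beta_ff=0.0, alpha_fb=0.0, beta_fb=0.0, temp=0.001)
    defaults.update(kw)
    return VariantParams(**defaults)


class TestGrid:
    def test_default_grid_is_symmetric_and_contains_zero(self, grid):
        assert grid.n == 37 and grid.circular
        assert np.allclose(grid.angles + grid.angles[::-1], 0.0)
        assert 0.0 in grid.angles

    def test_half_circle_grid(self, half_grid):
        assert half_grid.n == 37
        assert half_grid.angles[0] == -90.0 and half_grid.angles[-1] == 90.0
        assert half_grid.spacing == 5.0

    def test_invalid_grids_rejected(self):
        with pytest.raises(ValueError):
            DirectionGrid(np.array([0.0, -10.0, 10.0]))
        with pytest.raises(ValueError):
            DirectionGrid(np.array([-10.0, 0.0, 20.0]))


class TestKernel:
    def test_normalized_rows_sum_to_one(self, grid):
        k = direction_kernel(45.0, grid, normalized=True)
        assert np.allclose(k.sum(axis=1), 1.0)

    def test_symmetric_weights(self, grid):
        k = direction_kernel(45.0, grid)
        assert np.allclose(k, k.T)
        # equidistant inputs get equal weight
        i = grid.index_nearest(0.0)
        assert k[i, i - 2] == pytest.approx(k[i, i + 2])

    def test_narrow_sigma_limit_is_identity(self, grid):
        k = direction_kernel(1e-6, grid, normalized=True)
        assert np.allclose(k, np.eye(grid.n), atol=1e-12)

    def test_unnormalized_diagonal_is_one(self, grid):
        k = direction_kernel(45.0, grid, normalized=False)
        assert np.allclose(np.diag(k), 1.0)

    def test_rejects_nonpositive_sigma(self, grid):
        with pytest.raises(ValueError):
            direction_kernel(0.0, grid)


class TestDrives:
    def test_lambda_zero_gives_pure_convolution(self, grid):
        sig = protocols.adapt_signals(grid)["DSK"]
        state = CircuitState.resting(grid)
        state.v_mt[:] = 0.3
        d = compute_drives(state, sig, params_nosyn(lam=0.0))
        k = direction_kernel(45.0, grid)
        assert np.allclose(d.i_ex_v1, k @ sig.values)

    def test_silent_mt_removes_modulation(self, grid):
        sig = protocols.adapt_signals(grid)["DSK"]
        state = CircuitState.resting(grid)
        state.y_fb[:] = 0.123
        d = compute_drives(state, sig, params_nosyn(lam=20.0))
        assert np.allclose(d.i_mod_v1, 0.0)
        k = direction_kernel(45.0, grid)
        assert np.allclose(d.i_ex_v1, k @ sig.values)

    def test_uniform_input_balances_inhibition(self, grid):
        sig = DirectionSignal(grid, np.full(grid.n, 0.37))
        d = compute_drives(CircuitState.resting(grid), sig, params_nosyn(lam=20.0))
        assert np.allclose(d.i_ex_v1, d.i_inh_v1)
        assert d.i_inh_v1 == pytest.approx(d.i_ex_v1.mean())

    def test_grid_mismatch_rejected(self, grid, half_grid):
        sig = DirectionSignal(half_grid, np.zeros(half_grid.n))
        state = CircuitState.resting(DirectionGrid.full_circle(11))
        with pytest.raises(ValueError):
            compute_drives(state, sig, params_nosyn())


class TestEquilibria:
    @pytest.mark.parametrize(
        "i_ex,i_inh,expected",
        [(0.5, 0.5, 0.0), (1.0, 0.0, 0.5), (1e6, 1.0, pytest.approx(1.0, abs=1e-5))],
    )
    def test_membrane_fixed_point(self, i_ex, i_inh, expected):
        assert steady_state_membrane(i_ex, i_inh) == expected

    @pytest.mark.parametrize(
        "alpha,beta,v,expected",
        [
            (1.0, 0.0, 0.7, 1.0),
            (0.5, 10.0, 0.0, 1.0),
            (0.04, 1.2, 1.0, 0.04 / 1.24),  # 0.0322580...
            (1.2, 10.0, 1.0, 1.2 / 11.2),  # 0.1071428...
        ],
    )
    def test_synapse_equilibrium(self, alpha, beta, v, expected):
        assert steady_state_synapse(alpha, beta, v) == pytest.approx(expected, rel=1e-12)

    def test_undefined_equilibrium_rejected(self):
        with pytest.raises(ValueError):
            steady_state_synapse(0.0, 1.0, 0.0)

    @given(
        alpha=st.floats(0.01, 2.0), beta=st.floats(0.0, 20.0), v=st.floats(0.0, 1.0)
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_equilibrium_in_unit_interval(self, alpha, beta, v):
        y = steady_state_synapse(alpha, beta, v)
        assert 0.0 < y <= 1.0


class TestStep:
    def test_resting_fixed_point(self, grid):
        state = CircuitState.resting(grid)
        sig = DirectionSignal.zeros(grid)
        out = step(state, sig, 0.001, params_nosyn(lam=20.0))
        assert np.allclose(out.v_v1, 0) and np.allclose(out.v_mt, 0)
        assert np.allclose(out.y_ff, 1) and np.allclose(out.y_fb, 1)
        assert out.t == pytest.approx(0.001)

    def test_rejects_large_dt(self, grid):
        state = CircuitState.resting(grid)
        sig = DirectionSignal.zeros(grid)
        with pytest.raises(ValueError, match="dt"):
            step(state, sig, 0.01, params_nosyn())

    def test_state_invariant_validation(self, grid):
        state = CircuitState.resting(grid)
        state.v_v1[0] = 1.5
        with pytest.raises(ValueError, match="v_v1"):
            state.validate(tol=1e-6)


class TestRunSegment:
    def test_zero_duration_is_identity(self, grid):
        state = CircuitState.resting(grid)
        state.v_v1[:] = 0.2
        res = run_segment(state, DirectionSignal.zeros(grid), 0.0, 0.001, params_nosyn())
        assert np.allclose(res.state.v_v1, state.v_v1)
        assert res.state.t == state.t

    def test_blank_segment_replenishes_efficacies(self, grid):
        p = protocols.variant_params(5)
        state = CircuitState.resting(grid)
        state.y_ff[:] = 0.5
        res = run_segment(state, DirectionSignal.zeros(grid), 5.0, 0.001, p)
        # tau_syn/alpha_ff = 1 s: five time constants recover within 1%
        assert np.all(res.state.y_ff > 0.99)

    def test_halving_dt_changes_little(self, grid):
        p = protocols.variant_params(5)
        sig = protocols.adapt_signals(grid)["DSK"]
        a = run_segment(CircuitState.resting(grid), sig, 1.0, 0.001, p)
        b = run_segment(CircuitState.resting(grid), sig, 1.0, 0.0005, p)
        for name in ("v_v1", "v_mt"):
            diff = np.abs(getattr(a.state, name) - getattr(b.state, name)).max()
            assert diff < 1e-3, name

    def test_fast_and_reference_paths_agree(self, grid):
        p = protocols.variant_params(5)
        sig = protocols.adapt_signals(grid)["DSK"]
        state = CircuitState.resting(grid)
        a = run_segment(state, sig, 0.3, 0.001, p, use_fast=True)
        b = run_segment(state, sig, 0.3, 0.001, p, use_fast=False)
        for name in ("v_v1", "v_mt", "y_ff", "y_fb"):
            assert np.allclose(
                getattr(a.state, name), getattr(b.state, name), atol=1e-12
            ), name
        assert np.allclose(a.mean_rect_mt, b.mean_rect_mt, atol=1e-12)

    def test_trajectory_recording(self, grid):
        p = protocols.variant_params(5)
        sig = protocols.adapt_signals(grid)["DSK"]
        res = run_segment(
            CircuitState.resting(grid), sig, 0.05, 0.001, p, record_stride=10
        )
        assert res.trace is not None
        assert res.trace["v_v1"].shape[1] == grid.n
        assert res.trace["t"][-1] == pytest.approx(0.05)


class TestReadout:
    def test_weights_are_mirror_symmetric(self, grid):
        w = readout_weights(grid)
        assert np.allclose(w.g_up, w.g_down[::-1])

    def test_symmetric_activity_gives_half(self, grid):
        v = np.exp(-(grid.angles**2) / (2 * 15.0**2))
        p_up, p_down = readout(v, readout_weights(grid), temp=0.001)
        assert p_up == pytest.approx(0.5, abs=1e-12)
        assert p_up + p_down == pytest.approx(1.0)

    def test_small_temperature_limit_saturates(self, grid):
        v = np.exp(-((grid.angles - 20.0) ** 2) / (2 * 15.0**2))
        p_up, _ = readout(v, readout_weights(grid), temp=1e-12)
        assert p_up == pytest.approx(1.0)

    def test_swapping_channels_swaps_probabilities(self, grid):
        rng = np.random.default_rng(0)
        v = rng.random(grid.n)
        w = readout_weights(grid)
        swapped = circuit.ReadoutWeights(g_up=w.g_down, g_down=w.g_up)
        p_up, p_down = readout(v, w, temp=0.001)
        q_up, q_down = readout(v, swapped, temp=0.001)
        assert p_up == pytest.approx(q_down) and p_down == pytest.approx(q_up)

    def test_rejects_nonpositive_temperature(self, grid):
        with pytest.raises(ValueError):
            readout(np.zeros(grid.n), readout_weights(grid), temp=0.0)


class TestCircuitSymmetries:
    def test_mirror_equivariance_of_dynamics(self, grid):
        """Reflecting the input about 0° reflects all responses and swaps P_up/P_down."""
        p = protocols.variant_params(5)
        sig = protocols.adapt_signals(grid)["DSK"]
        res = run_segment(CircuitState.resting(grid), sig, 0.3, 0.001, p)
        resm = run_segment(CircuitState.resting(grid), sig.mirrored(), 0.3, 0.001, p)
        for name in ("v_v1", "v_mt", "y_ff", "y_fb"):
            assert np.allclose(
                getattr(res.state, name), getattr(resm.state, name)[::-1], atol=1e-12
            ), name
        w = readout_weights(grid)
        p_up, p_down = readout(res.state.v_mt, w, 0.001)
        q_up, q_down = readout(resm.state.v_mt, w, 0.001)
        assert p_up == pytest.approx(q_down, abs=1e-12)

    def test_probe_tuning_unadapted_peaks_at_probe(self, grid):
        p = protocols.variant_params(5)
        cv1, cmt = probe_tuning(CircuitState.resting(grid), [0.0], p, grid=grid)
        assert grid.angles[np.argmax(cv1[0])] == 0.0
        assert grid.angles[np.argmax(cmt[0])] == 0.0
        assert cv1.max() == pytest.approx(1.0)

    def test_probe_tuning_does_not_mutate_state(self, grid):
        p = protocols.variant_params(5)
        state = CircuitState.resting(grid)
        state.y_ff[:] = 0.7
        before = state.y_ff.copy()
        probe_tuning(state, [0.0, 5.0], p, grid=grid)
        assert np.array_equal(state.y_ff, before)


class TestPeakUtilities:
    def test_parabolic_peak_interpolation(self, grid):
        true_peak = 12.3
        vals = -((grid.angles - true_peak) ** 2)
        assert peak_location(grid, vals) == pytest.approx(true_peak, abs=1e-9)

    def test_count_modes_on_circular_profile(self, grid):
        two = (
            np.exp(-((grid.angles + 60) ** 2) / 200.0)
            + 0.8 * np.exp(-((grid.angles - 60) ** 2) / 200.0)
        )
        assert len(count_modes(two)) == 2
        one = np.exp(-(grid.angles**2) / 800.0)
        assert len(count_modes(one)) == 1

    def test_adaptation_response_is_normalized(self, grid):
        p = protocols.variant_params(5)
        sig = protocols.adapt_signals(grid)["DSK"]
        c1, cm, state = adaptation_response(p, sig, 0.1)
        assert c1.max() == pytest.approx(1.0) and cm.max() == pytest.approx(1.0)
        assert state.t == pytest.approx(0.1)
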