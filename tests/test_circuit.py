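"""Circuit dynamics: shunting equation, connectivity taps, and integration."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from blmotion import (
    LAYERS,
    Direction,
    LGNParams,
    NetworkState,
    ShuntingParams,
    StimulusSpec,
    cell_count,
    directional_rhs,
    full_rhs,
    interneuron_rhs,
    neighbor_ahead,
    neighbor_behind,
    offset_rhs,
    onset_rhs,
    rectify,
    shunting_rhs,
    simulate,
    srf_rhs,
)

L, R = Direction.L, Direction.R
P = ShuntingParams()


def shunting_equilibrium(I_exc, I_inh, p=P):
    """Closed-form fixed point of the shunting ODE under frozen drives."""
    return (p.alpha * I_exc - p.B * p.omega_bound * I_inh) / (
        p.A + I_exc + p.B * I_inh)


class TestShuntingEquation:
    def test_rectify(self):
        assert rectify(0.5) == 0.5
        assert rectify(-0.3) == 0
        assert rectify(0) == 0

    def test_quiescence(self):
        assert shunting_rhs(0.0, 0.0, 0.0, P) == 0.0

    def test_unit_excitation_from_rest(self):
        assert shunting_rhs(0.0, 1.0, 0.0, P) == pytest.approx(1.0)

    def test_slowdown_divides_rate_only(self):
        fast = shunting_rhs(0.2, 1.0, 0.5, P)
        slow = shunting_rhs(0.2, 1.0, 0.5, P, slowdown=P.C)
        assert slow == pytest.approx(fast / P.C)

    @pytest.mark.parametrize("I_exc, I_inh", [
        (1.0, 0.0), (0.0, 1.0), (0.5, 0.2), (2.0, 1.0), (0.01, 0.0)])
    def test_closed_form_equilibrium_is_stationary(self, I_exc, I_inh):
        x_star = shunting_equilibrium(I_exc, I_inh)
        assert shunting_rhs(x_star, I_exc, I_inh, P) == pytest.approx(0.0, abs=1e-12)

    def test_reference_equilibria(self):
        assert shunting_equilibrium(1.0, 0.0) == pytest.approx(1 / 1.1)
        assert shunting_equilibrium(0.0, 1.0) == pytest.approx(-3.0 / 10.1)

    @pytest.mark.parametrize("I_exc, I_inh, slowdown", [
        (1.0, 0.0, 1.0), (0.0, 1.0, 1.0), (0.7, 0.3, 1.0), (1.0, 0.0, 10.0)])
    def test_frozen_input_integration_reaches_equilibrium(self, I_exc, I_inh,
                                                          slowdown):
        # independent oracle: integrate the scalar ODE for 100 tau (1000 tau for
        # the slowed accumulator) and compare against the closed form
        horizon = 100.0 * P.tau * slowdown
        sol = solve_ivp(lambda t, x: shunting_rhs(x[0], I_exc, I_inh, P,
                                                  slowdown=slowdown),
                        (0, horizon), [0.0], rtol=1e-10, atol=1e-12)
        assert sol.y[0, -1] == pytest.approx(
            shunting_equilibrium(I_exc, I_inh), abs=1e-4)

    def test_negative_drive_rejected(self):
        with pytest.raises(ValueError):
            shunting_rhs(0.0, -0.1, 0.0, P)
        with pytest.raises(ValueError):
            shunting_rhs(0.0, 0.0, -0.1, P)


class TestNeighbors:
    def test_ahead(self):
        assert neighbor_ahead(4, R, 7) == 5
        assert neighbor_ahead(4, L, 7) == 3
        assert neighbor_ahead(7, R, 7) is None
        assert neighbor_ahead(1, L, 7) is None

    def test_behind(self):
        assert neighbor_behind(4, R, 7) == 3
        assert neighbor_behind(4, L, 7) == 5
        assert neighbor_behind(1, R, 7) is None
        assert neighbor_behind(7, L, 7) is None

    def test_ahead_behind_are_inverses(self):
        for i in range(2, 7):
            for d in (L, R):
                assert neighbor_behind(neighbor_ahead(i, d, 7), d, 7) == i

    def test_out_of_range_raises(self):
        with pytest.raises(IndexError):
            neighbor_ahead(0, R, 7)


class TestLayerTaps:
    """Worked substitution examples with Table-1 constants."""

    def test_interneuron_quiescent(self):
        s = NetworkState.zeros(7)
        assert interneuron_rhs(s, 4, R, 0.0, P) == 0.0

    def test_interneuron_pure_excitation(self):
        s = NetworkState.zeros(7)
        assert interneuron_rhs(s, 4, R, 1.0, P) == pytest.approx(1.0)

    def test_interneuron_nulling_inhibition(self):
        s = NetworkState.zeros(7)
        s.inh[4, L.index] = 0.5   # interneuron at position 5, leftward
        # 1*1 - 10*0.3*0.5 = -0.5
        assert interneuron_rhs(s, 4, R, 1.0, P) == pytest.approx(-0.5)

    def test_directional_shares_interneuron_taps(self):
        # same synaptic taps: for equal membrane states the derivatives match
        rng = np.random.default_rng(7)
        s = NetworkState.zeros(7)
        s.inh[:] = rng.uniform(-0.3, 1.0, s.inh.shape)
        s.dir[:] = s.inh
        for i in (1, 4, 7):
            for d in (L, R):
                assert directional_rhs(s, i, d, 0.6, P) == pytest.approx(
                    interneuron_rhs(s, i, d, 0.6, P))

    def test_srf_product_gating(self):
        s = NetworkState.zeros(7)
        s.dir[3, R.index] = 0.5   # position 4
        assert srf_rhs(s, 4, R, P) == 0.0      # behind factor zero
        s.dir[2, R.index] = 0.5   # position 3 (behind for rightward)
        # 10 * 0.25 * (1 - 0) = 2.5
        assert srf_rhs(s, 4, R, P) == pytest.approx(2.5)

    def test_srf_equilibrium_under_full_gating(self):
        assert shunting_equilibrium(10.0, 0.0) == pytest.approx(10 / 10.1)

    def test_srf_edge_cell_silent(self):
        s = NetworkState.zeros(7)
        s.dir[:, R.index] = 1.0
        assert srf_rhs(s, 1, R, P) == 0.0      # behind position off-grid

    def test_onset_preferred_sequence(self):
        s = NetworkState.zeros(7)
        s.srf[4, R.index] = 0.8   # position 5, ahead of 4
        assert onset_rhs(s, 4, R, P) == pytest.approx(0.8)

    def test_onset_null_sequence_vetoed(self):
        s = NetworkState.zeros(7)
        s.srf[4, R.index] = 0.8
        s.srf[3, R.index] = 0.8   # motion already passed through position 4
        # 0.8 - 10*0.3*0.8 = -1.6
        assert onset_rhs(s, 4, R, P) == pytest.approx(-1.6)

    def test_onset_opposite_variant_ignores_own_direction(self):
        s = NetworkState.zeros(7)
        s.srf[4, R.index] = 0.8
        s.srf[3, R.index] = 0.8
        assert onset_rhs(s, 4, R, P, inh_opposite=True) == pytest.approx(0.8)

    def test_offset_preferred_sequence(self):
        s = NetworkState.zeros(7)
        s.srf[2, R.index] = 0.8   # position 3, behind 4: motion stopped short
        assert offset_rhs(s, 4, R, P) == pytest.approx(0.8)

    def test_offset_constant_motion_vetoed(self):
        s = NetworkState.zeros(7)
        s.srf[2, R.index] = 0.8
        s.srf[3, R.index] = 0.8   # motion continued into position 4
        assert offset_rhs(s, 4, R, P) == pytest.approx(-1.6)


def mirror_flat(y: np.ndarray, n: int) -> np.ndarray:
    """Reflect positions and swap directions in the flat state vector."""
    x = y.reshape(len(LAYERS), n, 2)
    return x[:, ::-1, ::-1].ravel()


class TestFullRHS:
    spec, lgn = StimulusSpec(), LGNParams()

    def test_zero_state_no_drive_is_zero(self):
        y = np.zeros(70)
        assert np.all(full_rhs(10.0, y, self.spec, self.lgn, P) == 0.0)

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            full_rhs(0.0, np.zeros(69), self.spec, self.lgn, P)

    def test_matches_scalar_taps(self):
        rng = np.random.default_rng(11)
        y = rng.uniform(-0.3, 1.0, 70)
        t = 2.4
        dy = full_rhs(t, y, self.spec, self.lgn, P).reshape(len(LAYERS), 7, 2)
        state = NetworkState.from_flat(y, 7, time=t)
        from blmotion.stimulus import input_drive
        for i in range(1, 8):
            I_i = input_drive(self.spec, self.lgn, i, t)
            for d in (L, R):
                expected = {
                    "inh": interneuron_rhs(state, i, d, I_i, P),
                    "dir": directional_rhs(state, i, d, I_i, P),
                    "srf": srf_rhs(state, i, d, P),
                    "on": onset_rhs(state, i, d, P),
                    "off": offset_rhs(state, i, d, P),
                }
                for k, layer in enumerate(LAYERS):
                    assert dy[k, i - 1, d.index] == pytest.approx(
                        expected[layer], abs=1e-12), (layer, i, d)

    def test_boundary_derivative_points_inward(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            y = rng.uniform(-P.omega_bound, P.alpha, 70)
            k = rng.integers(70)
            hi = rng.random() < 0.5
            y[k] = P.alpha if hi else -P.omega_bound
            dy = full_rhs(rng.uniform(0, 8), y, self.spec, self.lgn, P)
            assert dy[k] <= 1e-12 if hi else dy[k] >= -1e-12

    def test_mirror_symmetry_of_connectivity(self):
        rng = np.random.default_rng(5)
        y = rng.uniform(-0.3, 1.0, 70)
        mirror_spec = StimulusSpec(start_pos=6, end_pos=2)
        for t in (0.3, 2.7, 4.9, 6.0):
            d1 = full_rhs(t, y, self.spec, self.lgn, P)
            d2 = full_rhs(t, mirror_flat(y, 7), mirror_spec, self.lgn, P)
            assert np.allclose(mirror_flat(d2, 7), d1, atol=1e-12)


class TestSimulate:
    def test_cell_count(self):
        assert cell_count(StimulusSpec()) == 77

    def test_zero_contrast_quiescence(self, defaults):
        spec, _, p = defaults
        traj = simulate(spec, LGNParams(contrast=0.0), p, t_end=8.0)
        assert np.all(traj.states == 0.0)
        assert np.all(traj.inputs == 0.0)

    def test_bounds_on_default_run(self, v1_run):
        _, traj = v1_run
        assert traj.states.min() >= -P.omega_bound - 1e-6
        assert traj.states.max() <= P.alpha + 1e-6

    def test_initial_state_zero_and_times_increasing(self, v1_run):
        _, traj = v1_run
        assert traj.t[0] == 0.0
        assert np.all(traj.states[0] == 0.0)
        assert np.all(np.diff(traj.t) > 0)

    def test_event_sequence_default_run(self, v1_run):
        """Onset activity at the appearance position near t = 0; after the
        input vanishes (t = 5) only a rightward offset cell is active."""
        _, traj = v1_run
        on2r = traj.activity("on", 2, R)
        early = traj.t < 2.5
        assert on2r[early].max() > 0.5
        # onset cells elsewhere stay silent (preemptive inhibition)
        for i in (1, 3, 4, 5, 6, 7):
            assert rectify(traj.activity("on", i, R)).max() == 0.0
        late = traj.t > 5.5
        assert traj.activity("off", 7, R)[late].max() > 0.5
        for i in range(1, 8):
            assert rectify(traj.activity("off", i, L)).max() == 0.0

    def test_null_direction_suppression(self, v1_run):
        """During constant motion only rightward motion is signalled."""
        _, traj = v1_run
        mid = (traj.t > 1.0) & (traj.t < 5.0)
        peak_r = max(rectify(traj.activity("dir", i, R)[mid]).max()
                     for i in range(1, 8))
        peak_l = max(rectify(traj.activity("dir", i, L)[mid]).max()
                     for i in range(1, 8))
        assert peak_l < peak_r
        srf_l = traj.states[:, LAYERS.index("srf"), :, L.index]
        assert rectify(srf_l).max() < 1e-6

    def test_mirror_equivariance(self, defaults):
        spec, lgn, p = defaults
        right = simulate(spec, lgn, p, t_end=12.0)
        left = simulate(StimulusSpec(start_pos=6, end_pos=2), lgn, p, t_end=12.0)
        assert np.allclose(left.t, right.t)
        reflected = left.states[:, :, ::-1, ::-1]
        assert np.max(np.abs(reflected - right.states)) < 1e-6

    def test_integrator_tolerance_independence(self, defaults):
        spec, lgn, p = defaults
        a = simulate(spec, lgn, p, t_end=12.0, rtol=1e-8, atol=1e-10)
        b = simulate(spec, lgn, p, t_end=12.0, rtol=5e-9, atol=5e-11)
        peaks_a = a.states.max(axis=0)
        peaks_b = b.states.max(axis=0)
        assert np.max(np.abs(peaks_a - peaks_b)) < 1e-5

    def test_switch_times_in_sample_grid(self, v1_run):
        _, traj = v1_run
        for m in range(6):
            assert np.any(traj.t == float(m))

    def test_invalid_horizon_rejected(self, defaults):
        spec, lgn, p = defaults
        with pytest.raises(ValueError):
            simulate(spec, lgn, p, t_end=-1.0)
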