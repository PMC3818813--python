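"""Rate dynamics: sigmoid, net inputs, Euler stepping, steady states."""

import numpy as np
import pytest

import ventnet as vn
from ventnet.dense import DenseSynapses
from ventnet.dynamics import (
    NetworkState,
    compute_net_inputs,
    run_to_steady_state,
    stack_stimuli,
    step,
)

from conftest import steady


class TestSigmoid:
    def test_center_and_saturation(self, cfg_full):
        assert vn.sigmoid(12.0, cfg_full) == pytest.approx(0.5)
        assert vn.sigmoid(1e3, cfg_full) == pytest.approx(1.0)
        assert vn.sigmoid(-1e3, cfg_full) == pytest.approx(0.0, abs=1e-12)

    def test_silent_state_value(self, cfg_full):
        # F(0) with the basal slope/center: 1 / (1 + e^{7.2})
        assert vn.sigmoid(0.0, cfg_full) == pytest.approx(1.0 / (1.0 + np.exp(7.2)))

    def test_strictly_increasing(self, cfg_full):
        u = np.linspace(-10, 30, 200)
        assert np.all(np.diff(vn.sigmoid(u, cfg_full)) > 0)


class TestNetInputs:
    def test_zero_state_no_stimuli(self, cfg_small, syn_small):
        state = NetworkState.null(cfg_small)
        u_v, u_a = compute_net_inputs(
            state.y_v, state.y_a, syn_small, np.zeros_like(state.y_v),
            np.zeros_like(state.y_a)
        )
        assert not u_v.any() and not u_a.any()

    def test_single_active_neuron_reads_one_weight(self, cfg_small, syn_small):
        """With exactly one active presynaptic neuron the lateral input at
        any other neuron is that single net synaptic weight."""
        y_a = np.zeros((cfg_small.n_azimuth_auditory, cfg_small.n_freq_auditory))
        y_a[30, 10] = 1.0
        l = syn_small.lateral_auditory(y_a)
        ex, inh = syn_small.auditory_weight((32, 11), (30, 10))
        assert l[32, 11] == pytest.approx(ex - inh, abs=1e-12)
        assert l[30, 10] == pytest.approx(0.0, abs=1e-12)  # no self-synapse

    def test_cross_modal_broadcast(self, cfg_small, syn_small):
        y_v = np.zeros(cfg_small.n_azimuth_visual)
        y_v[20] = 0.8
        y_a = np.zeros((cfg_small.n_azimuth_auditory, cfg_small.n_freq_auditory))
        u_v, u_a = compute_net_inputs(
            y_v, y_a, syn_small, np.zeros_like(y_v), np.zeros_like(y_a)
        )
        # one visual neuron drives its whole auditory frequency column equally
        assert np.allclose(u_a[20], syn_small.W_av * 0.8)
        assert np.allclose(u_a[[19, 21]], 0.0)

    def test_shape_mismatch_rejected(self, cfg_small, syn_small):
        with pytest.raises(ValueError):
            compute_net_inputs(
                np.zeros(7), np.zeros((3, 3)), syn_small, np.zeros(7), np.zeros((3, 3))
            )


class TestEulerStep:
    def test_fixed_point_is_stationary(self, cfg_small, syn_small):
        """If y already equals F(u(y)), a step leaves the state unchanged."""
        state = NetworkState.null(cfg_small)
        for _ in range(4000):
            new = step(state, syn_small, np.zeros_like(state.y_v),
                       np.zeros_like(state.y_a), cfg_small)
            if (
                np.abs(new.y_v - state.y_v).max() < 1e-14
                and np.abs(new.y_a - state.y_a).max() < 1e-14
            ):
                break
            state = new
        after = step(state, syn_small, np.zeros_like(state.y_v),
                     np.zeros_like(state.y_a), cfg_small)
        assert np.allclose(after.y_v, state.y_v, atol=1e-13)

    def test_single_step_from_null(self, cfg_small, syn_small):
        """One Euler step from zero activity: y = (dt / tau) F(e)."""
        stim = vn.StimulusSpec.visual(30)
        e_v, e_a = stack_stimuli([stim], cfg_small)
        state = step(NetworkState.null(cfg_small), syn_small, e_v[0], e_a[0], cfg_small)
        expect = cfg_small.dt / cfg_small.tau_y * vn.sigmoid(e_v[0], cfg_small)
        assert np.allclose(state.y_v, expect)
        assert state.t == pytest.approx(cfg_small.dt)

    def test_monotone_relaxation_under_constant_drive(self, cfg_full):
        """An isolated neuron with constant input approaches F(u) monotonically."""
        cfg = cfg_full
        target = vn.sigmoid(15.0, cfg)
        y, traj = 0.0, []
        for _ in range(300):
            y = y + cfg.dt / cfg.tau_y * (-y + target)
            traj.append(y)
        traj = np.array(traj)
        d = np.diff(traj)
        assert np.all(d >= 0)
        assert np.all(d[:30] > 0)  # strict growth until numerically converged
        assert traj[-1] == pytest.approx(target, abs=1e-6)


class TestSteadyState:
    def test_no_stimulus_stays_essentially_silent(self, cfg_small, syn_small):
        """Without input the network settles at the sigmoid's silent level."""
        stim = vn.StimulusSpec.visual(30, intensity=0.0)
        state = steady(syn_small, stim, cfg_small)
        assert state.y_v.max() < 1.5e-3
        assert state.y_a.max() < 1.5e-3

    def test_visual_stimulus_phantom_activation_stays_subthreshold(
        self, cfg_small, syn_small
    ):
        """A unimodal visual stimulus activates the visual layer sharply;
        the cross-modal drive alone leaves every auditory neuron far below
        the sigmoid center (no self-sustaining phantom activation), and
        columns away from the stimulus stay at the silent background."""
        base = steady(syn_small, vn.StimulusSpec.visual(30, intensity=0.0), cfg_small)
        state = steady(syn_small, vn.StimulusSpec.visual(30), cfg_small)
        assert state.y_v.max() > 0.9
        assert state.y_v[30] == state.y_v.max()
        assert state.y_a.max() < 0.1  # faint, sub-threshold cross-modal echo
        far = np.abs(state.y_a - base.y_a)[[0, 10, 50], :]
        assert far.max() < 1e-4

    def test_translation_equivariance_before_learning(self, cfg_small, syn_small):
        """Shifting both stimuli by a shared azimuth shifts the steady state
        exactly (circular symmetry of the untrained network)."""
        j = cfg_small.freq_anchor_index
        s1 = vn.StimulusSpec.bimodal(35, 25, j, 20.0)
        s2 = vn.StimulusSpec.bimodal((35 + 9) % 60, (25 + 9) % 60, j, 20.0)
        st_batch = run_to_steady_state(syn_small, [s1, s2], cfg_small)
        assert np.all(st_batch.converged)
        assert np.allclose(
            np.roll(st_batch.y_a[0], 9, axis=0), st_batch.y_a[1], atol=1e-12
        )
        assert np.allclose(np.roll(st_batch.y_v[0], 9), st_batch.y_v[1], atol=1e-12)

    def test_halving_dt_barely_moves_steady_state(self, cfg_small, syn_small):
        stim = vn.StimulusSpec.auditory(25, cfg_small.freq_anchor_index, 20.0)
        s1 = steady(syn_small, stim, cfg_small)
        s2 = steady(syn_small, stim, cfg_small.replace(dt=cfg_small.dt / 2))
        assert np.abs(s1.y_a - s2.y_a).max() < 10 * cfg_small.steady_tol

    def test_nonconvergence_is_flagged(self, cfg_small, syn_small):
        cfg = cfg_small.replace(t_max=1.0)  # far too short to converge
        stim = vn.StimulusSpec.auditory(25, cfg.freq_anchor_index, 20.0)
        state = run_to_steady_state(syn_small, stim, cfg)
        assert not state.converged

    def test_batch_matches_single_runs(self, cfg_small, syn_small):
        j = cfg_small.freq_anchor_index
        stims = [
            vn.StimulusSpec.auditory(25, j, 20.0),
            vn.StimulusSpec.bimodal(35, 25, j, 17.0),
        ]
        batch = run_to_steady_state(syn_small, stims, cfg_small)
        for b, stim in enumerate(stims):
            solo = steady(syn_small, stim, cfg_small)
            assert np.abs(batch.y_a[b] - solo.y_a).max() < 5 * cfg_small.steady_tol

    def test_window_and_dense_backends_agree_dynamically(self, cfg_small, syn_small):
        """Identical steady states from the windowed and dense backends."""
        stim = vn.StimulusSpec.bimodal(35, 25, cfg_small.freq_anchor_index, 20.0)
        dense = DenseSynapses(cfg_small)
        s_win = steady(syn_small, stim, cfg_small)
        s_dense = steady(dense, stim, cfg_small)
        assert np.abs(s_win.y_a - s_dense.y_a).max() < 1e-10
        assert np.abs(s_win.y_v - s_dense.y_v).max() < 1e-10

    def test_snapshots_returned_at_requested_times(self, cfg_small, syn_small):
        stim = vn.StimulusSpec.auditory(25, cfg_small.freq_anchor_index, 20.0)
        state, snaps = run_to_steady_state(
            syn_small, stim, cfg_small, snapshot_times=[1.0, 4.0, 25.0]
        )
        assert sorted(snaps) == [1.0, 4.0, 25.0]
        # activity grows through the early transient
        assert snaps[1.0].max() < snaps[4.0].max() <= snaps[25.0].max() + 1e-12
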