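"""Hebbian rule unit behavior, normalization conservation, and the
equivalence of the windowed learning path with the dense reference."""

import numpy as np
import pytest

import ventnet as vn
from ventnet.dense import DenseSynapses, max_abs_difference
from ventnet.dynamics import NetworkState, stack_stimuli, step
from ventnet.plasticity import (
    DegenerateNormalizationError,
    LearningSettings,
    adapt,
    hebbian_deltas,
    learn_step,
    normalize_incoming,
)


@pytest.fixture()
def toy_cfg():
    return vn.ModelConfig()


class TestHebbianDeltas:
    def test_subthreshold_post_gives_no_change(self, toy_cfg):
        """theta_post gates learning: post at 0.4 < 0.5 changes nothing."""
        y = np.array([0.9, 0.4])
        l_ex = np.full((2, 2), 0.1)
        l_in = np.full((2, 2), 0.1)
        d_ex, d_in = hebbian_deltas(y, y, l_ex, l_in, toy_cfg, 0.4,
                                    self_cols=np.array([0, 1]))
        assert not d_ex[1].any() and not d_in[1].any()
        assert d_ex[0, 1] > 0  # supra-threshold post does learn

    def test_saturated_excitatory_synapse_frozen(self, toy_cfg):
        y = np.array([1.0, 1.0])
        l_ex = np.full((2, 2), toy_cfg.Lmax_a)
        d_ex, _ = hebbian_deltas(y, y, l_ex, np.zeros((2, 2)), toy_cfg,
                                 toy_cfg.Lmax_a)
        assert np.allclose(d_ex, 0.0)

    def test_zero_inhibitory_synapse_cannot_go_negative(self, toy_cfg):
        y = np.array([1.0, 1.0])
        _, d_in = hebbian_deltas(y, y, np.zeros((2, 2)), np.zeros((2, 2)),
                                 toy_cfg, toy_cfg.Lmax_a)
        assert np.allclose(d_in, 0.0)

    def test_reciprocal_synapses_modify_asymmetrically(self, toy_cfg):
        """Two co-active neurons with unequal activities: the synapse onto
        the more active neuron changes more (its gate is wider open)."""
        y = np.array([0.9, 0.6])
        l_ex = np.full((2, 2), 0.1)
        d_ex, _ = hebbian_deltas(y, y, l_ex, l_ex.copy(), toy_cfg, 0.4,
                                 self_cols=np.array([0, 1]))
        onto_more_active = d_ex[0, 1]   # pre 0.6, gate 0.9 - 0.5
        onto_less_active = d_ex[1, 0]   # pre 0.9, gate 0.6 - 0.5
        assert onto_more_active != pytest.approx(onto_less_active)
        assert onto_more_active > onto_less_active

    def test_self_columns_forced_zero(self, toy_cfg):
        y = np.array([1.0, 1.0])
        d_ex, d_in = hebbian_deltas(y, y, np.full((2, 2), 0.1),
                                    np.full((2, 2), 0.1), toy_cfg, 0.4,
                                    self_cols=np.array([0, 1]))
        assert d_ex[0, 0] == d_ex[1, 1] == 0.0
        assert d_in[0, 0] == d_in[1, 1] == 0.0


class TestNormalization:
    def test_unchanged_weights_pass_through(self):
        l = np.array([[0.0, 1.0, 2.0], [3.0, 0.0, 1.0]])
        out = normalize_incoming(l.copy(), l.sum(axis=1))
        assert np.allclose(out, l)

    def test_row_sums_restored_exactly(self):
        rng = np.random.default_rng(0)
        l = rng.uniform(0.1, 1.0, (5, 8))
        target = np.full(5, 3.0)
        out = normalize_incoming(l, target)
        assert np.allclose(out.sum(axis=1), 3.0, rtol=1e-12)

    def test_potentiating_one_synapse_depresses_the_others(self):
        l = np.full((1, 6), 1.0)
        l[0, 2] += 0.5
        out = normalize_incoming(l, np.array([6.0]))
        others = np.delete(out[0], 2)
        assert np.all(others < 1.0)
        assert out[0, 2] > 1.0

    def test_zero_sum_raises(self):
        with pytest.raises(DegenerateNormalizationError):
            normalize_incoming(np.zeros((2, 3)), np.ones(2))


class TestAdaptation:
    def test_requires_bimodal_stimulus(self, cfg_small):
        with pytest.raises(ValueError):
            adapt(vn.StimulusSpec.visual(30), cfg_small)

    def test_gate_never_opens_leaves_synapses_bit_identical(
        self, cfg_small, bimodal_small
    ):
        """With theta_post = 1 no neuron can gate learning: the trained
        state equals the basal state bit for bit."""
        cfg = cfg_small.replace(theta_post=1.0, n_learning_steps=50)
        basal = vn.build_basal_synapses(cfg)
        trained, _ = adapt(bimodal_small, cfg)
        assert trained.n_modified == 0
        assert np.array_equal(trained.Lex_v, basal.Lex_v)
        assert np.array_equal(trained.Lin_v, basal.Lin_v)

    def test_adaptation_is_deterministic(self, cfg_small, bimodal_small):
        cfg = cfg_small.replace(n_learning_steps=40)
        a, _ = adapt(bimodal_small, cfg)
        b, _ = adapt(bimodal_small, cfg)
        assert np.array_equal(a.rows_ex, b.rows_ex)
        assert np.array_equal(a.rows_in, b.rows_in)
        assert np.array_equal(a.Lex_v, b.Lex_v)

    def test_learning_engages_on_small_grid(self, cfg_small, bimodal_small):
        cfg = cfg_small.replace(n_learning_steps=120)
        trained, summary = adapt(bimodal_small, cfg)
        assert trained.n_modified > 0
        assert summary["max_activity_auditory"].max() > cfg.theta_post

    def test_incoming_sums_conserved_and_bounds_hold_every_step(
        self, cfg_small, bimodal_small
    ):
        """The population-normalization rule keeps each neuron's incoming
        excitatory and inhibitory sums at their basal values at every
        learning step, while weights respect 0 <= Lex <= Lmax, Lin >= 0."""
        cfg = cfg_small
        syn = vn.build_basal_synapses(cfg)
        s_ex0, s_in0 = syn.incoming_sums_auditory()
        sv_ex0 = syn.Lex_v.sum(axis=1)
        e_v, e_a = stack_stimuli([bimodal_small], cfg)
        state = NetworkState.null(cfg)
        settings = LearningSettings()
        for _ in range(150):
            state = step(state, syn, e_v[0], e_a[0], cfg)
            learn_step(syn, state.y_v, state.y_a, cfg, settings)
            if syn.n_modified:
                assert syn.rows_ex.min() >= 0.0
                assert syn.rows_ex.max() <= cfg.Lmax_a + 1e-12
                assert syn.rows_in.min() >= 0.0
        s_ex, s_in = syn.incoming_sums_auditory()
        assert np.allclose(s_ex, s_ex0, rtol=1e-8)
        assert np.allclose(s_in, s_in0, rtol=1e-8)
        assert np.allclose(syn.Lex_v.sum(axis=1), sv_ex0, rtol=1e-8)
        assert syn.n_modified > 0  # learning actually happened

    def test_self_entries_stay_zero_through_learning(
        self, cfg_small, bimodal_small
    ):
        cfg = cfg_small.replace(n_learning_steps=80)
        trained, _ = adapt(bimodal_small, cfg)
        for i, j in trained.row_pos:
            ex, inh = trained.auditory_weight((i, j), (i, j))
            assert ex == 0.0 and inh == 0.0
        assert np.all(np.diag(trained.Lex_v) == 0.0)

    def test_windowed_learning_matches_dense_oracle(self, cfg_small, bimodal_small):
        """Same short adaptation on both backends: trained matrices agree."""
        cfg = cfg_small.replace(n_learning_steps=60)
        trained_win, _ = adapt(bimodal_small, cfg)
        dense = DenseSynapses(cfg)
        e_v, e_a = stack_stimuli([bimodal_small], cfg)
        state = NetworkState.null(cfg)
        settings = LearningSettings()
        for _ in range(60):
            state = step(state, dense, e_v[0], e_a[0], cfg)
            learn_step(dense, state.y_v, state.y_a, cfg, settings)
        assert max_abs_difference(trained_win, dense) < 1e-10

    def test_visual_layer_can_be_frozen(self, cfg_small, bimodal_small):
        cfg = cfg_small.replace(n_learning_steps=60)
        trained, _ = adapt(
            bimodal_small, cfg, LearningSettings(visual=False)
        )
        basal = vn.build_basal_synapses(cfg)
        assert np.array_equal(trained.Lex_v, basal.Lex_v)
        assert trained.n_modified > 0
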