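"""Shared fixtures: small-grid configurations and pre-built synapse states.

Full-grid (180 x 40) runs appear only in the acceptance suite; everything
else uses a reduced 60 x 20 auditory layer with correspondingly narrower
stimulus widths so activations stay localized on the smaller ring.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

import ventnet as vn

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def cfg_small() -> vn.ModelConfig:
    """60-azimuth / 20-frequency configuration for fast exact tests."""
    return vn.ModelConfig(
        n_azimuth_visual=60,
        n_azimuth_auditory=60,
        n_freq_auditory=20,
        sigma_p_a=10.0,
        sigma_f_a=7.0,
        sigma_in_p_v=12.0,
        t_max=600.0,
        freq_anchor_index=9,
    )


@pytest.fixture(scope="session")
def syn_small(cfg_small) -> vn.SynapseState:
    return vn.build_basal_synapses(cfg_small)


@pytest.fixture(scope="session")
def cfg_full() -> vn.ModelConfig:
    """The default full-scale configuration."""
    return vn.ModelConfig()


@pytest.fixture(scope="session")
def syn_full(cfg_full) -> vn.SynapseState:
    return vn.build_basal_synapses(cfg_full)


@pytest.fixture(scope="session")
def bimodal_small(cfg_small) -> vn.StimulusSpec:
    """Spatially discrepant pair mid-ring on the small grid."""
    return vn.StimulusSpec.bimodal(35, 25, cfg_small.freq_anchor_index, 20.0)


def steady(syn, stim, cfg):
    state = vn.run_to_steady_state(syn, stim, cfg)
    assert np.all(state.converged)
    return state
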