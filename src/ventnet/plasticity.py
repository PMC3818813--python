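"""Hebbian adaptation of the lateral synapses.

During exposure to a spatially discrepant audio-visual pair, the lateral
excitatory and inhibitory synapses of both layers are trained by a
potentiation rule gated by postsynaptic activity: a synapse changes only
when its postsynaptic neuron exceeds the threshold ``theta_post``, by an
amount proportional to presynaptic activity.  Excitatory synapses grow with
a learning factor that vanishes as the weight approaches ``Lmax`` (individual
saturation); inhibitory synapses shrink with a factor proportional to their
own value, so they can never become negative.  After every integration step
the incoming weights of each postsynaptic neuron are rescaled, separately
for the two components, so their sums stay at the basal values (population
normalization): potentiating some inputs necessarily depresses the others.

Self-synapses stay frozen at zero throughout.  Cross-modal weights do not
learn.  The same rules apply to the 1D visual layer with the frequency
dimension absent.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .config import ModelConfig
from .dynamics import NetworkState, stack_stimuli, step
from .stimuli import StimulusSpec
from .synapses import SynapseState, build_basal_synapses

__all__ = [
    "LearningSettings",
    "DegenerateNormalizationError",
    "hebbian_deltas",
    "normalize_incoming",
    "learn_step",
    "adapt",
]


class DegenerateNormalizationError(ArithmeticError):
    """Incoming-weight sum hit zero, so the normalization rescale is undefined."""


@dataclasses.dataclass
class LearningSettings:
    """Which layers learn and for how many integration steps."""

    visual: bool = True
    auditory: bool = True
    n_learning_steps: int | None = None  # default: cfg.n_learning_steps

    def __post_init__(self) -> None:
        if self.n_learning_steps is not None and self.n_learning_steps < 1:
            raise ValueError("n_learning_steps must be >= 1")


def _relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def hebbian_deltas(
    y_pre: np.ndarray,
    y_post: np.ndarray,
    l_ex: np.ndarray,
    l_in: np.ndarray,
    cfg: ModelConfig,
    lmax: float,
    self_cols: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-step weight changes for matrices indexed ``[post, pre]``.

    ``dLex = alpha_ex0 (Lmax - Lex) y_pre [y_post - theta_post]+`` and
    ``dLin = -alpha_in0 Lin y_pre [y_post - theta_post]+``.  ``self_cols``
    gives, per row, the column of the self-synapse to force to zero; for a
    square layer matrix this is simply the diagonal.
    """
    gate = _relu(y_post - cfg.theta_post)[:, None]
    hebb = gate * y_pre[None, :]
    d_ex = cfg.alpha_ex0 * (lmax - l_ex) * hebb
    d_in = -cfg.alpha_in0 * l_in * hebb
    if self_cols is not None:
        rows = np.arange(l_ex.shape[0])
        d_ex[rows, self_cols] = 0.0
        d_in[rows, self_cols] = 0.0
    return d_ex, d_in


def normalize_incoming(l_comp: np.ndarray, initial_sums: np.ndarray) -> np.ndarray:
    """Rescale each row (incoming weights of one neuron) to its initial sum."""
    sums = l_comp.sum(axis=tuple(range(1, l_comp.ndim)))
    if np.any(sums <= 0.0):
        raise DegenerateNormalizationError(
            "incoming-weight sum vanished during normalization"
        )
    factor = initial_sums / sums
    return l_comp * factor.reshape((-1,) + (1,) * (l_comp.ndim - 1))


# ----------------------------------------------------------------------
def _learn_visual(syn: SynapseState, y_v: np.ndarray, cfg: ModelConfig) -> None:
    gate = y_v > cfg.theta_post
    act = np.flatnonzero(gate)
    if act.size == 0:
        return
    d_ex, d_in = hebbian_deltas(
        y_v, y_v[act], syn.Lex_v[act], syn.Lin_v[act], cfg, cfg.Lmax_v, self_cols=act
    )
    syn.Lex_v[act] = normalize_incoming(syn.Lex_v[act] + d_ex, syn.init_sum_ex_v[act])
    syn.Lin_v[act] = normalize_incoming(syn.Lin_v[act] + d_in, syn.init_sum_in_v[act])


def _learn_auditory(syn: SynapseState, y_a: np.ndarray, cfg: ModelConfig) -> None:
    gate = y_a > cfg.theta_post
    if not np.any(gate):
        return
    i_act, j_act = np.nonzero(gate)
    idx = syn.ensure_rows(i_act, j_act)
    g = (y_a[i_act, j_act] - cfg.theta_post)[:, None, None]
    gather = (i_act[:, None] + syn.az_offsets[None, :]) % cfg.n_azimuth_auditory
    y_w = y_a[gather, :]  # (m, W, n_f) presynaptic windows
    m = np.arange(i_act.size)

    ex = syn.rows_ex[idx]
    d_ex = cfg.alpha_ex0 * (cfg.Lmax_a - ex) * y_w * g
    d_ex[m, syn._center, j_act] = 0.0
    new_ex = ex + d_ex
    sums = new_ex.sum(axis=(1, 2))
    if np.any(sums <= 0.0):
        raise DegenerateNormalizationError("auditory excitatory sums vanished")
    syn.rows_ex[idx] = new_ex * (syn.init_sum_ex_a / sums)[:, None, None]

    inh = syn.rows_in[idx]
    d_in = -cfg.alpha_in0 * inh * y_w * g
    d_in[m, syn._center, j_act] = 0.0
    new_in = inh + d_in
    sums = new_in.sum(axis=(1, 2))
    if np.any(sums <= 0.0):
        raise DegenerateNormalizationError("auditory inhibitory sums vanished")
    syn.rows_in[idx] = new_in * (syn.init_sum_in_a / sums)[:, None, None]


def learn_step(
    syn,
    y_v: np.ndarray,
    y_a: np.ndarray,
    cfg: ModelConfig,
    settings: LearningSettings,
) -> None:
    """Apply one Hebbian + normalization update to a synapse state in place.

    Dispatches on the storage backend: the windowed :class:`SynapseState`
    uses the row-window update, the dense reference backend the explicit
    matrix form.  Both implement the same rule.
    """
    if hasattr(syn, "rows_ex"):  # windowed backend
        if settings.visual:
            _learn_visual(syn, y_v, cfg)
        if settings.auditory:
            _learn_auditory(syn, y_a, cfg)
    else:  # dense reference backend
        syn.learn_step(y_v, y_a, settings)


def adapt(
    stim: StimulusSpec,
    cfg: ModelConfig,
    settings: LearningSettings | None = None,
    syn: SynapseState | None = None,
) -> tuple[SynapseState, dict]:
    """Run an adaptation phase and return the trained synapses.

    Starting from the null network state and basal synapses, the (bimodal)
    stimulus is held constant for ``n_learning_steps`` Euler steps; after
    each step the Hebbian deltas are computed from the new activities and
    the population normalization is applied, in both layers.  The returned
    summary records the stimulus, step count, per-step maximum activities
    and the final number of synapse rows touched by learning.
    """
    settings = settings or LearningSettings()
    stim.validate(cfg)
    if not (stim.visual_present and stim.auditory_present):
        raise ValueError("adaptation requires a bimodal stimulus")
    syn = syn.copy() if syn is not None else build_basal_synapses(cfg)
    n_steps = settings.n_learning_steps or cfg.n_learning_steps

    e_v, e_a = stack_stimuli([stim], cfg)
    e_v, e_a = e_v[0], e_a[0]
    state = NetworkState.null(cfg)
    max_v = np.empty(n_steps)
    max_a = np.empty(n_steps)
    for k in range(n_steps):
        state = step(state, syn, e_v, e_a, cfg)
        learn_step(syn, state.y_v, state.y_a, cfg, settings)
        max_v[k] = state.y_v.max()
        max_a[k] = state.y_a.max()

    syn.meta.update(
        trained=True,
        adapt_visual_azimuth=stim.visual_azimuth,
        adapt_auditory_azimuth=stim.auditory_azimuth,
        adapt_freq_index=stim.auditory_freq_index,
        adapt_intensity=stim.auditory_intensity,
        n_learning_steps=n_steps,
        config_hash=cfg.config_hash(),
    )
    summary = {
        "n_steps": n_steps,
        "max_activity_visual": max_v,
        "max_activity_auditory": max_a,
        "n_modified_rows": getattr(syn, "n_modified", None),
        "final_t_ms": state.t,
    }
    return syn, summary
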