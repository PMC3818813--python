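"""Network dynamics: net inputs, Euler steps, steady-state integration.

Each neuron obeys first-order rate dynamics
``tau_y * dy/dt = -y + F(u)`` with the logistic activation
``F(u) = 1 / (1 + exp(-s (u - theta)))`` saturating at 1.  The net input
``u`` is the sum of the external stimulus, the lateral Mexican-hat input and
the cross-modal input.  Integration is explicit Euler from the null state
(all activities zero), with a synchronous update: all net inputs are
computed from the current activities, then all activities advance one step.

Every routine accepts either a single network (``y_v`` of shape ``(n_v,)``,
``y_a`` of shape ``(n_az, n_f)``) or a batch with leading dimensions —
independent networks integrated in lockstep, which is how parameter sweeps
and tuning-curve probes are run efficiently.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .config import ModelConfig
from .stimuli import StimulusSpec, make_auditory_input, make_visual_input
from .synapses import SynapseState

__all__ = [
    "NetworkState",
    "sigmoid",
    "compute_net_inputs",
    "step",
    "run_to_steady_state",
    "stack_stimuli",
]


@dataclasses.dataclass
class NetworkState:
    """Activities and net inputs of both layers at time ``t`` (ms).

    ``converged`` reports whether the per-step activity change dropped below
    the steady-state tolerance before the integration cap ``t_max``; it is a
    boolean array for batched states.
    """

    y_v: np.ndarray
    y_a: np.ndarray
    u_v: np.ndarray
    u_a: np.ndarray
    t: float = 0.0
    n_steps: int = 0
    converged: np.ndarray | bool = False

    @classmethod
    def null(cls, cfg: ModelConfig, batch_shape: tuple[int, ...] = ()) -> "NetworkState":
        """The defined initial condition of every protocol: zero activity."""
        y_v = np.zeros(batch_shape + (cfg.n_azimuth_visual,))
        y_a = np.zeros(batch_shape + (cfg.n_azimuth_auditory, cfg.n_freq_auditory))
        return cls(y_v=y_v, y_a=y_a, u_v=np.zeros_like(y_v), u_a=np.zeros_like(y_a))


def sigmoid(u, cfg: ModelConfig):
    """Static activation ``F(u) = 1 / (1 + exp(-s (u - theta)))``."""
    return 1.0 / (1.0 + np.exp(-cfg.s * (np.asarray(u, dtype=float) - cfg.theta)))


def stack_stimuli(
    stims: list[StimulusSpec], cfg: ModelConfig
) -> tuple[np.ndarray, np.ndarray]:
    """External input arrays for a batch of stimuli (leading batch axis)."""
    e_v = np.stack([make_visual_input(s, cfg) for s in stims])
    e_a = np.stack([make_auditory_input(s, cfg) for s in stims])
    return e_v, e_a


def compute_net_inputs(
    y_v: np.ndarray,
    y_a: np.ndarray,
    syn: SynapseState,
    e_v: np.ndarray,
    e_a: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Net inputs ``u = e + l + c`` for both layers.

    The cross-modal input to a visual neuron is ``W_va`` times the summed
    activity of the auditory frequency column at its azimuth; every auditory
    neuron in a column receives ``W_av`` times the activity of the visual
    neuron at that azimuth.
    """
    if y_v.shape[-1] != syn.cfg.n_azimuth_visual or y_a.shape[-2:] != (
        syn.cfg.n_azimuth_auditory,
        syn.cfg.n_freq_auditory,
    ):
        raise ValueError("activity shapes inconsistent with configuration")
    u_v = e_v + syn.lateral_visual(y_v) + syn.W_va * y_a.sum(axis=-1)
    u_a = e_a + syn.lateral_auditory(y_a) + syn.W_av * y_v[..., :, None]
    return u_v, u_a


def step(
    state: NetworkState,
    syn: SynapseState,
    e_v: np.ndarray,
    e_a: np.ndarray,
    cfg: ModelConfig,
) -> NetworkState:
    """One synchronous Euler step ``y <- y + (dt / tau_y) (-y + F(u))``."""
    u_v, u_a = compute_net_inputs(state.y_v, state.y_a, syn, e_v, e_a)
    rate = cfg.dt / cfg.tau_y
    return NetworkState(
        y_v=state.y_v + rate * (-state.y_v + sigmoid(u_v, cfg)),
        y_a=state.y_a + rate * (-state.y_a + sigmoid(u_a, cfg)),
        u_v=u_v,
        u_a=u_a,
        t=state.t + cfg.dt,
        n_steps=state.n_steps + 1,
        converged=state.converged,
    )


def run_to_steady_state(
    syn: SynapseState,
    stims: StimulusSpec | list[StimulusSpec],
    cfg: ModelConfig,
    snapshot_times: list[float] | None = None,
) -> NetworkState | tuple[NetworkState, dict[float, np.ndarray]]:
    """Integrate from the null state under constant stimuli until steady.

    Steady state is declared when the largest per-step activity change in
    either layer falls below ``cfg.steady_tol``; if ``cfg.t_max`` is reached
    first the returned state is flagged ``converged=False`` (never silent).
    A list of stimuli runs as a batch of independent networks, stopping when
    every member has converged.

    When ``snapshot_times`` is given, auditory activation maps captured at
    the first step reaching each time are returned alongside the state.
    """
    single = isinstance(stims, StimulusSpec)
    stim_list = [stims] if single else list(stims)
    e_v, e_a = stack_stimuli(stim_list, cfg)
    state = NetworkState.null(cfg, batch_shape=(len(stim_list),))

    want = sorted(snapshot_times) if snapshot_times else []
    snaps: dict[float, np.ndarray] = {}
    n_max = int(round(cfg.t_max / cfg.dt))
    converged = np.zeros(len(stim_list), dtype=bool)
    for _ in range(n_max):
        new = step(state, syn, e_v, e_a, cfg)
        dv = np.max(np.abs(new.y_v - state.y_v), axis=-1)
        da = np.max(np.abs(new.y_a - state.y_a), axis=(-2, -1))
        converged = np.maximum(dv, da) < cfg.steady_tol
        state = new
        while want and state.t >= want[0] - 1e-9:
            snaps[want.pop(0)] = state.y_a[0] if single else state.y_a.copy()
        if converged.all():
            break
    state.converged = bool(converged[0]) if single else converged
    if single:
        state = NetworkState(
            y_v=state.y_v[0],
            y_a=state.y_a[0],
            u_v=state.u_v[0],
            u_a=state.u_a[0],
            t=state.t,
            n_steps=state.n_steps,
            converged=state.converged,
        )
    if snapshot_times is not None:
        return state, snaps
    return state
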