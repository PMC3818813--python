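"""Dense explicit-matrix reference backend (small grids).

This backend builds the auditory lateral connectivity as literal
``(N, N)`` matrices over flattened ``(azimuth, frequency)`` indices, directly
from the pairwise difference-of-Gaussians formulas, and runs the dynamics
and learning rules on those matrices with no structural shortcuts.  It is
deliberately simple and memory-hungry: its purpose is to serve as an
independent oracle for the windowed production backend on grids small
enough to afford it (e.g. a 60 x 20 auditory layer), not to run the full
model.
"""

from __future__ import annotations

import numpy as np

from .config import ModelConfig, circular_distance
from .synapses import SynapseState, _circ_gauss_matrix, _support_radius

__all__ = ["DenseSynapses", "build_dense_synapses", "max_abs_difference"]

_MAX_N = 4000  # refuse grids whose dense matrices would be enormous


class DenseSynapses:
    """Explicit-matrix synapse state sharing the :class:`SynapseState` API.

    ``L_ex_a`` / ``L_in_a`` are ``(N, N)`` with ``N = n_az * n_f`` and row
    index ``i * n_f + j`` for neuron ``(i, j)``; entry ``[post, pre]`` holds
    the weight from ``pre`` onto ``post``.  The same truncation rule as the
    windowed backend is applied (distance cutoff per dimension), so on grids
    where the cutoff exceeds the half-ring the two are exactly equivalent.
    """

    def __init__(self, cfg: ModelConfig):
        cfg.validate()
        self.cfg = cfg
        n_az, n_f = cfg.n_azimuth_auditory, cfg.n_freq_auditory
        n = n_az * n_f
        if n > _MAX_N:
            raise MemoryError(
                f"dense backend limited to {_MAX_N} auditory neurons, got {n}"
            )

        n_v = cfg.n_azimuth_visual
        r_v = _support_radius(cfg, cfg.sigma_in_p_v, n_v)
        self.Lex_v = _circ_gauss_matrix(n_v, cfg.sigma_ex_p_v, cfg.Lex0_v, r_v, True)
        self.Lin_v = _circ_gauss_matrix(n_v, cfg.sigma_in_p_v, cfg.Lin0_v, r_v, True)
        self.init_sum_ex_v = self.Lex_v.sum(axis=1)
        self.init_sum_in_v = self.Lin_v.sum(axis=1)

        idx = np.arange(n_az)
        d_az = circular_distance(idx[:, None], idx[None, :], n_az).astype(float)
        jdx = np.arange(n_f)
        d_f = circular_distance(jdx[:, None], jdx[None, :], n_f).astype(float)
        r_az = _support_radius(cfg, cfg.sigma_in_p_a, n_az)
        r_f = _support_radius(cfg, cfg.sigma_in_f_a, n_f)
        mask_az = np.ones_like(d_az) if r_az is None else (d_az <= r_az).astype(float)
        mask_f = np.ones_like(d_f) if r_f is None else (d_f <= r_f).astype(float)

        def component(amp: float, s_p: float, s_f: float) -> np.ndarray:
            g_az = np.exp(-(d_az**2) / (2.0 * s_p**2)) * mask_az
            g_f = np.exp(-(d_f**2) / (2.0 * s_f**2)) * mask_f
            full = amp * np.einsum("ih,jk->ijhk", g_az, g_f)
            return full.reshape(n, n)

        self.L_ex_a = component(cfg.Lex0_a, cfg.sigma_ex_p_a, cfg.sigma_ex_f_a)
        self.L_in_a = component(cfg.Lin0_a, cfg.sigma_in_p_a, cfg.sigma_in_f_a)
        np.fill_diagonal(self.L_ex_a, 0.0)
        np.fill_diagonal(self.L_in_a, 0.0)
        self.init_sum_ex_a = self.L_ex_a.sum(axis=1)
        self.init_sum_in_a = self.L_in_a.sum(axis=1)

        self.W_av = cfg.W_av
        self.W_va = cfg.W_va
        self.meta: dict = {"trained": False}

    # same duck-typed surface the dynamics module uses -----------------
    def lateral_visual(self, y_v: np.ndarray) -> np.ndarray:
        return y_v @ (self.Lex_v - self.Lin_v).T

    def lateral_auditory(self, y_a: np.ndarray) -> np.ndarray:
        n_az, n_f = self.cfg.n_azimuth_auditory, self.cfg.n_freq_auditory
        flat = y_a.reshape(y_a.shape[:-2] + (n_az * n_f,))
        out = flat @ (self.L_ex_a - self.L_in_a).T
        return out.reshape(y_a.shape)

    def incoming_sums_auditory(self) -> tuple[np.ndarray, np.ndarray]:
        shape = (self.cfg.n_azimuth_auditory, self.cfg.n_freq_auditory)
        return (
            self.L_ex_a.sum(axis=1).reshape(shape),
            self.L_in_a.sum(axis=1).reshape(shape),
        )

    def copy(self) -> "DenseSynapses":
        import copy as _copy

        return _copy.deepcopy(self)

    # learning ---------------------------------------------------------
    def learn_step(self, y_v, y_a, settings) -> None:
        from .plasticity import hebbian_deltas, normalize_incoming

        cfg = self.cfg
        if settings.visual:
            act = np.flatnonzero(y_v > cfg.theta_post)
            if act.size:
                d_ex, d_in = hebbian_deltas(
                    y_v,
                    y_v[act],
                    self.Lex_v[act],
                    self.Lin_v[act],
                    cfg,
                    cfg.Lmax_v,
                    self_cols=act,
                )
                self.Lex_v[act] = normalize_incoming(
                    self.Lex_v[act] + d_ex, self.init_sum_ex_v[act]
                )
                self.Lin_v[act] = normalize_incoming(
                    self.Lin_v[act] + d_in, self.init_sum_in_v[act]
                )
        if settings.auditory:
            flat = y_a.reshape(-1)
            act = np.flatnonzero(flat > cfg.theta_post)
            if act.size:
                d_ex, d_in = hebbian_deltas(
                    flat,
                    flat[act],
                    self.L_ex_a[act],
                    self.L_in_a[act],
                    cfg,
                    cfg.Lmax_a,
                    self_cols=act,
                )
                self.L_ex_a[act] = normalize_incoming(
                    self.L_ex_a[act] + d_ex, self.init_sum_ex_a[act]
                )
                self.L_in_a[act] = normalize_incoming(
                    self.L_in_a[act] + d_in, self.init_sum_in_a[act]
                )

    def dense_auditory(self) -> tuple[np.ndarray, np.ndarray]:
        return self.L_ex_a.copy(), self.L_in_a.copy()


def build_dense_synapses(cfg: ModelConfig) -> DenseSynapses:
    return DenseSynapses(cfg)


# convenience: make SynapseState comparable against this oracle
def max_abs_difference(win: SynapseState, dense: DenseSynapses) -> float:
    """Largest absolute weight discrepancy between the two backends."""
    w_ex, w_in = win.to_dense_auditory()
    d = max(
        float(np.abs(w_ex - dense.L_ex_a).max()),
        float(np.abs(w_in - dense.L_in_a).max()),
        float(np.abs(win.Lex_v - dense.Lex_v).max()),
        float(np.abs(win.Lin_v - dense.Lin_v).max()),
    )
    return d
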