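"""Lateral and cross-modal synapses: basal construction and storage.

Both layers carry Mexican-hat lateral connectivity: the weight between two
neurons is the difference of an excitatory and an inhibitory circular
Gaussian of their index distance, with excitation stronger but narrower than
inhibition, and no self-synapses.  The two components are stored separately
because the Hebbian rules treat them separately.  Cross-modal coupling is
two scalars: every auditory neuron receives ``W_av`` times the activity of
the visual neuron at its azimuth, and every visual neuron receives ``W_va``
times the summed activity of the auditory column at its azimuth.

Storage strategy
----------------
A dense auditory lateral matrix on the default grid would have
``(180*40)**2`` entries per component.  :class:`SynapseState` instead keeps

* the *basal* (untrained) connectivity in separable circulant form — a 1D
  azimuth profile times a frequency circulant per component — so the lateral
  input of an untrained network is two small matrix products; and
* explicit *rows* (incoming-weight windows) only for postsynaptic neurons
  whose synapses have been touched by learning, materialised on demand.

Row support is truncated at ``kernel_cutoff_sigmas`` times the inhibitory
sigma of each dimension (the wider component, so excitatory support is
always contained).  :mod:`ventnet.dense` provides an explicit-matrix
reference implementation used to verify this machinery on small grids.
"""

from __future__ import annotations

import copy
import json
import math

import numpy as np

from .config import ConfigError, ModelConfig, circular_distance

__all__ = ["SynapseState", "build_basal_synapses"]


def _circ_gauss_matrix(
    n: int,
    sigma: float,
    amplitude: float,
    cutoff_dist: int | None,
    zero_diag: bool = False,
) -> np.ndarray:
    """Circulant Gaussian-of-circular-distance matrix, optionally truncated."""
    d = circular_distance(np.arange(n)[:, None], np.arange(n)[None, :], n).astype(float)
    m = amplitude * np.exp(-(d**2) / (2.0 * sigma**2))
    if cutoff_dist is not None:
        m[d > cutoff_dist] = 0.0
    if zero_diag:
        np.fill_diagonal(m, 0.0)
    return m


def _support_radius(cfg: ModelConfig, sigma_in: float, n: int) -> int | None:
    if cfg.kernel_cutoff_sigmas is None:
        return None
    return min(int(math.ceil(cfg.kernel_cutoff_sigmas * sigma_in)), n // 2)


class SynapseState:
    """Lateral weights of both layers plus the cross-modal scalars.

    Visual lateral weights are small and kept as dense ``(n, n)`` matrices
    ``Lex_v`` / ``Lin_v`` indexed ``[post, pre]``.  Auditory lateral weights
    are windowed: a trained row for postsynaptic neuron ``(i, j)`` is an
    ``(W, n_f)`` array whose entry ``[w, k]`` is the weight from presynaptic
    neuron ``((i + az_offsets[w]) % n_az, k)``.  Untrained rows are implicit
    (separable circulant basal kernel).

    Per-neuron incoming sums of the basal state are recorded at construction
    (``init_sum_*``); the Hebbian normalization rule holds them fixed.
    """

    def __init__(self, cfg: ModelConfig):
        cfg.validate()
        self.cfg = cfg
        n_v = cfg.n_azimuth_visual
        n_az = cfg.n_azimuth_auditory
        n_f = cfg.n_freq_auditory

        # --- visual layer: dense matrices -----------------------------
        r_v = _support_radius(cfg, cfg.sigma_in_p_v, n_v)
        self.Lex_v = _circ_gauss_matrix(n_v, cfg.sigma_ex_p_v, cfg.Lex0_v, r_v, True)
        self.Lin_v = _circ_gauss_matrix(n_v, cfg.sigma_in_p_v, cfg.Lin0_v, r_v, True)
        self.init_sum_ex_v = self.Lex_v.sum(axis=1)
        self.init_sum_in_v = self.Lin_v.sum(axis=1)

        # --- auditory layer: separable circulant basal kernel ---------
        r_az = _support_radius(cfg, cfg.sigma_in_p_a, n_az)
        r_f = _support_radius(cfg, cfg.sigma_in_f_a, n_f)
        width = n_az if r_az is None else min(2 * r_az + 1, n_az)
        self.az_offsets = np.arange(width) - width // 2
        d_off = np.minimum(np.abs(self.az_offsets), n_az - np.abs(self.az_offsets))
        d_off = d_off.astype(float)
        self.gex_az = cfg.Lex0_a * np.exp(-(d_off**2) / (2.0 * cfg.sigma_ex_p_a**2))
        self.gin_az = cfg.Lin0_a * np.exp(-(d_off**2) / (2.0 * cfg.sigma_in_p_a**2))
        if r_az is not None:
            self.gex_az[d_off > r_az] = 0.0
            self.gin_az[d_off > r_az] = 0.0
        self.Fex = _circ_gauss_matrix(n_f, cfg.sigma_ex_f_a, 1.0, r_f)
        self.Fin = _circ_gauss_matrix(n_f, cfg.sigma_in_f_a, 1.0, r_f)

        # circulant azimuth matrices for the fast (basal) lateral input
        rows = np.arange(n_az)[:, None]
        cols = (rows + self.az_offsets[None, :]) % n_az
        self.Cex_az = np.zeros((n_az, n_az))
        self.Cin_az = np.zeros((n_az, n_az))
        self.Cex_az[rows, cols] = self.gex_az
        self.Cin_az[rows, cols] = self.gin_az

        # basal incoming sums (identical for every neuron by symmetry;
        # the self-entry contributes amplitude * 1 * 1 and is excluded)
        f_row_ex = float(self.Fex[0].sum())
        f_row_in = float(self.Fin[0].sum())
        self.init_sum_ex_a = float(self.gex_az.sum()) * f_row_ex - cfg.Lex0_a
        self.init_sum_in_a = float(self.gin_az.sum()) * f_row_in - cfg.Lin0_a

        # basal incoming window per postsynaptic frequency (row center at
        # az offset 0); self-entry zeroed
        center = width // 2
        self._center = center
        basal = np.empty((2, n_f, width, n_f))
        basal[0] = self.gex_az[None, :, None] * self.Fex[:, None, :]
        basal[1] = self.gin_az[None, :, None] * self.Fin[:, None, :]
        basal[:, np.arange(n_f), center, np.arange(n_f)] = 0.0
        self._basal_rows = basal

        # trained rows, materialised on demand
        self.rows_ex = np.empty((0, width, n_f))
        self.rows_in = np.empty((0, width, n_f))
        self.row_pos = np.empty((0, 2), dtype=np.int64)
        self.row_map = np.full((n_az, n_f), -1, dtype=np.int64)

        # cross-modal scalars
        self.W_av = cfg.W_av
        self.W_va = cfg.W_va

        #: provenance of any training applied to this state
        self.meta: dict = {"trained": False}

    # ------------------------------------------------------------------
    @property
    def n_modified(self) -> int:
        return self.row_pos.shape[0]

    @property
    def is_basal(self) -> bool:
        return self.n_modified == 0

    def copy(self) -> "SynapseState":
        return copy.deepcopy(self)

    # ------------------------------------------------------------------
    def basal_row(self, j: int) -> tuple[np.ndarray, np.ndarray]:
        """Basal incoming window (ex, in) of any neuron at frequency ``j``."""
        return self._basal_rows[0, j].copy(), self._basal_rows[1, j].copy()

    def ensure_rows(self, i_arr: np.ndarray, j_arr: np.ndarray) -> np.ndarray:
        """Materialise rows for the given postsynaptic neurons; return indices."""
        missing = self.row_map[i_arr, j_arr] < 0
        if np.any(missing):
            mi, mj = i_arr[missing], j_arr[missing]
            start = self.n_modified
            self.rows_ex = np.concatenate([self.rows_ex, self._basal_rows[0, mj]])
            self.rows_in = np.concatenate([self.rows_in, self._basal_rows[1, mj]])
            self.row_pos = np.concatenate(
                [self.row_pos, np.stack([mi, mj], axis=1)]
            )
            self.row_map[mi, mj] = np.arange(start, start + mi.size)
        return self.row_map[i_arr, j_arr]

    # ------------------------------------------------------------------
    def lateral_visual(self, y_v: np.ndarray) -> np.ndarray:
        """Net lateral input to the visual layer; supports leading batch dims."""
        return y_v @ (self.Lex_v - self.Lin_v).T

    def lateral_auditory(self, y_a: np.ndarray) -> np.ndarray:
        """Net lateral input to the auditory layer; supports leading batch dims.

        Basal part: two separable circulant products minus the self-entry
        correction ``(Lex0_a - Lin0_a) * y``.  Rows touched by learning are
        then recomputed explicitly from their stored windows.
        """
        l = np.matmul(self.Cex_az, np.matmul(y_a, self.Fex)) - np.matmul(
            self.Cin_az, np.matmul(y_a, self.Fin)
        )
        l -= (self.cfg.Lex0_a - self.cfg.Lin0_a) * y_a
        if self.n_modified:
            n_az = self.cfg.n_azimuth_auditory
            i_m, j_m = self.row_pos[:, 0], self.row_pos[:, 1]
            gather = (i_m[:, None] + self.az_offsets[None, :]) % n_az
            yw = y_a[..., gather, :]  # (..., m, W, n_f)
            net = self.rows_ex - self.rows_in
            l[..., i_m, j_m] = np.einsum("mwf,...mwf->...m", net, yw)
        return l

    # ------------------------------------------------------------------
    def auditory_weight(self, post: tuple[int, int], pre: tuple[int, int]):
        """(excitatory, inhibitory) weight of one auditory synapse."""
        i, j = post
        h, k = pre
        n_az = self.cfg.n_azimuth_auditory
        w = np.flatnonzero((i + self.az_offsets) % n_az == h)
        if w.size == 0:
            return 0.0, 0.0  # outside the truncated support
        w = int(w[0])
        idx = self.row_map[i, j]
        if idx >= 0:
            return float(self.rows_ex[idx, w, k]), float(self.rows_in[idx, w, k])
        return float(self._basal_rows[0, j, w, k]), float(self._basal_rows[1, j, w, k])

    def auditory_row(self, i: int, j: int) -> tuple[np.ndarray, np.ndarray]:
        """Incoming window (ex, in) of auditory neuron ``(i, j)``."""
        idx = self.row_map[i, j]
        if idx >= 0:
            return self.rows_ex[idx].copy(), self.rows_in[idx].copy()
        return self.basal_row(j)

    def incoming_sums_auditory(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-neuron incoming-weight sums ``(sum_ex, sum_in)``, each (n_az, n_f)."""
        n_az, n_f = self.cfg.n_azimuth_auditory, self.cfg.n_freq_auditory
        s_ex = np.full((n_az, n_f), self.init_sum_ex_a)
        s_in = np.full((n_az, n_f), self.init_sum_in_a)
        if self.n_modified:
            i_m, j_m = self.row_pos[:, 0], self.row_pos[:, 1]
            s_ex[i_m, j_m] = self.rows_ex.sum(axis=(1, 2))
            s_in[i_m, j_m] = self.rows_in.sum(axis=(1, 2))
        return s_ex, s_in

    def to_dense_auditory(self) -> tuple[np.ndarray, np.ndarray]:
        """Full ``(N, N)`` auditory matrices (small grids only; N = n_az * n_f)."""
        n_az, n_f = self.cfg.n_azimuth_auditory, self.cfg.n_freq_auditory
        n = n_az * n_f
        if n > 4000:
            raise MemoryError("dense export is intended for small grids only")
        dense = np.zeros((2, n, n))
        for i in range(n_az):
            cols = (i + self.az_offsets) % n_az
            for j in range(n_f):
                ex, inh = self.auditory_row(i, j)
                row = i * n_f + j
                dense[0, row].reshape(n_az, n_f)[cols] = ex
                dense[1, row].reshape(n_az, n_f)[cols] = inh
        return dense[0], dense[1]

    # ------------------------------------------------------------------
    def save(self, path) -> None:
        """Serialise to a compressed ``.npz`` archive with provenance."""
        np.savez_compressed(
            path,
            config=json.dumps(self.cfg.to_dict()),
            meta=json.dumps(self.meta),
            Lex_v=self.Lex_v,
            Lin_v=self.Lin_v,
            rows_ex=self.rows_ex,
            rows_in=self.rows_in,
            row_pos=self.row_pos,
        )

    @classmethod
    def load(cls, path) -> "SynapseState":
        with np.load(path, allow_pickle=False) as data:
            cfg = ModelConfig(**json.loads(str(data["config"])))
            syn = cls(cfg)
            syn.meta = json.loads(str(data["meta"]))
            syn.Lex_v = data["Lex_v"]
            syn.Lin_v = data["Lin_v"]
            row_pos = data["row_pos"]
            if row_pos.size:
                syn.rows_ex = data["rows_ex"]
                syn.rows_in = data["rows_in"]
                syn.row_pos = row_pos
                syn.row_map[row_pos[:, 0], row_pos[:, 1]] = np.arange(
                    row_pos.shape[0]
                )
        return syn


def build_basal_synapses(cfg: ModelConfig) -> SynapseState:
    """Construct the untrained (basal) connectivity for a configuration.

    Raises :class:`~ventnet.config.ConfigError` when the Mexican-hat
    conditions are violated.
    """
    try:
        return SynapseState(cfg)
    except ConfigError:
        raise
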