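"""Model configuration, grid geometry and frequency mapping.

The network consists of a one-dimensional visual layer (one neuron per degree
of azimuth) and a two-dimensional auditory layer whose neurons code jointly
for azimuth and tone frequency.  Both layers are rings: distances between
neuron indices are circular, which removes border effects.  The frequency
axis is logarithmic with five neurons per octave, so the 40-neuron default
grid spans eight octaves.

:class:`ModelConfig` collects every network parameter (layer sizes, stimulus
receptive-field widths, sigmoid, lateral-kernel and cross-modal strengths,
Hebbian-rule constants) together with the numerical-method settings (Euler
step, steady-state tolerance, learning duration).  The defaults are the basal
parameter set of the model; ``validate()`` enforces the Mexican-hat
conditions and positivity constraints.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from typing import Any

import numpy as np
import yaml

__all__ = [
    "ConfigError",
    "ModelConfig",
    "circular_distance",
]


class ConfigError(ValueError):
    """Raised when a configuration violates a structural constraint."""


def circular_distance(i1, i2, n: int):
    """Distance between indices ``i1`` and ``i2`` on a ring of ``n`` sites.

    Accepts scalars or arrays and returns ``min(|i1-i2|, n-|i1-i2|)``.
    The result is symmetric and never exceeds ``n // 2``.
    """
    i1 = np.asarray(i1)
    i2 = np.asarray(i2)
    if np.any(i1 < 0) or np.any(i1 >= n) or np.any(i2 < 0) or np.any(i2 >= n):
        raise IndexError(f"index out of range for ring of size {n}")
    d = np.abs(i1 - i2)
    out = np.minimum(d, n - d)
    return out if out.ndim else out.item()


# mapping of flat field names to the nested sections used in YAML files
_SECTIONS = {
    "dimensions": ["n_azimuth_visual", "n_azimuth_auditory", "n_freq_auditory"],
    "stimuli": ["E0_v", "sigma_p_v", "sigma_p_a", "sigma_f_a"],
    "neuron": ["s", "theta", "tau_y"],
    "visual_synapses": ["Lex0_v", "Lin0_v", "sigma_ex_p_v", "sigma_in_p_v"],
    "auditory_synapses": [
        "Lex0_a",
        "Lin0_a",
        "sigma_ex_p_a",
        "sigma_in_p_a",
        "sigma_ex_f_a",
        "sigma_in_f_a",
    ],
    "cross_modal": ["W_av", "W_va"],
    "hebbian": ["theta_post", "alpha_ex0", "alpha_in0", "Lmax_v", "Lmax_a"],
    "numerics": [
        "dt",
        "steady_tol",
        "t_max",
        "n_learning_steps",
        "kernel_cutoff_sigmas",
    ],
    "frequency_grid": ["freq_anchor_hz", "freq_anchor_index", "octaves_per_index"],
}


@dataclasses.dataclass
class ModelConfig:
    """All network parameters plus numerical-method settings.

    Synaptic widths (``sigma_*``) are dimensionless index distances; azimuth
    indices are degrees (one neuron per degree); ``tau_y``, ``dt`` and
    ``t_max`` are milliseconds; stimulus intensities are arbitrary units.
    """

    # layer dimensions
    n_azimuth_visual: int = 180
    n_azimuth_auditory: int = 180
    n_freq_auditory: int = 40

    # external stimuli
    E0_v: float = 15.0
    sigma_p_v: float = 4.0
    sigma_p_a: float = 30.0
    sigma_f_a: float = 14.0

    # neuron response (shared by both layers)
    s: float = 0.6
    theta: float = 12.0
    tau_y: float = 3.0

    # visual lateral (Mexican hat: strong narrow excitation, weak broad inhibition)
    Lex0_v: float = 2.4
    Lin0_v: float = 1.4
    sigma_ex_p_v: float = 2.0
    sigma_in_p_v: float = 24.0

    # auditory lateral
    Lex0_a: float = 0.4
    Lin0_a: float = 0.21
    sigma_ex_p_a: float = 1.45
    sigma_in_p_a: float = 8.0
    sigma_ex_f_a: float = 1.45
    sigma_in_f_a: float = 5.0

    # cross-modal scalars
    W_av: float = 8.5
    W_va: float = 0.22

    # Hebbian rules
    theta_post: float = 0.5
    alpha_ex0: float = 0.03
    alpha_in0: float = 0.05
    Lmax_v: float = 2.4
    Lmax_a: float = 0.4

    # numerics
    dt: float = 1.0
    steady_tol: float = 1e-6
    t_max: float = 1500.0
    n_learning_steps: int = 1000
    #: lateral-kernel (and learning) support cutoff in units of the
    #: inhibitory sigma per dimension; ``None`` (default) keeps the full
    #: ring as support.  Truncation barely affects the basal kernels but
    #: also clips Hebbian potentiation at long range, so the exact setting
    #: is the default.
    kernel_cutoff_sigmas: float | None = None

    # frequency grid: log-spaced, five neurons (1/5 octave each) per octave
    freq_anchor_hz: float = 1100.0
    freq_anchor_index: int = 17
    octaves_per_index: float = 0.2

    # ------------------------------------------------------------------
    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in (
            "n_azimuth_visual",
            "n_azimuth_auditory",
            "n_freq_auditory",
            "sigma_p_v",
            "sigma_p_a",
            "sigma_f_a",
            "sigma_ex_p_v",
            "sigma_in_p_v",
            "sigma_ex_p_a",
            "sigma_in_p_a",
            "sigma_ex_f_a",
            "sigma_in_f_a",
            "tau_y",
            "dt",
            "steady_tol",
            "t_max",
            "freq_anchor_hz",
            "octaves_per_index",
        ):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be strictly positive")
        if self.n_learning_steps < 1:
            raise ConfigError("n_learning_steps must be >= 1")
        if not 0.0 < self.theta_post <= 1.0:
            raise ConfigError("theta_post must lie in (0, 1]")
        if self.E0_v < 0:
            raise ConfigError("E0_v must be nonnegative")
        if not (self.Lex0_v > self.Lin0_v and self.sigma_ex_p_v < self.sigma_in_p_v):
            raise ConfigError(
                "visual Mexican-hat condition violated: need "
                "Lex0_v > Lin0_v and sigma_ex_p_v < sigma_in_p_v"
            )
        if not (
            self.Lex0_a > self.Lin0_a
            and self.sigma_ex_p_a < self.sigma_in_p_a
            and self.sigma_ex_f_a < self.sigma_in_f_a
        ):
            raise ConfigError(
                "auditory Mexican-hat condition violated: need Lex0_a > Lin0_a, "
                "sigma_ex_p_a < sigma_in_p_a and sigma_ex_f_a < sigma_in_f_a"
            )
        if not 0 <= self.freq_anchor_index < self.n_freq_auditory:
            raise ConfigError("freq_anchor_index outside the frequency grid")
        if self.kernel_cutoff_sigmas is not None and self.kernel_cutoff_sigmas <= 0:
            raise ConfigError("kernel_cutoff_sigmas must be positive or None")

    # ------------------------------------------------------------------
    # frequency grid
    def freq_index_to_hz(self, j) -> float | np.ndarray:
        """Frequency (Hz) of grid index ``j``.

        ``f_j = anchor_hz * 2**((j - anchor_index) * octaves_per_index)``.
        """
        j = np.asarray(j)
        if np.any(j < 0) or np.any(j >= self.n_freq_auditory):
            raise IndexError("frequency index outside grid")
        f = self.freq_anchor_hz * 2.0 ** (
            (j - self.freq_anchor_index) * self.octaves_per_index
        )
        return f if f.ndim else f.item()

    def hz_to_freq_index(self, hz: float) -> tuple[int, float]:
        """Nearest grid index for a frequency plus the residual in octaves.

        The residual is ``log2(hz / f_index)``: zero when the frequency sits
        exactly on the grid.
        """
        if hz <= 0:
            raise ValueError("frequency must be positive")
        exact = (
            self.freq_anchor_index
            + math.log2(hz / self.freq_anchor_hz) / self.octaves_per_index
        )
        j = int(round(exact))
        if not 0 <= j < self.n_freq_auditory:
            raise ValueError(
                f"{hz} Hz resolves to index {j}, outside the "
                f"{self.n_freq_auditory}-neuron grid"
            )
        residual = math.log2(hz / self.freq_index_to_hz(j))
        return j, residual

    @property
    def freq_grid_hz(self) -> np.ndarray:
        return np.asarray(self.freq_index_to_hz(np.arange(self.n_freq_auditory)))

    # ------------------------------------------------------------------
    def replace(self, **changes: Any) -> "ModelConfig":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        """Stable short hash of the full parameter set (for provenance logs)."""
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    # YAML round trip with nested sections; omitted fields keep their defaults
    def to_yaml(self, path) -> None:
        d = self.to_dict()
        nested = {sec: {k: d[k] for k in keys} for sec, keys in _SECTIONS.items()}
        with open(path, "w") as fh:
            yaml.safe_dump(nested, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ModelConfig":
        with open(path) as fh:
            nested = yaml.safe_load(fh) or {}
        known = {k for keys in _SECTIONS.values() for k in keys}
        flat: dict[str, Any] = {}
        for sec, entries in nested.items():
            if sec not in _SECTIONS:
                raise ConfigError(f"unknown configuration section {sec!r}")
            if entries is None:
                continue
            for key, value in entries.items():
                if key not in known or key not in _SECTIONS[sec]:
                    raise ConfigError(f"unknown key {key!r} in section {sec!r}")
                flat[key] = value
        return cls(**flat)
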