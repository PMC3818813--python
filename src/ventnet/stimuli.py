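"""External stimuli: Gaussian receptive-field inputs to the two layers.

A visual stimulus (e.g. a flash) appears to the network as a 1D Gaussian of
activity over the azimuth ring, centred at the stimulated position with the
width of the visual receptive fields.  A pure tone appears to the auditory
layer as a separable 2D Gaussian over (azimuth, frequency).  Distances on
both axes are circular.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .config import ModelConfig, circular_distance

__all__ = ["StimulusSpec", "make_visual_input", "make_auditory_input"]


@dataclasses.dataclass(frozen=True)
class StimulusSpec:
    """Placement and intensity of the external stimuli.

    A modality is absent when its azimuth is ``None``.  ``visual_intensity``
    defaults to the configured ``E0_v`` when left as ``None``; the auditory
    intensity must be given explicitly whenever the auditory stimulus is
    present, since it is the main experimental variable.
    """

    visual_azimuth: int | None = None
    visual_intensity: float | None = None
    auditory_azimuth: int | None = None
    auditory_freq_index: int | None = None
    auditory_intensity: float | None = None

    @property
    def visual_present(self) -> bool:
        return self.visual_azimuth is not None

    @property
    def auditory_present(self) -> bool:
        return self.auditory_azimuth is not None

    def validate(self, cfg: ModelConfig) -> None:
        if not (self.visual_present or self.auditory_present):
            raise ValueError("stimulus must include at least one modality")
        if self.visual_present:
            if not 0 <= self.visual_azimuth < cfg.n_azimuth_visual:
                raise ValueError("visual azimuth outside grid")
            if self.visual_intensity is not None and self.visual_intensity < 0:
                raise ValueError("visual intensity must be nonnegative")
        if self.auditory_present:
            if not 0 <= self.auditory_azimuth < cfg.n_azimuth_auditory:
                raise ValueError("auditory azimuth outside grid")
            if self.auditory_freq_index is None:
                raise ValueError("auditory stimulus needs a frequency index")
            if not 0 <= self.auditory_freq_index < cfg.n_freq_auditory:
                raise ValueError("auditory frequency index outside grid")
            if self.auditory_intensity is None or self.auditory_intensity < 0:
                raise ValueError("auditory stimulus needs a nonnegative intensity")

    # convenience constructors -----------------------------------------
    @classmethod
    def visual(cls, azimuth: int, intensity: float | None = None) -> "StimulusSpec":
        return cls(visual_azimuth=azimuth, visual_intensity=intensity)

    @classmethod
    def auditory(
        cls,
        azimuth: int,
        freq_index: int | None = None,
        intensity: float = 0.0,
        *,
        freq_hz: float | None = None,
        cfg: ModelConfig | None = None,
    ) -> "StimulusSpec":
        if freq_index is None:
            if freq_hz is None or cfg is None:
                raise ValueError("give freq_index, or freq_hz together with cfg")
            freq_index, _ = cfg.hz_to_freq_index(freq_hz)
        return cls(
            auditory_azimuth=azimuth,
            auditory_freq_index=freq_index,
            auditory_intensity=intensity,
        )

    @classmethod
    def bimodal(
        cls,
        visual_azimuth: int,
        auditory_azimuth: int,
        freq_index: int,
        auditory_intensity: float,
        visual_intensity: float | None = None,
    ) -> "StimulusSpec":
        return cls(
            visual_azimuth=visual_azimuth,
            visual_intensity=visual_intensity,
            auditory_azimuth=auditory_azimuth,
            auditory_freq_index=freq_index,
            auditory_intensity=auditory_intensity,
        )


def make_visual_input(stim: StimulusSpec, cfg: ModelConfig) -> np.ndarray:
    """External input to the visual layer: ``E0_v * exp(-d^2 / 2 sigma^2)``.

    Returns the all-zero vector when the visual stimulus is absent.
    """
    stim.validate(cfg)
    n = cfg.n_azimuth_visual
    if not stim.visual_present:
        return np.zeros(n)
    e0 = cfg.E0_v if stim.visual_intensity is None else stim.visual_intensity
    d = circular_distance(np.arange(n), stim.visual_azimuth, n)
    return e0 * np.exp(-(d.astype(float) ** 2) / (2.0 * cfg.sigma_p_v**2))


def make_auditory_input(stim: StimulusSpec, cfg: ModelConfig) -> np.ndarray:
    """External input to the auditory layer: separable circular 2D Gaussian.

    ``e[i, j] = E0_a * exp(-d_az(i)^2 / 2 sigma_p^2 - d_f(j)^2 / 2 sigma_f^2)``
    with the peak ``E0_a`` at the stimulated (azimuth, frequency) neuron.
    Returns the all-zero map when the auditory stimulus is absent.
    """
    stim.validate(cfg)
    shape = (cfg.n_azimuth_auditory, cfg.n_freq_auditory)
    if not stim.auditory_present:
        return np.zeros(shape)
    d_az = circular_distance(
        np.arange(shape[0]), stim.auditory_azimuth, shape[0]
    ).astype(float)
    d_f = circular_distance(
        np.arange(shape[1]), stim.auditory_freq_index, shape[1]
    ).astype(float)
    g_az = np.exp(-(d_az**2) / (2.0 * cfg.sigma_p_a**2))
    g_f = np.exp(-(d_f**2) / (2.0 * cfg.sigma_f_a**2))
    return stim.auditory_intensity * np.outer(g_az, g_f)
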