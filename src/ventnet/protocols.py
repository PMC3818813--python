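"""End-to-end experimental protocols.

Three experiments are orchestrated here, all deterministic:

* **Ventriloquism sweep** — bimodal steady states (no learning) over a grid
  of visual-auditory disparities and sound intensities; decodes the
  perceptual shift of each modality.  The visual stimulus sits at a fixed
  azimuth and the tone is displaced toward lower azimuths by the disparity.
* **Aftereffect experiment** — one adaptation phase (Hebbian learning under
  a spatially discrepant bimodal pair), then unimodal test tones at the
  adaptation position, learning off, decoding the residual auditory shift
  as a function of test frequency and intensity.
* **Generalization matrix** — the full cross of adaptation x test
  intensities, summarised by a generalization bandwidth: the octave
  distance from the adaptation frequency at which the aftereffect first
  drops below a floor (default 0.5 deg).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .config import ModelConfig
from .dynamics import run_to_steady_state
from .metrics import decode
from .plasticity import LearningSettings, adapt
from .stimuli import StimulusSpec
from .synapses import SynapseState, build_basal_synapses

__all__ = [
    "VentriloquismResult",
    "AftereffectCurve",
    "ventriloquism_sweep",
    "bimodal_shift",
    "unimodal_test_shift",
    "aftereffect_experiment",
    "generalization_matrix",
    "generalization_bandwidth",
    "DEFAULT_ADAPT_VISUAL_AZ",
    "DEFAULT_ADAPT_AUDITORY_AZ",
    "DEFAULT_ADAPT_FREQ_HZ",
]

# canonical adaptation geometry: visual flash at 100 deg, tone at 80 deg / 1.1 kHz
DEFAULT_ADAPT_VISUAL_AZ = 100
DEFAULT_ADAPT_AUDITORY_AZ = 80
DEFAULT_ADAPT_FREQ_HZ = 1100.0


@dataclasses.dataclass(frozen=True)
class VentriloquismResult:
    """Perceptual shifts for one (disparity, intensity) cell, learning off."""

    disparity: float
    E0_a: float
    shift_a: float
    shift_v: float
    converged: bool


@dataclasses.dataclass
class AftereffectCurve:
    """Auditory shift of a unimodal test tone versus test frequency."""

    adapt_intensity: float
    test_intensity: float
    freq_index: np.ndarray
    freq_hz: np.ndarray
    octave_distance: np.ndarray  # |octaves from the adaptation frequency|
    shift_a: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "freq_index": self.freq_index,
                "freq_hz": self.freq_hz,
                "octave_distance": self.octave_distance,
                "shift_a_deg": self.shift_a,
                "adapt_intensity": self.adapt_intensity,
                "test_intensity": self.test_intensity,
            }
        )


def _adapt_stimulus(cfg: ModelConfig, intensity: float) -> StimulusSpec:
    j, _ = cfg.hz_to_freq_index(DEFAULT_ADAPT_FREQ_HZ)
    return StimulusSpec.bimodal(
        DEFAULT_ADAPT_VISUAL_AZ, DEFAULT_ADAPT_AUDITORY_AZ, j, intensity
    )


def bimodal_shift(
    disparity: float,
    E0_a: float,
    cfg: ModelConfig,
    syn: SynapseState | None = None,
    visual_azimuth: int = DEFAULT_ADAPT_VISUAL_AZ,
) -> VentriloquismResult:
    """Steady-state shifts for one bimodal configuration (no learning)."""
    res = ventriloquism_sweep([disparity], [E0_a], cfg, syn, visual_azimuth)
    return res[0]


def ventriloquism_sweep(
    disparities,
    intensities,
    cfg: ModelConfig,
    syn: SynapseState | None = None,
    visual_azimuth: int = DEFAULT_ADAPT_VISUAL_AZ,
) -> list[VentriloquismResult]:
    """Bimodal steady states over disparity x intensity, learning off.

    The tone sits at ``visual_azimuth - disparity`` so the attraction toward
    the visual stimulus appears as a positive auditory shift.
    """
    syn = syn if syn is not None else build_basal_synapses(cfg)
    j, _ = cfg.hz_to_freq_index(DEFAULT_ADAPT_FREQ_HZ)
    cells = [(d, e) for d in disparities for e in intensities]
    stims = [
        StimulusSpec.bimodal(visual_azimuth, int(visual_azimuth - d), j, e)
        for d, e in cells
    ]
    state = run_to_steady_state(syn, stims, cfg)
    out = []
    for b, ((d, e), stim) in enumerate(zip(cells, stims)):
        loc = decode(state.y_v[b], state.y_a[b], stim)
        out.append(
            VentriloquismResult(
                disparity=float(d),
                E0_a=float(e),
                shift_a=loc.shift_a,
                shift_v=loc.shift_v,
                converged=bool(state.converged[b]),
            )
        )
    return out


def unimodal_test_shift(
    syn: SynapseState,
    cfg: ModelConfig,
    test_intensity: float,
    freq_indices=None,
    azimuth: int = DEFAULT_ADAPT_AUDITORY_AZ,
) -> np.ndarray:
    """Auditory shifts of unimodal test tones at ``azimuth`` (learning off)."""
    if freq_indices is None:
        freq_indices = np.arange(cfg.n_freq_auditory)
    freq_indices = np.asarray(freq_indices, dtype=int)
    stims = [
        StimulusSpec.auditory(azimuth, int(j), test_intensity) for j in freq_indices
    ]
    state = run_to_steady_state(syn, stims, cfg)
    if not np.all(state.converged):
        raise RuntimeError("unimodal test run failed to reach steady state")
    shifts = [
        decode(state.y_v[b], state.y_a[b], stims[b]).shift_a
        for b in range(len(stims))
    ]
    return np.asarray(shifts, dtype=float)


def aftereffect_experiment(
    adapt_intensity: float,
    test_intensities,
    cfg: ModelConfig,
    test_freq_indices=None,
    settings: LearningSettings | None = None,
    trained: SynapseState | None = None,
    adapt_stim: StimulusSpec | None = None,
) -> tuple[dict[float, AftereffectCurve], SynapseState]:
    """Adapt once, then measure aftereffect curves at each test intensity.

    The trained synapse state is returned (and accepted back via
    ``trained=``) so several test conditions can reuse one adaptation.
    ``adapt_stim`` overrides the canonical adaptation geometry (its auditory
    intensity is replaced by ``adapt_intensity``); test tones are placed at
    the adaptation position.
    """
    if trained is None:
        if adapt_stim is None:
            stim = _adapt_stimulus(cfg, adapt_intensity)
        else:
            stim = dataclasses.replace(
                adapt_stim, auditory_intensity=float(adapt_intensity)
            )
        trained, _ = adapt(stim, cfg, settings)
    j_adapt = trained.meta.get(
        "adapt_freq_index", cfg.hz_to_freq_index(DEFAULT_ADAPT_FREQ_HZ)[0]
    )
    test_azimuth = trained.meta.get(
        "adapt_auditory_azimuth", DEFAULT_ADAPT_AUDITORY_AZ
    )
    if test_freq_indices is None:
        test_freq_indices = np.arange(cfg.n_freq_auditory)
    test_freq_indices = np.asarray(test_freq_indices, dtype=int)
    octaves = np.abs(test_freq_indices - j_adapt) * cfg.octaves_per_index

    curves: dict[float, AftereffectCurve] = {}
    for e_test in test_intensities:
        shifts = unimodal_test_shift(
            trained, cfg, e_test, test_freq_indices, azimuth=test_azimuth
        )
        curves[float(e_test)] = AftereffectCurve(
            adapt_intensity=float(adapt_intensity),
            test_intensity=float(e_test),
            freq_index=test_freq_indices.copy(),
            freq_hz=np.asarray(cfg.freq_index_to_hz(test_freq_indices)),
            octave_distance=octaves,
            shift_a=shifts,
        )
    return curves, trained


def generalization_bandwidth(curve: AftereffectCurve, floor: float = 0.5) -> float:
    """Octave distance at which the aftereffect first drops below ``floor``.

    Test frequencies are grouped by octave distance from the adaptation
    frequency (ascending); the bandwidth is the first distance whose largest
    shift falls below the floor.  Zero means no aftereffect even at the
    adaptation frequency; if the shift never drops below the floor the
    largest probed distance is returned.
    """
    dists = np.unique(np.round(curve.octave_distance, 9))
    for d in dists:
        sel = np.isclose(curve.octave_distance, d)
        if np.max(curve.shift_a[sel]) < floor:
            return float(d)
    return float(dists[-1])


def generalization_matrix(
    adapt_intensities,
    test_intensities,
    cfg: ModelConfig,
    test_freq_indices=None,
    floor: float = 0.5,
    settings: LearningSettings | None = None,
    adapt_stim: StimulusSpec | None = None,
) -> pd.DataFrame:
    """Full cross of adaptation x test intensities with bandwidth summaries.

    Returns a tidy frame with one row per (adapt, test, frequency) triple
    plus a ``bandwidth_octaves`` column repeated within each curve.
    """
    frames = []
    for e_adapt in adapt_intensities:
        curves, _ = aftereffect_experiment(
            e_adapt, test_intensities, cfg, test_freq_indices, settings,
            adapt_stim=adapt_stim,
        )
        for curve in curves.values():
            frame = curve.to_frame()
            frame["bandwidth_octaves"] = generalization_bandwidth(curve, floor)
            frames.append(frame)
    return pd.concat(frames, ignore_index=True)
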