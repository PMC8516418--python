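"""Shared in-memory containers for recordings and time series.

All arrays are stored in SI units (seconds, amperes, siemens, farads) and
fluorescence in arbitrary units.  External tables use the field's display
units (pA, pS, fF, ms); conversion happens only in :mod:`synaptoquant.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Optional, Sequence

import numpy as np

__all__ = [
    "LockInTrace",
    "PatchCurrentTrace",
    "AmperometricTrace",
    "ImageStack",
    "StimProtocol",
    "ROITimeSeries",
    "TrainRecording",
]


def _as_1d(x) -> np.ndarray:
    a = np.asarray(x, dtype=float)
    if a.ndim != 1:
        raise ValueError(f"expected 1-D array, got shape {a.shape}")
    return a


@dataclass
class LockInTrace:
    """Two-channel admittance recording from a phase-sensitive lock-in.

    ``Re`` is the real (conductance-like) part and ``Im`` the imaginary
    (capacitance-like) part of the patch admittance, both in siemens.
    ``Im / omega`` is the capacitance display trace.
    """

    time: np.ndarray
    Re: np.ndarray
    Im: np.ndarray
    sampling_rate: float
    lockin_frequency: float
    channel_units: str = "S"

    def __post_init__(self):
        self.time = _as_1d(self.time)
        self.Re = _as_1d(self.Re)
        self.Im = _as_1d(self.Im)
        if not (len(self.time) == len(self.Re) == len(self.Im)):
            raise ValueError("time, Re, Im must have equal length")
        if len(self.time) > 1 and not np.all(np.diff(self.time) > 0):
            raise ValueError("time must be strictly increasing")
        if self.lockin_frequency <= 0:
            raise ValueError("lockin_frequency must be positive")

    @property
    def omega(self) -> float:
        """Angular lock-in frequency, rad/s."""
        return 2.0 * np.pi * self.lockin_frequency

    def __len__(self) -> int:
        return len(self.time)


@dataclass
class PatchCurrentTrace:
    """Ionic current through a cell-attached patch (amperes).

    ``V_patch`` is the command voltage across the patch membrane (volts);
    ``filter_hz`` records the analog low-pass corner applied upstream.
    """

    time: np.ndarray
    I: np.ndarray
    V_patch: float
    filter_hz: float = 500.0
    t_event: Optional[float] = None

    def __post_init__(self):
        self.time = _as_1d(self.time)
        self.I = _as_1d(self.I)
        if len(self.time) != len(self.I):
            raise ValueError("time and I must have equal length")

    @property
    def sampling_rate(self) -> float:
        return 1.0 / float(np.median(np.diff(self.time)))


@dataclass
class AmperometricTrace:
    """Single-channel oxidation current from a carbon-fiber electrode."""

    time: np.ndarray
    I: np.ndarray
    sampling_rate: float
    stim_time: float = 0.0

    def __post_init__(self):
        self.time = _as_1d(self.time)
        self.I = _as_1d(self.I)
        if len(self.time) != len(self.I):
            raise ValueError("time and I must have equal length")
        if not np.all(np.isfinite(self.I)):
            raise ValueError("current trace contains non-finite samples")
        if not (self.time[0] <= self.stim_time <= self.time[-1]):
            raise ValueError("stim_time must lie within the trace")


@dataclass
class ImageStack:
    """A fluorescence movie: frames indexed (t, row, col)."""

    frames: np.ndarray
    frame_times: np.ndarray

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        self.frame_times = _as_1d(self.frame_times)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (T, H, W) array")
        if self.frames.shape[0] != len(self.frame_times):
            raise ValueError("one frame time per frame required")
        if len(self.frame_times) > 1 and not np.all(np.diff(self.frame_times) > 0):
            raise ValueError("frame_times must be strictly increasing")

    @property
    def shape(self):
        return self.frames.shape


@dataclass
class StimProtocol:
    """Field/AP stimulation bookkeeping for optical recordings."""

    n_stimuli: int
    frequency: float
    onset: float
    acid_windows: Sequence[tuple] = field(default_factory=tuple)

    def __post_init__(self):
        if self.n_stimuli < 0 or self.frequency <= 0:
            raise ValueError("need n_stimuli >= 0 and frequency > 0")
        wins = sorted(tuple(map(float, w)) for w in self.acid_windows)
        for (a0, a1), (b0, b1) in zip(wins, wins[1:]):
            if b0 < a1:
                raise ValueError("acid windows must not overlap")
        self.acid_windows = tuple(wins)

    @property
    def end(self) -> float:
        """Time of the last stimulus."""
        if self.n_stimuli == 0:
            return self.onset
        return self.onset + (self.n_stimuli - 1) / self.frequency


Normalization = Literal["none", "dF_over_dFmax", "dF_over_F0"]


@dataclass
class ROITimeSeries:
    """Fluorescence versus time for one region of interest."""

    time: np.ndarray
    F: np.ndarray
    stim: StimProtocol
    F0: Optional[float] = None
    normalization: Normalization = "none"
    roi_id: int = 0

    def __post_init__(self):
        self.time = _as_1d(self.time)
        self.F = _as_1d(self.F)
        if len(self.time) != len(self.F):
            raise ValueError("time and F must have equal length")

    def with_values(self, F, normalization: Normalization) -> "ROITimeSeries":
        return replace(self, F=np.asarray(F, dtype=float), normalization=normalization)


@dataclass
class TrainRecording:
    """Evoked-response trace with its stimulus times.

    ``modality`` selects conventions downstream: IPSC peaks are searched in a
    1-50 ms post-stimulus window, iGluSnFR at single-frame resolution.
    Responses are stored positive-going.
    """

    time: np.ndarray
    response: np.ndarray
    stim_times: np.ndarray
    modality: Literal["ipsc", "iglusnfr"]

    def __post_init__(self):
        self.time = _as_1d(self.time)
        self.response = _as_1d(self.response)
        self.stim_times = _as_1d(self.stim_times)
        if len(self.time) != len(self.response):
            raise ValueError("time and response must have equal length")
        if len(self.stim_times) and not np.all(np.diff(self.stim_times) > 0):
            raise ValueError("stimulus times must be strictly increasing")
        if self.modality not in ("ipsc", "iglusnfr"):
            raise ValueError(f"unknown modality {self.modality!r}")
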