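"""Short-term depression metrics from evoked-response trains.

Converts IPSC or iGluSnFR train recordings into per-stimulus amplitudes
(with the residual decay of the previous response subtracted), normalized
series, steady-state depression and paired-pulse ratio.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .core import TrainRecording

__all__ = [
    "TrainResponse",
    "extract_train_amplitudes",
    "normalize_train",
    "steady_state",
    "paired_pulse_ratio",
    "analyze_train",
    "DEFAULT_LAST_N",
]

#: steady state averages the last 10 responses for IPSC trains, 5 for iGluSnFR
DEFAULT_LAST_N = {"ipsc": 10, "iglusnfr": 5}

#: peak search window after each stimulus, per modality (seconds)
PEAK_WINDOW = {"ipsc": (1e-3, 50e-3), "iglusnfr": (0.0, 60e-3)}


@dataclass
class TrainResponse:
    """Per-stimulus amplitudes and the derived depression metrics."""

    amplitudes: np.ndarray
    normalized: np.ndarray
    steady_state: float
    ppr: float
    last_n: int


def _residual_fit(t: np.ndarray, y: np.ndarray):
    """Exponential A exp(-t/tau) through tail samples, as a callable.

    Exact on noiseless exponentials (log-linear least squares).  Returns the
    zero function when the tail is non-positive or non-decaying, i.e. when
    there is nothing to extrapolate.
    """
    if len(t) < 3 or np.any(y <= 0):
        return lambda tt: np.zeros_like(np.asarray(tt, dtype=float))
    slope, intercept = np.polyfit(t, np.log(y), 1)
    if slope >= 0:
        return lambda tt: np.zeros_like(np.asarray(tt, dtype=float))
    return lambda tt: np.exp(intercept + slope * np.asarray(tt, dtype=float))


def extract_train_amplitudes(
    rec: TrainRecording,
    residual_fraction: float = 0.3,
    noise_sd: Optional[float] = None,
) -> np.ndarray:
    """Residual-subtracted peak amplitude of every response in a train.

    For each stimulus the raw peak is located in the modality's search
    window; the residual decay of the preceding activity is estimated by a
    single-exponential fit to the final ``residual_fraction`` of the
    previous inter-stimulus interval and extrapolated under the current
    response.  Amplitude = raw peak - residual at the peak time.

    When ``noise_sd`` is known, amplitudes below 3 noise SD are recorded as
    failures (0) and still enter normalization.
    """
    t, y = rec.time, rec.response
    stims = rec.stim_times
    if len(stims) == 0:
        return np.array([])
    isi = np.min(np.diff(stims)) if len(stims) > 1 else t[-1] - stims[0]
    w0, w1 = PEAK_WINDOW[rec.modality]
    w1 = min(w1, isi)
    if noise_sd is None:
        pre = t < stims[0]
        noise_sd = float(np.std(y[pre])) if pre.sum() >= 10 else 0.0

    amps = np.empty(len(stims))
    for k, ts in enumerate(stims):
        sel = (t >= ts + w0) & (t <= ts + w1)
        if not sel.any():
            raise ValueError("inter-stimulus interval not resolvable at this sampling rate")
        kk = np.flatnonzero(sel)
        ipk = kk[np.argmax(y[kk])]
        t_pk = t[ipk]
        if k == 0:
            residual = 0.0
        else:
            tail = (t >= stims[k] - residual_fraction * isi) & (t < stims[k])
            fit = _residual_fit(t[tail], y[tail])
            residual = float(fit(t_pk))
        amp = float(y[ipk] - residual)
        if noise_sd > 0 and amp < 3 * noise_sd:
            amp = 0.0
        amps[k] = amp
    return amps


def normalize_train(amplitudes) -> np.ndarray:
    """Divide every amplitude by the first response's amplitude."""
    a = np.asarray(amplitudes, dtype=float)
    if len(a) == 0:
        raise ValueError("empty amplitude sequence")
    if a[0] <= 0:
        raise ValueError("first response amplitude must be positive")
    return a / a[0]


def steady_state(normalized, last_n: int) -> float:
    """Mean of the final ``last_n`` normalized responses."""
    a = np.asarray(normalized, dtype=float)
    if len(a) < last_n:
        raise ValueError(f"train of {len(a)} responses is shorter than last_n={last_n}")
    return float(np.mean(a[-last_n:]))


def paired_pulse_ratio(amplitudes) -> float:
    """Second / first response amplitude."""
    a = np.asarray(amplitudes, dtype=float)
    if len(a) < 2:
        raise ValueError("paired-pulse ratio needs at least two responses")
    if a[0] <= 0:
        raise ValueError("first response amplitude must be positive")
    return float(a[1] / a[0])


def analyze_train(rec: TrainRecording, last_n: Optional[int] = None) -> TrainResponse:
    """Full train analysis: extraction, normalization, steady state, PPR."""
    if last_n is None:
        last_n = DEFAULT_LAST_N[rec.modality]
    amps = extract_train_amplitudes(rec)
    norm = normalize_train(amps)
    return TrainResponse(
        amplitudes=amps,
        normalized=norm,
        steady_state=steady_state(norm, last_n),
        ppr=paired_pulse_ratio(amps),
        last_n=last_n,
    )
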