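"""Carbon-fiber amperometry: spike detection and quantification.

Each amperometric spike reports catecholamine release from one large
dense-core vesicle.  Analysis follows the standard single-spike criteria:
(i) only spikes above 10 pA are considered, (ii) at most 100 spikes are
analyzed per cell, (iii) the pre-spike foot is delimited by the baseline
departure and the back-extrapolated spike onset, and (iv) feet shorter
than 0.5 ms are excluded from foot statistics.  Group statistics are
mean +/- SEM of per-cell medians, so n is the number of cells.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .core import AmperometricTrace

__all__ = [
    "AmperometricSpike",
    "Foot",
    "CellSummary",
    "baseline_stats",
    "detect_spikes",
    "spike_params",
    "detect_foot",
    "spike_frequency",
    "cell_summary",
    "group_summary",
]

DEFAULT_MIN_AMP = 10e-12  # amperes
DEFAULT_MAX_SPIKES = 100
DEFAULT_MIN_FOOT = 0.5e-3  # seconds
DEFAULT_FREQ_WINDOW = 15.0  # seconds


@dataclass
class Foot:
    """Pre-spike foot: flux through the transient fusion pore."""

    duration: float  # s, baseline departure to back-extrapolated onset
    amplitude: float  # A, plateau level above baseline
    counted: bool  # False when duration < the 0.5 ms criterion


@dataclass
class AmperometricSpike:
    """One detected release event with its shape parameters."""

    t_peak: float
    peak: float  # A, baseline-subtracted
    index: int  # sample index of the peak
    halfwidth: Optional[float] = None  # s; None when overlapped at half-max
    tau_decay: Optional[float] = None  # s
    quantal_size: Optional[float] = None  # C
    foot: Optional[Foot] = None
    overlapped: bool = False
    included: bool = True


@dataclass
class CellSummary:
    """Per-cell medians of the spike parameters."""

    cell_id: str
    n_spikes: int
    spike_frequency: int
    median_peak: float
    median_halfwidth: Optional[float]
    median_tau: Optional[float]
    median_quantal: Optional[float]
    median_foot_duration: Optional[float]


# --------------------------------------------------------------------------
# baseline and detection

def baseline_stats(trace: AmperometricTrace, pre_len: float = 5.0):
    """Baseline model from the pre-stimulus segment.

    Returns ``(baseline(t) array over the whole trace, noise SD)``: a
    first-order fit to the pre-stimulus segment removes slow drift, and the
    noise scale is the median absolute deviation of the residuals.
    """
    t, i = trace.time, trace.I
    pre = t < trace.stim_time
    if pre.sum() < 10:
        raise ValueError("no usable pre-stimulus baseline segment")
    t0 = max(trace.stim_time - pre_len, t[0])
    seg = pre & (t >= t0)
    coef = np.polyfit(t[seg], i[seg], 1)
    resid = i[seg] - np.polyval(coef, t[seg])
    sd = 1.4826 * float(np.median(np.abs(resid - np.median(resid))))
    return np.polyval(coef, t), sd


def detect_spikes(
    trace: AmperometricTrace,
    min_amp: float = DEFAULT_MIN_AMP,
    max_per_cell: int = DEFAULT_MAX_SPIKES,
    min_separation: float = 2e-3,
) -> list:
    """Detect spikes with baseline-subtracted peak > ``min_amp``.

    Spikes are returned earliest first and truncated at ``max_per_cell``.
    """
    base, _sd = baseline_stats(trace)
    corr = trace.I - base
    dist = max(int(min_separation * trace.sampling_rate), 1)
    peaks, _ = find_peaks(corr, height=min_amp, distance=dist)
    peaks = peaks[np.argsort(trace.time[peaks])][:max_per_cell]
    return [
        AmperometricSpike(t_peak=float(trace.time[k]), peak=float(corr[k]), index=int(k))
        for k in peaks
    ]


# --------------------------------------------------------------------------
# spike shape

def _cross_time(t0, y0, t1, y1, level):
    """Linear interpolation of the time where y crosses ``level``."""
    if y1 == y0:
        return t0
    return t0 + (level - y0) * (t1 - t0) / (y1 - y0)


def spike_params(
    trace: AmperometricTrace,
    spike: AmperometricSpike,
    tau_fit_range: tuple = (0.75, 0.25),
    extent_sd: float = 1.0,
) -> AmperometricSpike:
    """Fill in peak, halfwidth, decay tau and quantal size for one spike.

    halfwidth is the full width at half maximum with sub-sample interpolated
    crossings; tau_decay is a single-exponential fit of the falling phase
    between 75% and 25% of the peak; quantal_size integrates the
    baseline-subtracted current over the spike extent (from the baseline
    departure before the rise to the first return within ``extent_sd``
    baseline SDs after the decay).  A neighbouring spike inside the
    half-max region marks the spike as overlapped: halfwidth and tau are
    then left unset but the spike still counts toward frequency.
    """
    base, sd = baseline_stats(trace)
    corr = trace.I - base
    t = trace.time
    k = spike.index
    n = len(corr)
    half = 0.5 * corr[k]

    # walk left/right to the half-max crossings
    left = k
    while left > 0 and corr[left - 1] > half:
        left -= 1
    right = k
    while right < n - 1 and corr[right + 1] > half:
        right += 1
    # overlap check: another local max above half level inside the region
    region = corr[left:right + 1]
    interior = region[1:-1]
    if len(interior) >= 3:
        local_max = (interior[1:-1] > interior[:-2]) & (interior[1:-1] > interior[2:])
        n_maxima = int(np.sum(local_max)) + (1 if 0 < k - left < right - left else 0)
    else:
        n_maxima = 1
    overlapped = n_maxima > 1 or left == 0 or right == n - 1

    spike.overlapped = overlapped
    if not overlapped:
        t_left = _cross_time(t[left - 1], corr[left - 1], t[left], corr[left], half) \
            if left > 0 else t[left]
        t_right = _cross_time(t[right], corr[right], t[right + 1], corr[right + 1], half) \
            if right < n - 1 else t[right]
        spike.halfwidth = float(t_right - t_left)

        # falling-phase exponential between the tau_fit_range fractions of peak
        hi, lo = tau_fit_range
        fall = corr[k:]
        below_hi = np.flatnonzero(fall <= hi * corr[k])
        below_lo = np.flatnonzero(fall <= lo * corr[k])
        if len(below_hi) and len(below_lo) and below_lo[0] > below_hi[0] + 1:
            a, b = k + below_hi[0], k + below_lo[0]
            y = corr[a:b + 1]
            if np.all(y > 0):
                slope, _ = np.polyfit(t[a:b + 1], np.log(y), 1)
                if slope < 0:
                    spike.tau_decay = float(-1.0 / slope)

    # spike extent for charge integration
    floor_start = max(3 * sd, 5e-3 * corr[k])
    floor_end = max(extent_sd * sd, 1e-3 * corr[k])
    s = k
    while s > 0 and corr[s - 1] > floor_start:
        s -= 1
    e = k
    while e < n - 1 and corr[e + 1] > floor_end:
        e += 1
    spike.quantal_size = float(np.trapezoid(corr[s:e + 1], t[s:e + 1]))
    return spike


def detect_foot(
    trace: AmperometricTrace,
    spike: AmperometricSpike,
    min_foot: float = DEFAULT_MIN_FOOT,
    search_len: float = 10e-3,
) -> Optional[Foot]:
    """Pre-spike foot detection.

    The foot starts at the first sustained departure of the current above
    baseline + 3 SD before the rise; the spike onset is the back-extrapolated
    maximal-slope line of the rising phase, evaluated at the foot current
    level.  Feet shorter than ``min_foot`` are returned with
    ``counted=False`` (excluded from foot statistics); a spike with no
    resolvable plateau returns None.
    """
    base, sd = baseline_stats(trace)
    corr = trace.I - base
    t = trace.time
    k = spike.index
    fs = trace.sampling_rate
    lo = max(k - int(search_len * fs), 0)

    thr = max(3 * sd, 5e-3 * corr[k])
    seg = corr[lo:k + 1]
    below = np.flatnonzero(seg <= thr)
    if len(below) == 0:
        return None  # rise not resolved within the search window
    start = lo + below[-1] + 1  # first sample of the sustained departure
    if start >= k:
        return None

    # maximal slope of the rising phase
    dseg = np.diff(corr[start:k + 1])
    if len(dseg) == 0:
        return None
    im = start + int(np.argmax(dseg))
    slope = dseg[np.argmax(dseg)] * fs
    if slope <= 0:
        return None

    # foot level: median of plateau candidates below 25% of peak
    plateau = corr[start:k + 1]
    cand = plateau[plateau < 0.25 * corr[k]]
    if len(cand) < 2:
        return None  # footless: rise leaves baseline straight into the spike
    level = float(np.median(cand))

    t_mid = 0.5 * (t[im] + t[im + 1])
    y_mid = 0.5 * (corr[im] + corr[im + 1])
    onset = t_mid - (y_mid - level) / slope
    duration = float(onset - t[start])
    if duration <= 0:
        return None
    foot = Foot(duration=duration, amplitude=level, counted=duration >= min_foot)
    spike.foot = foot
    return foot


# --------------------------------------------------------------------------
# per-cell and group statistics

def spike_frequency(
    spikes: Sequence[AmperometricSpike],
    stim_time: float,
    window: float = DEFAULT_FREQ_WINDOW,
) -> int:
    """Number of spikes peaking within ``window`` seconds after stimulation."""
    return sum(1 for s in spikes if stim_time <= s.t_peak <= stim_time + window)


def _median(values):
    vals = [v for v in values if v is not None and np.isfinite(v)]
    return float(np.median(vals)) if vals else None


def cell_summary(
    spikes: Sequence[AmperometricSpike],
    cell_id: str,
    stim_time: float = 0.0,
    freq_window: float = DEFAULT_FREQ_WINDOW,
) -> CellSummary:
    """Medians of each spike parameter over the included spikes of one cell."""
    inc = [s for s in spikes if s.included]
    if not inc:
        raise ValueError(f"cell {cell_id!r} has no included spikes")
    feet = [s.foot.duration for s in inc if s.foot is not None and s.foot.counted]
    return CellSummary(
        cell_id=cell_id,
        n_spikes=len(inc),
        spike_frequency=spike_frequency(inc, stim_time, freq_window),
        median_peak=_median([s.peak for s in inc]),
        median_halfwidth=_median([s.halfwidth for s in inc]),
        median_tau=_median([s.tau_decay for s in inc]),
        median_quantal=_median([s.quantal_size for s in inc]),
        median_foot_duration=_median(feet),
    )


def group_summary(summaries: Sequence[CellSummary]) -> pd.DataFrame:
    """Mean +/- SEM of the cell medians: the statistical unit is the cell."""
    if not summaries:
        raise ValueError("no cell summaries supplied")
    df = pd.DataFrame(
        {
            "cell_id": [c.cell_id for c in summaries],
            "spike_frequency": [c.spike_frequency for c in summaries],
            "peak": [c.median_peak for c in summaries],
            "halfwidth": [c.median_halfwidth for c in summaries],
            "tau_decay": [c.median_tau for c in summaries],
            "quantal_size": [c.median_quantal for c in summaries],
            "foot_duration": [c.median_foot_duration for c in summaries],
        }
    ).set_index("cell_id")
    out = pd.DataFrame({
        "mean": df.mean(),
        "sem": df.sem(),
        "n_cells": df.count(),
    })
    return out
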