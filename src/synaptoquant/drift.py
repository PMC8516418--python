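"""Endocytosis-associated patch-current drift and its I-V relationship.

In double (whole-cell / cell-attached) patch recordings, a step change in
the patch current coincides with the downward capacitance step of
endocytosis: open channels on the internalized vesicle are lost from the
patch.  The drift is quantified as the difference between linear fits of
the current before and after the capacitance drop, both extrapolated to
the event time, and assembled into a current-voltage curve across cells.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import PatchCurrentTrace

__all__ = [
    "DriftMeasurement",
    "IVCurve",
    "measure_current_drift",
    "build_iv",
    "rectification_test",
]


@dataclass
class DriftMeasurement:
    """Current drift at one endocytic event."""

    V_patch: float  # volts
    delta_I: float  # amperes, post minus pre at the event time
    fit_window_pre: float
    fit_window_post: float
    fit_r2: float  # the poorer of the two fits

    def __post_init__(self):
        if not np.isfinite(self.delta_I):
            raise ValueError("delta_I must be finite")


@dataclass
class IVCurve:
    """Mean +/- SEM of the drift, grouped by patch voltage."""

    voltages: np.ndarray  # volts, ascending
    mean_delta_I: np.ndarray
    sem: np.ndarray
    n: np.ndarray


def _linfit(t: np.ndarray, y: np.ndarray):
    coef = np.polyfit(t, y, 1)
    pred = np.polyval(coef, t)
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return coef, r2


def measure_current_drift(
    trace: PatchCurrentTrace,
    t_event: float,
    pre_len: float = 0.100,
    post_len: float = 0.100,
    guard: float = 0.010,
) -> DriftMeasurement:
    """Drift = post-event linear fit minus pre-event linear fit, both
    extrapolated to ``t_event``.

    Window lengths must lie in [20, 100] ms.  A guard gap of ``guard``
    seconds on each side of the event keeps the low-pass-filtered transition
    itself out of both fits.  Extrapolating both fits to the event time
    cancels any common baseline slope.
    """
    for name, ln in (("pre_len", pre_len), ("post_len", post_len)):
        if not (0.020 <= ln <= 0.100):
            raise ValueError(f"{name} must be within [20, 100] ms, got {ln * 1e3:g} ms")
    t, i = trace.time, trace.I
    pre = (t >= t_event - guard - pre_len) & (t < t_event - guard)
    post = (t > t_event + guard) & (t <= t_event + guard + post_len)
    if pre.sum() < 3 or post.sum() < 3:
        raise ValueError("insufficient samples in the fit windows")
    coef_pre, r2_pre = _linfit(t[pre], i[pre])
    coef_post, r2_post = _linfit(t[post], i[post])
    delta = float(np.polyval(coef_post, t_event) - np.polyval(coef_pre, t_event))
    return DriftMeasurement(
        V_patch=trace.V_patch,
        delta_I=delta,
        fit_window_pre=pre_len,
        fit_window_post=post_len,
        fit_r2=min(r2_pre, r2_post),
    )


def build_iv(measurements: Sequence[DriftMeasurement]) -> IVCurve:
    """Group drift measurements by patch voltage: mean, SEM, n per voltage."""
    if not measurements:
        raise ValueError("no drift measurements supplied")
    volts = np.array([m.V_patch for m in measurements])
    deltas = np.array([m.delta_I for m in measurements])
    uniq = np.unique(volts)
    mean = np.empty_like(uniq)
    sem = np.empty_like(uniq)
    n = np.empty(len(uniq), dtype=int)
    for k, v in enumerate(uniq):
        vals = deltas[volts == v]
        n[k] = len(vals)
        mean[k] = vals.mean()
        sem[k] = vals.std(ddof=1) / np.sqrt(len(vals)) if len(vals) > 1 else np.nan
    return IVCurve(voltages=uniq, mean_delta_I=mean, sem=sem, n=n)


def rectification_test(iv: IVCurve):
    """Linearity diagnostics of a drift I-V curve.

    Returns ``(linear_r2, rectification_index)`` where ``linear_r2`` is the
    ordinary-least-squares fit through the mean I-V points and the index is
    |mean drift at the most positive voltage| / |mean drift at the most
    negative voltage|.  An ohmic conductance loss gives an index near 1; an
    outward rectifier gives an index well above 1.  A flat (all-zero) curve
    has no defined index and returns NaN.
    """
    v = iv.voltages
    if len(v) < 3 or v.min() >= 0 or v.max() <= 0:
        raise ValueError("need >= 3 voltages spanning negative and positive values")
    _, r2 = _linfit(v, iv.mean_delta_I)
    num = abs(iv.mean_delta_I[np.argmax(v)])
    den = abs(iv.mean_delta_I[np.argmin(v)])
    scale = np.max(np.abs(iv.mean_delta_I))
    if scale == 0 or den < 1e-6 * scale:
        return r2, float("nan")
    return r2, float(num / den)
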