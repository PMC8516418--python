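"""Optical reporter kinetics: ROI extraction, normalization and fitting.

Handles pHluorin endocytosis time constants, acid-quench reacidification
rates, GCaMP Ca transients (peak and decay), Fura-2 ratios, automatic
iGluSnFR ROI detection, and the photobleaching inclusion check.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
from scipy.ndimage import label
from scipy.optimize import curve_fit

from .core import ImageStack, ROITimeSeries, StimProtocol

__all__ = [
    "ROISet",
    "TauFit",
    "extract_roi_timeseries",
    "detect_iglusnfr_rois",
    "normalize_response",
    "fit_endocytic_tau",
    "fit_reacidification",
    "peak_transient",
    "fit_ca_decay",
    "fura_ratio",
    "photobleach_check",
]

BOX_SIZE = 4  # bouton ROIs are 4 x 4 pixel boxes


@dataclass
class ROISet:
    """Regions of interest: 4x4 boxes at bouton centres, or pixel masks.

    ``rois`` holds either (row, col) centre tuples (manual bouton boxes) or
    boolean masks (automatic iGluSnFR detection).
    """

    rois: Sequence[Union[tuple, np.ndarray]]
    provenance: str = "manual-bouton"  # or "iglusnfr-auto"

    def __len__(self):
        return len(self.rois)


@dataclass
class TauFit:
    """Result of a single-exponential decay fit."""

    tau: float  # s
    amplitude: float
    offset: float
    r2: float
    valid: bool  # False when the series does not decay


# --------------------------------------------------------------------------
# ROI extraction

def _roi_mask(roi, shape) -> np.ndarray:
    if isinstance(roi, np.ndarray):
        if roi.shape != shape:
            raise ValueError("ROI mask shape must match the frame shape")
        return roi.astype(bool)
    r, c = roi
    half = BOX_SIZE // 2
    r0, c0 = int(r) - half, int(c) - half
    if r0 < 0 or c0 < 0 or r0 + BOX_SIZE > shape[0] or c0 + BOX_SIZE > shape[1]:
        raise ValueError(f"4x4 ROI at {roi} exceeds the frame bounds {shape}")
    mask = np.zeros(shape, dtype=bool)
    mask[r0:r0 + BOX_SIZE, c0:c0 + BOX_SIZE] = True
    return mask


def extract_roi_timeseries(
    stack: ImageStack,
    rois: ROISet,
    stim: Optional[StimProtocol] = None,
    background_roi=None,
) -> list:
    """Per-frame mean intensity over each ROI.

    When ``background_roi`` is given its series is subtracted frame by frame
    (used for protein-level quantification).  ``F0`` is the mean over
    pre-stimulus frames when a protocol is supplied, else over all frames.
    """
    shape = stack.frames.shape[1:]
    bg = None
    if background_roi is not None:
        m = _roi_mask(background_roi, shape)
        bg = stack.frames[:, m].mean(axis=1)
    out = []
    for rid, roi in enumerate(rois.rois):
        m = _roi_mask(roi, shape)
        f = stack.frames[:, m].mean(axis=1)
        if bg is not None:
            f = f - bg
        if stim is not None:
            pre = stack.frame_times < stim.onset
            f0 = float(f[pre].mean()) if pre.any() else float(f[0])
            protocol = stim
        else:
            f0 = float(f.mean())
            protocol = StimProtocol(n_stimuli=0, frequency=1.0, onset=stack.frame_times[0])
        out.append(ROITimeSeries(
            time=stack.frame_times.copy(), F=f, stim=protocol, F0=f0, roi_id=rid,
        ))
    return out


def detect_iglusnfr_rois(
    stack: ImageStack,
    stim: StimProtocol,
    min_area: int = 10,
    k_sd: float = 3.0,
    response_len: Optional[float] = None,
) -> ROISet:
    """Automatic iGluSnFR ROI detection by image subtraction + thresholding.

    The difference image is mean(response frames) - mean(pre-stimulus
    frames); pixels above its mean + ``k_sd`` SD are kept and connected
    components with area strictly greater than ``min_area`` pixels become
    ROIs.  A stack with no suprathreshold pixels yields an empty set.
    """
    t = stack.frame_times
    pre = t < stim.onset
    if response_len is None:
        response_len = (stim.n_stimuli / stim.frequency) if stim.n_stimuli else 1.0
    resp = (t >= stim.onset) & (t <= stim.onset + response_len)
    if not pre.any() or not resp.any():
        raise ValueError("stack must span pre- and post-stimulus frames")
    diff = stack.frames[resp].mean(axis=0) - stack.frames[pre].mean(axis=0)
    thr = diff.mean() + k_sd * diff.std()
    labels, n = label(diff > thr)
    masks = []
    for lbl in range(1, n + 1):
        m = labels == lbl
        if m.sum() > min_area:
            masks.append(m)
    return ROISet(rois=masks, provenance="iglusnfr-auto")


# --------------------------------------------------------------------------
# normalization

def normalize_response(series: ROITimeSeries, mode: str) -> ROITimeSeries:
    """Normalize a raw fluorescence series.

    ``dF_over_dFmax`` divides dF = F - F0 by its post-onset peak (pHluorin,
    iGluSnFR convention); ``dF_over_F0`` divides by the baseline (GCaMP
    convention).  Normalizing an already-normalized series is a no-op.
    """
    if mode not in ("dF_over_dFmax", "dF_over_F0"):
        raise ValueError(f"unknown normalization mode {mode!r}")
    if series.normalization == mode:
        return series.with_values(series.F, mode)
    if series.normalization != "none":
        raise ValueError(
            f"series already normalized as {series.normalization!r}; "
            "renormalization between modes is not defined"
        )
    if series.F0 is None:
        raise ValueError("series has no baseline F0")
    df = series.F - series.F0
    if mode == "dF_over_F0":
        if series.F0 <= 0:
            raise ValueError("F0 must be positive for dF/F0 normalization")
        return series.with_values(df / series.F0, mode)
    post = series.time >= series.stim.onset
    dfmax = float(df[post].max()) if post.any() else float(df.max())
    if dfmax <= 0:
        raise ValueError("no positive fluorescence response: dFmax <= 0")
    return series.with_values(df / dfmax, mode)


# --------------------------------------------------------------------------
# exponential fits

def _exp_fit(t, y, fit_offset: bool, tau_guess: float):
    """Least-squares single-exponential fit y = A exp(-t/tau) (+ C)."""
    t = t - t[0]
    a0 = max(y[0] - (y[-1] if fit_offset else 0.0), 1e-12)
    c0 = y[-1] if fit_offset else 0.0
    if fit_offset:
        def model(tt, a, tau, c):
            return a * np.exp(-tt / tau) + c
        p0 = (a0, tau_guess, c0)
        bounds = ([0.0, 1e-6, -np.inf], [np.inf, np.inf, np.inf])
    else:
        def model(tt, a, tau):
            return a * np.exp(-tt / tau)
        p0 = (a0, tau_guess)
        bounds = ([0.0, 1e-6], [np.inf, np.inf])
    popt, _ = curve_fit(model, t, y, p0=p0, bounds=bounds, maxfev=10_000)
    pred = model(t, *popt)
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    a, tau = popt[0], popt[1]
    c = popt[2] if fit_offset else 0.0
    return a, tau, c, r2


def fit_endocytic_tau(
    series: ROITimeSeries,
    fit_start: Optional[float] = None,
    min_samples: int = 10,
) -> TauFit:
    """Endocytic time constant: single-exponential fit of the post-stimulus
    fluorescence decay, dF(t) = A exp(-(t - fit_start)/tau) + C.

    The offset C is left free because endocytosis can be incomplete (the
    series plateaus above baseline).  A fit with vanishing amplitude or a
    time constant pinned far beyond the observation window is flagged
    non-decaying (``valid=False``).
    """
    if fit_start is None:
        fit_start = series.stim.end
    sel = series.time >= fit_start
    if sel.sum() < min_samples:
        raise ValueError("not enough post-stimulus samples for the decay fit")
    t, y = series.time[sel], series.F[sel]
    span = t[-1] - t[0]
    try:
        a, tau, c, r2 = _exp_fit(t, y, fit_offset=True, tau_guess=span / 3)
    except RuntimeError:
        return TauFit(tau=np.nan, amplitude=np.nan, offset=np.nan, r2=0.0, valid=False)
    valid = (a > 1e-6 * max(abs(y).max(), 1e-12)) and (tau < 10 * span)
    return TauFit(tau=float(tau), amplitude=float(a), offset=float(c),
                  r2=r2, valid=bool(valid))


def fit_reacidification(
    series: ROITimeSeries,
    acid_window: tuple,
    settle: float = 0.5,
    min_samples: int = 5,
) -> float:
    """Reacidification rate (1/s) from the trapped-signal decay inside an
    acid-quench window.

    The first ``settle`` seconds of the window (solution exchange) are
    skipped; the remaining trapped signal is fit with a free-offset single
    exponential and the rate 1/tau is returned.
    """
    a0, a1 = acid_window
    sel = (series.time >= a0 + settle) & (series.time < a1)
    if sel.sum() < min_samples:
        raise ValueError("acid window too short for a reacidification fit")
    t, y = series.time[sel], series.F[sel]
    a, tau, _c, _r2 = _exp_fit(t, y, fit_offset=True, tau_guess=(t[-1] - t[0]) / 3)
    if a <= 1e-9 * max(abs(y).max(), 1e-12):
        return 0.0  # nothing trapped decays: flagged as no measurable rate
    return float(1.0 / tau)


def peak_transient(series: ROITimeSeries) -> float:
    """Peak dF/F0 of a Ca transient (maximum after stimulus onset)."""
    if series.normalization != "dF_over_F0":
        raise ValueError("peak_transient expects a dF/F0-normalized series")
    post = series.time >= series.stim.onset
    if not post.any():
        raise ValueError("no post-onset samples")
    k_global = int(np.argmax(series.F))
    if series.time[k_global] < series.stim.onset and series.F[k_global] > series.F[post].max():
        raise ValueError("peak precedes stimulus onset: artifact")
    return float(series.F[post].max())


def fit_ca_decay(series: ROITimeSeries, post_stim: Optional[float] = None) -> TauFit:
    """Decay time constant of a Ca transient after stimulus end.

    Fit is A exp(-t/tau) with the offset fixed at 0: Ca returns to the
    resting level.
    """
    if post_stim is None:
        post_stim = series.stim.end
    sel = series.time >= post_stim
    if sel.sum() < 5:
        raise ValueError("not enough post-stimulus samples")
    t, y = series.time[sel], series.F[sel]
    a, tau, _c, r2 = _exp_fit(t, y, fit_offset=False, tau_guess=(t[-1] - t[0]) / 3)
    valid = a > 1e-6 * max(abs(y).max(), 1e-12)
    return TauFit(tau=float(tau), amplitude=float(a), offset=0.0, r2=r2, valid=bool(valid))


# --------------------------------------------------------------------------
# Fura-2 and QC

def fura_ratio(f340, f380, bg340: float = 0.0, bg380: float = 0.0) -> np.ndarray:
    """Elementwise 340/380 excitation ratio after background subtraction.

    Samples with non-positive background-corrected F380 are masked (NaN).
    """
    f340 = np.asarray(f340, dtype=float) - bg340
    f380 = np.asarray(f380, dtype=float) - bg380
    if f340.shape != f380.shape:
        raise ValueError("channels must have equal length")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = f340 / f380
    return np.where(f380 > 0, ratio, np.nan)


def photobleach_check(series: ROITimeSeries, max_fraction: float = 0.02) -> bool:
    """Keep the recording unless baseline bleaching exceeds ``max_fraction``.

    A linear trend is fit to the stimulus-free baseline segment and
    extrapolated over the full recording; the recording is rejected only
    when the projected fractional decline strictly exceeds the threshold
    (2% by default, matching the inclusion criterion under which no bleach
    correction is needed).
    """
    pre = series.time < series.stim.onset
    if pre.sum() < 3:
        raise ValueError("no stimulus-free baseline segment available")
    slope, intercept = np.polyfit(series.time[pre], series.F[pre], 1)
    if intercept <= 0:
        raise ValueError("non-positive baseline intensity")
    decline = -slope * (series.time[-1] - series.time[0]) / intercept
    # strict inequality up to float round-off: exactly 2% is kept
    return bool(decline <= max_fraction * (1 + 1e-9))
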