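"""Forward models with known ground truth for every recording class.

Every generator here implements the physical model that the analysis stages
invert, so parameter recovery can be checked end to end without experimental
data.  Ground truth is returned alongside each trace and round-trips through
JSON.

Units are SI throughout (seconds, amperes, siemens, farads).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .core import (
    AmperometricTrace,
    ImageStack,
    LockInTrace,
    PatchCurrentTrace,
    ROITimeSeries,
    StimProtocol,
    TrainRecording,
)

__all__ = [
    "SimConfig",
    "PoreEventSpec",
    "SpikeSpec",
    "ReacidSchedule",
    "GroundTruth",
    "pore_admittance",
    "cascaded_lowpass",
    "simulate_fission_trace",
    "simulate_patch_current",
    "simulate_amperometric_trace",
    "simulate_phluorin_series",
    "simulate_depressing_train",
    "simulate_depletion_train",
    "simulate_whole_cell_admittance",
    "simulate_summating_train",
    "simulate_bouton_stack",
    "simulate_response_stack",
]


# --------------------------------------------------------------------------
# configuration and ground truth plumbing

@dataclass
class SimConfig:
    """Shared acquisition parameters for the trace generators.

    ``noise_sd`` is in the channel's native unit: siemens for admittance,
    amperes for current, a.u. for fluorescence.  The lock-in output filter is
    modelled as ``lockin_filter_order`` cascaded single-pole stages, each with
    time constant ``lockin_filter_tau`` (the hardware "1 ms, 24 dB/octave"
    setting corresponds to four poles).
    """

    seed: int = 0
    sampling_rate: float = 10_000.0
    duration: float = 1.0
    noise_sd: float = 0.0
    lockin_frequency: float = 20_000.0
    lockin_filter_tau: float = 1e-3
    lockin_filter_order: int = 4

    def __post_init__(self):
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be > 0")
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.lockin_frequency <= 0:
            raise ValueError("lockin_frequency must be > 0")

    @property
    def omega(self) -> float:
        return 2.0 * np.pi * self.lockin_frequency

    def time_axis(self) -> np.ndarray:
        n = int(round(self.duration * self.sampling_rate))
        return np.arange(n) / self.sampling_rate

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class GroundTruth:
    """What the generator put into a trace, serializable as a JSON sidecar."""

    kind: str
    events: list = field(default_factory=list)
    params: dict = field(default_factory=dict)

    def to_json(self, **kwargs) -> str:
        return json.dumps(
            {"kind": self.kind, "events": self.events, "params": self.params},
            sort_keys=True,
            **kwargs,
        )

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        return cls(kind=d["kind"], events=d["events"], params=d["params"])


def cascaded_lowpass(x: np.ndarray, fs: float, tau: float, order: int) -> np.ndarray:
    """Causal cascade of ``order`` identical single-pole RC stages.

    Matches the output-filter topology of analog lock-in amplifiers; a causal
    filter is used deliberately so the simulated traces carry the same group
    delay as hardware recordings.
    """
    if tau <= 0 or order <= 0:
        return np.asarray(x, dtype=float)
    a = np.exp(-1.0 / (fs * tau))
    y = np.asarray(x, dtype=float)
    # steady-state initial condition: assume the trace existed at x[0] forever
    from scipy.signal import lfilter

    for _ in range(order):
        zi = np.array([a * y[0]])
        y, _ = lfilter([1.0 - a], [1.0, -a], y, zi=zi)
    return y


# --------------------------------------------------------------------------
# cell-attached fission/fusion pore traces

def pore_admittance(gp, cv: float, omega: float) -> np.ndarray:
    """Complex admittance of a vesicle of capacitance ``cv`` behind a pore
    of conductance ``gp``:  Y = jwCv * Gp / (Gp + jwCv).

    Re(Y) = w^2 Cv^2 Gp / (Gp^2 + w^2 Cv^2);  Im(Y) = wCv Gp^2 / (Gp^2 + w^2 Cv^2).
    Gp -> inf gives the purely capacitive limit jwCv; Gp = 0 gives 0.
    """
    gp = np.asarray(gp, dtype=float)
    x = omega * cv
    with np.errstate(invalid="ignore"):
        denom = gp * gp + x * x
        re = x * x * gp / denom
        im = x * gp * gp / denom
    out = re + 1j * im
    return np.where(np.isinf(gp), 0.0 + 1j * x, out)


@dataclass
class PoreEventSpec:
    """One exo- or endocytic event with an explicit pore-conductance profile.

    ``gp_profile`` maps time since pore onset (0 .. pore_duration, seconds)
    to pore conductance in siemens.  ``pore_duration == 0`` means an
    instantaneous capacitance step.
    """

    t_start: float
    direction: str  # "endocytic" | "exocytic"
    cv: float
    pore_duration: float = 0.0
    gp_profile: Optional[Callable[[np.ndarray], np.ndarray]] = None

    def __post_init__(self):
        if self.direction not in ("endocytic", "exocytic"):
            raise ValueError(f"unknown direction {self.direction!r}")
        if self.cv <= 0:
            raise ValueError("Cv must be > 0")
        if self.pore_duration < 0:
            raise ValueError("pore_duration must be >= 0")
        if self.pore_duration > 0 and self.gp_profile is None:
            raise ValueError("a finite pore needs a gp_profile")

    @property
    def t_end(self) -> float:
        return self.t_start + self.pore_duration

    def describe(self) -> dict:
        return {
            "t_start": self.t_start,
            "direction": self.direction,
            "cv": self.cv,
            "pore_duration": self.pore_duration,
        }


def linear_closure(gp_start: float, duration: float) -> Callable:
    """Pore profile declining linearly from ``gp_start`` to 0 over ``duration``."""

    def profile(t):
        t = np.asarray(t, dtype=float)
        return np.clip(gp_start * (1.0 - t / duration), 0.0, None)

    return profile


def constant_pore(gp: float) -> Callable:
    def profile(t):
        return np.full_like(np.asarray(t, dtype=float), gp)

    return profile


def simulate_fission_trace(
    events: Sequence[PoreEventSpec],
    cfg: SimConfig,
    baseline_re: float = 0.0,
    baseline_im: float = 0.0,
    apply_filter: bool = True,
):
    """Render Re/Im lock-in channels for a set of pore events.

    An endocytic vesicle contributes jwCv to the patch admittance while still
    part of the plasma membrane, passes through ``pore_admittance`` while its
    fission pore constricts, and contributes nothing once the pore has closed.
    Exocytic events run the same path in reverse.  White Gaussian noise is
    added before the lock-in output filter.
    """
    ordered = sorted(events, key=lambda e: e.t_start)
    for a, b in zip(ordered, ordered[1:]):
        if b.t_start < a.t_end:
            raise ValueError(
                f"overlapping pore events at t={a.t_start:g}s and t={b.t_start:g}s"
            )
    t = cfg.time_axis()
    re = np.full_like(t, baseline_re)
    im = np.full_like(t, baseline_im)
    omega = cfg.omega
    for ev in ordered:
        x = omega * ev.cv
        if ev.direction == "endocytic":
            im[t < ev.t_start] += x
        else:
            im[t >= ev.t_end] += x
        if ev.pore_duration > 0:
            sel = (t >= ev.t_start) & (t < ev.t_end)
            y = pore_admittance(ev.gp_profile(t[sel] - ev.t_start), ev.cv, omega)
            re[sel] += y.real
            im[sel] += y.imag
    if cfg.noise_sd > 0:
        rng = cfg.rng()
        re = re + rng.normal(0.0, cfg.noise_sd, size=len(t))
        im = im + rng.normal(0.0, cfg.noise_sd, size=len(t))
    if apply_filter:
        re = cascaded_lowpass(re, cfg.sampling_rate, cfg.lockin_filter_tau, cfg.lockin_filter_order)
        im = cascaded_lowpass(im, cfg.sampling_rate, cfg.lockin_filter_tau, cfg.lockin_filter_order)
    trace = LockInTrace(
        time=t, Re=re, Im=im,
        sampling_rate=cfg.sampling_rate,
        lockin_frequency=cfg.lockin_frequency,
    )
    truth = GroundTruth(
        kind="fission_trace",
        events=[ev.describe() for ev in ordered],
        params={
            "seed": cfg.seed, "noise_sd": cfg.noise_sd,
            "lockin_frequency": cfg.lockin_frequency,
            "baseline_re": baseline_re, "baseline_im": baseline_im,
            "filtered": bool(apply_filter),
        },
    )
    return trace, truth


# --------------------------------------------------------------------------
# double-patch ionic current

def simulate_patch_current(
    V: float,
    g_loss_model: Callable[[float], float],
    t_event: float,
    baseline_slope: float,
    cfg: SimConfig,
    baseline_offset: float = 0.0,
    filter_hz: float = 500.0,
):
    """Patch current with a conductance-loss step at the endocytic event.

    At ``t_event`` the patch loses ``g_loss_model(V)`` of membrane conductance
    (channels internalized on the vesicle).  With the cell-attached sign
    convention used here, loss of outward current at positive patch potential
    registers as an upward step of the plotted current, so the injected step
    is ``+g(V) * V``.
    """
    g = float(g_loss_model(V))
    if not np.isfinite(g):
        raise ValueError(f"g_loss_model undefined at V={V}")
    t = cfg.time_axis()
    if not (t[0] <= t_event <= t[-1]):
        raise ValueError("t_event must lie within the trace")
    i = baseline_offset + baseline_slope * t
    delta_i = g * V
    i = i + delta_i * (t >= t_event)
    if cfg.noise_sd > 0:
        i = i + cfg.rng().normal(0.0, cfg.noise_sd, size=len(t))
    if filter_hz:
        i = cascaded_lowpass(i, cfg.sampling_rate, 1.0 / (2 * np.pi * filter_hz), 1)
    trace = PatchCurrentTrace(time=t, I=i, V_patch=V, filter_hz=filter_hz, t_event=t_event)
    truth = GroundTruth(
        kind="patch_current",
        events=[{"t_event": t_event, "delta_i": delta_i, "g_loss": g, "V": V}],
        params={"seed": cfg.seed, "noise_sd": cfg.noise_sd,
                "baseline_slope": baseline_slope, "baseline_offset": baseline_offset},
    )
    return trace, truth


# --------------------------------------------------------------------------
# carbon-fiber amperometry

@dataclass
class SpikeSpec:
    """One amperometric release event.

    ``t`` is the rise onset (snapped to the sample grid by the generator so
    closed-form charge/width identities hold exactly).  A foot, when present,
    is a plateau of ``foot_amp`` lasting ``foot_duration`` immediately before
    the rise.  The rise is a raised cosine over ``rise_time``; the falling
    phase decays exponentially with ``tau_decay`` from the peak.
    """

    t: float
    peak: float
    tau_decay: float
    rise_time: float = 0.0
    foot_amp: float = 0.0
    foot_duration: float = 0.0

    def __post_init__(self):
        for name in ("peak", "tau_decay", "rise_time", "foot_amp", "foot_duration"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.tau_decay == 0:
            raise ValueError("tau_decay must be > 0")

    def describe(self) -> dict:
        return {
            "t": self.t, "peak": self.peak, "tau_decay": self.tau_decay,
            "rise_time": self.rise_time, "foot_amp": self.foot_amp,
            "foot_duration": self.foot_duration,
            "charge": self.analytic_charge(),
        }

    def analytic_charge(self) -> float:
        """Closed-form integral of the noiseless waveform (coulombs)."""
        q_foot = self.foot_amp * self.foot_duration
        # raised cosine from foot_amp to peak averages (foot_amp + peak) / 2
        q_rise = 0.5 * (self.foot_amp + self.peak) * self.rise_time
        q_decay = self.peak * self.tau_decay
        return q_foot + q_rise + q_decay


def simulate_amperometric_trace(
    spikes: Sequence[SpikeSpec],
    cfg: SimConfig,
    stim_time: float = 0.0,
    baseline: float = 0.0,
):
    """Render an amperometric current trace from spike specifications."""
    ordered = sorted(spikes, key=lambda s: s.t)
    fs = cfg.sampling_rate
    t = cfg.time_axis()
    i = np.full_like(t, baseline)
    truth_events = []
    for sp in ordered:
        t0 = round(sp.t * fs) / fs  # snap rise onset to the grid
        # foot plateau
        if sp.foot_duration > 0:
            sel = (t >= t0 - sp.foot_duration) & (t < t0)
            i[sel] += sp.foot_amp
        # raised-cosine rise
        if sp.rise_time > 0:
            sel = (t >= t0) & (t < t0 + sp.rise_time)
            phase = (t[sel] - t0) / sp.rise_time
            i[sel] += sp.foot_amp + (sp.peak - sp.foot_amp) * 0.5 * (1 - np.cos(np.pi * phase))
        # exponential decay from the peak
        t_pk = t0 + sp.rise_time
        sel = t >= t_pk
        i[sel] += sp.peak * np.exp(-(t[sel] - t_pk) / sp.tau_decay)
        d = sp.describe()
        d["t"] = t0
        d["t_peak"] = t_pk
        truth_events.append(d)
    if cfg.noise_sd > 0:
        i = i + cfg.rng().normal(0.0, cfg.noise_sd, size=len(t))
    trace = AmperometricTrace(time=t, I=i, sampling_rate=fs, stim_time=stim_time)
    truth = GroundTruth(
        kind="amperometric_trace",
        events=truth_events,
        params={"seed": cfg.seed, "noise_sd": cfg.noise_sd,
                "stim_time": stim_time, "baseline": baseline},
    )
    return trace, truth


# --------------------------------------------------------------------------
# pHluorin / reacidification series

@dataclass
class ReacidSchedule:
    """Acid-quench protocol: surface fluorescence is quenched inside each
    window, leaving only vesicles endocytosed but not yet reacidified."""

    acid_windows: Sequence[tuple]
    tau_reacid: float

    def __post_init__(self):
        if self.tau_reacid <= 0:
            raise ValueError("tau_reacid must be > 0")
        self.acid_windows = tuple(tuple(map(float, w)) for w in self.acid_windows)


def simulate_phluorin_series(
    tau_endo: float,
    stim: StimProtocol,
    cfg: SimConfig,
    reacid: Optional[ReacidSchedule] = None,
    f0: float = 100.0,
    delta_fmax: float = 50.0,
    bleach_fraction: float = 0.0,
):
    """pHluorin fluorescence: stimulus-locked rise, mono-exponential decay.

    Surface reporter S rises linearly during the stimulus train to
    ``delta_fmax`` and is retrieved with time constant ``tau_endo``
    (``tau_endo=inf`` freezes retrieval: a flat post-stimulus plateau).
    With a reacidification schedule, retrieved reporter enters a trapped pool
    T that quenches with ``tau_reacid``; inside acid windows only T is
    visible (surface quenched), outside F = F0 + S + T.

    Without a schedule the visible decay is simply S (endocytosis +
    reacidification lumped, as in standard pHluorin rundown analysis).
    """
    if tau_endo <= 0:
        raise ValueError("tau_endo must be > 0 (use np.inf for no retrieval)")
    t = cfg.time_axis()
    if stim.end >= t[-1]:
        raise ValueError("stimulus train must end before the trace does")
    dt = 1.0 / cfg.sampling_rate
    t_on, t_off = stim.onset, stim.end
    rise_dur = max(t_off - t_on, dt)

    surface = np.zeros_like(t)
    ramp = (t >= t_on) & (t <= t_off)
    surface[ramp] = delta_fmax * (t[ramp] - t_on) / rise_dur
    post = t > t_off
    if np.isinf(tau_endo):
        surface[post] = delta_fmax
    else:
        surface[post] = delta_fmax * np.exp(-(t[post] - t_off) / tau_endo)

    trapped = np.zeros_like(t)
    in_acid = np.zeros_like(t, dtype=bool)
    if reacid is not None:
        for a0, a1 in reacid.acid_windows:
            in_acid |= (t >= a0) & (t < a1)
    if reacid is not None and not np.isinf(tau_endo):
        # two-pool update: retrieval feeds the visible trapped pool, which
        # quenches with tau_reacid.  Reporter endocytosed *inside* an acid
        # window was surface-quenched at pH 5.5 and stays dark, so the
        # visible pool receives no inflow there — its in-window decay is
        # purely the reacidification rate.
        decay = np.exp(-dt / reacid.tau_reacid)
        T = 0.0
        for k in range(len(t)):
            inflow = surface[k] / tau_endo * dt if (t[k] > t_off and not in_acid[k]) else 0.0
            T = T * decay + inflow
            trapped[k] = T

    f = f0 + surface + trapped
    if reacid is not None:
        f = np.where(in_acid, trapped, f)
    if bleach_fraction > 0:
        f = f * (1.0 - bleach_fraction * (t - t[0]) / (t[-1] - t[0]))
    if cfg.noise_sd > 0:
        f = f + cfg.rng().normal(0.0, cfg.noise_sd, size=len(t))

    series = ROITimeSeries(time=t, F=f, stim=stim, F0=f0)
    truth = GroundTruth(
        kind="phluorin_series",
        events=[{
            "tau_endo": tau_endo if np.isfinite(tau_endo) else None,
            "tau_reacid": reacid.tau_reacid if reacid else None,
            "delta_fmax": delta_fmax, "f0": f0,
            "bleach_fraction": bleach_fraction,
        }],
        params={"seed": cfg.seed, "noise_sd": cfg.noise_sd,
                "stim_onset": stim.onset, "stim_end": stim.end},
    )
    return series, truth


# --------------------------------------------------------------------------
# depressing trains

def simulate_depressing_train(
    n_stim: int,
    a_ss: float,
    r: float,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Geometric short-term-depression model a_n = a_ss + (1-a_ss) r^(n-1).

    The first amplitude is 1 by construction; the sequence relaxes
    monotonically to the steady-state fraction ``a_ss``.
    """
    if not (0.0 <= a_ss <= 1.0):
        raise ValueError("a_ss must be in [0, 1]")
    if not (0.0 <= r < 1.0):
        raise ValueError("r must be in [0, 1)")
    n = np.arange(n_stim)
    a = a_ss + (1.0 - a_ss) * r**n
    if noise_sd > 0:
        a = a + np.random.default_rng(seed).normal(0.0, noise_sd, size=n_stim)
    return a


def simulate_depletion_train(
    p: float,
    tau_rec: float,
    isi: float,
    n_stim: int,
) -> np.ndarray:
    """Deterministic vesicle-depletion model.

    A pool D (fraction of full) releases p*D per stimulus and recovers
    exponentially between stimuli: D_{n+1} = 1 - (1 - (1-p) D_n) e^(-isi/tau).
    Closed form for the paired-pulse ratio: a2/a1 = 1 - p * e^(-isi/tau_rec).
    """
    if not (0.0 < p <= 1.0):
        raise ValueError("p must be in (0, 1]")
    d = 1.0
    out = np.empty(n_stim)
    rec = np.exp(-isi / tau_rec)
    for k in range(n_stim):
        out[k] = p * d
        d_after = d * (1.0 - p)
        d = 1.0 - (1.0 - d_after) * rec
    return out


def simulate_summating_train(
    amplitudes: Sequence[float],
    stim_times: Sequence[float],
    tau_decay: float,
    cfg: SimConfig,
    modality: str = "ipsc",
    delay: float = 2e-3,
):
    """Superpose instant-rise exponential responses into a summating trace.

    Each stimulus k contributes amplitudes[k] * exp(-(t-t_k-delay)/tau) for
    t >= t_k + delay; successive responses ride on the residual decay of the
    previous ones, exactly the situation the residual-subtraction extractor
    must undo.
    """
    amplitudes = np.asarray(amplitudes, dtype=float)
    stim_times = np.asarray(stim_times, dtype=float)
    if len(amplitudes) != len(stim_times):
        raise ValueError("one amplitude per stimulus required")
    fs = cfg.sampling_rate
    t = cfg.time_axis()
    y = np.zeros_like(t)
    onsets = np.round((stim_times + delay) * fs) / fs  # snap to grid
    for a, t_on in zip(amplitudes, onsets):
        sel = t >= t_on
        y[sel] += a * np.exp(-(t[sel] - t_on) / tau_decay)
    if cfg.noise_sd > 0:
        y = y + cfg.rng().normal(0.0, cfg.noise_sd, size=len(t))
    rec = TrainRecording(time=t, response=y, stim_times=stim_times, modality=modality)
    truth = GroundTruth(
        kind="summating_train",
        events=[{"amplitudes": amplitudes.tolist(),
                 "stim_times": stim_times.tolist(),
                 "tau_decay": tau_decay, "delay": delay}],
        params={"seed": cfg.seed, "noise_sd": cfg.noise_sd, "modality": modality},
    )
    return rec, truth


# --------------------------------------------------------------------------
# whole-cell equivalent circuit (forward model)

def simulate_whole_cell_admittance(cm: float, gm: float, gs: float, f: float):
    """Exact admittance of the three-element patch circuit.

    Series access conductance Gs feeding the parallel pair (Gm, Cm):
    Y = Gs (Gm + jwCm) / (Gs + Gm + jwCm); DC conductance Gt = Gs Gm / (Gs + Gm).
    """
    if cm < 0 or gm <= 0 or gs <= 0 or f <= 0:
        raise ValueError("need Cm >= 0, Gm > 0, Gs > 0, f > 0")
    omega = 2.0 * np.pi * f
    zm = gm + 1j * omega * cm
    y = gs * zm / (gs + zm)
    gt = gs * gm / (gs + gm)
    return y, gt


# --------------------------------------------------------------------------
# synthetic image stacks

def simulate_bouton_stack(
    shape: tuple,
    centers: Sequence[tuple],
    timecourses: Sequence[np.ndarray],
    frame_times: np.ndarray,
    sigma: float = 1.2,
    baseline: float = 100.0,
    noise_sd: float = 0.0,
    seed: int = 0,
):
    """Movie of Gaussian boutons whose brightness follows given time courses."""
    h, w = shape
    frame_times = np.asarray(frame_times, dtype=float)
    nt = len(frame_times)
    rows, cols = np.mgrid[0:h, 0:w]
    stack = np.full((nt, h, w), baseline, dtype=float)
    for (r0, c0), tc in zip(centers, timecourses):
        tc = np.asarray(tc, dtype=float)
        if len(tc) != nt:
            raise ValueError("time course length must match frame count")
        kernel = np.exp(-((rows - r0) ** 2 + (cols - c0) ** 2) / (2 * sigma**2))
        stack += tc[:, None, None] * kernel[None, :, :]
    if noise_sd > 0:
        stack += np.random.default_rng(seed).normal(0.0, noise_sd, size=stack.shape)
    return ImageStack(frames=stack, frame_times=frame_times)


def simulate_response_stack(
    shape: tuple,
    blobs: Sequence[tuple],
    frame_times: np.ndarray,
    stim: StimProtocol,
    baseline: float = 100.0,
    noise_sd: float = 1.0,
    seed: int = 0,
):
    """Movie with pixel-mask blobs that brighten after the stimulus.

    ``blobs`` is a sequence of (bool mask, amplitude) pairs; each blob adds
    ``amplitude`` to its pixels on every post-onset frame, giving exact
    ground-truth ROI areas for the detection contracts.
    """
    frame_times = np.asarray(frame_times, dtype=float)
    nt = len(frame_times)
    stack = np.full((nt,) + tuple(shape), baseline, dtype=float)
    responding = frame_times >= stim.onset
    for mask, amp in blobs:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != tuple(shape):
            raise ValueError("blob mask shape must match the frame shape")
        stack[responding] += amp * mask[None, :, :]
    if noise_sd > 0:
        stack += np.random.default_rng(seed).normal(0.0, noise_sd, size=stack.shape)
    return ImageStack(frames=stack, frame_times=frame_times)
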