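"""End-to-end WT-vs-KO pipeline on synthetic cohorts.

Generates paired wild-type and knockout cohorts for every assay class,
analyzes them with the library stages, and tests the group differences the
generators encode: the knockout arm has longer fission-pore durations,
a reduced positive-voltage current drift, a slower endocytic time constant,
and deeper steady-state depression — while event counts, vesicle sizes and
amperometric release are unchanged.  Everything is deterministic given the
run seed.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, amperometry as amp, capacitance as cap, drift as dr
from . import io as sqio
from . import optical as opt
from . import stats as st
from . import synthetic as syn
from . import trains as tn
from .core import StimProtocol

__all__ = ["RunConfig", "run_pipeline", "simulate_cohorts", "analyze_cohorts"]


@dataclass
class RunConfig:
    """Parameters of the WT/KO synthetic study.

    KO scale factors encode the effect directions: fission-pore durations
    x1.6, positive-voltage drift conductance x0.2, endocytic tau x1.75,
    IPSC steady state x0.44 and iGluSnFR steady state x0.64.  Amperometric
    release parameters are identical in both arms (no effect expected).
    """

    seed: int = 1
    outdir: str = "results/pipeline"

    # fission-pore cohort (cell-attached)
    fission_cells: int = 10
    fission_events_per_cell: int = 3
    fission_duration_wt: float = 0.040  # s, log-normal median
    fission_duration_sigma: float = 0.25  # log-SD
    fission_ko_duration_scale: float = 1.6
    fission_cv_median: float = 1.0e-15
    fission_gp_start: float = 2e-9
    fission_noise_sd: float = 1e-12
    fission_sampling: float = 10_000.0

    # drift I-V cohort (double patch)
    drift_voltages: tuple = (-0.040, -0.030, -0.020, 0.0, 0.020, 0.030, 0.040)
    drift_n_per_voltage: int = 12
    drift_g_positive: float = 50e-12
    drift_g_negative: float = 12.5e-12
    drift_ko_positive_scale: float = 0.2
    drift_noise_sd: float = 0.5e-12
    drift_sampling: float = 5_000.0

    # amperometry cohort (no KO effect)
    amp_cells: int = 8
    amp_spikes_per_cell: int = 25
    amp_peak_median: float = 40e-12
    amp_tau_median: float = 2e-3
    amp_foot_fraction: float = 0.5
    amp_foot_duration_median: float = 2e-3
    amp_noise_sd: float = 0.5e-12
    amp_sampling: float = 10_000.0

    # optical endocytosis cohort
    optical_boutons: int = 40
    optical_tau_wt: float = 15.0
    optical_ko_tau_scale: float = 1.75
    optical_snr: float = 10.0
    optical_sampling: float = 2.0

    # train-depression cohorts
    ipsc_cells_wt: int = 10
    ipsc_cells_ko: int = 8
    ipsc_n_stim: int = 250
    ipsc_freq: float = 10.0
    ipsc_a_ss_wt: float = 0.5
    ipsc_ko_scale: float = 0.44
    iglu_cells: int = 10
    iglu_n_stim: int = 50
    iglu_a_ss_wt: float = 0.5
    iglu_ko_scale: float = 0.64
    train_r: float = 0.9
    train_tau_decay: float = 0.040
    train_noise_sd: float = 1e-12

    alpha: float = 0.05

    def __post_init__(self):
        if self.seed < 0:
            raise ValueError("seed must be non-negative")
        for name in ("fission_duration_wt", "optical_tau_wt", "drift_g_positive"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def _child_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.default_rng(seed).integers(0, 2**31 - 1, size=n)


# --------------------------------------------------------------------------
# cohort generation

def _fission_cohort(cfg: RunConfig, arm: str, seed: int):
    rng = np.random.default_rng(seed)
    scale = cfg.fission_ko_duration_scale if arm == "ko" else 1.0
    cells = []
    for c in range(cfg.fission_cells):
        events = []
        t0 = 1.0
        for _ in range(cfg.fission_events_per_cell):
            dur = float(np.exp(rng.normal(
                np.log(cfg.fission_duration_wt * scale), cfg.fission_duration_sigma)))
            cv = float(np.exp(rng.normal(np.log(cfg.fission_cv_median), 0.2)))
            events.append(syn.PoreEventSpec(
                t_start=t0, direction="endocytic", cv=cv, pore_duration=dur,
                gp_profile=syn.linear_closure(cfg.fission_gp_start, dur),
            ))
            t0 += 1.0 + dur
        sim = syn.SimConfig(
            seed=int(rng.integers(0, 2**31 - 1)),
            sampling_rate=cfg.fission_sampling,
            duration=t0 + 1.0,
            noise_sd=cfg.fission_noise_sd,
        )
        trace, truth = syn.simulate_fission_trace(events, sim, baseline_re=1e-9,
                                                  baseline_im=2e-10)
        cells.append((f"{arm}_cell{c:02d}", trace, truth))
    return cells


def _analyze_fission(cells):
    rows = []
    for cell_id, trace, truth in cells:
        detected = cap.detect_capacitance_steps(trace, gap=0.15, min_separation=0.3)
        for ev in detected:
            if ev.direction != "endocytic":
                continue
            try:
                cap.measure_fission_pore(trace, ev)
            except ValueError:
                continue
            rows.append({
                "cell_id": cell_id,
                "t_step_s": ev.t_step,
                "Cv_fF": ev.cv * 1e15,
                "duration_ms": (ev.fission_pore_duration or 0.0) * 1e3,
                "Gp_mean_pS": np.nan if ev.gp_mean is None else ev.gp_mean * 1e12,
                "kinetics_valid": ev.kinetics_valid,
            })
    return pd.DataFrame(rows)


def _drift_cohort(cfg: RunConfig, arm: str, seed: int):
    rng = np.random.default_rng(seed)
    pos_scale = cfg.drift_ko_positive_scale if arm == "ko" else 1.0

    def g_loss(V: float) -> float:
        g = cfg.drift_g_positive if V > 0 else cfg.drift_g_negative
        return g * (pos_scale if V > 0 else 1.0)

    measurements = []
    for V in cfg.drift_voltages:
        for _ in range(cfg.drift_n_per_voltage):
            sim = syn.SimConfig(
                seed=int(rng.integers(0, 2**31 - 1)),
                sampling_rate=cfg.drift_sampling, duration=0.6,
                noise_sd=cfg.drift_noise_sd,
            )
            trace, _ = syn.simulate_patch_current(
                V, g_loss, t_event=0.3,
                baseline_slope=float(rng.normal(0.0, 2e-12)), cfg=sim,
            )
            measurements.append(dr.measure_current_drift(trace, 0.3))
    return measurements


def _amp_cohort(cfg: RunConfig, arm: str, seed: int):
    rng = np.random.default_rng(seed)
    cells = []
    for c in range(cfg.amp_cells):
        n_spk = max(int(rng.poisson(cfg.amp_spikes_per_cell)), 3)
        times = np.sort(rng.uniform(6.0, 20.0, size=n_spk))
        # enforce separability
        times = times[np.concatenate([[True], np.diff(times) > 0.05])]
        spikes = []
        for ts in times:
            has_foot = rng.random() < cfg.amp_foot_fraction
            spikes.append(syn.SpikeSpec(
                t=float(ts),
                peak=float(np.exp(rng.normal(np.log(cfg.amp_peak_median), 0.3))),
                tau_decay=float(np.exp(rng.normal(np.log(cfg.amp_tau_median), 0.2))),
                rise_time=0.3e-3,
                foot_amp=5e-12 if has_foot else 0.0,
                foot_duration=float(np.exp(rng.normal(
                    np.log(cfg.amp_foot_duration_median), 0.3))) if has_foot else 0.0,
            ))
        sim = syn.SimConfig(
            seed=int(rng.integers(0, 2**31 - 1)),
            sampling_rate=cfg.amp_sampling, duration=25.0,
            noise_sd=cfg.amp_noise_sd,
        )
        trace, truth = syn.simulate_amperometric_trace(spikes, sim, stim_time=5.0)
        cells.append((f"{arm}_amp{c:02d}", trace, truth))
    return cells


def _analyze_amp(cells):
    summaries = []
    for cell_id, trace, _truth in cells:
        spikes = amp.detect_spikes(trace)
        for s in spikes:
            amp.spike_params(trace, s)
            amp.detect_foot(trace, s)
        summaries.append(amp.cell_summary(spikes, cell_id, stim_time=trace.stim_time))
    return summaries


def _optical_cohort(cfg: RunConfig, arm: str, seed: int):
    rng = np.random.default_rng(seed)
    tau = cfg.optical_tau_wt * (cfg.optical_ko_tau_scale if arm == "ko" else 1.0)
    stim = StimProtocol(n_stimuli=100, frequency=20.0, onset=10.0)
    dfmax = 50.0
    out = []
    for _ in range(cfg.optical_boutons):
        sim = syn.SimConfig(
            seed=int(rng.integers(0, 2**31 - 1)),
            sampling_rate=cfg.optical_sampling, duration=100.0,
            noise_sd=dfmax / cfg.optical_snr,
        )
        series, _ = syn.simulate_phluorin_series(tau, stim, sim, delta_fmax=dfmax)
        out.append(series)
    return out


def _analyze_optical(series_list):
    taus = []
    for s in series_list:
        fit = opt.fit_endocytic_tau(opt.normalize_response(s, "dF_over_dFmax"))
        if fit.valid:
            taus.append(fit.tau)
    return np.array(taus)


def _train_cohort(cfg: RunConfig, arm: str, modality: str, seed: int):
    rng = np.random.default_rng(seed)
    if modality == "ipsc":
        n_cells = cfg.ipsc_cells_ko if arm == "ko" else cfg.ipsc_cells_wt
        n_stim, freq = cfg.ipsc_n_stim, cfg.ipsc_freq
        a_ss_wt, ko_scale = cfg.ipsc_a_ss_wt, cfg.ipsc_ko_scale
        fs, unit = 5_000.0, 100e-12
    else:
        n_cells = cfg.iglu_cells
        n_stim, freq = cfg.iglu_n_stim, cfg.ipsc_freq
        a_ss_wt, ko_scale = cfg.iglu_a_ss_wt, cfg.iglu_ko_scale
        fs, unit = 50.0, 1.0
    a_ss = a_ss_wt * (ko_scale if arm == "ko" else 1.0)
    r = cfg.train_r
    if arm == "ko":
        # deeper depression with a slower onset: the KO rate is chosen so the
        # second response matches WT, keeping the paired-pulse ratio unchanged
        # while the trains diverge later in the stimulus sequence
        a2_wt = a_ss_wt + (1.0 - a_ss_wt) * cfg.train_r
        r = (a2_wt - a_ss) / (1.0 - a_ss)
    recs = []
    for _ in range(n_cells):
        amps = syn.simulate_depressing_train(
            n_stim, a_ss=a_ss, r=r,
            noise_sd=0.02, seed=int(rng.integers(0, 2**31 - 1)),
        ) * unit
        stim_times = 1.0 + np.arange(n_stim) / freq
        sim = syn.SimConfig(
            seed=int(rng.integers(0, 2**31 - 1)), sampling_rate=fs,
            duration=stim_times[-1] + 1.0,
            noise_sd=cfg.train_noise_sd * (unit / 100e-12),
        )
        rec, _ = syn.simulate_summating_train(
            amps, stim_times, cfg.train_tau_decay, sim, modality=modality)
        recs.append(rec)
    return recs


def _analyze_trains(recs):
    ss, ppr = [], []
    for rec in recs:
        res = tn.analyze_train(rec)
        ss.append(res.steady_state)
        ppr.append(res.ppr)
    return np.array(ss), np.array(ppr)


# --------------------------------------------------------------------------
# orchestration

def simulate_cohorts(cfg: RunConfig) -> dict:
    """All WT and KO synthetic cohorts, deterministically from cfg.seed."""
    seeds = _child_seeds(cfg.seed, 10)
    return {
        "fission": {"wt": _fission_cohort(cfg, "wt", seeds[0]),
                    "ko": _fission_cohort(cfg, "ko", seeds[1])},
        "drift": {"wt": _drift_cohort(cfg, "wt", seeds[2]),
                  "ko": _drift_cohort(cfg, "ko", seeds[3])},
        "amperometry": {"wt": _amp_cohort(cfg, "wt", seeds[4]),
                        "ko": _amp_cohort(cfg, "ko", seeds[5])},
        "optical": {"wt": _optical_cohort(cfg, "wt", seeds[6]),
                    "ko": _optical_cohort(cfg, "ko", seeds[7])},
        "ipsc": {"wt": _train_cohort(cfg, "wt", "ipsc", seeds[8]),
                 "ko": _train_cohort(cfg, "ko", "ipsc", seeds[8] + 1)},
        "iglusnfr": {"wt": _train_cohort(cfg, "wt", "iglusnfr", seeds[9]),
                     "ko": _train_cohort(cfg, "ko", "iglusnfr", seeds[9] + 1)},
    }


def _compare(wt: np.ndarray, ko: np.ndarray, expected: str, alpha: float) -> dict:
    if np.var(wt) == 0 and np.var(ko) == 0:
        # degenerate zero-variance case (e.g. identical event counts)
        t, p, df = 0.0, 1.0, len(wt) + len(ko) - 2
        if np.mean(wt) != np.mean(ko):
            t, p = np.inf, 0.0
    else:
        t, p, df = st.ttest_unpaired(wt, ko)
    observed = "ko_higher" if np.mean(ko) > np.mean(wt) else "ko_lower"
    return {
        "wt_mean": float(np.mean(wt)), "wt_sem": float(np.std(wt, ddof=1) / np.sqrt(len(wt))),
        "ko_mean": float(np.mean(ko)), "ko_sem": float(np.std(ko, ddof=1) / np.sqrt(len(ko))),
        "n_wt": int(len(wt)), "n_ko": int(len(ko)),
        "t": t, "p": p, "df": df,
        "expected_direction": expected,
        "observed_direction": observed,
        "significant": bool(p < alpha),
        "effect_confirmed": bool(p < alpha and observed == expected)
        if expected != "none" else bool(p >= alpha),
    }


def analyze_cohorts(cfg: RunConfig, cohorts: dict) -> dict:
    """Run every analysis stage and assemble the KO-vs-WT comparisons."""
    results: dict = {"parameters": asdict(cfg), "version": __version__}

    # fission pores: log10 duration comparison on kinetics-valid events
    fission_tables = {arm: _analyze_fission(cells)
                      for arm, cells in cohorts["fission"].items()}
    dur = {arm: df.loc[df.kinetics_valid, "duration_ms"].to_numpy()
           for arm, df in fission_tables.items()}
    results["fission_log_duration"] = _compare(
        st.log_transform(dur["wt"]), st.log_transform(dur["ko"]),
        expected="ko_higher", alpha=cfg.alpha)
    counts = {arm: np.array([
        cap.count_endocytic_events([
            cap.CapacitanceEvent("endocytic", t, 1e-15)
            for t in df.loc[df.cell_id == c, "t_step_s"]])
        for c in df.cell_id.unique()])
        for arm, df in fission_tables.items()}
    results["fission_event_count"] = _compare(
        counts["wt"], counts["ko"], expected="none", alpha=cfg.alpha)
    results["fission_cv"] = _compare(
        fission_tables["wt"]["Cv_fF"].to_numpy(),
        fission_tables["ko"]["Cv_fF"].to_numpy(), expected="none", alpha=cfg.alpha)

    # drift I-V
    iv = {}
    drift_compare = {}
    for arm, ms in cohorts["drift"].items():
        iv[arm] = dr.build_iv(ms)
    for k, V in enumerate(iv["wt"].voltages):
        wt_vals = np.array([m.delta_I for m in cohorts["drift"]["wt"] if m.V_patch == V])
        ko_vals = np.array([m.delta_I for m in cohorts["drift"]["ko"] if m.V_patch == V])
        if V == 0:
            continue
        expected = "ko_lower" if V > 0 else "none"
        drift_compare[f"{V * 1e3:+.0f}mV"] = _compare(
            wt_vals * 1e12, ko_vals * 1e12, expected=expected, alpha=cfg.alpha)
    r2_wt, idx_wt = dr.rectification_test(iv["wt"])
    results["drift_iv"] = {
        "per_voltage": drift_compare,
        "wt_linear_r2": r2_wt, "wt_rectification_index": idx_wt,
    }

    # amperometry (no effect expected)
    amp_sum = {arm: _analyze_amp(cells) for arm, cells in cohorts["amperometry"].items()}
    for param in ("median_quantal", "median_halfwidth", "spike_frequency"):
        wt = np.array([getattr(c, param) for c in amp_sum["wt"]], dtype=float)
        ko = np.array([getattr(c, param) for c in amp_sum["ko"]], dtype=float)
        results[f"amperometry_{param}"] = _compare(wt, ko, expected="none", alpha=cfg.alpha)

    # optical endocytic tau
    taus = {arm: _analyze_optical(series)
            for arm, series in cohorts["optical"].items()}
    results["optical_tau"] = _compare(taus["wt"], taus["ko"],
                                      expected="ko_higher", alpha=cfg.alpha)

    # trains
    for modality, expected_ss in (("ipsc", "ko_lower"), ("iglusnfr", "ko_lower")):
        ss, ppr = {}, {}
        for arm, recs in cohorts[modality].items():
            ss[arm], ppr[arm] = _analyze_trains(recs)
        results[f"{modality}_steady_state"] = _compare(
            ss["wt"], ss["ko"], expected=expected_ss, alpha=cfg.alpha)
        results[f"{modality}_ppr"] = _compare(
            ppr["wt"], ppr["ko"], expected="none", alpha=cfg.alpha)

    results["_tables"] = {"fission": fission_tables, "amperometry": amp_sum}
    return results


def run_pipeline(cfg: RunConfig) -> dict:
    """Simulate, analyze, and write the result bundle + manifest.

    Returns the results dict.  Output files are deterministic for a given
    config (the manifest records parameters, package version and SHA-256
    digests of every written file; no timestamps).
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohorts = simulate_cohorts(cfg)
    results = analyze_cohorts(cfg, cohorts)
    tables = results.pop("_tables")

    written = []
    for arm, df in tables["fission"].items():
        p = outdir / f"fission_events_{arm}.csv"
        df.to_csv(p, index=False)
        written.append(p)
    for arm, cells in tables["amperometry"].items():
        p = outdir / f"amperometry_cells_{arm}.csv"
        amp.group_summary(cells).to_csv(p)
        written.append(p)
    p = outdir / "comparisons.json"
    sqio.write_json(p, {k: v for k, v in results.items() if k != "parameters"})
    written.append(p)

    digests = {f.name: hashlib.sha256(f.read_bytes()).hexdigest() for f in written}
    params = asdict(cfg)
    params.pop("outdir")  # location is not part of the scientific configuration
    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "parameters": params,
        "outputs": digests,
    }
    sqio.write_json(outdir / "manifest.json", manifest)
    results["manifest"] = manifest
    return results
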