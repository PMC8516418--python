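# synaptoquant

Quantitative analysis of single-vesicle endocytosis and synaptic
transmission recordings, with a synthetic-recording generator that makes
every stage verifiable by parameter recovery.

Neuroendocrine and neuronal secretion experiments produce a family of
heterogeneous signals that are usually analyzed with one-off lab scripts:
cell-attached lock-in admittance traces that resolve single endocytic
vesicles as sub-femtofarad capacitance steps, patch ionic currents that
drift when channel-bearing membrane is internalized, carbon-fiber
amperometric spikes reporting single-vesicle catecholamine release,
pHluorin/GCaMP/iGluSnFR fluorescence kinetics, and evoked-response trains
showing short-term depression.  `synaptoquant` implements the complete
analysis chain for all of these as a tested library, plus forward models
for each recording class so every estimator can be validated against known
ground truth — no animal data required.

## Core quantities

- **Fission-pore conductance** from lock-in channels: `Gp = (Re²+Im²)/Re`,
  or from the capacitance channel alone, `Gp = ωCv/√(ωCv/Im−1)`; both are
  exact inverses of the pore admittance `Y = jωCv·Gp/(Gp+jωCv)`.
  Capacitance steps are detectable above 0.2 fF; pore durations ≤ 15 ms are
  excluded from kinetics (lock-in filter distortion).
- **Whole-cell equivalent circuit**: closed-form inversion of
  `Y = Gs(Gm+jωCm)/(Gs+Gm+jωCm)` and `Gt = GsGm/(Gs+Gm)` for (Cm, Gm, Gs),
  with ΔCm, leak QC (>150 pS discarded) and Ca²⁺-influx charge.
- **Endocytosis-associated current drift**: difference of linear fits
  (20–100 ms) before/after the capacitance drop, extrapolated to the event;
  I-V assembly and a rectification index.
- **Amperometric spikes**: >10 pA, ≤100 per cell, halfwidth / decay τ /
  quantal size (`Q = ∫I dt`; `A·τ` for an exponential spike), pre-spike
  feet (<0.5 ms excluded); statistics as mean ± SEM of cell medians.
- **Optical kinetics**: ΔF/ΔFmax and ΔF/F₀ normalization, endocytic τ,
  reacidification rate from acid-quench windows, Ca-transient peak and
  decay, Fura-2 340/380 ratios, automatic iGluSnFR ROIs (>10 px), ≤2%
  photobleaching gate.
- **Train depression**: residual-subtracted per-stimulus amplitudes,
  normalization to the first response, steady state (mean of last 10 or 5),
  paired-pulse ratio.
- **Statistics**: log₁₀ transform for pore durations, two-tailed Student
  t-tests, one-way ANOVA with Student–Newman–Keuls post hoc, mean ± SEM
  summaries.

## Worked example

```python
import numpy as np
from synaptoquant import synthetic as syn, capacitance as cap

# simulate a cell-attached trace with one endocytic event: a 1 fF vesicle
# whose fission pore closes linearly from 2 nS over 40 ms
ev = syn.PoreEventSpec(t_start=1.0, direction="endocytic", cv=1e-15,
                       pore_duration=0.040,
                       gp_profile=syn.linear_closure(2e-9, 0.040))
cfg = syn.SimConfig(seed=1, duration=3.0, noise_sd=1e-12)   # 20 kHz lock-in
trace, truth = syn.simulate_fission_trace([ev], cfg)

events = cap.detect_capacitance_steps(trace, gap=0.15)
e = events[0]
dur, gp_mean, valid = cap.measure_fission_pore(trace, e)
print(f"{e.direction} step of {e.cv*1e15:.2f} fF at t={e.t_step:.3f} s")
print(f"pore duration {dur*1e3:.1f} ms, mean Gp {gp_mean*1e12:.0f} pS, "
      f"kinetics_valid={valid}")
```

prints

```
endocytic step of 0.98 fF at t=1.040 s
pore duration 40.0 ms, mean Gp 867 pS, kinetics_valid=True
```

— the detector recovers the injected 1 fF vesicle, the pore closure
duration matches the generated 40 ms, and the mean conductance reflects
the average of the linear 2 nS → 0 closure over its measurable range.

## Analysis scripts

`analysis/01_simulate_recordings.py` … `07_full_pipeline.py` run the whole
study on paired wild-type/knockout synthetic cohorts (the knockout
generators encode slower fission-pore closure, a reduced positive-voltage
current drift, slower endocytic τ, and deeper steady-state depression,
with unchanged exocytosis) and write tables under `results/`.  The full
pipeline (`07`) is deterministic: identical seeds give byte-identical
outputs, recorded in a manifest with SHA-256 digests.

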