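# Methods

`synaptoquant` quantifies single-vesicle endocytosis and synaptic
transmission from five recording classes: cell-attached lock-in admittance
(fission/fusion pores), double-patch ionic currents (endocytosis-associated
drift), carbon-fiber amperometry (single-vesicle catecholamine release),
fluorescence reporter time series (pHluorin, GCaMP, iGluSnFR, Fura-2), and
evoked-response trains (short-term depression).  Every analysis stage has a
matching forward model in `synaptoquant.synthetic`, so the package is
validated end to end by parameter recovery on synthetic recordings with
known ground truth rather than on irreproducible animal data.

Units are SI in memory (seconds, amperes, siemens, farads); tables and
reports use the field's display units (pA, pS, fF, ms).

## Fission-pore model and inversion

A vesicle of capacitance Cv connected to the pipette lumen through a pore of
conductance Gp contributes the series admittance

    Y(Gp) = jωCv·Gp / (Gp + jωCv)

at the lock-in angular frequency ω.  Before fission the vesicle membrane is
part of the patch (contribution jωCv); as the pore constricts its
contribution follows Y(Gp(t)); after closure it is zero, so a completed
endocytic event is a downward Im step of ωCv regardless of pore duration.
The two standard inversions,

    Gp = (Re² + Im²) / Re        (both channels)
    Gp = ωCv / √(ωCv/Im − 1)     (Im channel alone, 0 < Im < ωCv)

are algebraically exact inverses of Y(Gp); the suite verifies both to 1e-6
relative over Gp ∈ [10 pS, 10 nS], Cv ∈ [0.2, 10] fF.  Event-attributable
Im is referenced to the post-closure plateau (the Im-only formula requires
it); Re is referenced to the pre-event baseline.

The cell-attached carrier frequency is a free parameter (default 20 kHz,
standard for sub-femtofarad work); whole-cell analysis uses 1 kHz.

### Lock-in output filter

The output filter is modelled as four cascaded single-pole stages of 1 ms
each (the "1 ms, 24 dB/octave" hardware setting), applied causally so
simulated traces carry the same group delay as recordings.  For pore
kinetics the known filter is deconvolved exactly (the inverse of each
one-pole stage is a two-tap FIR) and the trace re-smoothed with a zero-phase
1 ms Gaussian: the causal cascade's asymmetric lag otherwise biases a 20 ms
pore duration by about +4 ms, outside the ±2 ms contract the suite enforces
for 20–100 ms pores.

### Step detection

The paper-scale threshold is 0.2 fF; the detector thresholds a two-window
mean-difference statistic at max(0.2 fF·ω, 3×noise), with the noise scale of
the statistic estimated by median absolute deviation.  The window gap is
configurable and should be set to the longest expected pore transition when
detecting gradual events.  Because every statistic position whose windows
bracket the whole transition attains the full step, the transition is
located from the endpoints of the ≥80%-of-peak plateau and the step size
re-estimated from guard-gapped plateau means (10 ms guard) — using the raw
argmax position instead makes the size estimate collapse for slow pores.

### Pore duration

Duration runs from the first sample whose Gp estimate falls to g_on = 2 nS
(pore becomes measurable) to the first later sample with Gp ≤ g_off = 10 pS
(closure); both bounds are configurable — the source analyses state no
onset/closure criterion, so these are package defaults bracketing the
measurable range.  Durations ≤ 15 ms are flagged `kinetics_valid=False`
(distorted by the output filter) and excluded from kinetic statistics; the
statistics use base-10 log-transformed durations, which are approximately
log-normal.

Known limitation: at g_on the Im deviation is only ~0.3% of ωCv — far below
any realistic noise floor — so the onset crossing cannot be estimated
unbiasedly from noisy data.  The implementation anchors the pore window at
the robust mid-amplitude crossing and searches outward, with a 2 ms median
filter on the Gp trace for crossings only.  Noiseless recovery is within
±1.5 ms over 20–100 ms; at 1–5 pS pre-filter noise, durations bias short by
roughly 2–12 ms.  Both cohort arms share this bias, so group comparisons
remain valid, but the measured KO/WT duration ratio is compressed relative
to the generator's 1.6×.

## Whole-cell equivalent circuit

The three-element circuit (series access Gs feeding parallel Gm, Cm) has
admittance Y = Gs(Gm+jωCm)/(Gs+Gm+jωCm) and DC conductance Gt =
GsGm/(Gs+Gm).  The closed-form inversion Gs = (A²+B²−A·Gt)/(A−Gt) with
Gm + jωCm = GsY/(Gs−Y) (A = Re Y, B = Im Y) is verified by round trip to
1e-9 relative over a 10×10×10 log grid.  Degenerate purely resistive input
returns Cm = 0, Gm = Gt, Gs = ∞; Re(Y) ≤ Gt otherwise is rejected as
non-physical.  Derived quantities follow the standard windows: ΔCm = mean
Cm over 40–100 ms post-depolarization minus a 50 ms pre-depolarization
baseline (the first 40 ms skipped for the gating artifact); cells with leak
> 150 pS (strict) are discarded; Ca influx charge integrates |I − baseline|
over the depolarization excluding its first 10 ms.

## Current drift and its I-V curve

Drift is the difference of straight-line fits over up to 100 ms (20 ms
minimum) of patch current before and after the capacitance drop, both
extrapolated to the event time — extrapolation, rather than differencing
window means, cancels any common baseline slope exactly.  A 10 ms guard gap
on each side keeps the 500 Hz-filtered transition out of the fits.  Sign
convention: loss of outward current at positive patch potential appears as
an upward (positive) drift, so the generator injects +g(V)·V.

The rectification index is |mean drift at the most positive voltage| /
|mean drift at the most negative voltage| (undefined for a flat curve);
linearity is the OLS r² through the mean I-V points.  "No change at
negative voltages" between cohorts is assessed with one pooled t-test on
the apparent conductance loss ΔI/V across all negative voltages, a single
α = 0.05 null test; by construction it fails in about 5% of seeds.

## Amperometry

Spikes are detected on the baseline-corrected current (first-order fit to
the 5 s pre-stimulus segment; noise by MAD) with the standard criteria:
peaks > 10 pA, at most 100 spikes per cell, feet < 0.5 ms excluded from
foot statistics.  Halfwidth uses interpolated half-max crossings; the decay
τ is a log-linear fit between 75% and 25% of peak; quantal size integrates
from the baseline departure to the first return within 1 SD.  The foot is
delimited by the 3-SD baseline departure and the maximal-slope line of the
rising phase back-extrapolated to the foot level (one of several published
onset constructions; documented here as this package's choice).  Spikes
overlapping at half-max are excluded from shape statistics but counted in
frequency.  Group statistics are mean ± SEM of per-cell medians: n is the
number of cells.

Closed-form anchors (instant-rise exponential spike, peak A, decay τ):
charge = A·τ, halfwidth = τ·ln 2, verified at 0.5% and 2% respectively.

## Optical kinetics

Bouton ROIs are fixed 4×4-pixel boxes; iGluSnFR ROIs are detected
automatically from the difference image (mean response frames minus mean
pre-stimulus frames) thresholded at mean + 3 SD, keeping connected
components larger than 10 pixels.  Normalization is ΔF/ΔFmax for pHluorin
and iGluSnFR, ΔF/F0 for GCaMP; normalization is idempotent and
cross-mode renormalization is refused.

Endocytic τ is a free-offset single-exponential fit of the post-stimulus
decay (the offset absorbs incomplete retrieval); Ca decay fixes the offset
at zero (Ca returns to rest).  Fits with vanishing amplitude or τ pinned
far beyond the observation window are flagged non-decaying.  The
reacidification rate is fit inside an acid-quench window: the generator's
two-pool model feeds retrieved reporter into a visible trapped pool that
quenches with τ_reacid, and reporter endocytosed *during* an acid window is
already surface-quenched and stays dark — which is exactly why the
in-window decay carries 1/τ_reacid alone.  The recovery studies place the
first window 5 s after the stimulus train, where the trapped pool is
largest.  Recordings whose projected baseline decline exceeds 2% (strict)
are rejected rather than bleach-corrected.

## Trains

Per-stimulus amplitudes subtract the residual of preceding activity: a
single exponential is fit (log-linear) to the final 30% of the previous
inter-stimulus interval and extrapolated under the current peak.  Because a
sum of same-τ exponentials is itself a single exponential, the extraction
is exact to machine precision on noiseless summating trains.  Peaks are
searched 1–50 ms after each stimulus for IPSCs and at frame resolution for
50 Hz iGluSnFR.  Amplitudes below 3 noise SD are recorded as failures (0)
and kept in normalization.  Steady state averages the last 10 normalized
responses (IPSC) or last 5 (iGluSnFR); PPR is a₂/a₁.  All metrics are
invariant to a positive gain.

## Synthetic study conditions (the WT/KO fixture)

The paired-cohort pipeline encodes the knockout phenotype in its
generators: fission-pore durations ×1.6 (log-normal, WT median 40 ms,
log-SD 0.25), positive-voltage drift conductance ×0.2 (WT 50 pS above 0 mV,
12.5 pS below, n = 12 per voltage as in the source I-V data), endocytic τ
×1.75 (WT 15 s, imaging SNR 10), IPSC steady state ×0.44 and iGluSnFR
steady state ×0.64 (250 and 50 stimuli at 10 Hz; 10/8 and 10/10 cells).
The KO train rate is chosen so the second response matches WT — depression
deepens later in the train while the paired-pulse ratio stays unchanged,
matching the phenomenology the steady-state effect comes from.
Amperometric release parameters are identical in both arms.  Cohort sizes
(10 cells × 3 events for fission, 40 boutons, 8 amperometry cells per arm)
are desk-scale choices that keep every encoded effect detectable at
α = 0.05 while a full two-run determinism check stays inexpensive.

What the generators do not emulate: pipette drift and seal instability,
pore flicker/reopening, camera shot noise and focus drift, network activity
in neuronal cultures, and cell-to-cell heterogeneity beyond the stated
log-normal parameter spreads.  Passing recovery tests therefore
demonstrates correctness of the estimators under the stated models, not
robustness to every pathology of real recordings.

## Numerical choices

- Noise is additive white Gaussian, injected before the lock-in filter.
- Random streams: `numpy.random.default_rng`; every cohort draws child
  seeds from the run seed, so equal seeds give bit-identical traces and
  byte-identical result files (manifests contain no timestamps and record
  SHA-256 digests of all outputs).
- Exponential fits use `scipy.optimize.curve_fit` with non-negativity
  bounds on amplitude and τ where a model requires them; residual and
  decay-τ fits on strictly positive noiseless data use exact log-linear
  least squares.
- The Student–Newman–Keuls post hoc is implemented on
  `scipy.stats.studentized_range` with the standard stepwise gating (a
  pair is tested only when every enclosing range was significant), which
  caps the familywise error at α under the complete null; critical values
  are cached, and p-value evaluation can be skipped for large null
  simulations where only decisions matter.
- Intervals are half-open [start, end); sample indexing is 0-based.

## Validation suite

`synaptoquant.validation` regenerates every check from scratch:
formula-equivalence and circuit round-trip identities, detector
soundness/recall (0 false positives across 100 event-free traces; ≥95%
recall at SNR 5), pore-duration recovery through the filter, drift I-V
discrimination (ohmic vs rectifying vs KO), amperometric closed forms,
optical τ/rate recovery, train exactness, t-test and SNK null calibration
(10,000 reps), and two-run byte-identity of the full pipeline.
`scripts/acceptance.py` writes all of these as JSON;
`tests/test_acceptance.py` asserts them at their stated tolerances.
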