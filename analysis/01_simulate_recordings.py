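"""Generate one example of every synthetic recording class with ground truth.

Writes HDF5 traces, a TIFF stack and JSON ground-truth sidecars under
results/sim/ — the file formats every later stage reads.
"""

from pathlib import Path

import numpy as np

from synaptoquant import io as sqio
from synaptoquant import synthetic as syn
from synaptoquant.core import StimProtocol

OUT = Path("results/sim")
OUT.mkdir(parents=True, exist_ok=True)
SEED = 1

# cell-attached lock-in trace with one 40 ms fission pore
ev = syn.PoreEventSpec(t_start=1.0, direction="endocytic", cv=1e-15,
                       pore_duration=0.040,
                       gp_profile=syn.linear_closure(2e-9, 0.040))
cfg = syn.SimConfig(seed=SEED, duration=3.0, noise_sd=1e-12)
trace, truth = syn.simulate_fission_trace([ev], cfg, baseline_re=1e-9, baseline_im=2e-10)
sqio.write_lockin_h5(OUT / "fission_example.h5", trace)
sqio.write_ground_truth(OUT / "fission_example.json", truth)
print(f"fission trace: 1 endocytic event, Cv=1 fF, 40 ms pore -> {OUT}/fission_example.h5")

# double-patch current with a rectifying conductance loss at +40 mV
cfg = syn.SimConfig(seed=SEED + 1, sampling_rate=5000, duration=0.8, noise_sd=0.5e-12)
itrace, itruth = syn.simulate_patch_current(
    0.040, lambda V: 50e-12 if V > 0 else 12.5e-12, t_event=0.4,
    baseline_slope=1e-12, cfg=cfg)
sqio.write_current_h5(OUT / "patch_current_example.h5", itrace)
sqio.write_ground_truth(OUT / "patch_current_example.json", itruth)
print(f"patch current: dI = {itruth.events[0]['delta_i'] * 1e12:.2f} pA at +40 mV "
      f"-> {OUT}/patch_current_example.h5")

# amperometric trace: 12 spikes, half with feet
rng = np.random.default_rng(SEED + 2)
spikes = [syn.SpikeSpec(t=float(t), peak=float(rng.uniform(20e-12, 80e-12)),
                        tau_decay=2e-3, rise_time=0.3e-3,
                        foot_amp=5e-12 if k % 2 else 0.0,
                        foot_duration=2e-3 if k % 2 else 0.0)
          for k, t in enumerate(np.sort(rng.uniform(6.0, 19.0, 12)))]
cfg = syn.SimConfig(seed=SEED + 2, duration=22.0, noise_sd=0.5e-12)
atrace, atruth = syn.simulate_amperometric_trace(spikes, cfg, stim_time=5.0)
sqio.write_amperometric_h5(OUT / "amperometry_example.h5", atrace)
sqio.write_ground_truth(OUT / "amperometry_example.json", atruth)
print(f"amperometry: {len(spikes)} spikes, {sum(1 for s in spikes if s.foot_duration)} "
      f"with feet -> {OUT}/amperometry_example.h5")

# iGluSnFR-style image stack with two responding blobs
stim = StimProtocol(n_stimuli=50, frequency=10.0, onset=8.0)
m1 = np.zeros((64, 64), bool); m1[10:14, 10:15] = True
m2 = np.zeros((64, 64), bool); m2[40:44, 40:44] = True
stack = syn.simulate_response_stack((64, 64), [(m1, 30.0), (m2, 25.0)],
                                    np.arange(0, 20, 0.5), stim,
                                    noise_sd=1.0, seed=SEED + 3)
sqio.write_stack_tiff(OUT / "iglusnfr_example.tiff", stack)
print(f"image stack: 2 responding blobs (20 and 16 px) -> {OUT}/iglusnfr_example.tiff")
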