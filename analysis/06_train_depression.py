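"""Short-term depression: IPSC and iGluSnFR train analysis, WT vs KO.

Extracts residual-subtracted amplitudes from summating trains, normalizes
to the first response, and compares steady-state depression (last 10
responses for IPSCs, last 5 for iGluSnFR) and paired-pulse ratios.
"""

from pathlib import Path

import numpy as np

from synaptoquant import io as sqio
from synaptoquant import stats as st
from synaptoquant.pipeline import RunConfig, _analyze_trains, _train_cohort

OUT = Path("results")
OUT.mkdir(exist_ok=True)
cfg = RunConfig(seed=1)

report = {}
for modality in ("ipsc", "iglusnfr"):
    ss, ppr = {}, {}
    for arm, seed in (("wt", 707), ("ko", 808)):
        recs = _train_cohort(cfg, arm, modality, seed)
        ss[arm], ppr[arm] = _analyze_trains(recs)
    t, p, _ = st.ttest_unpaired(ss["wt"], ss["ko"])
    t2, p2, _ = st.ttest_unpaired(ppr["wt"], ppr["ko"])
    reduction = 100 * (ss["wt"].mean() - ss["ko"].mean()) / ss["wt"].mean()
    report[modality] = {
        "wt_steady_state": float(ss["wt"].mean()),
        "ko_steady_state": float(ss["ko"].mean()),
        "relative_reduction_pct": float(reduction),
        "steady_state_p": p,
        "wt_ppr": float(np.mean(ppr["wt"])), "ko_ppr": float(np.mean(ppr["ko"])),
        "ppr_p": p2,
    }
    print(f"{modality}: steady state WT {ss['wt'].mean():.3f}, "
          f"KO {ss['ko'].mean():.3f} ({reduction:.0f}% reduction, p = {p:.2e}); "
          f"PPR p = {p2:.2f} (no change expected)")
sqio.write_json(OUT / "train_depression.json", report)
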