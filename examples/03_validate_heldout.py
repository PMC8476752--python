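"""Transfer a fitted pair signature to a held-out cohort.

Scoring a new cohort recomputes the pair indicators from that cohort's own
enrichment scores and re-derives the high/low cutoff there — only the pair
list travels, which is what makes the signature platform-robust.
"""

import numpy as np

import icpscore as icp

cfg = icp.SimulationConfig(seed=7)
study = icp.simulate_study(cfg)
collection = icp.signature_collection(cfg)
cohorts = [(icp.ssgsea(c.expression, collection), c.clinical) for c in study]

model = icp.fit_icp(cohorts[:3])
heldout_enr, heldout_clin = cohorts[3]

horizon = float(np.median(heldout_clin["time"]))
report = icp.validate(model, heldout_enr, heldout_clin, horizons=[horizon])

print(f"held-out cohort: n = {report['n_samples']}, "
      f"events = {report['n_events']}")
print(f"ICP score cutoff (re-derived): {report['cutoff']:g}")
print(f"group sizes: {report['group_sizes']}")
print(f"log-rank: chi2 = {report['logrank']['chi2']:.1f}, "
      f"p = {report['logrank']['p']:.2e}")
print(f"Cox high vs low: HR = {report['cox_high_vs_low']['hr']:.2f}")
print(f"C-index of the raw score: {report['c_index']:.3f}")
auc = report["auc_at_horizon"][str(horizon)]
print(f"time-dependent AUC at median follow-up ({horizon:.1f}): {auc:.3f}")
print("\np < 0.01 and HR > 1 mean the transferred signature stratifies "
      "survival in data it never saw; C-index/AUC above 0.5 quantify "
      "discrimination of the integer score itself.")
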