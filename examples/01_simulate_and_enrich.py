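"""Simulate a cohort and score immune-cell signatures with ssGSEA.

Builds one synthetic cohort (latent cell abundances -> marker-gene
expression -> survival), runs single-sample enrichment for every signature,
and shows that the enrichment rank tracks the latent abundance rank.
"""

import numpy as np
from scipy import stats

import icpscore as icp

cfg = icp.SimulationConfig(n_cohorts=1, n_samples=100, n_cells=8,
                           genes_per_signature=20, n_noise_genes=60, seed=42)
cohort = icp.simulate_cohort(cfg, 0)
collection = icp.signature_collection(cfg)

print(f"expression matrix: {cohort.expression.shape[0]} genes x "
      f"{cohort.expression.shape[1]} samples")
print(f"events observed: {cohort.clinical['event'].sum()} of {len(cohort.clinical)} "
      f"(censoring target {cfg.censoring:.0%})")

enr = icp.ssgsea(cohort.expression, collection)
print("\nssGSEA scores (first 3 cell types, first 4 samples):")
print(enr.iloc[:3, :4].round(3).to_string())

# the enrichment score is a pure rank statistic: it should order samples
# the same way the true (unobservable) cell abundance does
print("\nSpearman correlation of enrichment vs latent abundance per cell:")
for cell in cfg.cell_names[:4]:
    rho = stats.spearmanr(enr.loc[cell],
                          cohort.truth["log_abundance"].loc[cell]).statistic
    print(f"  {cell}: rho = {rho:.3f}")
print("values near 1 mean enrichment faithfully ranks the cell's abundance.")
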