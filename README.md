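# icpscore

Immune cell pair (ICP) prognostic scoring from bulk tumor transcriptomes.

## The problem

Enrichment-based estimates of tumor-infiltrating immune cells (ssGSEA scores
of marker gene sets) are informative about patient prognosis, but their
absolute values are not comparable across expression platforms, cohorts or
normalisation pipelines. `icpscore` implements a signature built entirely
from **within-sample relative rankings**: for a pair of cell types
(C<sub>i</sub>, C<sub>j</sub>) the binary indicator

Score<sub>ij</sub> = 1 if exp<sub>C<sub>i</sub></sub> − exp<sub>C<sub>j</sub></sub> > 0, else 0

depends only on which of two enrichment scores is larger *inside one
sample*, so it survives any monotone per-sample transform of expression —
log-scaling, quantile shifts, platform changes. The per-sample **ICP score**
is the count of selected pairs with indicator 1:

ICP = Σ Score<sub>ij</sub> ∈ {0, …, #pairs}

The pair list is chosen on discovery cohorts in four steps:

1. **Anchors** C<sub>i</sub>: cell types whose ssGSEA enrichment is
   associated with overall survival (univariate Cox, Wald p < 0.05) in
   *every* discovery cohort.
2. Each anchor is paired with every catalogued cell type; each indicator is
   scored by Harrell's C-index and a univariate Cox fit.
3. Per anchor, the significant pair with the highest C-index is kept; pairs
   with hazard ratio ≤ 1 are dropped.
4. Duplicates under unordered-pair identity are removed.

Validation on a new cohort recomputes indicators from that cohort's own
enrichment and re-derives the high/low cutoff with a maximally selected
log-rank statistic — only the pair list transfers. The package is aimed at
computational oncology / tumor-immunology analysts working with expression
matrices, clinical survival tables and GMT marker catalogues.

All survival machinery (Cox partial likelihood with Efron/Breslow ties,
Harrell's C, Kaplan–Meier, log-rank, maximally selected cutpoints, IPCW
time-dependent AUC) is implemented in the package and cross-checked against
independent oracles in the test suite. A synthetic-cohort generator with
known ground truth (latent cell abundances → marker expression;
proportional-hazards survival; independent censoring; per-cohort batch
shifts) makes every stage testable without any data download.

## Worked example

```python
import icpscore as icp

cfg = icp.SimulationConfig(seed=7)          # 3 discovery cohorts + 1 held-out
study = icp.simulate_study(cfg)
coll = icp.signature_collection(cfg)
cohorts = [(icp.ssgsea(c.expression, coll), c.clinical) for c in study]

model = icp.fit_icp(cohorts[:3])            # anchors + best pairs
report = icp.validate(model, cohorts[3][0], study[3].clinical)
```

Running `python examples/02_fit_pair_signature.py` prints:

```
truly prognostic cells: ['cell00', 'cell01']
anchors recovered:      ['cell00', 'cell01']

selected pairs (2):
anchor     partner     C-index      HR          p
cell00     cell04        0.605    2.12   2.04e-20
cell01     cell14        0.606    2.24   1.84e-22
```

Both simulated prognostic cell types are recovered as anchors; each keeps
one partner whose indicator has C-index ≈ 0.61 (concordance of a single
binary split) and hazard ratio ≈ 2. `examples/03_validate_heldout.py`
transfers this model to the untouched fourth cohort and prints

```
log-rank: chi2 = 40.9, p = 1.62e-10
Cox high vs low: HR = 2.59
C-index of the raw score: 0.637
```

i.e. the two-pair signature significantly stratifies survival in data it
never saw. The other examples cover enrichment/abundance concordance and
therapy-response group comparisons.

## Command line

```bash
icpscore simulate --config sim.yaml --out data/        # synthetic cohorts
icpscore fit      --config run.yaml --out fit/         # model.json
icpscore score    --config run.yaml --model fit/model.json --out scores/
icpscore validate --config run.yaml --model fit/model.json --out reports/
```

Configs are YAML (`cohorts:` expression/clinical TSV paths, `gmt:` marker
catalogue, `params:` alpha levels, minprop, ties, horizons); command-line
flags override config values. Outputs are never overwritten without
`--force`, and every report embeds package version, config hash and seed.
An illustrative marker catalogue ships in
`examples/data/illustrative_signatures.gmt`.

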