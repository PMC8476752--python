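"""Synthetic multi-cohort expression + survival data with known ground truth.

The generator emulates the statistical structure the pair pipeline assumes:
each sample carries latent immune-cell abundances A_{c,s} ~ LogNormal(0, 1);
marker genes of cell c express around ``exp(baseline + loading * log A_{c,s}
+ batch_shift_g + noise)`` so that ssGSEA enrichment tracks abundance; and
survival follows a proportional-hazards law whose linear predictor is
``sum_c beta_c * z(log A_{c,s})`` with per-cohort standardised log-abundance,
so each beta_c is a log hazard ratio per SD of abundance. Censoring is an
independent Uniform(0, c_max) time with c_max solved by bisection to hit the
configured censoring rate. Cohorts share signatures and effects but receive
independent samples and per-cohort gene-level batch shifts, mimicking a
multi-platform discovery/validation design; by convention the last cohort is
held out for validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .signatures import GeneSet, SignatureCollection

__all__ = [
    "SimulationConfig",
    "SyntheticCohort",
    "signature_collection",
    "simulate_cohort",
    "simulate_study",
    "simulate_response_labels",
]


@dataclass
class SimulationConfig:
    """Study design for the synthetic generator.

    Defaults describe the reference recovery design: 3 discovery cohorts
    plus one held-out cohort of 300 samples each, a catalogue of 20 cell
    types with 30 marker genes per signature, two truly prognostic cells
    with a log hazard ratio of 1.0 per SD of log-abundance, moderate
    expression noise and ~30% independent censoring.
    """

    n_cohorts: int = 4
    n_samples: int = 300
    n_cells: int = 20
    genes_per_signature: int = 30
    n_noise_genes: int = 100
    prognostic_cells: dict[str, float] | None = None  # cell -> beta (log-HR/SD)
    n_prognostic: int = 2
    beta: float = 1.0
    signature_loading: float = 1.0
    baseline_log_expression: float = 3.0
    noise_sd: float = 0.5
    baseline_hazard: float = 0.1
    censoring: float = 0.3
    batch_shift_sd: float = 0.3
    weibull_shape: float = 1.0  # 1.0 = exponential baseline
    signature_overlap: float = 0.0  # fraction of markers shared with previous cell
    response_model: dict | None = None  # {"eta0": float, "gamma": {cell: g} | None}
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_cohorts", "n_samples", "n_cells", "genes_per_signature"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0 (constant expression is degenerate)")
        if not (0 <= self.censoring < 1):
            raise ValueError("censoring rate must be in [0, 1)")
        if not (0 <= self.signature_overlap < 1):
            raise ValueError("signature_overlap must be in [0, 1)")
        if self.prognostic_cells is None:
            cells = self.cell_names
            self.prognostic_cells = {
                cells[i]: self.beta for i in range(min(self.n_prognostic, self.n_cells))
            }
        unknown = set(self.prognostic_cells) - set(self.cell_names)
        if unknown:
            raise ValueError(f"prognostic_cells not in catalogue: {sorted(unknown)}")

    @property
    def cell_names(self) -> list[str]:
        return [f"cell{i:02d}" for i in range(self.n_cells)]


@dataclass
class SyntheticCohort:
    """One simulated cohort plus its generating truth."""

    cohort_index: int
    expression: pd.DataFrame  # genes x samples, TPM-like positive values
    clinical: pd.DataFrame  # sample-indexed: time, event
    truth: dict = field(default_factory=dict)


def signature_collection(config: SimulationConfig) -> SignatureCollection:
    """The marker-gene catalogue implied by a configuration (deterministic)."""
    sets = []
    prev: list[str] = []
    n_shared = int(config.signature_overlap * config.genes_per_signature)
    for c, cell in enumerate(config.cell_names):
        own = [f"{cell}_g{j:02d}" for j in range(config.genes_per_signature)]
        genes = list(own)
        if c > 0 and n_shared > 0:
            genes = prev[:n_shared] + own[: config.genes_per_signature - n_shared]
        sets.append(GeneSet(cell, frozenset(genes), ["synthetic"]))
        prev = own
    return SignatureCollection(sets)


def _solve_cmax(t: np.ndarray, u: np.ndarray, target: float) -> float:
    """Bisect c_max so that the realised censoring fraction hits ``target``.

    With C_i = u_i * c_max the number of censored subjects is monotone
    non-increasing in c_max, so bisection converges to within 1/n of the
    target rate.
    """
    lo, hi = 1e-9, float(t.max()) / max(u.min(), 1e-9) + 1.0
    for _ in range(200):
        mid = (lo + hi) / 2
        rate = float((u * mid < t).mean())
        if rate > target:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


def simulate_cohort(config: SimulationConfig, cohort_index: int = 0) -> SyntheticCohort:
    """Generate one cohort; deterministic given (config.seed, cohort_index)."""
    rng = np.random.default_rng([config.seed, cohort_index])
    n_s, n_c = config.n_samples, config.n_cells
    cells = config.cell_names
    coll = signature_collection(config)
    sig_genes: list[str] = []
    for s in coll:
        for g in sorted(s.genes):
            if g not in sig_genes:
                sig_genes.append(g)
    noise_genes = [f"noise_{j:03d}" for j in range(config.n_noise_genes)]
    genes = sig_genes + noise_genes
    samples = [f"coh{cohort_index}_s{j:03d}" for j in range(n_s)]

    log_a = rng.standard_normal((n_c, n_s))  # log abundances, LogNormal(0,1)
    shift = rng.normal(0.0, config.batch_shift_sd, size=len(genes))
    eps = rng.normal(0.0, config.noise_sd, size=(len(genes), n_s))

    membership = coll.membership()
    log_expr = np.full((len(genes), n_s), config.baseline_log_expression)
    gene_pos = {g: i for i, g in enumerate(genes)}
    for c, cell in enumerate(cells):
        rows = [gene_pos[g] for g in sorted(membership[cell])]
        log_expr[rows] += config.signature_loading * log_a[c]
    log_expr += shift[:, None] + eps
    expression = pd.DataFrame(np.exp(log_expr),
                              index=pd.Index(genes, name="gene"), columns=samples)

    # proportional-hazards survival from standardised log-abundance
    z = (log_a - log_a.mean(axis=1, keepdims=True)) / log_a.std(axis=1, keepdims=True)
    linpred = np.zeros(n_s)
    for c, cell in enumerate(cells):
        b = config.prognostic_cells.get(cell, 0.0)
        if b:
            linpred += b * z[c]
    rate = config.baseline_hazard * np.exp(linpred)
    e_std = rng.exponential(1.0, size=n_s)
    if config.weibull_shape == 1.0:
        t_true = e_std / rate
    else:
        t_true = (e_std / rate) ** (1.0 / config.weibull_shape)

    if config.censoring > 0:
        u = rng.random(n_s)
        u = np.clip(u, 1e-9, None)
        cmax = _solve_cmax(t_true, u, config.censoring)
        c_time = u * cmax
        time = np.minimum(t_true, c_time)
        event = (t_true <= c_time).astype(int)  # deaths precede censoring at ties
    else:
        time = t_true
        event = np.ones(n_s, dtype=int)
    clinical = pd.DataFrame({"time": time, "event": event},
                            index=pd.Index(samples, name="sample"))

    truth = {
        "log_abundance": pd.DataFrame(log_a, index=cells, columns=samples),
        "beta": dict(config.prognostic_cells),
        "linpred": pd.Series(linpred, index=samples, name="linpred"),
        "time_true": pd.Series(t_true, index=samples, name="time_true"),
    }
    cohort = SyntheticCohort(cohort_index, expression, clinical, truth)
    if config.response_model is not None:
        cohort.truth["response_prob"] = _response_prob(cohort, config)
    return cohort


def _response_prob(cohort: SyntheticCohort, config: SimulationConfig) -> pd.Series:
    rm = config.response_model or {}
    eta0 = float(rm.get("eta0", 0.0))
    gamma = rm.get("gamma") or dict(config.prognostic_cells)
    log_a = cohort.truth["log_abundance"]
    z = log_a.sub(log_a.mean(axis=1), axis=0).div(log_a.std(axis=1), axis=0)
    eta = pd.Series(eta0, index=log_a.columns, dtype=float)
    for cell, g in gamma.items():
        eta -= float(g) * z.loc[cell]  # high-hazard profiles respond less
    return (1.0 / (1.0 + np.exp(-eta))).rename("response_prob")


def simulate_study(config: SimulationConfig) -> list[SyntheticCohort]:
    """All cohorts of a study; the last one is conventionally held out."""
    return [simulate_cohort(config, i) for i in range(config.n_cohorts)]


def simulate_response_labels(cohort: SyntheticCohort,
                             config: SimulationConfig) -> pd.Series:
    """Draw binary responder labels from the configured logistic model."""
    if config.response_model is None:
        raise ValueError("config.response_model is not set")
    prob = cohort.truth.get("response_prob")
    if prob is None:
        prob = _response_prob(cohort, config)
    rng = np.random.default_rng([config.seed, cohort.cohort_index, 7919])
    labels = (rng.random(len(prob)) < prob.to_numpy()).astype(int)
    return pd.Series(labels, index=prob.index, name="response")
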