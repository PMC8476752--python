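"""The immune-cell-pair (ICP) prognostic signature.

The signature is built from within-sample *relative rankings* of immune-cell
enrichment scores, which makes it transferable across expression platforms
without normalisation:

1. Cells whose enrichment is associated with overall survival (univariate
   Cox, Wald p < alpha) in *every* discovery cohort become anchors Ci.
2. Each anchor is paired with every other catalogued cell Cj; the binary
   indicator Score_ij is 1 when the sample's enrichment for Ci exceeds that
   for Cj, else 0.
3. Each indicator is scored by Harrell's C-index against survival and by a
   univariate Cox fit; per anchor the pair with the highest C-index among
   the significant ones is kept, pairs with hazard ratio <= 1 are discarded,
   and duplicates under unordered-pair identity are removed.
4. A sample's ICP score is the number of selected pairs whose indicator is 1;
   cohorts are dichotomised at the maximally selected log-rank cutpoint into
   high- and low-score groups.

Transfer to a new cohort recomputes the indicators from that cohort's own
enrichment scores and re-derives the cutoff there; only the pair list
travels.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import survival as ss
from .signatures import SignatureCollection
from .enrichment import ssgsea

logger = logging.getLogger(__name__)

SCHEMA_VERSION = "1.0"

__all__ = [
    "PairKey",
    "PairStats",
    "PairScoreMatrix",
    "ICPModel",
    "ICPResult",
    "select_prognostic_cells",
    "pair_indicator_matrix",
    "evaluate_pairs",
    "select_pairs",
    "score_samples",
    "dichotomize",
    "fit_icp",
    "validate",
]


@dataclass(frozen=True)
class PairKey:
    """An ordered cell pair: prognostic anchor ``ci`` and partner ``cj``."""

    ci: str
    cj: str

    def __post_init__(self) -> None:
        if self.ci == self.cj:
            raise ValueError("self-pairs (ci == cj) are excluded")

    @property
    def unordered(self) -> frozenset[str]:
        return frozenset((self.ci, self.cj))


@dataclass
class PairStats:
    """Fitted statistics of one pair indicator against survival."""

    pair: PairKey
    c_index: float
    hr: float
    p: float


@dataclass
class PairScoreMatrix:
    """Binary pair indicators: rows = ordered pairs, columns = samples."""

    indicator: pd.DataFrame  # MultiIndex (ci, cj) x samples, values in {0,1}

    @property
    def pair_keys(self) -> list[PairKey]:
        return [PairKey(ci, cj) for ci, cj in self.indicator.index]

    @property
    def sample_ids(self) -> list[str]:
        return [str(c) for c in self.indicator.columns]


@dataclass
class ICPModel:
    """The transferable signature: an ordered list of selected cell pairs.

    Invariants (enforced at construction): no duplicate unordered pairs,
    every hazard ratio > 1, every p below the selection alpha.
    """

    selected_pairs: list[PairStats]
    parameters: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)
    schema_version: str = SCHEMA_VERSION

    def __post_init__(self) -> None:
        seen: set[frozenset[str]] = set()
        alpha = self.parameters.get("alpha_pairs", 0.05)
        for ps in self.selected_pairs:
            if ps.pair.unordered in seen:
                raise ValueError(f"duplicate unordered pair {set(ps.pair.unordered)}")
            seen.add(ps.pair.unordered)
            if ps.hr <= 1:
                raise ValueError(f"pair {ps.pair} violates HR > 1 (hr={ps.hr})")
            if ps.p >= alpha:
                raise ValueError(f"pair {ps.pair} violates p < {alpha} (p={ps.p})")

    @property
    def anchors(self) -> list[str]:
        out: list[str] = []
        for ps in self.selected_pairs:
            if ps.pair.ci not in out:
                out.append(ps.pair.ci)
        return out

    @property
    def cell_types(self) -> list[str]:
        out: list[str] = []
        for ps in self.selected_pairs:
            for c in (ps.pair.ci, ps.pair.cj):
                if c not in out:
                    out.append(c)
        return out

    def __len__(self) -> int:
        return len(self.selected_pairs)

    def to_dict(self) -> dict:
        return {
            "schema_version": self.schema_version,
            "parameters": self.parameters,
            "selected_pairs": [
                {"ci": ps.pair.ci, "cj": ps.pair.cj, "c_index": ps.c_index,
                 "hr": ps.hr, "p": ps.p}
                for ps in self.selected_pairs
            ],
            "provenance": self.provenance,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ICPModel":
        if d.get("schema_version") != SCHEMA_VERSION:
            raise ValueError(
                f"unsupported model schema_version {d.get('schema_version')!r}"
            )
        pairs = [
            PairStats(PairKey(e["ci"], e["cj"]), float(e["c_index"]),
                      float(e["hr"]), float(e["p"]))
            for e in d["selected_pairs"]
        ]
        return cls(pairs, dict(d.get("parameters", {})),
                   dict(d.get("provenance", {})))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True)
                              + "\n", encoding="utf-8")

    @classmethod
    def from_json(cls, path: str | Path) -> "ICPModel":
        return cls.from_dict(json.loads(Path(path).read_text(encoding="utf-8")))


@dataclass
class ICPResult:
    """Per-sample ICP scores with the cohort's cutoff and group labels."""

    scores: pd.Series  # integer per sample
    cutoff: float
    group: pd.Series  # "high" iff score > cutoff else "low"


def _align(enr: pd.DataFrame, clinical: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Intersect enrichment samples with clinical samples, enrichment order."""
    common = [s for s in enr.columns if s in clinical.index]
    if len(common) < 2:
        raise ValueError("fewer than 2 samples shared between enrichment and clinical table")
    if len(common) < enr.shape[1]:
        logger.info("aligning cohorts: %d of %d samples have clinical data",
                    len(common), enr.shape[1])
    return enr[common], clinical.loc[common]


def select_prognostic_cells(
    cohorts: Sequence[tuple[pd.DataFrame, pd.DataFrame]],
    alpha: float = 0.05,
    ties: str = "efron",
) -> list[str]:
    """Cells whose enrichment predicts OS (Wald p < alpha) in every cohort.

    Each cohort is a (cell_types x samples enrichment matrix, clinical
    table) pair. A univariate Cox model is fitted per cell per cohort; the
    intersection of significant cells across cohorts is returned in the
    first cohort's catalogue order. Cells with constant enrichment or a
    non-converged fit in some cohort are treated as not significant there.
    """
    if not cohorts:
        raise ValueError("need at least one cohort")
    catalogue = list(cohorts[0][0].index)
    shared = [c for c in catalogue
              if all(c in enr.index for enr, _ in cohorts)]
    if not shared:
        raise ValueError("cohorts share no cell types")
    aligned = [_align(enr, clinical) for enr, clinical in cohorts]
    selected = []
    for cell in shared:
        ok = True
        for enr_a, clin_a in aligned:
            try:
                fit = ss.cox_fit(enr_a.loc[cell].to_numpy(), clin_a, ties=ties)
            except ValueError:
                ok = False
                break
            if not fit.converged or not (fit.wald_p[0] < alpha):
                ok = False
                break
        if ok:
            selected.append(cell)
    if not selected:
        raise ValueError(
            f"no cell type significant at alpha={alpha} in all {len(cohorts)} "
            "cohorts; consider a larger alpha or fewer discovery cohorts"
        )
    return selected


def pair_indicator_matrix(
    enr: pd.DataFrame,
    anchors: Sequence[str],
    partners: Sequence[str] | None = None,
) -> PairScoreMatrix:
    """Binary indicators Score_ij = 1 iff enrichment(Ci) > enrichment(Cj).

    One row per ordered pair (Ci, Cj) with Ci an anchor and Cj any other
    catalogued cell; ties count as 0 so that Score_ij + Score_ji <= 1 always
    and equals 1 exactly when the two enrichments differ.
    """
    partners = list(partners) if partners is not None else list(enr.index)
    missing = [c for c in list(anchors) + partners if c not in enr.index]
    if missing:
        raise ValueError(f"cell type(s) absent from enrichment matrix: {sorted(set(missing))}")
    rows = []
    keys = []
    values = enr.to_numpy(dtype=float)
    pos = {c: i for i, c in enumerate(enr.index)}
    for ci in anchors:
        for cj in partners:
            if ci == cj:
                continue
            keys.append((ci, cj))
            rows.append((values[pos[ci]] - values[pos[cj]] > 0).astype(np.int8))
    if not keys:
        raise ValueError("no pairs to construct (anchors empty or equal to partners)")
    idx = pd.MultiIndex.from_tuples(keys, names=["ci", "cj"])
    return PairScoreMatrix(pd.DataFrame(np.vstack(rows), index=idx, columns=enr.columns))


def evaluate_pairs(
    psm: PairScoreMatrix,
    clinical: pd.DataFrame,
    ties: str = "efron",
) -> list[PairStats]:
    """C-index and univariate Cox statistics for every pair indicator.

    Rows whose indicator is constant across samples carry no ranking
    information and are excluded (logged), as are rows whose Cox fit does
    not converge (monotone likelihood).
    """
    enr_ind, clin = _align(psm.indicator, clinical)
    out: list[PairStats] = []
    n_degenerate = 0
    for (ci, cj), row in enr_ind.iterrows():
        x = row.to_numpy(dtype=float)
        if np.ptp(x) == 0:
            n_degenerate += 1
            logger.info("pair (%s, %s): constant indicator, excluded", ci, cj)
            continue
        fit = ss.cox_fit(x, clin, ties=ties)
        if not fit.converged:
            n_degenerate += 1
            logger.info("pair (%s, %s): Cox fit did not converge, excluded", ci, cj)
            continue
        c = ss.harrell_c(x, clin)
        out.append(PairStats(PairKey(ci, cj), c_index=c,
                             hr=float(fit.hr[0]), p=float(fit.wald_p[0])))
    if not out:
        raise ValueError(
            f"all {n_degenerate} pair indicators degenerate (constant or non-converged)"
        )
    return out


def select_pairs(
    stats: Sequence[PairStats],
    alpha: float = 0.05,
    anchor_order: Sequence[str] | None = None,
    dedupe: str = "unordered",
    psm: PairScoreMatrix | None = None,
    parameters: dict | None = None,
    provenance: dict | None = None,
) -> ICPModel:
    """Reduce pair statistics to the final signature.

    Steps, in order: (1) keep pairs with p < alpha; (2) per anchor keep the
    single pair with the highest C-index (ties broken toward larger hazard
    ratio, then lexicographically smaller partner); (3) drop pairs with
    hazard ratio <= 1; (4) remove duplicates — by default under unordered
    pair identity {Ci, Cj}, keeping the first in anchor order; with
    ``dedupe="indicator"`` (requires ``psm``) pairs whose indicator row
    duplicates an earlier retained row are dropped instead. The result is
    ordered by ``anchor_order`` (first-appearance order if not given).
    """
    if not stats:
        raise ValueError("no pair statistics supplied")
    counts = {"input": len(stats)}

    sig = [ps for ps in stats if ps.p < alpha]
    counts["after_p_filter"] = len(sig)

    if anchor_order is None:
        anchor_order = []
        for ps in stats:
            if ps.pair.ci not in anchor_order:
                anchor_order.append(ps.pair.ci)
    best: list[PairStats] = []
    for ci in anchor_order:
        mine = [ps for ps in sig if ps.pair.ci == ci]
        if not mine:
            continue
        mine.sort(key=lambda ps: (-ps.c_index, -ps.hr, ps.pair.cj))
        best.append(mine[0])
    counts["after_best_per_anchor"] = len(best)

    hazardous = [ps for ps in best if ps.hr > 1]
    counts["after_hr_filter"] = len(hazardous)

    kept: list[PairStats] = []
    if dedupe == "unordered":
        seen: set[frozenset[str]] = set()
        for ps in hazardous:
            if ps.pair.unordered in seen:
                continue
            seen.add(ps.pair.unordered)
            kept.append(ps)
    elif dedupe == "indicator":
        if psm is None:
            raise ValueError("dedupe='indicator' requires the pair score matrix")
        seen_rows: set[bytes] = set()
        for ps in hazardous:
            row = psm.indicator.loc[(ps.pair.ci, ps.pair.cj)].to_numpy(np.int8).tobytes()
            if row in seen_rows:
                continue
            seen_rows.add(row)
            kept.append(ps)
    elif dedupe == "none":
        kept = hazardous
    else:
        raise ValueError(f"unknown dedupe mode {dedupe!r}")
    counts["after_dedupe"] = len(kept)

    if not kept:
        raise ValueError(
            "no pair survived selection; eliminated per step: "
            + ", ".join(f"{k}={v}" for k, v in counts.items())
        )
    params = {"alpha_pairs": alpha, "dedupe": dedupe}
    if parameters:
        params.update(parameters)
    prov = dict(provenance or {})
    prov["selection_counts"] = counts
    return ICPModel(kept, parameters=params, provenance=prov)


def score_samples(
    model: ICPModel,
    enr: pd.DataFrame,
    permissive: bool = False,
) -> pd.Series:
    """ICP score per sample: the count of selected pairs with Score_ij = 1.

    Indicators are recomputed from ``enr`` (the target cohort's own
    enrichment scores), so only the pair list transfers between cohorts.
    An empty model raises unless ``permissive``, in which case all scores
    are 0.
    """
    if len(model) == 0:
        if permissive:
            return pd.Series(0, index=enr.columns, name="icp_score", dtype=int)
        raise ValueError("model has no selected pairs")
    missing = [c for c in model.cell_types if c not in enr.index]
    if missing:
        raise ValueError(f"cell type(s) absent from enrichment matrix: {missing}")
    total = np.zeros(enr.shape[1], dtype=int)
    for ps in model.selected_pairs:
        total += (
            enr.loc[ps.pair.ci].to_numpy(dtype=float)
            > enr.loc[ps.pair.cj].to_numpy(dtype=float)
        ).astype(int)
    return pd.Series(total, index=enr.columns, name="icp_score")


def dichotomize(
    scores: pd.Series,
    clinical: pd.DataFrame,
    minprop: float = 0.1,
) -> ICPResult:
    """Split a cohort at the maximally selected log-rank cutpoint.

    Samples with score strictly above the cutoff form the high group.
    """
    common = [s for s in scores.index if s in clinical.index]
    s = scores.loc[common]
    cut = ss.max_sel_cutpoint(s.to_numpy(dtype=float), clinical.loc[common],
                              minprop=minprop)
    group = pd.Series(np.where(s.to_numpy(dtype=float) > cut.cutoff, "high", "low"),
                      index=s.index, name="group")
    return ICPResult(scores=s, cutoff=cut.cutoff, group=group)


def fit_icp(
    discovery: Sequence[tuple[pd.DataFrame, pd.DataFrame]],
    alpha_cells: float = 0.05,
    alpha_pairs: float = 0.05,
    eval_cohort: int | None = None,
    ties: str = "efron",
    dedupe: str = "unordered",
) -> ICPModel:
    """Fit the full pair signature on one or more discovery cohorts.

    Anchors are cells significant in every discovery cohort; pair indicators
    are evaluated either on the pooled discovery samples (default) or, with
    ``eval_cohort=i``, on the i-th cohort alone. Raises with the failing
    step named when any stage eliminates everything.
    """
    if not discovery:
        raise ValueError("need at least one discovery cohort")
    try:
        anchors = select_prognostic_cells(discovery, alpha=alpha_cells, ties=ties)
    except ValueError as exc:
        raise ValueError(f"cell selection: {exc}") from exc

    catalogue = list(discovery[0][0].index)
    if eval_cohort is None:
        aligned = [_align(enr, clin) for enr, clin in discovery]
        enr_eval = pd.concat([enr.loc[catalogue] for enr, _ in aligned], axis=1)
        clin_eval = pd.concat([clin for _, clin in aligned], axis=0)
        if enr_eval.columns.has_duplicates:
            raise ValueError(
                "pooled discovery cohorts share sample IDs; "
                "disambiguate them or set eval_cohort"
            )
        eval_label = "pooled"
    else:
        enr_eval, clin_eval = discovery[eval_cohort]
        eval_label = f"cohort_{eval_cohort}"

    try:
        psm = pair_indicator_matrix(enr_eval, anchors, catalogue)
        stats = evaluate_pairs(psm, clin_eval, ties=ties)
        model = select_pairs(
            stats, alpha=alpha_pairs, anchor_order=anchors, dedupe=dedupe, psm=psm,
            parameters={"alpha_cells": alpha_cells, "ties": ties},
            provenance={
                "n_discovery_cohorts": len(discovery),
                "cohort_sizes": [int(enr.shape[1]) for enr, _ in discovery],
                "n_anchors": len(anchors),
                "anchors": anchors,
                "pair_evaluation": eval_label,
            },
        )
    except ValueError as exc:
        raise ValueError(f"pair selection: {exc}") from exc
    return model


def validate(
    model: ICPModel,
    enr_or_expr: pd.DataFrame,
    clinical: pd.DataFrame,
    horizons: Sequence[float] = (),
    minprop: float = 0.1,
    collection: SignatureCollection | None = None,
    ssgsea_alpha: float = 0.25,
    ties: str = "efron",
) -> dict:
    """Apply a fitted signature to a cohort and report its performance.

    Pass an enrichment matrix directly, or an expression matrix together
    with ``collection`` to run ssGSEA first. The report contains per-sample
    scores and groups, the re-derived cutoff, Kaplan-Meier curves per group,
    the log-rank test, the high-vs-low Cox hazard ratio, the concordance of
    the raw score, time-dependent AUCs at the requested horizons, and
    associations with any extra clinical columns (Pearson for numeric,
    rank tests + ROC AUC for binary, Kruskal-Wallis for categorical).
    """
    enr = ssgsea(enr_or_expr, collection, alpha=ssgsea_alpha) \
        if collection is not None else enr_or_expr
    scores = score_samples(model, enr)
    common = [s for s in scores.index if s in clinical.index]
    scores = scores.loc[common]
    clin = clinical.loc[common]
    result = dichotomize(scores, clin, minprop=minprop)
    high = (result.group == "high").to_numpy()

    chi2, p = ss.logrank(high, clin)
    cox_hl = ss.cox_fit(high.astype(float), clin, ties=ties)
    report: dict = {
        "n_samples": len(common),
        "n_events": int(clin["event"].sum()),
        "n_pairs": len(model),
        "cutoff": result.cutoff,
        "group_sizes": {"high": int(high.sum()), "low": int((~high).sum())},
        "logrank": {"chi2": chi2, "p": p},
        "cox_high_vs_low": {"hr": float(cox_hl.hr[0]), "p": float(cox_hl.wald_p[0]),
                            "converged": cox_hl.converged},
        "c_index": ss.harrell_c(scores.to_numpy(dtype=float), clin),
        "samples": {
            "sample": list(scores.index),
            "icp_score": [int(v) for v in scores],
            "group": list(result.group),
        },
    }
    km = {}
    for label, mask in (("high", high), ("low", ~high)):
        sub = clin.loc[mask]
        if sub["event"].sum() > 0:
            curve = ss.km_curve(sub)
            km[label] = {"event_times": curve.event_times.tolist(),
                         "survival": curve.survival.tolist(),
                         "at_risk": curve.at_risk.tolist()}
    report["km"] = km
    aucs = {}
    for h in horizons:
        try:
            aucs[str(h)] = ss.auc_at_horizon(scores.to_numpy(dtype=float), clin, h)
        except ValueError as exc:
            aucs[str(h)] = {"error": str(exc)}
    report["auc_at_horizon"] = aucs

    annotations = {}
    for col in clin.columns:
        if col in ("time", "event"):
            continue
        ann = clin[col]
        entry: dict = {}
        try:
            if pd.api.types.is_numeric_dtype(ann):
                vals = ann.to_numpy(dtype=float)
                if np.isin(vals[~np.isnan(vals)], (0, 1)).all():
                    entry["roc_auc"] = ss.roc_auc(scores.to_numpy(dtype=float),
                                                  vals.astype(int))
                    entry["wilcoxon_p"] = ss.group_compare(
                        scores.to_numpy(dtype=float), vals.astype(int), "wilcoxon")
                else:
                    r, pr = ss.correlate(scores.to_numpy(dtype=float), vals)
                    entry["pearson_r"], entry["pearson_p"] = r, pr
            else:
                levels = ann.astype(str)
                test = "wilcoxon" if levels.nunique() == 2 else "kruskal"
                entry[f"{test}_p"] = ss.group_compare(
                    scores.to_numpy(dtype=float), levels.to_numpy(), test)
        except ValueError as exc:
            entry["error"] = str(exc)
        annotations[col] = entry
    report["annotations"] = annotations
    return report
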