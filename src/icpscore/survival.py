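"""Survival and association statistics for prognostic-signature work.

Self-contained implementations of the estimators the cell-pair pipeline
depends on, with every convention pinned down so results are deterministic:

* Cox proportional-hazards regression by Newton-Raphson on the partial
  likelihood, with Efron (default) or Breslow handling of tied event times;
* Harrell's concordance index over comparable pairs;
* the two-group log-rank test with hypergeometric variance;
* the Kaplan-Meier product-limit estimator;
* the maximally selected log-rank cutpoint (survminer-style dichotomisation);
* ROC AUC (Mann-Whitney with half-credit ties) and cumulative/dynamic
  time-dependent AUC with inverse-probability-of-censoring weights;
* Pearson correlation and Wilcoxon / Kruskal-Wallis group comparisons
  (delegated to scipy.stats).

Clinical tables are plain DataFrames indexed by sample ID with columns
``time`` (overall survival, positive, cohort-local units) and ``event``
(1 = death observed, 0 = right-censored); further columns are treated as
per-sample annotations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "CoxFit",
    "KMCurve",
    "CutpointResult",
    "validate_clinical",
    "read_clinical",
    "write_clinical",
    "cox_fit",
    "harrell_c",
    "logrank",
    "km_curve",
    "max_sel_cutpoint",
    "roc_auc",
    "auc_at_horizon",
    "correlate",
    "group_compare",
]


# ---------------------------------------------------------------------------
# clinical table plumbing

def validate_clinical(clinical: pd.DataFrame) -> pd.DataFrame:
    """Check a clinical table: unique samples, positive finite times, 0/1 events."""
    for col in ("time", "event"):
        if col not in clinical.columns:
            raise ValueError(f"clinical table lacks required column {col!r}")
    if clinical.index.has_duplicates:
        raise ValueError("duplicate sample IDs in clinical table")
    t = clinical["time"].to_numpy(dtype=float)
    if not np.isfinite(t).all() or (t <= 0).any():
        raise ValueError("survival times must be positive and finite")
    e = clinical["event"].to_numpy()
    if not np.isin(e, (0, 1)).all():
        raise ValueError("event indicator must be 0 (censored) or 1 (death)")
    return clinical


def read_clinical(path: str | Path) -> pd.DataFrame:
    """Read a tab-delimited clinical table with columns sample, time, event."""
    df = pd.read_csv(path, sep="\t")
    if "sample" not in df.columns:
        raise ValueError("clinical table needs a 'sample' column")
    df = df.set_index("sample")
    df.index = df.index.astype(str)
    return validate_clinical(df)


def write_clinical(clinical: pd.DataFrame, path: str | Path) -> None:
    clinical.to_csv(path, sep="\t", index_label="sample")


def _time_event(clinical: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    validate_clinical(clinical)
    return (clinical["time"].to_numpy(dtype=float),
            clinical["event"].to_numpy(dtype=int))


# ---------------------------------------------------------------------------
# Cox proportional hazards

@dataclass
class CoxFit:
    """Result of a Cox proportional-hazards fit.

    ``hr = exp(beta)`` elementwise; ``wald_p`` are two-sided Wald p-values
    from the observed information. ``converged`` is False when the partial
    likelihood is monotone (e.g. perfect separation) — the fit is returned
    flagged, never silently.
    """

    beta: np.ndarray
    hr: np.ndarray
    se: np.ndarray
    wald_p: np.ndarray
    loglik: float
    n_events: int
    converged: bool
    names: list[str] = field(default_factory=list)

    def summary(self) -> pd.DataFrame:
        names = self.names or [f"x{i}" for i in range(len(self.beta))]
        return pd.DataFrame(
            {"beta": self.beta, "hr": self.hr, "se": self.se, "p": self.wald_p},
            index=names,
        )


def _cox_ll_grad_hess(beta: np.ndarray, X: np.ndarray, t: np.ndarray,
                      e: np.ndarray, ties: str):
    """Partial log-likelihood, gradient and (negative) Hessian.

    Arrays must be sorted by ascending time. Risk set at an event time t_k is
    {j : t_j >= t_k} (deaths precede censorings at ties).
    """
    if ties not in ("breslow", "efron"):
        raise ValueError(f"unknown ties method {ties!r}")
    n, p = X.shape
    eta = np.clip(X @ beta, -500, 500)
    w = np.exp(eta)
    wx = w[:, None] * X
    wxx = wx[:, :, None] * X[:, None, :]
    # suffix sums: S*[i] = sum over j >= i (risk set at t[i])
    s0 = np.cumsum(w[::-1])[::-1]
    s1 = np.cumsum(wx[::-1], axis=0)[::-1]
    s2 = np.cumsum(wxx[::-1], axis=0)[::-1]

    death = e == 1
    td = t[death]
    ut, first = np.unique(td, return_index=True)
    counts = np.diff(np.append(first, len(td)))
    i0 = np.searchsorted(t, ut, side="left")
    r0, r1, r2 = s0[i0], s1[i0], s2[i0]

    ll = eta[death].sum()
    grad = X[death].sum(axis=0)
    if ties == "breslow":
        ll -= (counts * np.log(r0)).sum()
        grad -= ((counts / r0)[:, None] * r1).sum(axis=0)
        info = ((counts / r0)[:, None, None] * r2).sum(axis=0) \
            - np.einsum("k,ki,kj->ij", counts / r0**2, r1, r1)
    else:  # efron: one row per (event-time group, death rank l)
        d0 = np.add.reduceat(w[death], first)
        d1 = np.add.reduceat(wx[death], first, axis=0)
        d2 = np.add.reduceat(wxx[death], first, axis=0)
        grp = np.repeat(np.arange(len(ut)), counts)
        frac = (np.arange(len(td)) - np.repeat(first, counts)) \
            / np.repeat(counts, counts)
        a0 = r0[grp] - frac * d0[grp]
        a1 = r1[grp] - frac[:, None] * d1[grp]
        a2 = r2[grp] - frac[:, None, None] * d2[grp]
        ll -= np.log(a0).sum()
        grad -= (a1 / a0[:, None]).sum(axis=0)
        info = (a2 / a0[:, None, None]).sum(axis=0) \
            - np.einsum("r,ri,rj->ij", 1 / a0**2, a1, a1)
    return ll, grad, info


def cox_fit(covariates, clinical: pd.DataFrame, ties: str = "efron",
            max_iter: int = 60) -> CoxFit:
    """Fit a Cox model by Newton-Raphson on the partial likelihood.

    Parameters
    ----------
    covariates:
        samples x p array or DataFrame aligned to ``clinical`` rows.
    clinical:
        table with ``time`` and ``event`` columns.
    ties:
        ``"efron"`` (default; better with heavily tied event times, as with
        integer pair scores) or ``"breslow"``.

    Convergence: max |gradient| < 1e-9 or log-likelihood change < 1e-12.
    A monotone likelihood (perfect separation) yields ``converged=False``.
    """
    names: list[str] = []
    if isinstance(covariates, pd.DataFrame):
        names = [str(c) for c in covariates.columns]
        X = covariates.to_numpy(dtype=float)
    elif isinstance(covariates, pd.Series):
        names = [str(covariates.name or "x0")]
        X = covariates.to_numpy(dtype=float)[:, None]
    else:
        X = np.asarray(covariates, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
    t, e = _time_event(clinical)
    if X.shape[0] != len(t):
        raise ValueError("covariates and clinical table have different lengths")
    if e.sum() == 0:
        raise ValueError("no events observed; Cox model is not identifiable")
    const = np.ptp(X, axis=0) == 0
    if const.any():
        bad = [names[i] if names else str(i) for i in np.where(const)[0]]
        raise ValueError(f"constant covariate(s): {bad}")

    # centre covariates for numerical stability; beta is unchanged
    mu = X.mean(axis=0)
    Xc = X - mu
    order = np.argsort(t, kind="stable")
    Xs, ts, es = Xc[order], t[order], e[order]

    p = X.shape[1]
    beta = np.zeros(p)
    ll, grad, info = _cox_ll_grad_hess(beta, Xs, ts, es, ties)
    converged = False
    for _ in range(max_iter):
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(info, grad, rcond=None)[0]
        # step-halving keeps the likelihood non-decreasing
        factor = 1.0
        for _ in range(30):
            new_beta = beta + factor * step
            new_ll, new_grad, new_info = _cox_ll_grad_hess(new_beta, Xs, ts, es, ties)
            if new_ll >= ll - 1e-14:
                break
            factor /= 2
        delta_ll = new_ll - ll
        beta, ll, grad, info = new_beta, new_ll, new_grad, new_info
        if np.abs(grad).max() < 1e-9 or abs(delta_ll) < 1e-12:
            converged = True
            break
    try:
        cov = np.linalg.inv(info)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
        converged = False
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    # monotone likelihood (perfect separation): the estimate drifts to a huge
    # value while the flattening likelihood inflates se, so |z| collapses
    separated = (np.abs(beta) > 10) & (np.abs(z) < 0.1)
    if (np.abs(beta) > 30).any() or separated.any() or not np.isfinite(se).all():
        converged = False
        logger.warning("cox_fit: likely monotone partial likelihood; "
                       "estimates unreliable")
    wald_p = 2 * stats.norm.sf(np.abs(z))
    return CoxFit(beta=beta, hr=np.exp(beta), se=se, wald_p=wald_p,
                  loglik=float(ll), n_events=int(e.sum()),
                  converged=converged, names=names)


# ---------------------------------------------------------------------------
# concordance

def harrell_c(risk, clinical: pd.DataFrame) -> float:
    """Harrell's concordance index of a risk score against survival.

    A pair (i, j) is comparable with i the earlier subject when i died and
    either ``t_i < t_j``, or ``t_i == t_j`` with j censored. Concordant
    pairs (higher risk fails first) count 1, risk ties count 0.5.
    """
    r = np.asarray(risk, dtype=float)
    t, e = _time_event(clinical)
    if len(r) != len(t):
        raise ValueError("risk and clinical table have different lengths")
    ei = e[:, None].astype(bool)
    lt = t[:, None] < t[None, :]
    teq = t[:, None] == t[None, :]
    comparable = ei & (lt | (teq & ~e[None, :].astype(bool)))
    n_comp = comparable.sum()
    if n_comp == 0:
        raise ValueError("no comparable pairs (all times tied with events?)")
    gt = r[:, None] > r[None, :]
    req = r[:, None] == r[None, :]
    weight = (comparable & gt).sum() + 0.5 * (comparable & req).sum()
    return float(weight / n_comp)


# ---------------------------------------------------------------------------
# log-rank

def _logrank_oe_var(group: np.ndarray, t: np.ndarray, e: np.ndarray):
    """Observed-minus-expected deaths in group 1 and hypergeometric variance."""
    g = np.asarray(group).astype(bool)
    event_times = np.unique(t[e == 1])
    oe = 0.0
    var = 0.0
    for tk in event_times:
        at_risk = t >= tk
        nk = at_risk.sum()
        n1k = (at_risk & g).sum()
        dk = ((t == tk) & (e == 1)).sum()
        d1k = ((t == tk) & (e == 1) & g).sum()
        oe += d1k - dk * n1k / nk
        if nk > 1:
            var += dk * (n1k / nk) * (1 - n1k / nk) * (nk - dk) / (nk - 1)
    return oe, var


def logrank(group, clinical: pd.DataFrame) -> tuple[float, float]:
    """Two-group log-rank test: (chi-square with 1 df, p-value)."""
    g = np.asarray(group).astype(bool)
    t, e = _time_event(clinical)
    if len(g) != len(t):
        raise ValueError("group labels and clinical table have different lengths")
    if g.all() or (~g).all():
        raise ValueError("both groups must be non-empty")
    if e.sum() == 0:
        raise ValueError("no events observed")
    oe, var = _logrank_oe_var(g, t, e)
    if var == 0:
        return 0.0, 1.0
    chi2 = oe**2 / var
    return float(chi2), float(stats.chi2.sf(chi2, 1))


# ---------------------------------------------------------------------------
# Kaplan-Meier

@dataclass
class KMCurve:
    """Product-limit survival curve evaluated at the distinct event times."""

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray

    def at(self, times) -> np.ndarray:
        """Step-function value S(t) (right-continuous; S = 1 before the first event)."""
        idx = np.searchsorted(self.event_times, np.atleast_1d(times), side="right")
        s = np.concatenate([[1.0], self.survival])
        return s[idx]

    def at_left(self, times) -> np.ndarray:
        """Left limit S(t-)."""
        idx = np.searchsorted(self.event_times, np.atleast_1d(times), side="left")
        s = np.concatenate([[1.0], self.survival])
        return s[idx]


def km_curve(clinical: pd.DataFrame | None = None, *, time=None, event=None) -> KMCurve:
    """Kaplan-Meier estimator. Censored-only times reduce the risk set only."""
    if clinical is not None:
        t, e = _time_event(clinical)
    else:
        t = np.asarray(time, dtype=float)
        e = np.asarray(event, dtype=int)
    if len(t) == 0:
        raise ValueError("empty survival data")
    if e.sum() == 0:
        raise ValueError("no events observed")
    event_times = np.unique(t[e == 1])
    surv = np.empty(len(event_times))
    at_risk = np.empty(len(event_times), dtype=int)
    s = 1.0
    for i, tk in enumerate(event_times):
        nk = (t >= tk).sum()
        dk = ((t == tk) & (e == 1)).sum()
        s *= 1 - dk / nk
        surv[i] = s
        at_risk[i] = nk
    return KMCurve(event_times=event_times, survival=surv, at_risk=at_risk)


# ---------------------------------------------------------------------------
# maximally selected cutpoint

@dataclass
class CutpointResult:
    """Outcome of a maximally selected log-rank cutpoint search."""

    cutoff: float
    max_stat: float
    candidates: np.ndarray
    candidate_stats: np.ndarray


def max_sel_cutpoint(score, clinical: pd.DataFrame,
                     minprop: float = 0.1) -> CutpointResult:
    """Cutpoint maximising the standardised two-group log-rank statistic.

    Candidates are midpoints between consecutive distinct score values that
    leave at least ``minprop * n`` samples on each side. The statistic per
    candidate is |O - E| / sqrt(V) for the split ``score > candidate``; ties
    between candidates break toward the lower one.
    """
    s = np.asarray(score, dtype=float)
    t, e = _time_event(clinical)
    if len(s) != len(t):
        raise ValueError("score and clinical table have different lengths")
    if not (0 < minprop < 0.5):
        raise ValueError("minprop must be in (0, 0.5)")
    uniq = np.unique(s)
    if len(uniq) < 2:
        raise ValueError("need >=2 distinct score values for a cutpoint")
    n = len(s)
    candidates = []
    for lo, hi in zip(uniq[:-1], uniq[1:]):
        mid = (lo + hi) / 2
        n_low = (s <= mid).sum()
        if n_low >= minprop * n and n - n_low >= minprop * n:
            candidates.append(mid)
    if not candidates:
        raise ValueError(
            f"no candidate cutpoint leaves >= {minprop:.0%} of {n} samples on each side"
        )
    cand = np.asarray(candidates)
    zs = np.empty(len(cand))
    for i, c in enumerate(cand):
        oe, var = _logrank_oe_var(s > c, t, e)
        zs[i] = abs(oe) / np.sqrt(var) if var > 0 else 0.0
    best = int(np.argmax(zs))  # argmax keeps first (lowest candidate) on ties
    return CutpointResult(cutoff=float(cand[best]), max_stat=float(zs[best]),
                          candidates=cand, candidate_stats=zs)


# ---------------------------------------------------------------------------
# ROC / AUC

def roc_auc(score, label) -> float:
    """AUC via the Mann-Whitney statistic, 0.5 credit for tied scores."""
    s = np.asarray(score, dtype=float)
    y = np.asarray(label).astype(int)
    if not np.isin(y, (0, 1)).all():
        raise ValueError("labels must be binary 0/1")
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(s)
    u = ranks[y == 1].sum() - n1 * (n1 + 1) / 2
    return float(u / (n1 * n0))


def auc_at_horizon(score, clinical: pd.DataFrame, t: float) -> float:
    """Cumulative/dynamic time-dependent AUC at horizon ``t`` with IPCW.

    Cases are subjects with an observed event by ``t``; controls are those
    still at risk beyond ``t``. Each case i is weighted by 1/G(t_i-) and
    each control by 1/G(t), where G is the Kaplan-Meier estimate of the
    censoring survival function.
    """
    s = np.asarray(score, dtype=float)
    tt, e = _time_event(clinical)
    cases = (tt <= t) & (e == 1)
    controls = tt > t
    if cases.sum() == 0:
        raise ValueError(f"no events observed by horizon t={t}")
    if controls.sum() == 0:
        raise ValueError(f"no subject at risk beyond horizon t={t}")
    if e.mean() == 1.0:
        g = None  # no censoring: weights collapse to 1
        w_case = np.ones(int(cases.sum()))
        w_ctrl = 1.0
    else:
        g = km_curve(time=tt, event=1 - e)
        w_case = 1.0 / np.clip(g.at_left(tt[cases]), 1e-12, None)
        w_ctrl = float(1.0 / np.clip(g.at(np.array([t]))[0], 1e-12, None))
    sc = s[cases]
    sk = s[controls]
    gt = sc[:, None] > sk[None, :]
    eq = sc[:, None] == sk[None, :]
    num = (w_case[:, None] * (gt + 0.5 * eq) * w_ctrl).sum()
    den = w_case.sum() * w_ctrl * len(sk)
    return float(num / den)


# ---------------------------------------------------------------------------
# association tests

def correlate(x, y) -> tuple[float, float]:
    """Pearson correlation with its two-sided t-distribution p-value."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if len(xa) != len(ya) or len(xa) < 3:
        raise ValueError("need aligned vectors of length >= 3")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise ValueError("correlation undefined for constant input")
    res = stats.pearsonr(xa, ya)
    return float(res.statistic), float(res.pvalue)


def group_compare(values, groups, test: str = "wilcoxon") -> float:
    """Rank-based comparison of a value across groups; returns the p-value.

    ``wilcoxon``: two-group rank-sum with normal approximation and tie
    correction. ``kruskal``: Kruskal-Wallis chi-square for >= 2 groups.
    """
    v = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    labels, counts = np.unique(g, return_counts=True)
    if (counts == 0).any() or len(labels) < 2:
        raise ValueError("need >= 2 non-empty groups")
    if test == "wilcoxon":
        if len(labels) != 2:
            raise ValueError("wilcoxon requires exactly 2 groups")
        res = stats.mannwhitneyu(v[g == labels[0]], v[g == labels[1]],
                                 alternative="two-sided", method="asymptotic")
        return float(res.pvalue)
    if test == "kruskal":
        res = stats.kruskal(*(v[g == lab] for lab in labels))
        return float(res.pvalue)
    raise ValueError(f"unknown test {test!r}")
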