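"""Per-sample immune-cell enrichment (ssGSEA) and expression-unit utilities.

The enrichment score of a gene set S in one sample is a rank-weighted
running-sum statistic over the sample's genes ordered by decreasing
expression: walking down the ranking, the weighted fraction of set genes
encountered so far (weights = rank^alpha) is compared to the plain fraction
of non-set genes, and the differences are summed over all positions,

    ES = sum_i [ P_in(i) - P_out(i) ],
    P_in(i)  = sum_{g in S, pos(g) <= i} r_g^alpha / sum_{g in S} r_g^alpha,
    P_out(i) = |{g not in S, pos(g) <= i}| / (N - |S|),

with r_g the gene's rank from the top (N for the highest-expressed gene;
ties receive average ranks). Because only within-sample ranks enter, the
score is invariant under any strictly increasing per-sample transform of
expression — the property that makes downstream cell-pair indicators
comparable across platforms.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .signatures import GeneSet, SignatureCollection

__all__ = [
    "validate_expression",
    "read_expression",
    "write_expression",
    "fpkm_to_tpm",
    "ssgsea_sample",
    "ssgsea",
]


def validate_expression(matrix: pd.DataFrame) -> pd.DataFrame:
    """Validate a genes x samples expression matrix.

    Requires unique gene and sample identifiers, finite non-negative values
    and at least a 2 x 2 shape.
    """
    if matrix.index.has_duplicates:
        dup = matrix.index[matrix.index.duplicated()].unique().tolist()[:5]
        raise ValueError(f"duplicate gene IDs: {dup} ...")
    if matrix.columns.has_duplicates:
        dup = matrix.columns[matrix.columns.duplicated()].unique().tolist()[:5]
        raise ValueError(f"duplicate sample IDs: {dup} ...")
    if matrix.shape[0] < 2 or matrix.shape[1] < 2:
        raise ValueError(f"need >=2 genes and >=2 samples, got {matrix.shape}")
    values = matrix.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("expression matrix contains non-finite values")
    if (values < 0).any():
        raise ValueError("expression matrix contains negative values")
    return matrix


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a tab-delimited genes x samples matrix (first column gene IDs)."""
    matrix = pd.read_csv(path, sep="\t", index_col=0)
    matrix.index = matrix.index.astype(str)
    matrix.columns = matrix.columns.astype(str)
    return validate_expression(matrix)


def write_expression(matrix: pd.DataFrame, path: str | Path,
                     index_label: str = "gene") -> None:
    matrix.to_csv(path, sep="\t", index_label=index_label)


def fpkm_to_tpm(matrix: pd.DataFrame) -> pd.DataFrame:
    """Rescale FPKM columns to TPM: each sample column sums to 1e6.

    TPM_gj = FPKM_gj / sum_g FPKM_gj * 1e6. Idempotent; raises if a sample
    column is all zero (no signal to normalise).
    """
    validate_expression(matrix)
    totals = matrix.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(f"all-zero sample column(s): {zero.index.tolist()}")
    return matrix.div(totals, axis=1) * 1e6


def _rank_weights(x: np.ndarray, alpha: float) -> tuple[np.ndarray, np.ndarray]:
    """Descending position order (stable) and rank-from-top weights r^alpha."""
    order = np.argsort(-x, kind="stable")
    ranks = rankdata(x, method="average")  # top gene gets rank N
    return order, ranks ** alpha


def ssgsea_sample(expr_col: pd.Series, gene_set: GeneSet | frozenset[str],
                  alpha: float = 0.25) -> float:
    """Un-normalised enrichment score of one gene set in one sample."""
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    genes = gene_set.genes if isinstance(gene_set, GeneSet) else frozenset(gene_set)
    x = expr_col.to_numpy(dtype=float)
    n = len(x)
    mask = expr_col.index.isin(genes)
    k = int(mask.sum())
    if k == 0:
        raise ValueError("gene set has no gene in the expression index")
    if k == n:
        raise ValueError("gene set covers every gene; out-of-set fraction undefined")
    order, w = _rank_weights(x, alpha)
    m = mask[order]
    p_in = np.cumsum(w[order] * m) / (w * mask).sum()
    p_out = np.cumsum(~m) / (n - k)
    return float((p_in - p_out).sum())


def ssgsea(matrix: pd.DataFrame, collection: SignatureCollection,
           alpha: float = 0.25, normalize: bool = True) -> pd.DataFrame:
    """ssGSEA scores for every (gene set, sample): cell_types x samples.

    The collection should be pre-filtered to the matrix's gene universe
    (:func:`icpscore.signatures.filter_to_universe`); sets with no gene in
    the matrix raise. When ``normalize`` is set, all scores are divided by
    the range (max - min) taken over the whole output matrix, as in the
    ssGSEA mode of the reference enrichment tooling; pairing downstream uses
    only within-sample comparisons, so this shared scaling does not affect
    cell-pair indicators.
    """
    validate_expression(matrix)
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    n, n_samples = matrix.shape
    masks = []
    for s in collection:
        m = matrix.index.isin(s.genes)
        k = int(m.sum())
        if k == 0:
            raise ValueError(
                f"signature {s.cell_type!r} has no gene in the matrix; "
                "filter the collection to the matrix universe first"
            )
        if k == n:
            raise ValueError(f"signature {s.cell_type!r} covers every gene")
        masks.append(m)
    mask_mat = np.vstack(masks)  # sets x genes
    values = matrix.to_numpy(dtype=float)
    ks = mask_mat.sum(axis=1)

    scores = np.empty((len(collection), n_samples))
    for j in range(n_samples):
        order, w = _rank_weights(values[:, j], alpha)
        m_sorted = mask_mat[:, order]
        w_sorted = w[order]
        in_w = m_sorted * w_sorted
        p_in = np.cumsum(in_w, axis=1) / in_w.sum(axis=1, keepdims=True)
        p_out = np.cumsum(~m_sorted, axis=1) / (n - ks)[:, None]
        scores[:, j] = (p_in - p_out).sum(axis=1)

    if normalize:
        rng = scores.max() - scores.min()
        if rng > 0:
            scores = scores / rng
    out = pd.DataFrame(scores, index=pd.Index(collection.cell_types, name="cell_type"),
                       columns=matrix.columns)
    return out


def read_enrichment(path: str | Path) -> pd.DataFrame:
    """Read a tab-delimited cell_types x samples score matrix."""
    enr = pd.read_csv(path, sep="\t", index_col=0)
    enr.index = enr.index.astype(str)
    enr.columns = enr.columns.astype(str)
    if enr.index.has_duplicates or enr.columns.has_duplicates:
        raise ValueError("duplicate cell types or sample IDs in enrichment matrix")
    if not np.isfinite(enr.to_numpy(dtype=float)).all():
        raise ValueError("enrichment matrix contains non-finite values")
    return enr


def write_enrichment(enr: pd.DataFrame, path: str | Path) -> None:
    enr.to_csv(path, sep="\t", index_label="cell_type")
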