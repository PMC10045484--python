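"""One-vs-rest marker-gene detection per cell type.

Mirrors the standard Seurat ``FindAllMarkers`` retention rule: a gene is a
marker of a cell type when it is expressed (value > 0) in at least
``min_pct`` of the cells of that type, its log2 fold change against all
other cells exceeds ``min_logfc`` (strict by default; a flag makes the
boundary inclusive), and its Benjamini-Hochberg FDR — computed per cell
type across the genes that passed the expression/fold-change prefilter —
is below ``max_fdr``.  Only positively enriched genes are reported.

The test statistic is the two-sided Wilcoxon rank-sum (Mann-Whitney U):
exact enumeration of rank assignments when the combined sample size is at
most 12, otherwise the normal approximation with tie and continuity
corrections.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
from scipy.stats import mannwhitneyu, rankdata

from .types import CellAnnotation, ExpressionMatrix, GeneSet

log = logging.getLogger(__name__)

__all__ = [
    "MarkerResult",
    "wilcoxon_test",
    "log_fold_change",
    "find_markers",
    "gy_set",
]

EXACT_MAX_N = 12


@dataclass
class MarkerResult:
    gene_id: str
    cell_type: str
    log_fc: float
    pct_in: float
    pct_out: float
    p_value: float
    fdr: float


def wilcoxon_test(x, y) -> tuple:
    """Two-sided Wilcoxon rank-sum test; returns ``(U, p)`` with U for ``x``.

    For combined sample sizes up to 12 the null distribution of U is
    enumerated exactly over all rank assignments (mean ranks under ties; the
    two-sided p doubles the smaller tail, capped at 1).  Larger samples use
    the normal approximation with tie and continuity corrections.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    nx, ny = x.size, y.size
    n = nx + ny
    ranks = rankdata(np.concatenate([x, y]), method="average")
    u_obs = ranks[:nx].sum() - nx * (nx + 1) / 2.0
    if n <= EXACT_MAX_N:
        total = comb(n, nx)
        base = nx * (nx + 1) / 2.0
        le = ge = 0
        for idx in combinations(range(n), nx):
            u = ranks[list(idx)].sum() - base
            if u <= u_obs + 1e-12:
                le += 1
            if u >= u_obs - 1e-12:
                ge += 1
        p = min(1.0, 2.0 * min(le, ge) / total)
        return float(u_obs), float(p)
    res = mannwhitneyu(x, y, alternative="two-sided", method="asymptotic",
                       use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def log_fold_change(x_in, x_out) -> float:
    """Seurat-convention log2 fold change of log-normalized values.

    ``log2((mean(expm1(x_in)) + 1) / (mean(expm1(x_out)) + 1))`` — the
    pseudocount keeps all-zero groups finite (and equal groups at 0).
    """
    x_in = np.asarray(x_in, dtype=np.float64)
    x_out = np.asarray(x_out, dtype=np.float64)
    return float(np.log2((np.expm1(x_in).mean() + 1.0) / (np.expm1(x_out).mean() + 1.0)))


def bh_adjust_local(p: np.ndarray) -> np.ndarray:
    # thin wrapper to avoid a circular import; the canonical BH lives in signature
    from .signature import bh_adjust
    return bh_adjust(p)


def _marker_frame_for_type(m: ExpressionMatrix, in_mask: np.ndarray,
                           min_pct: float, min_logfc: float,
                           logfc_inclusive: bool):
    """Prefilter + test one cell type; returns parallel arrays for tested genes."""
    x_in = m.values[:, in_mask]
    x_out = m.values[:, ~in_mask]
    pct_in = (x_in > 0).mean(axis=1)
    pct_out = (x_out > 0).mean(axis=1)
    mean_in = np.expm1(x_in).mean(axis=1)
    mean_out = np.expm1(x_out).mean(axis=1)
    log_fc = np.log2((mean_in + 1.0) / (mean_out + 1.0))
    if logfc_inclusive:
        fc_pass = log_fc >= min_logfc
    else:
        fc_pass = log_fc > min_logfc
    tested = (pct_in >= min_pct) & fc_pass
    idx = np.flatnonzero(tested)
    if idx.size == 0:
        return idx, pct_in, pct_out, log_fc, np.array([])
    n_in, n_out = int(in_mask.sum()), int((~in_mask).sum())
    if n_in + n_out <= EXACT_MAX_N:
        pvals = np.array([wilcoxon_test(x_in[i], x_out[i])[1] for i in idx])
    else:
        res = mannwhitneyu(x_in[idx], x_out[idx], alternative="two-sided",
                           method="asymptotic", use_continuity=True, axis=1)
        pvals = np.asarray(res.pvalue, dtype=np.float64)
    return idx, pct_in, pct_out, log_fc, pvals


def find_markers(m: ExpressionMatrix, ann: CellAnnotation, min_pct: float = 0.25,
                 min_logfc: float = 0.25, max_fdr: float = 0.05,
                 logfc_inclusive: bool = False) -> list:
    """Positively enriched marker genes for every annotated cell type.

    Requires log-normalized input and at least two cell types; types with
    fewer than 3 cells are skipped with a warning.  Output is sorted by
    (cell_type, gene_id) so it is invariant to cell and gene ordering.
    """
    if m.layer != "lognorm":
        raise ValueError("find_markers expects the lognorm layer")
    labels = ann.as_series().reindex(m.obs_ids)
    if labels.isna().any():
        missing = list(labels.index[labels.isna()][:5])
        raise ValueError(f"cells without annotation: {missing}")
    types = sorted(labels.unique())
    if len(types) < 2:
        raise ValueError("need >= 2 cell types for one-vs-rest testing")
    out = []
    gene_ids = np.array(m.gene_ids, dtype=object)
    for ct in types:
        in_mask = (labels == ct).to_numpy()
        if in_mask.sum() < 3:
            log.warning("cell type %s has %d cells (< 3); skipped", ct, int(in_mask.sum()))
            continue
        idx, pct_in, pct_out, log_fc, pvals = _marker_frame_for_type(
            m, in_mask, min_pct, min_logfc, logfc_inclusive)
        if idx.size == 0:
            continue
        fdr = bh_adjust_local(pvals)
        for j, i in enumerate(idx):
            if fdr[j] < max_fdr:
                out.append(MarkerResult(
                    gene_id=str(gene_ids[i]), cell_type=str(ct),
                    log_fc=float(log_fc[i]), pct_in=float(pct_in[i]),
                    pct_out=float(pct_out[i]), p_value=float(pvals[j]),
                    fdr=float(fdr[j])))
    out.sort(key=lambda r: (r.cell_type, r.gene_id))
    return out


def gy_set(markers, cell_type: str = "TEC", dataset_id: str = "") -> GeneSet:
    """Project retained markers of the endothelial type into the Gy gene set."""
    genes = sorted({r.gene_id for r in markers if r.cell_type == cell_type})
    if not genes:
        raise ValueError(f"no retained markers for cell type {cell_type!r}")
    return GeneSet(name=f"Gy:{dataset_id}" if dataset_id else "Gy", genes=genes)
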