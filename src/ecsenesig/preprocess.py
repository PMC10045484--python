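"""Cell-level quality control and normalization.

QC keeps cells whose number of detected genes (count > 0) lies in
``[min_genes, max_genes]`` and whose mitochondrial fraction is at most
``max_mito_pct`` percent of total counts.  The defaults (300, 6500, 10%)
are the conventional droplet-scRNA-seq cutoffs: the exclusion rules are
strict inequalities, so the boundaries themselves are retained.

Normalization is log1p counts-per-10k: ``ln(1 + count * scale / cell_total)``.
Every rank-based statistic downstream (ECDF enrichment, Spearman, Wilcoxon)
depends only on within-gene orderings, which this transform preserves.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .types import ExpressionMatrix

log = logging.getLogger(__name__)

__all__ = ["QCThresholds", "QCReport", "qc_filter_cells", "lognormalize"]


@dataclass
class QCThresholds:
    min_genes: int = 300
    max_genes: int = 6500
    max_mito_pct: float = 10.0
    mito_prefix: str = "MT-"

    def __post_init__(self) -> None:
        if not (0 < self.min_genes < self.max_genes):
            raise ValueError("need 0 < min_genes < max_genes")
        if not (0 <= self.max_mito_pct <= 100):
            raise ValueError("max_mito_pct must be in [0, 100]")


@dataclass
class QCReport:
    n_input: int = 0
    n_retained: int = 0
    excluded_low_genes: int = 0
    excluded_high_genes: int = 0
    excluded_mito: int = 0
    excluded_zero_counts: int = 0

    def to_rows(self) -> list:
        return [
            ("n_input", self.n_input),
            ("n_retained", self.n_retained),
            ("excluded_low_genes", self.excluded_low_genes),
            ("excluded_high_genes", self.excluded_high_genes),
            ("excluded_mito", self.excluded_mito),
            ("excluded_zero_counts", self.excluded_zero_counts),
        ]


def qc_filter_cells(m: ExpressionMatrix, thresholds: QCThresholds | None = None):
    """Filter cells on detected genes and mitochondrial percentage.

    Returns ``(filtered_matrix, QCReport)``.  A cell can fail several
    criteria; the report counts each criterion independently and the cell is
    excluded once.  Zero-total cells are excluded and flagged, never an
    arithmetic error.
    """
    if m.layer != "counts":
        raise ValueError("qc_filter_cells expects the counts layer")
    t = thresholds or QCThresholds()
    counts = m.values
    detected = (counts > 0).sum(axis=0)
    totals = counts.sum(axis=0)
    mito_rows = np.array([g.startswith(t.mito_prefix) for g in m.gene_ids])
    mito_counts = counts[mito_rows, :].sum(axis=0) if mito_rows.any() else np.zeros(m.n_obs)
    zero_total = totals == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_pct = np.where(zero_total, 0.0, mito_counts / np.where(zero_total, 1.0, totals) * 100.0)

    low = detected < t.min_genes
    high = detected > t.max_genes
    mito_bad = mito_pct > t.max_mito_pct
    keep = ~(low | high | mito_bad | zero_total)

    report = QCReport(
        n_input=m.n_obs,
        n_retained=int(keep.sum()),
        excluded_low_genes=int((low & ~zero_total).sum()),
        excluded_high_genes=int(high.sum()),
        excluded_mito=int(mito_bad.sum()),
        excluded_zero_counts=int(zero_total.sum()),
    )
    kept_ids = [o for o, k in zip(m.obs_ids, keep) if k]
    filtered = ExpressionMatrix(
        gene_ids=list(m.gene_ids),
        obs_ids=kept_ids,
        values=counts[:, keep].copy(),
        layer="counts",
        dataset_id=m.dataset_id,
    )
    log.info("QC %s: retained %d/%d cells (low=%d high=%d mito=%d zero=%d)",
             m.dataset_id, report.n_retained, report.n_input,
             report.excluded_low_genes, report.excluded_high_genes,
             report.excluded_mito, report.excluded_zero_counts)
    return filtered, report


def lognormalize(m: ExpressionMatrix, scale: float = 1e4) -> ExpressionMatrix:
    """log1p counts-per-``scale`` normalization: ``ln(1 + c * scale / total)``."""
    if m.layer != "counts":
        raise ValueError("lognormalize expects the counts layer")
    totals = m.values.sum(axis=0)
    if np.any(totals == 0):
        bad = [m.obs_ids[i] for i in np.flatnonzero(totals == 0)[:5]]
        raise ValueError(
            f"cells with zero total counts (e.g. {bad}); run qc_filter_cells first")
    values = np.log1p(m.values * (scale / totals))
    return ExpressionMatrix(gene_ids=list(m.gene_ids), obs_ids=list(m.obs_ids),
                            values=values, layer="lognorm", dataset_id=m.dataset_id)
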