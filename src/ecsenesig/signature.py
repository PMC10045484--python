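"""Cross-dataset derivation of the endothelial-senescence gene signature.

Per dataset two evidence channels are collected for every gene:

* **Gx** — genes whose expression across tumor endothelial cells (TEC)
  correlates positively with the per-cell senescence enrichment score
  (Spearman rho > 0, BH FDR < 0.05 across the genes tested in that dataset);
* **Gy** — genes positively enriched in the endothelial type by the marker
  test (see :mod:`ecsenesig.markers`).

Their intersection **Gn** holds the dataset's endothelial-senescence
candidates.  The consensus step pools candidates across datasets: for each
gene the geometric mean of its Spearman coefficients over the datasets where
it qualified is computed, and genes whose geometric mean exceeds the
membership threshold (default 0.2, strict) with sufficient dataset support
enter the signature.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .enrichment import EnrichmentScores
from .types import CellAnnotation, ExpressionMatrix, GeneSet

log = logging.getLogger(__name__)

__all__ = [
    "CorrelationResult",
    "DatasetCandidates",
    "ConsensusSignature",
    "spearman",
    "bh_adjust",
    "gx_set",
    "dataset_candidates",
    "consensus",
]


@dataclass
class CorrelationResult:
    gene_id: str
    dataset_id: str
    rho: float
    p_value: float
    fdr: float


@dataclass
class DatasetCandidates:
    dataset_id: str
    gx: GeneSet
    gy: GeneSet
    gn: GeneSet | None  # None when the intersection is empty

    def __post_init__(self) -> None:
        if self.gn is not None:
            gx, gy = set(self.gx.genes), set(self.gy.genes)
            if not set(self.gn.genes) <= gx or not set(self.gn.genes) <= gy:
                raise ValueError("gn must be a subset of both gx and gy")


@dataclass
class ConsensusSignature:
    """Per-gene consensus table; members form the derived signature.

    ``table`` columns: gene_id, n_support, geo_mean, member, plus one
    ``rho:<dataset_id>`` column per dataset (NaN where the gene did not
    qualify).  Rows are sorted by geo_mean descending, ties by gene_id.
    """

    table: pd.DataFrame
    threshold: float
    min_support: int

    def members(self) -> list:
        return list(self.table.loc[self.table["member"], "gene_id"])

    def gene_set(self, name: str = "EC.SENESCENCE.SIG") -> GeneSet:
        return GeneSet(name=name, genes=self.members())

    def to_tsv(self, path: str) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.10g")


def spearman(x, y) -> tuple:
    """Spearman correlation (mean-tie ranks) with a t-approximation p-value.

    Requires equal lengths >= 4 and non-constant vectors.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if x.size < 4:
        raise ValueError(f"need length >= 4, got {x.size}")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("spearman is undefined for constant vectors")
    res = scipy.stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def spearman_matrix(X: np.ndarray, y: np.ndarray) -> tuple:
    """Row-wise Spearman of a (genes x n) matrix against a length-n vector.

    Vectorized rank-Pearson with the same t-approximation as :func:`spearman`.
    Rows must be non-constant.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    n = y.size
    rx = scipy.stats.rankdata(X, axis=1, method="average")
    ry = scipy.stats.rankdata(y, method="average")
    rx = rx - rx.mean(axis=1, keepdims=True)
    ry = ry - ry.mean()
    denom = np.sqrt((rx ** 2).sum(axis=1) * (ry ** 2).sum())
    if np.any(denom == 0):
        raise ValueError("constant row or score vector in spearman_matrix")
    rho = np.clip(rx @ ry / denom, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho ** 2))
    p = np.where(np.abs(rho) == 1.0, 0.0, 2.0 * scipy.stats.t.sf(np.abs(t), df=n - 2))
    return rho, p


def bh_adjust(p, m: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, clipped at 1.

    ``m`` overrides the number of hypotheses (defaults to ``len(p)``).
    """
    p = np.asarray(p, dtype=np.float64)
    if p.ndim != 1:
        raise ValueError("p must be a 1-D vector")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    k = p.size
    if k == 0:
        return p.copy()
    m = k if m is None else int(m)
    if m < k:
        raise ValueError("m must be >= len(p)")
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, k + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(k)
    out[order] = np.minimum(adj, 1.0)
    return out


def gx_set(m: ExpressionMatrix, ann: CellAnnotation, sen_scores: EnrichmentScores,
           cell_type: str = "TEC", max_fdr: float = 0.05,
           min_cells_expr: int = 10) -> tuple:
    """Senescence-correlated genes within the endothelial compartment.

    For every gene expressed (value > 0) in at least ``min_cells_expr`` of
    the ``cell_type`` cells, computes Spearman correlation between its
    expression across those cells and their senescence enrichment scores,
    adjusts across the tested genes by BH, and returns
    ``(GeneSet, [CorrelationResult ...])`` with Gx = {rho > 0, fdr < max_fdr}.
    """
    if m.layer != "lognorm":
        raise ValueError("gx_set expects the lognorm layer")
    cells = ann.cells_of_type(cell_type)
    cells = [c for c in cells if c in set(m.obs_ids)]
    if len(cells) < 10:
        raise ValueError(f"need >= 10 {cell_type} cells, got {len(cells)}")
    sub = m.subset_obs(cells)
    scores = sen_scores.subset(cells).scores
    if np.all(scores == scores[0]):
        raise ValueError("senescence scores are constant across the selected cells")

    expressed = (sub.values > 0).sum(axis=1) >= min_cells_expr
    constant = np.all(sub.values == sub.values[:, :1], axis=1)
    testable = expressed & ~constant
    n_skipped = int(expressed.sum() - testable.sum())
    if n_skipped:
        log.info("%s: %d constant expressed genes excluded from correlation testing",
                 m.dataset_id, n_skipped)
    idx = np.flatnonzero(testable)
    if idx.size == 0:
        raise ValueError("no genes pass the expression floor for correlation testing")
    rho, p = spearman_matrix(sub.values[idx], scores)
    fdr = bh_adjust(p)
    results = [
        CorrelationResult(gene_id=str(sub.gene_ids[i]), dataset_id=m.dataset_id,
                          rho=float(rho[j]), p_value=float(p[j]), fdr=float(fdr[j]))
        for j, i in enumerate(idx)
    ]
    gx_genes = sorted(r.gene_id for r in results if r.rho > 0 and r.fdr < max_fdr)
    if not gx_genes:
        raise ValueError(f"{m.dataset_id}: Gx is empty (no positively correlated genes)")
    gx = GeneSet(name=f"Gx:{m.dataset_id}" if m.dataset_id else "Gx", genes=gx_genes)
    return gx, results


def dataset_candidates(gx: GeneSet, gy: GeneSet, dataset_id: str) -> DatasetCandidates:
    """Intersect the correlation and marker evidence channels into Gn."""
    inter = sorted(set(gx.genes) & set(gy.genes))
    if not inter:
        log.warning("%s: Gx and Gy are disjoint; Gn is empty", dataset_id)
        gn = None
    else:
        gn = GeneSet(name=f"Gn:{dataset_id}", genes=inter)
    return DatasetCandidates(dataset_id=dataset_id, gx=gx, gy=gy, gn=gn)


def consensus(candidates, correlations, threshold: float = 0.2,
              min_support: int = 1) -> ConsensusSignature:
    """Geometric-mean consensus over per-dataset candidate genes.

    For each gene in the union of the Gn sets, the geometric mean of its
    Spearman coefficients is taken over the datasets where it qualified
    (all positive by Gx construction).  Membership requires
    ``geo_mean > threshold`` (strict) and ``n_support >= min_support``.
    """
    if not candidates:
        raise ValueError("need at least one dataset")
    if min_support < 1:
        raise ValueError("min_support must be >= 1")
    rho_lookup = {(c.dataset_id, c.gene_id): c.rho for c in correlations}
    dataset_ids = [c.dataset_id for c in candidates]
    per_gene: dict = {}
    for c in candidates:
        if c.gn is None:
            continue
        for g in c.gn.genes:
            key = (c.dataset_id, g)
            if key not in rho_lookup:
                raise ValueError(
                    f"gene {g!r} in Gn of {c.dataset_id!r} has no recorded rho")
            rho = rho_lookup[key]
            if not rho > 0:
                raise ValueError(
                    f"gene {g!r} in Gn of {c.dataset_id!r} has non-positive rho {rho}")
            per_gene.setdefault(g, {})[c.dataset_id] = rho

    rows = []
    for g, rhos in per_gene.items():
        vals = np.array(list(rhos.values()))
        geo = float(np.exp(np.mean(np.log(vals))))
        row = {
            "gene_id": g,
            "n_support": len(rhos),
            "geo_mean": geo,
            "member": bool(geo > threshold and len(rhos) >= min_support),
        }
        for d in dataset_ids:
            row[f"rho:{d}"] = rhos.get(d, np.nan)
        rows.append(row)
    cols = ["gene_id", "n_support", "geo_mean", "member"] + [f"rho:{d}" for d in dataset_ids]
    table = pd.DataFrame(rows, columns=cols)
    if len(table):
        table = table.sort_values(["geo_mean", "gene_id"], ascending=[False, True],
                                  kind="stable").reset_index(drop=True)
    return ConsensusSignature(table=table, threshold=threshold, min_support=min_support)
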