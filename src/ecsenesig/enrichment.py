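"""Single-sample gene-set enrichment via a rank random-walk statistic.

The scorer is a GSVA-style two-step procedure:

1. **Gene-level statistic** ``z_ij``: for each gene *i*, how extreme
   observation *j* is relative to the other observations.  The ``ecdf``
   kernel uses mean-tie ranks divided by *n* (making scores invariant to any
   strictly increasing per-gene transform of expression).  The ``gaussian``
   kernel uses the kernel-smoothed CDF ``mean_k Phi((x_ij - x_ik) / h_i)``
   with bandwidth ``h_i = sd_i / 4``, falling back to ``ecdf`` for constant
   genes.

2. **Random walk over the gene ranking**: per observation the genes are
   ordered by decreasing ``z_ij`` (ties broken lexically by gene id) into
   ranks ``r = 1..p``; each gene carries the symmetric weight
   ``w = |p/2 - r| ** tau``.  Walking down the ranking, an in-set gene adds
   ``w / sum(in-set w)`` and an out-set gene subtracts ``1 / (p - |G|)``.
   The ``maxdev`` score is the signed deviation of maximal magnitude; the
   ``maxdiff`` score is the maximal positive deviation plus the minimal
   negative deviation.  Both lie in ``[-1, 1]``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.special import ndtr
from scipy.stats import rankdata

from .types import ExpressionMatrix, GeneSet

log = logging.getLogger(__name__)

__all__ = [
    "EnrichmentScores",
    "SenescenceSplit",
    "gene_stat",
    "score_gene_set",
    "median_split",
]


@dataclass
class EnrichmentScores:
    """Per-observation enrichment scores for one gene set."""

    set_name: str
    obs_ids: list
    scores: np.ndarray
    method: str = "maxdiff"
    kernel: str = "ecdf"
    tau: float = 1.0

    def __post_init__(self) -> None:
        self.obs_ids = list(map(str, self.obs_ids))
        self.scores = np.asarray(self.scores, dtype=np.float64)
        if self.scores.shape != (len(self.obs_ids),):
            raise ValueError("one score per observation required")
        if np.any(np.abs(self.scores) > 1 + 1e-12):
            raise ValueError("enrichment scores must lie in [-1, 1]")

    def as_dict(self) -> dict:
        return dict(zip(self.obs_ids, self.scores))

    def subset(self, obs_ids) -> "EnrichmentScores":
        d = self.as_dict()
        missing = [o for o in obs_ids if o not in d]
        if missing:
            raise KeyError(f"observations without scores: {missing[:5]}")
        return EnrichmentScores(
            set_name=self.set_name, obs_ids=list(obs_ids),
            scores=np.array([d[o] for o in obs_ids]),
            method=self.method, kernel=self.kernel, tau=self.tau)


@dataclass
class SenescenceSplit:
    """High/low split of observations at the median score.

    ``label = "HS"`` iff score > threshold; ties at the median go to ``"LS"``.
    """

    obs_ids: list
    labels: list
    threshold: float

    def high(self) -> list:
        return [o for o, l in zip(self.obs_ids, self.labels) if l == "HS"]

    def low(self) -> list:
        return [o for o, l in zip(self.obs_ids, self.labels) if l == "LS"]


def gene_stat(m: ExpressionMatrix, kernel: str = "ecdf") -> np.ndarray:
    """Gene-level statistic matrix ``z`` (genes x observations).

    Requires at least 3 observations; kernel estimation is degenerate below
    that.  ``gaussian`` is O(p * n^2) and intended for moderate *n*.
    """
    if m.n_obs < 3:
        raise ValueError(f"need >= 3 observations, got {m.n_obs}")
    x = m.values
    if kernel == "ecdf":
        return rankdata(x, axis=1, method="average") / m.n_obs
    if kernel == "gaussian":
        z = np.empty_like(x)
        sd = x.std(axis=1, ddof=1)
        for i in range(m.n_genes):
            if sd[i] == 0:
                z[i] = rankdata(x[i], method="average") / m.n_obs
            else:
                h = sd[i] / 4.0
                z[i] = ndtr((x[i][:, None] - x[i][None, :]) / h).mean(axis=1)
        return z
    raise ValueError(f"unknown kernel {kernel!r}")


def score_gene_set(m: ExpressionMatrix, gene_set: GeneSet, method: str = "maxdiff",
                   kernel: str = "ecdf", tau: float = 1.0) -> EnrichmentScores:
    """Score every observation for enrichment of ``gene_set``.

    Set genes absent from the matrix are dropped with a logged warning; an
    empty intersection, or a set covering every gene, raises.
    """
    if method not in ("maxdiff", "maxdev"):
        raise ValueError(f"unknown method {method!r}")
    present = [g for g in gene_set.genes if g in set(m.gene_ids)]
    dropped = len(gene_set.genes) - len(present)
    if dropped:
        log.warning("gene set %s: %d/%d genes absent from matrix %s",
                    gene_set.name, dropped, len(gene_set.genes), m.dataset_id)
    if not present:
        raise ValueError(f"gene set {gene_set.name!r} has no genes in the matrix")
    p = m.n_genes
    if len(present) == p:
        raise ValueError(f"gene set {gene_set.name!r} covers every matrix gene")

    # Lexically pre-sort genes so a stable descending argsort breaks z-ties
    # by gene id, deterministically across platforms.
    lex = np.argsort(np.array(m.gene_ids, dtype=object))
    z = gene_stat(m, kernel=kernel)[lex, :]
    inset = np.isin(np.array(m.gene_ids, dtype=object)[lex], present)

    order = np.argsort(-z, axis=0, kind="stable")          # p x n gene ordering
    inset_ord = inset[order]                               # p x n
    ranks = np.arange(1, p + 1, dtype=np.float64)
    w = np.abs(p / 2.0 - ranks) ** tau                     # symmetric rank weight
    in_norm = (w[:, None] * inset_ord).sum(axis=0)         # sum of in-set weights
    n_out = p - len(present)
    # degenerate column: every in-set gene sits exactly at rank p/2 (weight 0);
    # fall back to equal in-set weights there
    degenerate = in_norm == 0
    if np.any(degenerate):
        w_col = np.broadcast_to(w[:, None], inset_ord.shape).copy()
        w_col[:, degenerate] = 1.0
        in_norm = (w_col * inset_ord).sum(axis=0)
        steps = np.where(inset_ord, w_col / in_norm, -1.0 / n_out)
    else:
        steps = np.where(inset_ord, w[:, None] / in_norm, -1.0 / n_out)
    profile = np.cumsum(steps, axis=0)

    pmax = profile.max(axis=0)
    pmin = profile.min(axis=0)
    if method == "maxdev":
        scores = np.where(pmax >= -pmin, pmax, pmin)
    else:
        scores = np.maximum(pmax, 0.0) + np.minimum(pmin, 0.0)
    scores = np.clip(scores, -1.0, 1.0)
    return EnrichmentScores(set_name=gene_set.name, obs_ids=list(m.obs_ids),
                            scores=scores, method=method, kernel=kernel, tau=tau)


def median_split(scores: EnrichmentScores, obs_subset=None) -> SenescenceSplit:
    """Dichotomize observations at the median score (ties go low).

    Raises when fewer than 2 observations remain or all scores are identical.
    """
    sub = scores if obs_subset is None else scores.subset(list(obs_subset))
    vals = sub.scores
    if len(vals) < 2:
        raise ValueError("median split needs >= 2 observations")
    if np.all(vals == vals[0]):
        raise ValueError("degenerate split: all scores identical")
    threshold = float(np.median(vals))
    labels = ["HS" if v > threshold else "LS" for v in vals]
    return SenescenceSplit(obs_ids=list(sub.obs_ids), labels=labels, threshold=threshold)
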