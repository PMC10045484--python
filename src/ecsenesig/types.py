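"""Shared data model for the pipeline.

All expression matrices are stored genes x observations (the 10x MTX
convention); observations are cells for single-cell data and samples for
bulk cohorts.  Validation happens at construction time: a value of these
types is either fully valid or was never created.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "CellAnnotation",
    "GeneSet",
    "SurvivalRecord",
]


def _check_unique(ids, what: str) -> None:
    if len(ids) != len(set(ids)):
        seen, dups = set(), []
        for i in ids:
            if i in seen:
                dups.append(i)
            seen.add(i)
        raise ValueError(f"duplicate {what}: {sorted(set(dups))[:5]}")


@dataclass
class ExpressionMatrix:
    """Dense genes x observations expression matrix.

    Parameters
    ----------
    gene_ids
        Unique gene symbols, one per row.
    obs_ids
        Unique observation (cell / sample) identifiers, one per column.
    values
        Non-negative, finite matrix of shape ``(len(gene_ids), len(obs_ids))``.
    layer
        ``"counts"`` for raw counts, ``"lognorm"`` for log-normalized values.
    dataset_id
        Free-form dataset label carried through the pipeline.
    """

    gene_ids: list
    obs_ids: list
    values: np.ndarray
    layer: str = "counts"
    dataset_id: str = ""

    def __post_init__(self) -> None:
        self.gene_ids = list(map(str, self.gene_ids))
        self.obs_ids = list(map(str, self.obs_ids))
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.layer not in ("counts", "lognorm"):
            raise ValueError(f"unknown layer {self.layer!r}")
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix (genes x observations)")
        if self.values.shape != (len(self.gene_ids), len(self.obs_ids)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.obs_ids)} observations"
            )
        _check_unique(self.gene_ids, "gene_ids")
        _check_unique(self.obs_ids, "obs_ids")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"non-finite value at gene {self.gene_ids[bad[0]]!r}, "
                f"observation {self.obs_ids[bad[1]]!r}"
            )
        if np.any(self.values < 0):
            bad = np.argwhere(self.values < 0)[0]
            raise ValueError(
                f"negative value at gene {self.gene_ids[bad[0]]!r}, "
                f"observation {self.obs_ids[bad[1]]!r}"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_obs(self) -> int:
        return len(self.obs_ids)

    def gene_index(self, genes) -> np.ndarray:
        idx = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in idx]
        if missing:
            raise KeyError(f"genes not in matrix: {missing[:5]}")
        return np.array([idx[g] for g in genes], dtype=int)

    def obs_index(self, obs) -> np.ndarray:
        idx = {o: i for i, o in enumerate(self.obs_ids)}
        missing = [o for o in obs if o not in idx]
        if missing:
            raise KeyError(f"observations not in matrix: {missing[:5]}")
        return np.array([idx[o] for o in obs], dtype=int)

    def subset_obs(self, obs_ids) -> "ExpressionMatrix":
        cols = self.obs_index(obs_ids)
        return ExpressionMatrix(
            gene_ids=list(self.gene_ids),
            obs_ids=[self.obs_ids[c] for c in cols],
            values=self.values[:, cols].copy(),
            layer=self.layer,
            dataset_id=self.dataset_id,
        )

    def subset_genes(self, genes) -> "ExpressionMatrix":
        rows = self.gene_index(genes)
        return ExpressionMatrix(
            gene_ids=[self.gene_ids[r] for r in rows],
            obs_ids=list(self.obs_ids),
            values=self.values[rows, :].copy(),
            layer=self.layer,
            dataset_id=self.dataset_id,
        )


@dataclass
class CellAnnotation:
    """Cell-type labels for the observations of one dataset."""

    obs_ids: list
    cell_types: list
    dataset_id: str = ""

    def __post_init__(self) -> None:
        self.obs_ids = list(map(str, self.obs_ids))
        self.cell_types = list(map(str, self.cell_types))
        if len(self.obs_ids) != len(self.cell_types):
            raise ValueError("obs_ids and cell_types differ in length")
        _check_unique(self.obs_ids, "annotation obs_ids")

    def as_series(self) -> pd.Series:
        return pd.Series(self.cell_types, index=self.obs_ids, name="cell_type")

    def cells_of_type(self, cell_type: str) -> list:
        return [o for o, t in zip(self.obs_ids, self.cell_types) if t == cell_type]

    def types(self) -> list:
        return sorted(set(self.cell_types))


@dataclass
class GeneSet:
    """A named, ordered list of unique gene symbols."""

    name: str
    genes: list

    def __post_init__(self) -> None:
        self.genes = list(map(str, self.genes))
        if not self.name:
            raise ValueError("gene set needs a non-empty name")
        if len(self.genes) == 0:
            raise ValueError(f"gene set {self.name!r} is empty")
        _check_unique(self.genes, f"genes in set {self.name!r}")

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in set(self.genes)


@dataclass
class SurvivalRecord:
    """One patient's follow-up: (time, event) plus optional covariates."""

    sample_id: str
    time: float
    event: int
    covariates: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sample_id = str(self.sample_id)
        self.time = float(self.time)
        self.event = int(self.event)
        if not self.time > 0:
            raise ValueError(f"sample {self.sample_id!r}: time must be > 0, got {self.time}")
        if self.event not in (0, 1):
            raise ValueError(f"sample {self.sample_id!r}: event must be 0 or 1, got {self.event}")
        for k, v in self.covariates.items():
            if not np.isfinite(float(v)):
                raise ValueError(f"sample {self.sample_id!r}: covariate {k!r} is not finite")


def records_to_frame(records) -> pd.DataFrame:
    """Tabulate survival records (one row per sample, covariates as columns)."""
    rows = []
    for r in records:
        row = {"sample_id": r.sample_id, "time": r.time, "event": r.event}
        row.update(r.covariates)
        rows.append(row)
    return pd.DataFrame(rows)
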