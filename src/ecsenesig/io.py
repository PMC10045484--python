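"""Readers and writers for the standard formats the pipeline touches.

Supported formats
-----------------
* 10x-style MTX directory: ``matrix.mtx(.gz)`` (MatrixMarket coordinate,
  1-based), ``features.tsv(.gz)`` or ``genes.tsv(.gz)``, ``barcodes.tsv(.gz)``.
* Dense TSV expression table: gene rows x observation columns, header row of
  observation ids, first column of gene symbols.
* GMT gene sets (MSigDB dialect): ``name<TAB>description<TAB>gene...``.
* Clinical TSV with required columns ``sample_id``, ``time``, ``event``.

Gene identity is the bare symbol string, case-sensitive; duplicate symbols
are disambiguated deterministically with ``.1``, ``.2`` suffixes in file
order.  Readers either return a fully validated object or raise.
"""

from __future__ import annotations

import gzip
import logging
import os

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .types import CellAnnotation, ExpressionMatrix, GeneSet, SurvivalRecord

log = logging.getLogger(__name__)

__all__ = [
    "read_expression",
    "write_expression",
    "read_gmt",
    "write_gmt",
    "read_annotation",
    "write_annotation",
    "read_clinical",
    "write_clinical",
    "deduplicate_symbols",
]


def deduplicate_symbols(symbols) -> list:
    """Disambiguate duplicate gene symbols with ``.1``, ``.2`` ... in order."""
    counts: dict = {}
    out = []
    for s in symbols:
        s = str(s)
        k = counts.get(s, 0)
        out.append(s if k == 0 else f"{s}.{k}")
        counts[s] = k + 1
    return out


def _find_companion(directory: str, stems) -> str:
    for stem in stems:
        for suffix in ("", ".gz"):
            p = os.path.join(directory, stem + suffix)
            if os.path.exists(p):
                return p
    raise FileNotFoundError(
        f"missing companion file in {directory!r}: expected one of {list(stems)}"
    )


def _read_tsv_column(path: str, column: int = 0) -> list:
    opener = gzip.open if path.endswith(".gz") else open
    out = []
    with opener(path, "rt") as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if column >= len(fields):
                # fall back to the last available field (genes.tsv may have 1 col)
                out.append(fields[-1])
            else:
                out.append(fields[column])
    return out


def _read_mtx_dir(path: str) -> tuple:
    matrix_path = _find_companion(path, ("matrix.mtx",))
    features_path = _find_companion(path, ("features.tsv", "genes.tsv"))
    barcodes_path = _find_companion(path, ("barcodes.tsv",))
    if matrix_path.endswith(".gz"):
        with gzip.open(matrix_path, "rb") as fh:
            mat = scipy.io.mmread(fh)
    else:
        mat = scipy.io.mmread(matrix_path)
    if scipy.sparse.issparse(mat):
        mat = mat.toarray()
    mat = np.asarray(mat, dtype=np.float64)
    # 10x features.tsv carries (gene_id, symbol, type); use the symbol column
    symbols = _read_tsv_column(features_path, column=1)
    barcodes = _read_tsv_column(barcodes_path, column=0)
    if mat.shape != (len(symbols), len(barcodes)):
        raise ValueError(
            f"{matrix_path}: matrix shape {mat.shape} does not match "
            f"{len(symbols)} features x {len(barcodes)} barcodes"
        )
    return symbols, barcodes, mat


def _read_dense_tsv(path: str) -> tuple:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] == 0:
        raise ValueError(f"{path}: no observation columns found")
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        for col in df.columns:
            bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
            if bad.any():
                row = df.index[np.argmax(bad.to_numpy())]
                raise ValueError(
                    f"{path}: non-numeric entry at gene {row!r}, column {col!r}"
                )
        raise ValueError(f"{path}: non-numeric entries present")
    return list(df.index.astype(str)), list(df.columns.astype(str)), values.astype(np.float64)


def read_expression(path: str, format: str = "mtx_dir", layer: str = "counts",
                    dataset_id: str = "") -> ExpressionMatrix:
    """Read an expression matrix from a 10x MTX directory or a dense TSV.

    Duplicate gene symbols are suffixed ``.1``, ``.2`` in file order.  Negative
    or non-finite entries are rejected with the offending coordinate named.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if format == "mtx_dir":
        symbols, obs, values = _read_mtx_dir(path)
    elif format == "tsv":
        symbols, obs, values = _read_dense_tsv(path)
    else:
        raise ValueError(f"unknown format {format!r}")
    if np.any(values < 0):
        g, o = np.argwhere(values < 0)[0]
        raise ValueError(
            f"{path}: negative value at gene {symbols[g]!r} (row {g + 1}), "
            f"observation {obs[o]!r} (column {o + 1})"
        )
    gene_ids = deduplicate_symbols(symbols)
    if gene_ids != list(map(str, symbols)):
        n_dup = sum(a != str(b) for a, b in zip(gene_ids, symbols))
        log.warning("%s: disambiguated %d duplicate gene symbols", path, n_dup)
    return ExpressionMatrix(gene_ids=gene_ids, obs_ids=obs, values=values,
                            layer=layer, dataset_id=dataset_id or os.path.basename(path))


def write_expression(m: ExpressionMatrix, path: str, format: str = "mtx_dir") -> None:
    """Write an expression matrix as an MTX directory or a dense TSV."""
    if format == "mtx_dir":
        os.makedirs(path, exist_ok=True)
        scipy.io.mmwrite(os.path.join(path, "matrix.mtx"),
                         scipy.sparse.coo_matrix(m.values))
        with open(os.path.join(path, "features.tsv"), "w") as fh:
            for g in m.gene_ids:
                fh.write(f"{g}\t{g}\tGene Expression\n")
        with open(os.path.join(path, "barcodes.tsv"), "w") as fh:
            fh.write("\n".join(m.obs_ids) + "\n")
    elif format == "tsv":
        df = pd.DataFrame(m.values, index=m.gene_ids, columns=m.obs_ids)
        df.index.name = "gene_id"
        df.to_csv(path, sep="\t", float_format="%.10g")
    else:
        raise ValueError(f"unknown format {format!r}")


def read_gmt(path: str) -> list:
    """Parse a GMT file into a list of :class:`GeneSet`.

    Within-line duplicate genes are removed keeping the first occurrence.
    Lines with fewer than three fields raise with the line number.
    """
    sets = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{ln}: GMT line has {len(fields)} fields, need >= 3")
            name = fields[0]
            genes, seen = [], set()
            for g in fields[2:]:
                if g and g not in seen:
                    genes.append(g)
                    seen.add(g)
            sets.append(GeneSet(name=name, genes=genes))
    return sets


def write_gmt(sets, path: str, description: str = "na") -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.name, description] + list(s.genes)) + "\n")


def read_annotation(path: str, dataset_id: str = "") -> CellAnnotation:
    """Read a cell-type annotation TSV with columns ``obs_id``, ``cell_type``."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("obs_id", "cell_type"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    return CellAnnotation(obs_ids=list(df["obs_id"]), cell_types=list(df["cell_type"]),
                          dataset_id=dataset_id)


def write_annotation(ann: CellAnnotation, path: str) -> None:
    pd.DataFrame({"obs_id": ann.obs_ids, "cell_type": ann.cell_types}).to_csv(
        path, sep="\t", index=False)


def read_clinical(path: str) -> list:
    """Read a clinical TSV into survival records.

    Rows with missing time or event are dropped and the drop count logged.
    Non-positive times and events outside {0, 1} raise.  Extra numeric
    columns are carried along as covariates.
    """
    df = pd.read_csv(path, sep="\t")
    for col in ("sample_id", "time", "event"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    missing = df["time"].isna() | df["event"].isna()
    n_dropped = int(missing.sum())
    if n_dropped:
        log.warning("%s: dropped %d rows with missing time/event", path, n_dropped)
    df = df.loc[~missing]
    extra = [c for c in df.columns if c not in ("sample_id", "time", "event")]
    records = []
    for _, row in df.iterrows():
        cov = {}
        for c in extra:
            if pd.notna(row[c]):
                cov[c] = float(row[c])
        ev = float(row["event"])
        if ev not in (0.0, 1.0):
            raise ValueError(
                f"{path}: sample {row['sample_id']!r}: event must be 0 or 1, got {row['event']}")
        records.append(SurvivalRecord(sample_id=str(row["sample_id"]),
                                      time=float(row["time"]),
                                      event=int(ev),
                                      covariates=cov))
    if len({r.sample_id for r in records}) != len(records):
        raise ValueError(f"{path}: duplicate sample_ids")
    return records


def write_clinical(records, path: str) -> None:
    from .types import records_to_frame
    records_to_frame(records).to_csv(path, sep="\t", index=False, float_format="%.10g")
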