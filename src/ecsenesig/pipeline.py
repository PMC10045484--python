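"""The two end-to-end workflows.

``run_derive`` — per dataset: QC -> log-normalization -> senescence
enrichment scoring of the endothelial cells -> Gx (correlation evidence)
and Gy (marker evidence) -> Gn; then the cross-dataset geometric-mean
consensus signature.

``run_prognostic`` — bulk cohort: z-scored signature-gene expression ->
Cox coefficients (supplied or fit) -> linear risk score -> median split ->
Kaplan-Meier per group, log-rank test, Harrell's C.

Both runners write plain-text TSV outputs plus the exact configuration
(hash-stamped) and a one-line-per-stage log, and are fully deterministic
for a fixed configuration and inputs.
"""

from __future__ import annotations

import logging
import os

import numpy as np
import pandas as pd

from . import io as eio
from .config import PipelineConfig
from .enrichment import score_gene_set
from .markers import find_markers, gy_set
from .preprocess import lognormalize, qc_filter_cells
from .signature import ConsensusSignature, consensus, dataset_candidates, gx_set
from .survival import (CoxModel, concordance, cox_fit, dichotomize, km_estimate,
                       logrank_test, risk_score)
from .types import ExpressionMatrix, GeneSet, records_to_frame

log = logging.getLogger(__name__)

__all__ = ["derive_signature", "run_derive", "run_prognostic", "prognostic_evaluation"]

FLOAT_FMT = "%.10g"


def derive_signature(datasets, senescence_set: GeneSet,
                     config: PipelineConfig | None = None):
    """Library entry point for the signature derivation.

    ``datasets`` is a list of ``(ExpressionMatrix[counts], CellAnnotation)``
    pairs.  Returns ``(ConsensusSignature, [DatasetCandidates], [CorrelationResult])``.
    """
    config = config or PipelineConfig()
    candidates, correlations = [], []
    for matrix, ann in datasets:
        did = matrix.dataset_id or f"dataset{len(candidates) + 1}"
        filtered, report = qc_filter_cells(matrix, config.qc)
        log.info("derive[%s]: QC retained %d/%d cells", did,
                 report.n_retained, report.n_input)
        norm = lognormalize(filtered)
        kept = set(norm.obs_ids)
        sub_ann = type(ann)(
            obs_ids=[o for o in ann.obs_ids if o in kept],
            cell_types=[t for o, t in zip(ann.obs_ids, ann.cell_types) if o in kept],
            dataset_id=ann.dataset_id)
        scores = score_gene_set(norm, senescence_set, method=config.method,
                                kernel=config.kernel, tau=config.tau)
        gx, corr = gx_set(norm, sub_ann, scores, cell_type=config.endothelial_type,
                          max_fdr=config.max_fdr, min_cells_expr=config.min_cells_expr)
        marks = find_markers(norm, sub_ann, min_pct=config.min_pct,
                             min_logfc=config.min_logfc, max_fdr=config.max_fdr,
                             logfc_inclusive=config.logfc_inclusive)
        gy = gy_set(marks, cell_type=config.endothelial_type, dataset_id=did)
        cand = dataset_candidates(gx, gy, did)
        n_gn = 0 if cand.gn is None else len(cand.gn)
        log.info("derive[%s]: |Gx|=%d |Gy|=%d |Gn|=%d", did, len(gx), len(gy), n_gn)
        candidates.append(cand)
        correlations.extend(corr)
    sig = consensus(candidates, correlations, threshold=config.consensus_threshold,
                    min_support=config.min_support)
    log.info("derive: consensus signature has %d member genes", len(sig.members()))
    return sig, candidates, correlations


def _write_gene_set_tsv(genes, path: str) -> None:
    pd.DataFrame({"gene_id": sorted(genes)}).to_csv(path, sep="\t", index=False)


def run_derive(manifest, senescence_set: GeneSet, config: PipelineConfig,
               out_dir: str) -> ConsensusSignature:
    """Run the derivation workflow and write its outputs under ``out_dir``.

    ``manifest`` is a list of dicts with keys ``dataset_id``, ``matrix``
    (path to an MTX directory or TSV, or an in-memory matrix), ``format``
    (for paths), and ``annotation`` (path or in-memory annotation).
    """
    os.makedirs(out_dir, exist_ok=True)
    run_log = []
    datasets = []
    for entry in manifest:
        did = entry["dataset_id"]
        try:
            matrix = entry["matrix"]
            if isinstance(matrix, str):
                matrix = eio.read_expression(matrix, format=entry.get("format", "mtx_dir"),
                                             layer="counts", dataset_id=did)
            else:
                matrix.dataset_id = did
            ann = entry["annotation"]
            if isinstance(ann, str):
                ann = eio.read_annotation(ann, dataset_id=did)
        except Exception as e:
            raise RuntimeError(f"stage=load dataset={did}: {e}") from e
        run_log.append(f"load dataset={did} genes={matrix.n_genes} cells={matrix.n_obs}")
        datasets.append((matrix, ann))

    try:
        sig, candidates, correlations = derive_signature(datasets, senescence_set, config)
    except Exception as e:
        raise RuntimeError(f"stage=derive: {e}") from e

    for cand in candidates:
        _write_gene_set_tsv(cand.gx.genes, os.path.join(out_dir, f"gx_{cand.dataset_id}.tsv"))
        _write_gene_set_tsv(cand.gy.genes, os.path.join(out_dir, f"gy_{cand.dataset_id}.tsv"))
        gn_genes = [] if cand.gn is None else cand.gn.genes
        _write_gene_set_tsv(gn_genes, os.path.join(out_dir, f"gn_{cand.dataset_id}.tsv"))
        run_log.append(f"candidates dataset={cand.dataset_id} "
                       f"gx={len(cand.gx)} gy={len(cand.gy)} gn={len(gn_genes)}")
    corr_df = pd.DataFrame([vars(c) for c in correlations]).sort_values(
        ["dataset_id", "gene_id"], kind="stable")
    corr_df.to_csv(os.path.join(out_dir, "correlations.tsv"), sep="\t",
                   index=False, float_format=FLOAT_FMT)
    sig.to_tsv(os.path.join(out_dir, "signature.tsv"))
    run_log.append(f"consensus members={len(sig.members())} "
                   f"threshold={config.consensus_threshold} min_support={config.min_support}")
    config.write(os.path.join(out_dir, "config.yaml"))
    run_log.append(f"config_hash={config.config_hash()}")
    with open(os.path.join(out_dir, "run.log"), "w") as fh:
        fh.write("\n".join(run_log) + "\n")
    return sig


def prognostic_evaluation(expr: ExpressionMatrix, clinical, signature_genes,
                          coef: dict | None = None,
                          config: PipelineConfig | None = None) -> dict:
    """Library entry point for the prognostic stage.

    When ``coef`` is None, a multivariate Cox model over the (z-scored)
    signature genes is fit to the cohort; otherwise the supplied
    coefficients are used as-is.  Returns a dict with the fitted model,
    risk scores, group labels, KM estimates, log-rank result and C-index.
    """
    config = config or PipelineConfig()
    genes = list(signature_genes)
    missing = [g for g in genes if g not in set(expr.gene_ids)]
    if missing:
        raise ValueError(f"signature genes absent from expression matrix: {missing[:5]}")
    sample_ids = [r.sample_id for r in clinical]
    expr_sub = expr.subset_obs([s for s in sample_ids if s in set(expr.obs_ids)])
    if expr_sub.n_obs < len(sample_ids):
        lost = sorted(set(sample_ids) - set(expr_sub.obs_ids))
        raise ValueError(f"clinical samples absent from expression matrix: {lost[:5]}")

    if coef is None:
        from .survival import zscore_genes
        sub = expr_sub.subset_genes(genes)
        z = zscore_genes(sub) if config.zscore_expression else sub.values
        zmap = {s: z[:, j] for j, s in enumerate(sub.obs_ids)}
        fit_records = [
            type(r)(sample_id=r.sample_id, time=r.time, event=r.event,
                    covariates={g: float(zmap[r.sample_id][i]) for i, g in enumerate(genes)})
            for r in clinical
        ]
        model = cox_fit(fit_records, genes, ties=config.cox_ties)
    else:
        model = CoxModel(coef={g: float(coef[g]) for g in genes}, loglik=float("nan"),
                         converged=True, n_events=int(sum(r.event for r in clinical)))

    scores = risk_score(expr_sub, model, zscore=config.zscore_expression)
    groups, threshold = dichotomize(scores)
    km = {g: km_estimate([r for r in clinical if groups[r.sample_id] == g])
          for g in ("high", "low")}
    lr = logrank_test(clinical, groups)
    cindex = concordance(clinical, scores)
    return {"model": model, "scores": scores, "groups": groups,
            "threshold": threshold, "km": km, "logrank": lr, "c_index": cindex}


def run_prognostic(expr, clinical, signature_genes, coef: dict | None,
                   config: PipelineConfig, out_dir: str) -> dict:
    """Run the prognostic workflow and write its outputs under ``out_dir``."""
    os.makedirs(out_dir, exist_ok=True)
    if isinstance(expr, str):
        expr = eio.read_expression(expr, format="tsv", layer="lognorm")
    if isinstance(clinical, str):
        clinical = eio.read_clinical(clinical)
    res = prognostic_evaluation(expr, clinical, signature_genes, coef=coef, config=config)

    pd.DataFrame({
        "sample_id": [s.sample_id for s in res["scores"]],
        "score": [s.score for s in res["scores"]],
        "group": [res["groups"][s.sample_id] for s in res["scores"]],
    }).to_csv(os.path.join(out_dir, "risk_scores.tsv"), sep="\t", index=False,
              float_format=FLOAT_FMT)

    km_rows = []
    for g in ("high", "low"):
        km = res["km"][g]
        for t, n, d, s in zip(km.times, km.at_risk, km.events, km.survival):
            km_rows.append({"group": g, "time": t, "at_risk": n, "events": d, "survival": s})
    pd.DataFrame(km_rows).to_csv(os.path.join(out_dir, "km_curves.tsv"), sep="\t",
                                 index=False, float_format=FLOAT_FMT)

    lr = res["logrank"]
    pd.DataFrame([{
        "chi_square": lr.chi_square, "p": lr.p_value,
        "observed_high": lr.observed.get("high", np.nan),
        "expected_high": lr.expected.get("high", np.nan),
        "observed_low": lr.observed.get("low", np.nan),
        "expected_low": lr.expected.get("low", np.nan),
        "c_index": res["c_index"],
        "median_threshold": res["threshold"],
    }]).to_csv(os.path.join(out_dir, "logrank.tsv"), sep="\t", index=False,
               float_format=FLOAT_FMT)

    coefs = res["model"].coef
    pd.DataFrame({"gene_id": list(coefs), "coef": list(coefs.values())}).to_csv(
        os.path.join(out_dir, "coefficients.tsv"), sep="\t", index=False,
        float_format=FLOAT_FMT)

    config.write(os.path.join(out_dir, "config.yaml"))
    with open(os.path.join(out_dir, "run.log"), "w") as fh:
        fh.write(f"samples={len(clinical)} events={sum(r.event for r in clinical)}\n")
        fh.write(f"logrank chi_square={lr.chi_square:.6g} p={lr.p_value:.6g} "
                 f"c_index={res['c_index']:.6g}\n")
        fh.write(f"config_hash={config.config_hash()}\n")
    return res
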