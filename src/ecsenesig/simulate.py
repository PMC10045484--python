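"""Synthetic single-cell and bulk data with planted ground truth.

The single-cell generator emulates a multi-dataset tumor-microenvironment
study in which a latent endothelial-senescence program drives a planted
gene module:

* Every cell carries a **pan-lineage senescence activity** ``g ~ U(0, 1)``
  (senescence occurs in all lineages of the tumor microenvironment); for
  tumor endothelial cells (TEC) this same value is the **EC senescence
  activity** ``s``, which is zero elsewhere.
* The stand-in senescence readout set (the role the published
  senescence-up gene set plays on real data) responds to ``g`` in every
  cell type, so scoring it tracks senescence without being
  endothelial-enriched.
* The planted EC-senescence genes respond to ``s`` (i.e. only within TEC)
  and additionally carry an endothelial baseline shift, so they pass both
  the correlation (Gx) and the marker (Gy) filters.  A fraction of them is
  mixed into the readout set (``overlap_fraction``), mirroring the partial
  overlap between a senescence readout set and the signature derived from
  it.
* A matched set of **decoy genes** responds to ``g`` in all cell types but
  has no endothelial enrichment: decoys land in Gx yet must be excluded
  from Gn by the Gy filter.

Counts are negative binomial with per-cell log-normal library sizes; a
small block of ``MT-`` genes yields realistic mitochondrial fractions so
generated data exercise the QC stage.

The bulk generator draws a per-sample activity ``a ~ N(0, 1)``, loads it
onto the signature genes of a log-intensity expression table, and draws
exponential survival times with hazard ``baseline_hazard * exp(beta_true *
a)``; independent exponential censoring is calibrated by root finding to
hit the requested censoring fraction in expectation.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .types import CellAnnotation, ExpressionMatrix, GeneSet, SurvivalRecord

__all__ = [
    "SCSimConfig",
    "BulkSimConfig",
    "GroundTruth",
    "SCSimResult",
    "BulkSimResult",
    "simulate_sc",
    "simulate_bulk",
    "stage_seed",
]

DEFAULT_CELL_COUNTS = {"TEC": 300, "Tumor": 800, "CAF": 200, "Tcell": 400, "Myeloid": 300}


def stage_seed(seed: int, stage: str) -> int:
    """Derive a per-stage seed from the global seed by name hashing (< 2^31)."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


@dataclass
class SCSimConfig:
    n_datasets: int = 6
    cell_counts: dict = field(default_factory=lambda: dict(DEFAULT_CELL_COUNTS))
    n_genes: int = 2000
    n_senescence_set: int = 50
    n_planted_ec: int = 40
    n_decoy: int = 40
    effect: float = 1.0            # log-expression shift per unit latent senescence
    marker_shift: float = 4.0      # EC baseline fold change of planted genes
    nb_dispersion: float = 3.0     # NB size r; var = mu + mu^2 / r
    libsize_sigma: float = 0.35    # sd of log library-size factor
    overlap_fraction: float = 0.2  # fraction of the readout set drawn from planted genes
    n_mito: int = 10
    mito_fraction: float = 0.05    # expected mitochondrial share of counts
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_datasets < 1:
            raise ValueError("n_datasets must be >= 1")
        if any(v <= 0 for v in self.cell_counts.values()):
            raise ValueError("all cell counts must be positive")
        n_overlap = round(self.overlap_fraction * self.n_senescence_set)
        n_special = (self.n_senescence_set - n_overlap) + self.n_planted_ec + self.n_decoy
        if n_special + self.n_mito > self.n_genes:
            raise ValueError("gene budget too small for the requested special sets")
        if not (0 <= self.overlap_fraction <= 1):
            raise ValueError("overlap_fraction must be in [0, 1]")
        if self.nb_dispersion <= 0 or self.marker_shift <= 0:
            raise ValueError("nb_dispersion and marker_shift must be positive")


@dataclass
class BulkSimConfig:
    n_samples: int = 500
    n_genes: int = 300
    n_signature: int = 37
    beta_true: float = 0.7         # log hazard ratio per unit activity
    baseline_hazard: float = 0.05
    censor_rate: float = 0.3
    noise_sd: float = 1.0
    loading: float = 1.0
    baseline_level: float = 8.0    # log-intensity scale of the expression table
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.censor_rate < 1):
            raise ValueError("censor_rate must be in [0, 1)")
        if self.n_signature > self.n_genes:
            raise ValueError("n_signature cannot exceed n_genes")
        if self.baseline_hazard <= 0 or self.noise_sd < 0:
            raise ValueError("baseline_hazard must be > 0 and noise_sd >= 0")


@dataclass
class GroundTruth:
    """Planted truth recorded for every generated observation."""

    cells: pd.DataFrame | None = None      # dataset_id, obs_id, cell_type, ec_senescence, pan_senescence
    planted_genes: list | None = None
    decoy_genes: list | None = None
    readout_genes: list | None = None
    samples: pd.DataFrame | None = None    # sample_id, activity, linear_predictor


@dataclass
class SCSimResult:
    datasets: list                  # [(ExpressionMatrix[counts], CellAnnotation), ...]
    truth: GroundTruth
    senescence_set: GeneSet         # the stand-in readout set


@dataclass
class BulkSimResult:
    expression: ExpressionMatrix    # genes x samples, log-intensity scale
    clinical: list                  # [SurvivalRecord, ...]
    truth: GroundTruth
    signature: GeneSet


def _gene_architecture(config: SCSimConfig, rng: np.random.Generator):
    """Pick gene names, special-gene index sets, and base mean expression."""
    gene_ids = [f"MT-{i + 1}" for i in range(config.n_mito)]
    gene_ids += [f"G{i + 1:04d}" for i in range(config.n_genes - config.n_mito)]
    non_mito = np.arange(config.n_mito, config.n_genes)

    n_overlap = round(config.overlap_fraction * config.n_senescence_set)
    n_pure_readout = config.n_senescence_set - n_overlap
    n_special = config.n_planted_ec + n_pure_readout + config.n_decoy
    special = rng.choice(non_mito, size=n_special, replace=False)
    planted = np.sort(special[:config.n_planted_ec])
    pure_readout = np.sort(special[config.n_planted_ec:config.n_planted_ec + n_pure_readout])
    decoy = np.sort(special[config.n_planted_ec + n_pure_readout:])
    overlap = rng.choice(planted, size=n_overlap, replace=False) if n_overlap else np.array([], dtype=int)
    readout = np.sort(np.concatenate([pure_readout, overlap]).astype(int))

    base = rng.lognormal(mean=np.log(1.5), sigma=1.0, size=config.n_genes)
    program = np.concatenate([planted, pure_readout, decoy]).astype(int)
    base[program] = rng.lognormal(mean=np.log(2.0), sigma=0.4, size=program.size)
    # mitochondrial block sized to hit the target share of total counts
    non_mito_total = base[config.n_mito:].sum()
    f = config.mito_fraction
    base[:config.n_mito] = f / (1 - f) * non_mito_total / config.n_mito
    return gene_ids, planted, readout, decoy, base


def simulate_sc(config: SCSimConfig) -> SCSimResult:
    """Generate ``n_datasets`` single-cell count matrices with planted truth.

    The gene architecture (which genes are planted / readout / decoy) is
    shared across datasets, as gene identity must be for a cross-dataset
    consensus; baseline expression and all counts are redrawn per dataset.
    """
    arch_rng = np.random.default_rng(stage_seed(config.seed, "sc-architecture"))
    gene_ids, planted_idx, readout_idx, decoy_idx, _ = _gene_architecture(config, arch_rng)
    gene_arr = np.array(gene_ids, dtype=object)
    planted_genes = [str(g) for g in gene_arr[planted_idx]]
    readout_genes = [str(g) for g in gene_arr[readout_idx]]
    decoy_genes = [str(g) for g in gene_arr[decoy_idx]]

    cell_rows = []
    datasets = []
    r = config.nb_dispersion
    for d in range(config.n_datasets):
        dataset_id = f"sim{d + 1}"
        rng = np.random.default_rng(stage_seed(config.seed, f"sc-dataset-{d}"))
        # per-dataset baseline expression, shared special-gene architecture
        base = rng.lognormal(mean=np.log(1.5), sigma=1.0, size=config.n_genes)
        program = np.concatenate([planted_idx, readout_idx, decoy_idx])
        base[program] = rng.lognormal(mean=np.log(2.0), sigma=0.4, size=program.size)
        non_mito_total = base[config.n_mito:].sum()
        f = config.mito_fraction
        base[:config.n_mito] = f / (1 - f) * non_mito_total / config.n_mito

        cell_types = []
        for ct, n in config.cell_counts.items():
            cell_types += [ct] * n
        n_cells = len(cell_types)
        obs_ids = [f"{dataset_id}-c{i + 1:05d}" for i in range(n_cells)]
        is_tec = np.array([ct == "TEC" for ct in cell_types])

        g_act = rng.uniform(0.0, 1.0, size=n_cells)   # pan-lineage senescence
        s_act = np.where(is_tec, g_act, 0.0)          # EC senescence (TEC only)
        libsize = rng.lognormal(mean=0.0, sigma=config.libsize_sigma, size=n_cells)

        mu = np.outer(base, libsize)
        mu[readout_idx] *= np.exp(config.effect * g_act)[None, :]
        mu[decoy_idx] *= np.exp(config.effect * g_act)[None, :]
        # planted genes: EC-specific senescence response + EC baseline shift
        planted_factor = np.where(is_tec, config.marker_shift * np.exp(config.effect * s_act), 1.0)
        overlap_set = set(readout_idx.tolist())
        pure_planted = np.array([i for i in planted_idx if i not in overlap_set], dtype=int)
        mu[pure_planted] *= planted_factor[None, :]
        # overlap genes are planted genes inside the readout set: replace the
        # pan-lineage response applied above with the EC-specific one
        overlap_idx = np.array([i for i in planted_idx if i in overlap_set], dtype=int)
        if overlap_idx.size:
            mu[overlap_idx] /= np.exp(config.effect * g_act)[None, :]
            mu[overlap_idx] *= planted_factor[None, :]

        counts = rng.negative_binomial(n=r, p=r / (r + mu)).astype(np.float64)
        matrix = ExpressionMatrix(gene_ids=gene_ids, obs_ids=obs_ids, values=counts,
                                  layer="counts", dataset_id=dataset_id)
        ann = CellAnnotation(obs_ids=obs_ids, cell_types=cell_types, dataset_id=dataset_id)
        datasets.append((matrix, ann))
        cell_rows.append(pd.DataFrame({
            "dataset_id": dataset_id, "obs_id": obs_ids, "cell_type": cell_types,
            "ec_senescence": s_act, "pan_senescence": g_act,
        }))

    truth = GroundTruth(cells=pd.concat(cell_rows, ignore_index=True),
                        planted_genes=planted_genes, decoy_genes=decoy_genes,
                        readout_genes=readout_genes)
    senescence_set = GeneSet(name="SENESCENCE.STANDIN", genes=readout_genes)
    return SCSimResult(datasets=datasets, truth=truth, senescence_set=senescence_set)


def _calibrate_censor_rate(rates: np.ndarray, target: float) -> float:
    """Exponential censoring rate c with mean_i c/(c + lambda_i) = target."""
    def frac(c):
        return float(np.mean(c / (c + rates))) - target
    lo, hi = 1e-12, float(rates.max())
    while frac(hi) < 0:
        hi *= 10
        if hi > 1e12:
            raise RuntimeError("censoring calibration failed")
    return brentq(frac, lo, hi)


def simulate_bulk(config: BulkSimConfig) -> BulkSimResult:
    """Generate one bulk cohort whose hazard is log-linear in a latent activity."""
    rng = np.random.default_rng(stage_seed(config.seed, "bulk"))
    gene_ids = [f"BG{i + 1:04d}" for i in range(config.n_genes)]
    sig_idx = np.sort(rng.choice(config.n_genes, size=config.n_signature, replace=False))
    sig_genes = [gene_ids[i] for i in sig_idx]
    sample_ids = [f"s{i + 1:04d}" for i in range(config.n_samples)]

    a = rng.normal(0.0, 1.0, size=config.n_samples)
    expr = config.baseline_level + rng.normal(0.0, config.noise_sd,
                                              size=(config.n_genes, config.n_samples))
    expr[sig_idx] += config.loading * a[None, :]
    expr = np.clip(expr, 0.0, None)

    rates = config.baseline_hazard * np.exp(config.beta_true * a)
    t_event = rng.exponential(1.0 / rates)
    if config.censor_rate > 0:
        c_rate = _calibrate_censor_rate(rates, config.censor_rate)
        t_censor = rng.exponential(1.0 / c_rate, size=config.n_samples)
        time = np.minimum(t_event, t_censor)
        event = (t_event <= t_censor).astype(int)
    else:
        time = t_event
        event = np.ones(config.n_samples, dtype=int)
    time = np.maximum(time, 1e-9)

    records = [SurvivalRecord(sample_id=s, time=float(t), event=int(e),
                              covariates={"activity": float(av)})
               for s, t, e, av in zip(sample_ids, time, event, a)]
    matrix = ExpressionMatrix(gene_ids=gene_ids, obs_ids=sample_ids, values=expr,
                              layer="lognorm", dataset_id="bulk-sim")
    truth = GroundTruth(samples=pd.DataFrame({
        "sample_id": sample_ids, "activity": a,
        "linear_predictor": config.beta_true * a,
    }))
    return BulkSimResult(expression=matrix, clinical=records, truth=truth,
                         signature=GeneSet(name="BULK.SIGNATURE", genes=sig_genes))
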