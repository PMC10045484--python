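# ecsenesig

Derivation and prognostic evaluation of a tumor-endothelial senescence gene
signature from transcriptomic data.

Senescent tumor endothelial cells (TEC) adopt a pro-inflammatory secretory
phenotype that reshapes the tumor microenvironment and correlates with poor
outcomes across solid cancers. This package implements the full analysis
chain for studying that program computationally, for bioinformaticians
working with multi-cohort single-cell and bulk RNA-seq:

1. **Single-sample enrichment scoring** — a GSVA-style rank random-walk
   statistic assigns every cell (or bulk sample) an enrichment score for a
   senescence gene set.
2. **Consensus signature derivation** — per dataset, genes positively
   correlated with the senescence score in endothelial cells (Spearman
   ρ > 0, BH FDR < 0.05; set *Gx*) are intersected with endothelial marker
   genes (Wilcoxon one-vs-rest, pct ≥ 0.25, log2FC > 0.25, FDR < 0.05; set
   *Gy*) to give candidates *Gn*. Across datasets, a gene enters the
   consensus signature when the geometric mean of its correlation
   coefficients, (∏_d ρ_d)^(1/k) over the k datasets where it qualified,
   exceeds 0.2.
3. **Prognostic stage** — a linear Cox risk score over signature genes,
   score_j = Σ_g β_g · z_gj (z = per-gene z-scored expression), median
   dichotomization into high/low-risk groups, Kaplan–Meier curves, the
   log-rank test and Harrell's C. The Cox model is fit by Newton–Raphson on
   the Breslow tie-corrected partial likelihood (Efron optional).
4. **Synthetic data with planted truth** — a negative-binomial single-cell
   generator with a latent senescence activity driving a planted endothelial
   gene program (plus pan-lineage decoy genes), and a bulk generator whose
   hazard is log-linear in a latent activity, so every stage of the pipeline
   is testable end to end without external downloads.

Inputs are plain formats: 10x-style MTX directories or dense TSV expression
tables (genes × observations), GMT gene sets, and clinical TSVs
(`sample_id`, `time`, `event`).

## Worked example

Generate two synthetic single-cell datasets, derive the signature, then
evaluate a planted bulk cohort:

```sh
ecsenesig simulate-sc --seed 5 --out work/sc
ecsenesig derive-signature --datasets work/sc/manifest.tsv \
    --senescence-gmt work/sc/senescence.gmt --seed 5 --out work/sig
ecsenesig simulate-bulk --seed 5 --out work/bulk
ecsenesig survival --expr work/bulk/expression.tsv \
    --clinical work/bulk/clinical.tsv \
    --signature work/bulk/signature.gmt --out work/surv
```

which prints, for example:

```
signature members: 9 (outputs in work/sig)
log-rank chi2=118.5 p=1.335e-27 C=0.7069 (outputs in work/surv)
```

`work/sig/signature.tsv` lists each candidate gene with its per-dataset
Spearman coefficients, geometric mean, dataset support and membership flag;
`work/surv/` contains the per-sample risk scores and groups, the KM tables
per group, and the log-rank/C-index summary. The log-rank χ² of 118.5
(p ≈ 10⁻²⁷) says the median split of the fitted risk score separates
survival strongly — as it must here, since the generator planted a log
hazard ratio of 0.7 per unit of latent activity; C ≈ 0.71 is the fraction
of usable patient pairs where the higher-risk patient died earlier.

The same stages are available as a library:

```python
from ecsenesig import (SCSimConfig, simulate_sc, PipelineConfig,
                       derive_signature)

sim = simulate_sc(SCSimConfig(seed=1))
sig, candidates, correlations = derive_signature(
    sim.datasets, sim.senescence_set, PipelineConfig(seed=1))
print(len(sig.members()))   # 40 — the planted program, fully recovered
```

## Layout

- `src/ecsenesig/io.py` — MTX/TSV/GMT/clinical readers and writers
- `src/ecsenesig/preprocess.py` — cell QC and log1p-CP10K normalization
- `src/ecsenesig/enrichment.py` — rank random-walk enrichment scores, median split
- `src/ecsenesig/markers.py` — Wilcoxon one-vs-rest marker detection (Gy)
- `src/ecsenesig/signature.py` — Spearman/BH, Gx, Gn, geometric-mean consensus
- `src/ecsenesig/survival.py` — Cox (Breslow/Efron), risk score, KM, log-rank, C
- `src/ecsenesig/simulate.py` — planted-truth single-cell and bulk generators
- `src/ecsenesig/pipeline.py`, `config.py`, `cli.py` — workflows, config, CLI
- `docs/methods.md` — model assumptions, parameter choices, limitations
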