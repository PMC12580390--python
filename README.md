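# spatialtme

Spatial tumor-microenvironment analysis of multiplex immunofluorescence
(mIF) cell tables, built around the question: *does the spatial coupling
between cancer-associated fibroblasts (CAFs) and tumor-associated
endothelial cells (TAECs) predict pathological response to neoadjuvant
therapy in non-small cell lung cancer?*

It is a library for analysts working with per-cell exports from mIF
platforms (one row per segmented cell: centroid in μm plus binary marker
positivity for CK, α-SMA, CD31, PD-L1, PD-1), taking them from raw tables
to cohort-level inference without touching the images.

## What it computes

**Phenotype gating.** CAF = α-SMA⁺/CK⁻, TAEC = CD31⁺/CK⁻, tumor = CK⁺,
else "other". Rules are ordered; double positives resolve to the first
matching rule deterministically.

**Spatial metrics**, per core and aggregated per patient:

- *density*: 1000 · n(phenotype) / n(cells) — also used for PD-L1⁺/PD-1⁺
  cell counts;
- *mean NND*: (1/n_CAF) Σᵢ minⱼ ‖xᵢ − yⱼ‖, the mean over CAFs of the
  Euclidean distance (μm) to the nearest TAEC;
- *proximity(r)*: #{i : minⱼ ‖xᵢ − yⱼ‖ ≤ r}, the number of CAFs with at
  least one TAEC within r = 30 μm (a plausible range for direct or
  paracrine cell–cell interaction).

**Cohort statistics**: Yates-corrected χ² / Fisher exact tests on response
tables (Fisher whenever an expected count is < 5), exact and asymptotic
Mann-Whitney U comparisons, median (Q1, Q3) summaries, median-split
univariate odds ratios with Wald CIs, and empirical ROC curves with
trapezoidal AUC (= the concordance U-statistic) and Youden-optimal cutoff.

**Synthetic cohorts**: cores as point patterns with vessel-like clustered
TAECs and a coupling fraction κ of CAFs placed at Gaussian offsets
(σ = 15 μm) from TAECs; responder groups differ only in their κ
distribution. This provides the ground truth for every validation in the
test suite.

## Worked example

`examples/03_response_tables.py` runs the categorical dispatch on the
published response counts (rows: response yes/no; columns: squamous vs
adenocarcinoma):

```
MPR, full cohort (50.0% vs 22.4%): yates_chi2, p = 0.006
MPR, chemoimmunotherapy (72.7% vs 30.8%): yates_chi2, p = 0.038
pCR, full cohort: yates_chi2, p = 0.025
pCR, chemoimmunotherapy: fisher_exact, p = 0.150
ORR, full cohort: yates_chi2, p = 0.301
```

Squamous tumors reach major pathological response (MPR, ≤10% viable tumor
cells) more often than adenocarcinomas, while the radiologic response rate
(ORR) does not differ. `examples/04_roc_biomarker.py` evaluates the
nearest-neighbor distance as a response predictor on a 7-responder /
4-non-responder ordering with exactly three discordant pairs:

```
AUC = 0.893
sensitivity = 0.857, specificity = 1.000
Mann-Whitney (asymptotic) p = 0.038
```

`examples/05_full_pipeline.py` runs the whole cascade on a synthetic
11-patient cohort in which responders have weaker CAF–TAEC coupling, and
prints the group comparison (responders: median NND 35.4 μm vs 22.0 μm,
p = 0.006) plus the ROC summary. The other examples cover gating and the
per-core metrics; the `spatialtme` CLI (`simulate`, `phenotype`,
`metrics`, `compare`, `roc`, `run`) exposes the same steps from a shell.

## Layout

- `src/spatialtme/cell_model.py` — parsing, validation, phenotype rules
- `src/spatialtme/spatial_metrics.py` — density, NND, proximity, per-patient aggregation
- `src/spatialtme/cohort_stats.py` — contingency, rank tests, OR, ROC
- `src/spatialtme/synthetic_cohort.py` — point-pattern and cohort simulation
- `src/spatialtme/pipeline.py`, `cli.py` — orchestration and the thin CLI
- `docs/methods.md` — models, parameter choices, numerical conventions, limitations
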