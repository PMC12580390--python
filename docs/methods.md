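# Methods

## Setting and data model

The package analyzes per-cell tables exported from multiplex
immunofluorescence imaging of tissue-microarray (TMA) cores: each row is a
segmented, DAPI⁺ cell with a centroid in μm and binary positivity for CK
(epithelium), α-SMA (fibroblast), CD31 (endothelium), PD-L1 and PD-1.
Images, spectral unmixing and segmentation are upstream and out of scope;
coordinates are taken as exported (origin top-left, y increasing downward —
distances are unaffected by the origin convention). A configurable scale
factor is available if an exporter emits pixels, but no conversion happens
by default.

Phenotypes are assigned by marker-combination rules applied in priority
order: CAF = α-SMA⁺/CK⁻, TAEC = CD31⁺/CK⁻, tumor = CK⁺, remainder
"other". The gating platform's own resolution of multi-phenotype cells is
not documented anywhere we could follow, so we make no attempt to guess
it: a cell matching several rules takes the first match (default order
CAF, TAEC, tumor — configurable), and the count of such conflicted cells
is reported so the choice is auditable. Gating is idempotent and, with the
default rules plus "other", a partition.

## Spatial metrics

Three per-core quantities, the study's measurement layer:

- **Density per 1000 cells** — 1000 · n(phenotype)/n(total). PD-L1/PD-1
  "expression" is the same quantity on marker-positive cells. An empty
  core has *undefined* density, not zero.
- **Mean nearest-neighbor distance (NND)** — mean over CAFs of the
  Euclidean distance to the closest TAEC, in μm. Computed with a k-d tree
  (`scipy.spatial.cKDTree`), which is exact; the test suite additionally
  pins it to an all-pairs brute-force oracle.
- **Proximity(r)** — number of CAFs whose nearest TAEC lies within
  r = 30 μm. "Within" is inclusive (≤ 30.0): a neighbor exactly on the
  circle counts.

No edge correction is applied: cells near core borders keep their observed
nearest neighbor. This matches the measurement the analysis is modeled on
and keeps per-core values directly comparable; the bias it introduces is
shared by all cores of similar geometry.

Undefined metrics (no CAFs, or no TAECs, in a core) propagate as explicit
undefined values and never as 0 — a zero would fake maximal proximity.
Cores with undefined values are simply excluded from that metric's
patient-level aggregate, with the number of contributing cores recorded.

**Core→patient aggregation.** How multiple cores collapse to one patient
value is not specified by the workflow we emulate, so all three defensible
rules are implemented and recorded in the output: unweighted mean over
defined cores (default), cell-count-weighted mean, and pooling all cores
into one point set (cores are offset far apart so no cross-core pair can
become a nearest neighbor). The default is the unweighted mean because TMA
cores are deliberately sized comparably.

**Proximity normalization.** Published per-patient proximity values of
order 1–5 are far below any plausible raw CAF count, so some unreported
normalization was applied there. We emit both the raw definitional count
and a per-1000-cells variant, and do not attempt to match those printed
magnitudes.

## Cohort statistics

- **Categorical tests.** Pearson χ² with df = (r−1)(c−1); for 2×2 tables
  the Yates continuity correction by default, switching to Fisher's exact
  test (two-sided by the point-probability rule) when any expected count
  is < 5. This dispatch is the convention that reproduces the published
  response-table p-values (0.006 / 0.038 / 0.025 / 0.301 with Yates,
  0.150 with Fisher — plain Pearson reproduces none of them). χ² and
  Fisher are delegated to `scipy.stats`; the Fisher p is pinned in tests
  to a full hypergeometric enumeration oracle.
- **Mann-Whitney U.** U from midranks. Exact mode: the classical counting
  recursion on the U distribution when the pooled sample has no ties, and
  full enumeration of group assignments (feasible to n₁+n₂ = 12) with
  ties; two-sided p is the probability of |U − n₁n₂/2| at least as large
  as observed. Asymptotic mode: tie-corrected normal approximation with
  *no* continuity correction — the variant that yields the published
  p = 0.038 for U = 3 at group sizes (7, 4). `auto` uses exact for
  n₁+n₂ ≤ 12 without ties, else asymptotic. Degenerate data (all values
  identical) returns p = 1 with a warning rather than an error.
- **Summaries.** Median (Q1, Q3); quartiles by linear interpolation
  (default) or the (n+1)p weighted-average rule, selectable because
  different stats packages print different quartiles for small n.
- **Dichotomization and odds ratios.** Continuous predictors are split at
  the sample median of the analyzed subset; values equal to the cut go to
  "high" (deterministic, documented). OR = ad/bc from the 2×2
  cross-tabulation, 95% CI exp(ln OR ± 1.96·SE) with
  SE = √(1/a+1/b+1/c+1/d), p from the Wald z; a zero cell triggers the
  Haldane–Anscombe +0.5 correction on all cells and is flagged. The CI
  construction used for the published OR 36.00 (2.68–1486.88) is unknown
  and the underlying 2×2 split is unpublished, so the Wald CI here is a
  method implementation, not a value reproduction.
- **ROC.** Empirical curve over all distinct thresholds (predict positive
  when score ≥ t). The trapezoidal AUC is cross-checked at run time
  against the concordance identity AUC = (concordant + ½ ties)/(n₊·n₋);
  disagreement raises. If the raw AUC is below 0.5 the score is negated
  and the flip recorded. The Youden-optimal point maximizes
  sensitivity + specificity − 1 with ties broken toward higher
  specificity.

All tests are two-sided at α = 0.05. No multiple-testing correction is
applied; the run manifest records how many tests a pipeline run performed
so readers can judge the family size.

## Synthetic cohorts

The generator produces the statistical structure the pipeline assumes,
not biophysically realistic tissue:

- **Core geometry**: 1000 × 1000 μm, 2000 cells by default — within the
  plausible range for TMA cores (0.6–1.5 mm, 10²–10⁴ cells). Compartment
  counts are multinomial at configured fractions (defaults CAF 0.45,
  TAEC 0.12, tumor 0.30, other 0.13, chosen so densities per 1000 fall in
  the few-hundred range typical of stroma-rich tumor regions).
- **TAECs**: homogeneous Poisson, or (default) a Thomas-style cluster
  process — 25 uniform parents, Gaussian offspring scatter of 30 μm —
  mimicking vessel cross-sections.
- **CAF–TAEC coupling**: a fraction κ ∈ [0, 1] of CAFs is placed at a
  uniformly chosen TAEC plus an isotropic Gaussian offset (σ = 15 μm,
  rejection-resampled into bounds); the rest are uniform. κ is the single
  effect dial: sweeping it moves the mean NND monotonically through
  roughly 13–68 μm under the clustered default (17–33 μm under Poisson
  TAECs), covering the range observed in real cores. The coupling
  mechanism itself is a modeling choice — only summary statistics of the
  real patterns are known.
- **Cohorts**: patients carry regimen (chemoimmunotherapy/chemotherapy),
  histology (squamous/adeno) and ORR/MPR/pCR flags assigned as exact
  counts from a configured rate table (deterministic rounding, pCR ⊆
  MPR), so the scaffold presets reproduce the published group sizes
  exactly; only spatial structure and κ are stochastic. Per-patient κ is
  Beta-distributed by response group: responders Beta(6, 4) (mean 0.60 →
  patient NND around 35 μm), non-responders Beta(17, 3) (mean 0.85 →
  around 22 μm). This places both group medians inside the observed
  17–35 μm band with the responder group higher, at an effect size a
  7-vs-4 comparison detects most of the time — deliberately a clear
  effect, not a calibration to the published medians, which the proximity
  normalization issue above makes unmatchable anyway.
- **Seeding**: one master seed; every patient/core stream derives from
  `SeedSequence(master, patient_index[, core_index])`, so any piece of a
  cohort regenerates independently and runs are bit-reproducible.

What the generator does *not* emulate: real vessel topology, cell-size
exclusion effects, staining intensity distributions, batch effects, or
core-to-core heterogeneity within a patient beyond sampling noise.
Passing tests therefore certify the *measurement and inference machinery*
on known ground truth — they do not certify that real cohorts carry the
simulated effect.

## Validation strategy

Patient-level results (metric medians, the published OR CI) cannot be
reproduced because the per-patient data are unpublished. Validation
instead uses:

1. arithmetic the published tables fully determine (contingency
   p-values at printed precision; the AUC/sensitivity/specificity/p
   triple, which a 7-vs-4 design with 3 discordant pairs fixes exactly);
2. independent oracles — brute-force nearest neighbors, hypergeometric
   and permutation enumeration, the concordance identity, closed forms
   for Poisson patterns (E[NND] = 1/(2√λ); P(neighbor ≤ r) =
   1 − exp(−λπr²)) within 3 Monte-Carlo SE;
3. simulation calibration — null cohorts (identical κ distributions)
   give a rank-test rejection rate within 3 binomial SE of α = 0.05 over
   500 replicates; at the configured effect size the group-difference
   sign is recovered in ≥90% of replicates. Calibration replicates use
   300–400-cell single-core patients, which keeps the whole suite under
   a minute without changing what is being tested.

## Limitations

- The 30 μm radius and all defaults are conventions of the emulated
  workflow, not optimized values.
- The exact-with-ties Mann-Whitney is combinatorial and restricted to
  n₁+n₂ ≤ 12; larger tied samples use the asymptotic branch.
- Wald CIs for odds ratios are anti-conservative in tiny samples; with
  7-vs-4 groups they should be read as descriptive.
- No survival/time-to-event layer, no multivariable models, and no
  border-corrected spatial statistics (Ripley's K etc.) — deliberately
  out of scope.
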