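# Methods

This note records the models and procedures implemented in `spatialpheno`,
the parameters that matter, the choices made where the design was open, and
what the synthetic benchmarks do and do not establish.

## Spatial phenotyping from cell tables

**Input model.** A cell table holds one row per segmented cell: sample,
stamp (a 670 × 502 µm² field of view; area 0.33634 mm²), region (border =
invasive margin, ~50% tumoral / 50% peritumoral tissue; center), tumor or
stroma compartment, marker, and µm coordinates with a per-stamp local
origin. Stamps are disjoint fields of view: no distance is defined across
stamps.

**Densities.** The default density estimate pools counts over stamps:
λ(marker, region) = total count / (n_stamps × 0.33634 mm²). A per-stamp
median variant (`method="stamp-median"`, median over stamps of per-stamp
density, zero-count stamps included) is provided because the upstream
description of "median CD8+ T cell density" is ambiguous between the two
readings; pooled is the default since enumerations are summarized over all
stamps per sample, and for homogeneous patterns the two estimators agree in
expectation. Samples with fewer than 3 stamps at either region are flagged
and receive no phenotype call; a region with zero stamps yields missing
(NaN) densities, never zero.

**Digital assignment.** CD8 density at border and center (tumor + stroma
combined; compartment-resolved densities are still reported) is thresholded:

| rule | call |
|---|---|
| border > 200 cells/mm² and border/center < 10 | inflamed |
| border > 200 cells/mm² and border/center > 10 | excluded |
| border < 150 and center < 150 cells/mm² | ignored |

A zero center density gives a ratio of +∞ (the limiting behavior of the
rule), hence *excluded* when the border clears 200. The three predicates
are mutually exclusive but not exhaustive: a border density in [150, 200],
a low border with center ≥ 150, or a ratio of exactly 10 match no rule.
Such scans return `unassigned` with a machine-readable reason; we refuse to
guess what an unstated convention would have done, and the mutual
exclusivity plus gap behavior is property-tested over a dense density grid.

**Manual-scoring mirror.** The count-based rule (excluded when border has
> 10× the center count; ignored when both counts are "hardly any") needs a
numeric reading of "hardly any"; we use < 10 cells per region, configurable,
as a round single-field count that is clearly negligible at these stamp
areas. Remaining cases are inflamed (near-equal frequencies).

**Neighbor statistics.** Counts within a radius use a closed ball
(d ≤ 10 µm by default) — the boundary convention is asserted in tests — with
the reference cell excluded from its own neighborhood; nearest-neighbor
distances to a target marker are per-stamp, with self-exclusion when
reference and target markers coincide. Both are implemented with k-d trees
and verified against all-pairs brute force on ≤ 500-cell instances.

## The rank-correlation gene classifier

**Selection.** For each phenotype p, a gene is a p-signature gene when
mean_p − mean_q > 1 log2 unit for *each* other phenotype q, and both
pairwise Welch t-tests reach BH-adjusted p < 0.05 (adjustment per contrast
across all genes). The all-pairwise reading produces the mutually exclusive
tri-block signature structure; a one-vs-rest contrast is available behind
`ClassifierConfig(contrast="one-vs-rest")` since the original contrast
design is not recoverable. Per-gene Welch tests with BH stand in for a
moderated linear-model DE fit; on log-scale data with ≥ 30 samples per
group the selection boundary is equivalent to first order, and the
moderated fit belongs to the upstream ecosystem rather than this package.

**Centroids and assignment.** Signature-gene expressions are averaged per
phenotype and each centroid vector is rank-transformed (average ranks for
ties; ascending, highest expression → highest rank — any consistent
direction yields identical assignments, asserted by test). An unknown
sample's raw values are Spearman-correlated against each phenotype's rank
vector (value-vs-rank and rank-vs-rank are equivalent under Spearman; the
convention is fixed for bit-reproducibility), and the argmax wins. Samples
are left unassigned when: the top two correlations agree within
`tie_epsilon` (default 1e-12 — "equally high" read as exact ties up to
floating point); fewer than 50% of classifier genes are available (pairwise
deletion above that floor, consistent with an upstream QC that required
samples to express > 75% of classifier genes); or the sample is constant
across classifier genes (ρ undefined).

`spearman_rho` is Pearson on average ranks, clipped to [−1, 1]; it is
oracle-tested against an independent Pearson-on-ranks computation and
against `scipy.stats.spearmanr` to 1e-12, including tied inputs.

## Evaluation statistics

**Confusion conventions.** Rows are staining-derived truth, columns
classifier calls, fixed order (excluded, ignored, inflamed).
Sensitivity_k = diagonal/row total. The quantity clinical validation
tables label "Specificity" is mathematically the column precision
(diagonal/column total): all six published values match precision and none
match 1 − FPR, so the package exposes it as `specificity_paper` and reports
textbook one-vs-rest specificity separately as `specificity_true`. Zero
margins yield NaN, never 0.

**The primary-table accuracy denominator.** The transcribed primary-cohort
matrix cells sum to 42 while its published grand total is 43 and the
published accuracy is 35/43 = 81%; the sensitivities and precisions are all
consistent with the 42 cells, so the 43rd sample evidently received no
classifier call yet stayed in the accuracy denominator.
`run_paper_fixtures` therefore computes the published accuracy as
trace / cohort total (43, resp. 12 for the metastasis table, where cells
and total agree) and additionally reports trace / cell-sum. Any
perturbation of a fixture cell breaks the exact checks and exits nonzero.

**NPV/PPV.** With inflamed as test-positive and response (CR/PR/SD > 24
weeks vs PD — encoded as a label pair, never re-derived) as
condition-positive: PPV = responders among inflamed / inflamed total,
NPV = nonresponders among excluded+ignored / that group's total. Values are
kept unrounded internally; the published presentation rounds to one decimal
(0.9 / 0.6 from 35/39 and 6/10).

**ROC/AUC.** Thresholds are all midpoints between adjacent distinct scores
plus ±∞, which makes the trapezoidal area *identical* to the Mann–Whitney
pair statistic with 0.5 credit for ties; both are computed and asserted
equal to 1e-12 on every call. Orientation is caller-specified and recorded
(for the excluded gene-set, higher scores predict non-response, so the
caller flips).

**Logistic odds ratios.** Univariate logistic regression by
iteratively-reweighted least squares (tolerance 1e-10 on the coefficient
step, ≤ 100 iterations, weights floored at 1e-10). OR = exp(slope) with
Wald 95% CI exp(slope ± 1.96·SE); the CI method is a stated choice — Wald
intervals are anti-conservative in small separated samples. Because the
original scaling (per-unit vs per-SD) is not recoverable, `standardize=True`
exposes the per-SD variant. A slope diverging past |30| is flagged as
non-converged (perfect separation). On a binary covariate the fitted OR
equals the 2×2 cross-product ratio, which serves as the closed-form oracle
(13.125 for the response table).

**Benjamini–Hochberg.** Standard step-up with monotonicity enforcement,
delegated to `statsmodels.stats.multitest` behind the module surface and
cross-checked against an independent step-up implementation in tests.

## TCR clonality

Skewness is the uncorrected Gini–Simpson index 1 − Σpᵢ² over clonotype
read proportions (0 monoclonal; 1 − 1/K at uniformity); the small-sample
correction N/(N−1) is available behind `bias_corrected=True` since the
variant used by upstream repertoire tooling is not stated. "Diversity" is
reported as the number of distinct clonotypes (the quantity actually
analyzed per figure axes), with total reads exposed as a separate field;
clonotype identity is taken from the id column as provided.

## Synthetic-data generators

The generators define the study conditions for all stochastic tests:

- **Expression cohorts**: 3 × 30 samples, 20 marker genes per phenotype at
  effect size 2.0 log2 units over a constant baseline of 5.0, 500 noise
  genes, Gaussian noise SD 1.0 on the log2 scale. The Gaussian log-scale
  model is a deliberate simplification: the classifier contract is
  rank-based, so any monotone-equivalent noise model tests the same
  decision behavior; what it cannot emulate is cross-platform
  (microarray → RNA-seq) transfer, batch structure, or gene–gene
  correlation.
- **Cell patterns**: homogeneous Poisson per stamp and marker with
  archetype CD8 intensities (border, center) of (400, 10) excluded,
  (50, 30) ignored, (400, 300) inflamed — placed well clear of the
  200/150/ratio-10 thresholds so recovery failures indicate bugs, not
  sampling luck (at 8 stamps per region the density SEs are a few
  cells/mm²). Real tissue is not homogeneous Poisson; clustering,
  compartment structure and segmentation error are out of scope.
- **Repertoires**: symmetric Dirichlet proportions (concentration ≪ 1 →
  clonal skew) with multinomial reads; zero-count clonotypes dropped with
  a log record.
- **Response labels**: Bernoulli per sample at the clinical-validation
  rates (0.6 inflamed, 4/39 excluded+ignored).

Every generator is a pure function of config + integer seed
(`numpy.random.default_rng`); no global RNG state.

## Problem sizes and what the benchmarks show

The test suite and `scripts/acceptance.py` use: 20 (tests) / 10
(acceptance) discovery–validation seed pairs at 90 + 90 samples for
classifier recovery; ≥ 102 seeded patterns for archetype recovery; 1000
random instances for the ROC and Spearman oracle identities; n = 3000 for
the simulated anti-PD1 experiment, at which the binomial SEs of NPV/PPV
(~0.006 / ~0.016) sit well inside the ±0.03 / ±0.05 convergence bands.
These sizes give stable pass/fail behavior at interactive runtimes.

Passing synthetic benchmarks show the pipeline's *arithmetic and logic*
are correct under the stated generative model. They do not reproduce the
published real-data accuracies (81% primary, 83% nodal metastases) or the
cohort-level AUCs/ORs, which require controlled-access patient cohorts;
the fixture tables reproduce the published evaluation arithmetic exactly,
and the synthetic recovery experiments substitute for the cohorts
themselves.

## Known limitations

- The digital rules are deliberately non-total; scans in threshold gaps
  need human review (`unassigned` + reason).
- Welch-per-gene selection ignores variance moderation; with very few
  samples per phenotype it is noisier than a moderated fit.
- Wald CIs and the uncorrected Gini–Simpson index are simple conventions;
  alternatives sit behind flags but defaults were chosen once and kept.
- The synthetic generator's independence assumptions (genes, cells,
  clonotypes) make recovery easier than on real data; accuracy numbers on
  synthetic cohorts are upper bounds, not estimates of clinical
  performance.
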