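# spatialpheno

Spatial immunophenotyping of tumors from multiplexed-imaging cell tables and
bulk gene expression, aimed at triple-negative breast cancer (TNBC) but
applicable to any tumor where CD8+ T cell localization matters.

Tumors fall into three *spatial immunophenotypes* by where their CD8+ T cells
sit: **inflamed** (T cells throughout border and center), **excluded**
(T cells restricted to the invasive border) and **ignored** (near-absence of
T cells). These phenotypes carry prognostic information and predict response
to anti-PD1 immune checkpoint inhibition. `spatialpheno` provides, as tested
library code plus a CLI:

1. **Density-based phenotype assignment** from segmented-cell tables.
   Cells are counted in 670 × 502 µm² fields of view ("stamps") at the tumor
   border and center; pooled densities λ = count / (n_stamps × 0.33634 mm²)
   feed fixed thresholds on the CD8 density:
   - inflamed: λ_border > 200 cells/mm² and λ_border/λ_center < 10
   - excluded: λ_border > 200 cells/mm² and λ_border/λ_center > 10
   - ignored: λ_border < 150 and λ_center < 150 cells/mm²

   plus nearest-neighbor statistics (counts within a 10 µm radius, mean
   nearest distances) computed per stamp.
2. **A nearest-centroid rank-correlation gene classifier** so phenotypes can
   be assigned from expression data alone. Classifier genes are those whose
   mean log2 expression in one phenotype beats *both* others by > 1 log2FC
   with Benjamini–Hochberg-adjusted Welch tests at padj < 0.05; per-phenotype
   centroid means are converted to rank vectors, and an unknown sample is
   assigned to the phenotype with the highest Spearman ρ between its values
   and the centroid ranks (ties → unassigned). Rank correlation makes the
   call invariant to any monotone transform of the sample's scale.
3. **Clinical evaluation statistics**: 3×3 confusion matrices with per-class
   sensitivity and the column-precision convention clinical tables often
   label "specificity", NPV/PPV of the inflamed-vs-rest dichotomy for
   therapy response, ROC/AUC (trapezoid ≡ Mann–Whitney, asserted), logistic
   odds ratios (own IRLS fit, Wald CIs), and gene-set mean scores.
4. **TCR repertoire clonality**: Gini–Simpson skewness 1 − Σpᵢ² over
   clonotype read proportions and distinct-clonotype diversity.
5. **Synthetic-data generators** for expression cohorts, stamp point
   patterns, repertoires and response labels, so the full pipeline is
   testable end-to-end without any controlled-access download.

## Worked example

```python
import spatialpheno as sp

# simulate an "excluded" tumor: CD8 dense at the border, sparse at center
cells = sp.generate_cell_pattern("excluded", seed=7)
prof = sp.compute_densities(cells, n_stamps={"border": 8, "center": 8})["SYN001"]
print(f"border CD8: {prof.cd8('border'):.1f} cells/mm2")
print(f"center CD8: {prof.cd8('center'):.1f} cells/mm2")
print("phenotype:", sp.assign_phenotype_digital(prof.cd8("border"), prof.cd8("center")).label)

# train the gene classifier on one synthetic cohort, score a held-out one
report = sp.run_synthetic_benchmark(seed=42)
print("classifier genes:", report["n_classifier_genes"])
print("held-out accuracy:", report["accuracy"])

# clonality of a skewed synthetic repertoire
rep = sp.generate_tcr_repertoire(100, 10000, concentration=0.3, seed=3)
print(f"Gini-Simpson: {sp.gini_simpson(rep):.3f}  diversity: {sp.tcr_diversity(rep)}")
```

prints

```
border CD8: 391.0 cells/mm2
center CD8: 10.8 cells/mm2
phenotype: excluded
classifier genes: 60
held-out accuracy: 1.0
Gini-Simpson: 0.962  diversity: 85
```

The simulated border density (391 cells/mm²) clears the 200 cells/mm²
threshold and the border/center ratio (≈36) exceeds 10, so the scan is
called *excluded* — the archetype it was generated from. The classifier
recovers all 60 planted marker genes (20 per phenotype) and assigns every
held-out sample correctly at the default effect size (2 log2 units over
noise SD 1). The repertoire drawn from a Dirichlet with concentration 0.3
is clonally skewed: 85 clonotypes survive sampling and the Gini–Simpson
index sits below the uniform maximum of 0.99.

The same steps are available as CLI subcommands
(`spatialpheno simulate-cells | phenotype-cells | train-classifier |
assign | evaluate | tcr-metrics | benchmark | paper-fixtures`).

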