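# sermeth

Serum cell-free DNA (cfDNA) methylome analysis for the colorectal
**serrated pathway** — the route to colorectal cancer that runs through
hyperplastic polyps and sessile serrated lesions rather than conventional
adenomas. Screening programmes miss these lesions disproportionately, and
their stepwise epigenetic dysregulation (up to a CpG-island methylator
phenotype) makes circulating methylation marks a natural biomarker
substrate.

`sermeth` re-implements, as a reusable and tested Python library, the full
analysis chain of a pooled-serum EPIC-array biomarker study:

1. **Synthetic cohort generator** (`sermeth.synthdata`) — individual-level
   beta values per pathology group (NCF, LR-SL, HR-HP, HR-SP, SAC),
   equal-mass pooling of 10 sex-balanced individuals per array, slide
   batch effects on the M scale, spatially clustered differential regions,
   detection statistics, and MS-qPCR plates from a log-linear
   standard-curve model. Every stage downstream is testable against the
   recorded ground truth.
2. **Preprocessing** (`sermeth.preprocess`) — detection-p / bead-count /
   cross-reactive / SNP / sex-chromosome probe filters, a
   regression-assumption screen (Shapiro–Wilk, Breusch–Pagan,
   Durbin–Watson, RESET-style linearity), parametric empirical-Bayes
   (ComBat-type) batch adjustment, and the beta ↔ M conversion
   `M = log2(β/(1−β))`.
3. **Probe-level differential methylation** (`sermeth.diffmeth`) —
   per-CpG linear models on M values, empirical-Bayes moderated t
   statistics with variance shrinkage
   `s̃² = (d₀s₀² + d·s²)/(d₀+d)`, Benjamini–Hochberg FDR, and DMP calls at
   the joint criterion *p* < 0.01 and |Δβ| ≥ 0.10, plus Fisher enrichment
   of DMPs in CpG-island/feature categories.
4. **Region-level bump hunting** (`sermeth.dmr`) — probe clusters within
   250 bp, candidate regions as runs of ≥ 2 same-sign effect exceedances
   scored by area, and group-label permutation significance: per-region
   *p* and family-wise error rate (FWER), reported significant at
   FWER < 0.10, *p* < 0.01, ≥ 2 CpGs.
5. **Gene-ontology enrichment** (`sermeth.ontology`) — promoter DMP → gene
   mapping, Wallenius noncentral hypergeometric over-representation
   (correcting each gene's probe-count bias), and Jaccard term-similarity
   clustering.
6. **MS-qPCR quantification** (`sermeth.msqpcr`) — standard curves
   (`Cq = intercept + slope·log10(%)`, efficiency `10^(−1/slope) − 1`,
   QC at efficiency > 90% and R² > 0.99), raw methylation percentages, and
   the input-normalized methylation percentage

   ```
   NMP = (RMP_sample / ACTB_sample) / (RMP_fmc / ACTB_fmc) × 100
   ```

   against the fully methylated control (fmc), analysed as log10(NMP+1).
7. **Biomarker evaluation** (`sermeth.classify`) — unpenalized logistic
   models (IRLS), leave-one-out cross-validated probabilities, rank-based
   AUC with DeLong 95% CI, Youden-index operating points with exact
   binomial CIs, and detection-rate tables by lesion subtype/location.

## Worked example

Scripts under `examples/` each exercise one capability. Calling a marker
panel on a simulated 80-sample serum cohort
(`python examples/06_biomarker_classification.py`):

```
NSN vs HR-SL: n+ = 40, n- = 40
AUC = 0.977 (95% CI 0.952-1.000)
Youden cutoff = 0.336: sensitivity 97.5% (86.8-99.9), specificity 90.0% (76.3-97.2)
```

Every probability behind the AUC is out-of-fold (the model scoring a
sample never saw it), the CI is DeLong's, and the sensitivity/specificity
intervals are exact Clopper–Pearson. Region calling
(`python examples/03_dmr_bumphunting.py`) prints the bump-hunting cutoff,
the permutation count, and each candidate region's area, mean Δβ, *p* and
FWER next to the injected truth.

The same pipeline runs end to end from a shell:

```sh
sermeth run out/ --seed 1            # simulate -> filter -> DMP -> DMR -> qPCR -> classify
sermeth dmp beta.tsv sheet.csv HR-SP:NCF dmps.tsv
sermeth qpcr plate.csv DMR7 measurements.tsv
```

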