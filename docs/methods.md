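# Methods

This note documents the statistical models, the synthetic-data
assumptions, and the numerical choices behind `sermeth`, in the spirit of
the model documentation shipped by simulation and statistics packages.

## Data scales

Methylation at a CpG is a fraction β ∈ [0,1] (methylated signal over
total signal). β is reported for interpretability; all testing happens on
M = log2(β′/(1−β′)) with β′ = clip(β, ε, 1−ε), ε = 1e−6 by default. The
clip keeps M finite; `m_to_beta` inverts the transform exactly on clipped
values. M values are approximately Gaussian and variance-stabilized,
which the linear models below assume.

## Synthetic cohort generator

The generator emulates the structure of a pooled-serum array study, not
any particular dataset:

- **Groups and sizes.** Five pathology groups ordered by severity — no
  colorectal findings (NCF), low-risk serrated lesions (LR-SL), high-risk
  hyperplastic polyps (HR-HP), high-risk serrated polyps (HR-SP),
  serrated adenocarcinoma (SAC) — with default cohort sizes
  30/30/20/20/10 individuals. Pools of 10 (5 male + 5 female, stratified
  on centre and age) give 3+3+2+2+1 = 11 array samples, the design this
  kind of study uses to make scarce cfDNA measurable.
- **Baseline methylation** is bimodal across the array: CpG-island probes
  draw low means (Beta(1.5,10)), opensea probes high (Beta(10,1.8)),
  shores/shelves in between — the canonical two-hump beta-value
  distribution.
- **Individual noise.** Individual betas are Beta-distributed around the
  group mean with precision κ (default 100, i.e. SD ≈ 0.05 at β = 0.5).
  Bounded support makes a Beta noise model the natural choice; no claim
  is made that real inter-individual variation is exactly Beta.
- **Injected signal.** Isolated differential positions shift the affected
  groups' mean by a signed Δβ drawn from (0.15, 0.25) by default.
  Differential regions shift 3–6 consecutive probes coherently; region
  probes get intermediate baselines (U(0.25, 0.75)) so the shift is never
  truncated by the [0,1] bounds, which would silently break the
  consistent-direction property the region caller relies on. Flanking
  gaps are widened past 250 bp so each injected region coincides with a
  maximal probe cluster.
- **Pooling** is an equal-weight mean of member betas (equal DNA mass),
  followed by an additive slide effect on the M scale (a per-slide
  Gaussian level plus per-probe scatter — exactly the location/scale
  structure the ComBat adjustment models) and Beta measurement noise with
  SD ≈ 0.01 on the beta scale. Pools are spread round-robin over slides,
  emulating a design that avoids confounding slide with pathology.
- **Detection statistics** are simulated directly (good probes get
  p < 0.005 and 5–30 beads; a configurable fraction fails by p > 0.01 or
  < 3 beads in one sample). Deriving them from negative-control
  intensities would require simulating raw two-channel intensities, which
  is out of scope — the pipeline starts at beta values.
- **qPCR plates** follow Cq = intercept + slope·log10(%) with Gaussian
  replicate noise, an Undetermined sentinel beyond cycle 40 (or at 0%
  template), a five-point dilution series (100…0.01%), fully methylated /
  fully unmethylated / no-template controls, and an ACTB input assay whose
  template scales with the sample's DNA input while the target scales
  with input × methylation — making NMP, but not RMP, input-invariant.

What the generator does *not* emulate: raw intensities and dye bias,
copy-number or SNP artefacts, probe cross-hybridization chemistry,
age/sex-associated methylation drift. Tests passing on this generator
therefore validate the statistical machinery, not array chemistry.

## Probe filtering and assumption screen

Filters apply in a fixed order (detection p > 0.01 in any sample → bead
count < 3 in any sample → cross-reactive → SNP-overlapping → sex
chromosomes → assumption screen), with each removal attributed to the
first criterion that catches it, so the per-criterion counts sum exactly
to the total removed. "Any sample" is the conservative reading
appropriate for a small number of pooled arrays. Mean detection p per
sample is reported for failed-sample QC.

The assumption screen fits M ~ group per probe and tests the
standardized residuals four ways: Shapiro–Wilk (normality),
Breusch–Pagan against fitted values (homoscedasticity), Durbin–Watson in
sample order flagged outside [1,3] (uncorrelatedness), and the
significance of a squared-fitted-value term (linearity, RESET-style,
skipped when fitted values take < 3 levels, as in two-group designs).
The four test choices are this package's own — the screen's composition
is recorded per probe so alternatives can be swapped in. Constant probes
are removed with an explicit "degenerate" reason. Under i.i.d. Gaussian
nulls the screen rejects at roughly the union bound (≈ 2–4 α empirically).

## Batch adjustment

`combat_adjust` implements the parametric empirical-Bayes location/scale
model: per-probe standardization that preserves the protected biological
covariate, Normal prior on per-batch means, Inverse-Gamma prior on
per-batch variances with method-of-moments hyperparameters, iterative
conditional updates, and back-transformation. The non-parametric branch
is omitted. The implementation matches the Bioconductor reference
(`sva::ComBat`) to ~1e−6 on a frozen fixture (tests/data). Note the EB
shrinkage deliberately leaves part of the per-probe sampling noise in the
batch means — only the systematic component is removed — so per-batch
probe means do not collapse to equality at small n. Single batches pass
through unchanged; single-sample batches and batch⊥group confounding are
errors.

## Moderated t and DMP calling

Per probe, a two-group OLS on M values gives effect (case − control mean
difference), residual variance s² on d = n−2 df, and unscaled SD
√(1/n₁+1/n₂). The ensemble of s² identifies a scaled inverse-chi-square
prior (d₀, s₀²) by matching mean and variance of log s² to their
digamma/trigamma expressions (trigamma inverted by Newton iteration);
zero excess dispersion yields the d₀ = ∞ sentinel (pure pooling), and
exactly-constant variances short-circuit to (∞, that constant). The
moderated statistic uses s̃² = (d₀s₀² + d·s²)/(d₀+d) with d₀+d degrees of
freedom; it reduces to the ordinary t at both prior limits (checked to
1e−10). DMPs require p < 0.01 *and* |Δβ| ≥ 0.10 jointly (the Δβ threshold
is inclusive); Δβ is computed on the filtered, batch-adjusted beta scale
as case minus control. BH FDR q-values accompany every test. With three
pools per side, injected Δβ = 0.15 is recovered with sensitivity ≥ 0.9
and false-discovery proportion ≈ 0.

## Bump hunting and permutation FWER

Probes cluster greedily within maxgap = 250 bp (inclusive; chromosome
changes always split). The bump cutoff K defaults to the 0.99 quantile of
|effect| — the cutoff is not prescribed anywhere authoritative, so it is
configuration, recorded in the result metadata. Candidates are maximal
runs of ≥ 2 consecutive same-sign exceedances, scored by area = Σ|effect|.
No loess smoothing is applied by default (few samples, sparse probes).

Significance comes from group-label permutations re-extracting candidates
with the *same* K. Estimators carry +1 corrections:
p = (1+#{null areas ≥ a})/(1+N_null), FWER = (1+#{perm maxima ≥ a})/(1+B).
Because the area statistic is symmetric under swapping case and control,
a labeling and its complement are the same permutation; balanced
contrasts are therefore enumerated over unordered partitions. With 3
pools per side that leaves 9 distinct null partitions, so the exact-test
FWER floor is 1/10 = 0.10 — at this design size a region can at best
*attain* the floor, and FWER < 0.10 becomes reachable only when the
labeling space is large enough to sample B = 100 permutations (floor
1/101 ≈ 0.0099). This resolution limit is a property of the exact test,
not of the implementation; estimators that sample labelings with
replacement and omit the +1 can report smaller values only by biasing
below the floor. Null calibration: across 200 seeded null cohorts
(20k probes, 3 pools/side), the fraction reporting any region with
FWER < 0.10 is ~0, within the nominal 0.10 + Monte-Carlo slack.

Reported regions satisfy FWER < 0.10, p < 0.01 and ≥ 2 CpGs; intervals
are 1-based inclusive (min/max member probe position, so a 2-probe region
2 bp apart has length 3 bp), converted to 0-based half-open only in BED
export. Region annotation takes the union of member-probe genes and
majority votes for feature/CGI class (ties → first probe). The region
"methylation difference" is the mean member-probe Δβ × 100.

## Gene-set enrichment

Promoter DMPs (TSS200, TSS1500, 5'UTR, first exon) map to genes;
multi-gene probes count once per gene. The per-gene probe count over the
whole array is the bias covariate: a gene with many probes is more likely
hit by chance. Each set's selection odds w are the ratio of mean probe
counts of in-set vs out-of-set universe genes — a deliberate
simplification of full probability-weighting approaches, recorded as
method "mean-ratio Wallenius" — and the p-value is the upper Wallenius
noncentral hypergeometric tail, which at w = 1 equals the one-sided
Fisher test exactly (verified against brute-force enumeration to 1e−9).
The universe defaults to all annotated array genes (configurable).
Significance is p < 0.005; hyper- and hypomethylated DMPs are tested
separately in the pipeline. Term similarity is the Jaccard index over
member genes (optionally restricted to the differentially methylated
genes), clustered complete-linkage on 1−J. The shipped gene-set
collection is synthetic (random draws with curated-term size structure);
a GMT loader accepts real collections.

## MS-qPCR quantification

Replicate Cq values average over determined replicates (all-undetermined
propagates the sentinel; replicate SD reported). Standard curves are OLS
of Cq on log10(%); the intercept is the Cq at the 1% reference point.
Efficiency is 10^(−1/slope) − 1 with QC at efficiency > 0.90 and
R² > 0.99 — a QC-failed curve refuses to quantify unless explicitly
overridden. RMP = 10^((Cq−intercept)/slope), with undetermined Cq → 0%.
RMP uses the mean Cq of replicates (not per-replicate RMP averaging).
NMP divides the sample's RMP/ACTB ratio by the fully methylated control's
and multiplies by 100; it is dimensionless, deliberately uncapped above
100 (the downstream log10(NMP+1) absorbs it), and undefined (flagged,
not zeroed) when the sample has no measurable ACTB input. Group
comparisons use exact Wilcoxon tests up to n = 25 per side (rank-sum
unpaired; signed-rank with zero differences dropped for matched tissue
pairs) and the continuity-corrected normal approximation beyond.

## Classification

Markers enter as log10(NMP+1). Logistic models are fitted by IRLS with no
penalty (|Δdeviance| < 1e−8, ≤ 100 iterations); complete separation is
detected (deviance → 0) and flagged rather than regularized away — the
coefficients are unstable but the probabilities remain usable, the honest
behaviour for a small cohort with a near-perfect marker. LOOCV produces
one out-of-fold probability per sample; ROC/AUC uses the rank (Mann–
Whitney) formulation with half credit for ties, equal to trapezoidal
integration of the pooled ROC curve (a single curve over pooled
out-of-fold probabilities, not per-fold averaging). The AUC CI is
DeLong's; sensitivity/specificity CIs are exact Clopper–Pearson; the
operating point maximizes Youden's J over observed thresholds with ties
resolved toward higher specificity. Note that pooled LOOCV probabilities
are *pessimistic* under the null — removing a positive lowers the
training intercept, anti-correlating held-out labels with fitted
probabilities — so null AUC falls below 0.5; the suite checks the
one-sided property (no optimistic bias). Detection rates are per-subtype
percentages among positive samples (empty subtypes are not reported as
0), with a two-sided Fisher test of detected × distal/proximal.

## Problem sizes and determinism

The test and acceptance workloads run at desk scale by design: 20k-probe
arrays (vs 866k on the real platform), 200-replicate calibration loops,
50k-probe prior-recovery draws, and 80-sample serum panels — large enough
for the asymptotics the checks rely on while keeping the full suite in
the order of a minute. Every random draw flows from an explicit seed
(`numpy.random.default_rng`); identical (config, seed) pairs reproduce
every pipeline output byte-for-byte, which the pipeline's run manifest
(config hash + per-output checksums) makes auditable.

## Known limitations

- The pipeline starts at beta values: no IDAT parsing, background/dye
  correction, or normalization of raw intensities.
- The bump-hunting cutoff quantile and the mean-ratio bias odds are
  pragmatic defaults, not estimated quantities.
- The exact permutation test's FWER resolution at 2–3 pools per side is
  coarse (floors of 0.10–0.17); conclusions at those design sizes rest on
  the region attaining its floor, not on small nominal FWERs.
- Synthetic gene sets carry no real biology; enrichment results on them
  validate the distribution theory only.
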