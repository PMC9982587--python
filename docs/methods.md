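# Methods

## The analysis model

`braintx` treats a case-control imaging study and a spatial transcriptome as
two views of the same cortical parcellation (default: 210 regions). The
pipeline estimates, per region and measure (GMV, ALFF, fALFF, ReHo), the
standardized case-control difference (Cohen's d), summarizes the three
functional difference maps by their first principal component (funcPC1) and
the region × gene expression matrix by its first principal component
(genePC1), and then asks two questions:

- does the dominant expression gradient (genePC1) spatially align with the
  abnormality maps (Spearman correlation across regions)?
- which individual genes' regional expression profiles track funcPC1 or the
  GMV difference map (mass-univariate Spearman screen, Bonferroni over the
  gene universe, split by correlation sign into four sets)?

Downstream, the per-gene correlates are linked to gene-level
differential-expression (DGE) betas from postmortem cortex, and the selected
gene sets are tested for over-representation in annotation collections.

### Statistical details and conventions

- **t-test**: pooled-variance Student t (case − control), df = n₁ + n₂ − 2;
  Welch available as an option. Conversion d = t·√(1/n₁ + 1/n₂), the
  standard two-sample formula. Sign of d always equals sign of t.
- **Residualization**: OLS on age, sex, education, head motion plus an
  intercept, fitted on all subjects pooled, per region. A rank-deficient
  design is an error naming the collinear columns; covariates that are
  constant in the analyzed sample (e.g. sex after a subgroup split) carry no
  information beyond the intercept and are dropped with a warning.
- **PCA**: SVD of the column-standardized matrix — deterministic, no
  randomized solver. PCA signs are arbitrary, so both components carry an
  explicit convention: funcPC1 is oriented to correlate positively with the
  mean of its input maps (which are themselves positively intercorrelated);
  genePC1 is oriented so the mean gene loading is non-negative, i.e. it
  tracks the dominant shared expression gradient rather than its mirror.
  Effect maps are standardized before PCA (a switch disables this).
- **Spearman p values**: two-sided, from t = r·√((n−2)/(1−r²)) with n − 2
  df; below 10 observations an exact permutation tail is used instead so toy
  fixtures are not exposed to approximation error. |r| = 1 returns p = 0 by
  convention on both paths.
- **Multiple testing**: Bonferroni at α/G per target map for gene selection
  (each screen is its own family — two screens are reported as four sets);
  BH-FDR across regions for effect maps and within each collection for
  enrichment.
- **Bin-based estimator**: genes ranked by correlate descending, ties broken
  by gene id ascending; N genes split into B contiguous bins with the first
  N mod B bins holding ⌈N/B⌉ genes (numpy's array-split rule, documented
  because any consistent remainder rule satisfies the collapse identity);
  Spearman over per-bin means. B = N reproduces the direct gene-level
  correlation to machine precision.
- **Fisher enrichment**: exact hypergeometric upper tail (one-sided,
  over-representation); odds ratio (a·d)/(b·c) with a Haldane 0.5 continuity
  correction applied to the ratio only when a cell is zero, flagged in the
  output. Default background universe: the gene universe of the correlate
  screen, because selection occurred within it — not the genome.
- **ALFF/fALFF**: one-sided amplitude spectrum (|DFT|·2/T) of the linearly
  detrended series, no taper; ALFF summarizes in-band (0.01–0.08 Hz)
  amplitudes by their mean (a sum option exists; fALFF, a ratio of sums over
  in-band and full non-DC spectrum, is unaffected by the choice). Detrending
  a finite sinusoid leaves a small broadband residual, so fALFF of an
  in-band tone approaches 1 only as the series lengthens.
- **ReHo**: Kendall's W of the voxel rank series with the standard tie
  correction, W = 12·S / (V²(T³−T) − V·ΣT_v). All-constant blocks are a
  degeneracy error rather than a number.

## The synthetic-data generator

The generator is first-class, tested code: it defines the conditions under
which every downstream guarantee is demonstrated.

A per-region latent **gradient** (z-scaled Gaussian) plays the role of the
cortex's dominant expression axis. Causal genes are `gradient × loading +
noise` with loadings ~ N(0.5, 1) and noise SD 0.5; remaining genes are pure
noise. The positive loading mean gives the expression PC1 a reproducible
orientation relative to the gradient — with symmetric loadings the
component's sign would be a coin flip per realization and no directional
claim could be planted; it also mirrors the positive-dominant covariance of
real bulk cortical expression. Gene-level ground truth (the exact
model-implied gene-gradient correlation) is stored alongside.

**Couplings on the Spearman scale.** A difference map coupled to the
gradient at Spearman ρ is built by mixing the gradient's normal scores (a
noise-free, perfectly rank-aligned target) with independent Gaussian noise
at Pearson weight 2·sin(πρ/6) — the bivariate-normal identity that makes the
population Spearman correlation exactly ρ. The three functional measures
share one latent coupled map with weight √0.75 (pairwise correlation of the
true maps 0.75), GMV gets its own coupled map.

**Effect amplitude.** The true per-region Cohen's d is the z-scaled coupled
map times 0.12. This default comes from a design (power) calculation: the
sampling noise of an estimated d map is ≈ √(1/n₁+1/n₂) per region (0.1 at
200 + 200 subjects), so the Spearman attenuation of the recovered coupling
is ≈ a/√(a²+se²) per map (less after averaging three functional maps in
funcPC1). At a = 0.12 the expected recovered couplings are ≈ −0.25 and
≈ +0.27 for planted −0.3/+0.35 — inside the ±0.1 recovery band the generator
promises — while observed |d| stays in a plausible case-control range
(≲ 0.3–0.4) and the observed pairwise correlations of functional effect maps
land around 0.4–0.65 at a few hundred subjects per group. Covariates (age
U(18, 65), sex Bernoulli(½), education 6–22 y, head motion log-normal)
contribute additively with small betas and are removed by residualization.

**DGE betas** are `sign × z(correlate truth) + t₃ noise`, after which 80% of
genes (default) are shrunk toward zero by a factor 0.05 — reproducing the
zero-concentrated, heavy-tailed shape of meta-analytic DGE estimates that
motivates the bin-based estimator. The default coupling sign is +1 (aligned
with the gradient), which yields a negative bin correlation against the
funcPC1 correlates and a positive one against the GMV correlates — the
opposite-sign structure the pipeline is designed to resolve.

**Probe-level samples** plant, per gene, one representative probe that
tracks a gene-specific regional profile consistently across donors, and
decoy probes that are donor-specific noise; a stated fraction of decoys is
flagged below background in exactly 70% of samples so the 50% filter removes
exactly them. Voxel-neighborhood time series mix a shared low-frequency
component (synchrony → ReHo) with independent noise, with a band-weight
parameter controlling in-band amplitude (→ ALFF/fALFF).

### What the generator does not emulate

- **Spatial autocorrelation** between regions: regions are exchangeable, so
  the per-gene p values are exactly calibrated here; on real cortical maps
  they would be optimistic absent a spatially constrained null. Passing
  tests therefore demonstrate estimator correctness, not robustness to
  spatial autocorrelation.
- **Site/scanner heterogeneity**: no site term by default (residualization
  covers age/sex/education/motion only, matching the analysis model); a site
  intercept can be added for robustness checks by supplying custom
  covariates.
- Donor-specific anatomy, MRI volumes and preprocessing, hemispheric
  structure.

## Problem sizes used by the test and acceptance runs

Integration properties are demonstrated at 210 regions, 2,000 genes and
200 + 200 subjects (coupling recovery over 100 seeds; null error control
over 200 replicates), 10,000 genes for the p-value calibration and
bin-estimator power checks, and 1,000 genes × 3 probes for atlas recovery —
sizes chosen so each property is measured with adequate Monte-Carlo
resolution while the whole suite stays fast. `scripts/acceptance.py` runs
one full pipeline at 210 regions × 15,633 genes with 848 + 794 subjects.

## Known limitations and open choices

- The per-gene screen's two screening families (funcPC1, GMV) are corrected
  separately, by design; a global 2G correction would be stricter.
- The representative-probe criterion is differential stability; with a
  single donor it falls back to highest mean intensity (warned). Probe
  selection is global, not per hemisphere — the generator has no hemispheric
  structure.
- Normalization before regional aggregation defaults to a within-donor
  z-score; a scaled robust sigmoid is available.
- The recovered genePC1–map correlations are attenuated relative to the
  planted couplings by subject-level sampling noise in the effect maps; the
  recovery tests bound this bias rather than correcting it.
- Real-data mode expects inputs already reduced to regions (expression TSV,
  subject × region tables); voxelwise whole-brain computation is out of
  scope.
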