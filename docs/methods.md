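# Methods

This note records the statistical model behind `glialseq`, the choices
made where the standard workflow leaves room, and what the simulation-
based tests do and do not establish.

## The pipeline model

The package targets a two-group bulk RNA-seq comparison with small n
(the motivating design is 5 vs 5 animals, ~18,000 detected genes). The
observed data are integer counts y_gs for gene g in sample s with library
size L_s.

**Filtering.** Genes are kept if their raw CPM (y/L · 10⁶, unnormalized
library sizes) reaches `min_cpm` (default 1) in at least `min_samples`
samples (default: the smaller group size). The threshold is a
convention, not an estimate; it exists to remove genes whose log-CPM is
dominated by the prior count and whose variances would otherwise distort
the empirical-Bayes fit.

**TMM normalization.** Composition differences (a few highly expressed
genes monopolizing one library) bias per-library scaling. TMM picks as
reference the sample whose upper-quartile CPM is closest to the mean
upper quartile, computes per-gene log-ratios M and average abundances A
against it over genes expressed in both samples, trims 30% of each M
tail and 5% of each A tail, and averages the surviving M values weighted
by inverse asymptotic binomial variance. Factors are rescaled to
geometric mean 1. Exact depth-invariance holds when all M-values are
zero; otherwise depth enters weakly through the binomial weights, which
is a property of the estimator, not an implementation artifact. The
implementation reproduces edgeR's `calcNormFactors(method="TMM")` to
1e-8 on simulated data (checked in the test suite via Rscript).

**log₂-CPM.** Entry (g, s) is `log2((y + c) / (L·f + 2c) · 10⁶)` with
prior count c = 0.5. The 2c library correction keeps the transform
monotone and bounded for zero counts. No precision (voom-style) weights
are applied and no mean–variance trend is fitted in the shrinkage step;
both are deliberate simplifications exposed as future options rather
than silently approximated.

**Moderated t.** Per gene, the two-group OLS fit gives β̂ (treatment −
control), s²_g on d_g = n − 2 df. Under the conjugate model
s²_g | σ²_g ~ σ²_g χ²_{d}/d with 1/σ²_g ~ χ²_{d₀}/(d₀ s₀²), the log
sample variances e_g = ln s²_g − ψ(d/2) + ln(d/2) have excess variance
trigamma(d₀/2) beyond trigamma(d/2); moment matching (mean and variance
of e_g, trigamma inverted by Newton iteration) yields d₀ and s₀². The
posterior variance s̃²_g = (d₀ s₀² + d s²_g)/(d₀ + d) defines
t_g = β̂ / (s̃_g √(1/n₁ + 1/n₂)) on d₀ + d df. When the observed
variances are (numerically) identical, d₀ = ∞ and the statistic
degenerates to a z-like test against s₀², with a warning. The fit
matches limma's `eBayes` (d₀, s₀², t, p, adjusted p) to 1e-8 on
simulated data. Setting d₀ = 0 recovers the ordinary pooled t exactly —
the oracle equivalence asserted in the tests.

**Multiple testing.** Benjamini–Hochberg step-up via statsmodels;
significance at adjusted p ≤ 0.05, with fold-change tiers |log₂FC| ≥ 0.5
(global/volcano reporting) and ≥ 0.25 (microglia categorization).

**Phenotype categorization.** Significant genes are intersected with the
cell type's union marker list; intersecting genes are assigned to every
category membership list containing them. The fold-change floor is
0.25 for the microglia scheme and 0 for astrocytes and oligodendrocyte
lineage — the published categorized astrocyte/oligodendrocyte tables
contain entries down to |log₂FC| = 0.14, so a floor there would be
unfaithful. Category schemes are treated as non-exclusive labels: a gene
in two lists is kept in both and flagged. Gene symbols are harmonized by
uppercasing only; no alias or orthology mapping (cross-source case
differences are the only mismatch the curated lists exhibit). Duplicate
DE rows collapse to the smallest adjusted p, ties to larger |log₂FC|.

**Set statistic.** Genes are z-scored across all samples jointly (n − 1
sd; both groups together, matching the heatmap convention), a set's
per-sample score is the mean z over its genes, and groups are compared
with a pooled-variance two-tailed Student's t on n₁ + n₂ − 2 df (Welch
available by flag). Sets with fewer than 4 genes present are recorded as
"not tested", the minimum inferred from the practice of declining to
test 2- and 3-gene categories. The statistic treats member genes as
independent replicates within a sample; correlated genes (common in
co-regulated marker panels) inflate significance. The test suite
calibrates the mechanics on independent genes only and makes no claim
about biological calibration. Z-scoring uses the full filtered log-CPM
matrix, not a significant-genes-only submatrix; this is the package's
choice where conventions differ.

**Reports.** PCA is computed by SVD of the gene-centered (unscaled)
sample × gene matrix with a deterministic sign convention (largest-|x|
coordinate positive). Hierarchical clustering uses 1 − Pearson r with
average linkage (complete available); the scipy linkage is verified
against a naive O(n³) oracle. Volcano classes are sig_up / sig_down / ns
at (α, τ) thresholds. Figures never gate tables: all TSVs are written
before any plotting.

## The simulator

`SimConfig` draws per-gene baseline means 2^U(2, 11) (spanning the bulk
dynamic range from near-filter level to highly expressed), NB counts
with variance μ + φμ² (default φ = 0.1, a typical bulk biological CV of
~0.3; φ = 0 gives Poisson), log-normal library scales (σ = 0.2 log₂
units), and a default design of 5 vs 5 samples. Planted effects
multiply the treatment-group mean by 2^lfc, either for a background
fraction of genes or for directional marker sets; composition bias
(default off) inflates a random gene fraction in one group without
entering the DE truth table. Defaults of 2,000 genes keep the suite
fast; 18,000-gene instances and the curated marker-list sizes
(822/309/381/55/9/347/7) are exercised where the scale matters.

What the simulator does **not** emulate: inter-gene correlation, batch
effects, gene length or GC bias, outlier samples, and annotation error.
Passing calibration tests therefore shows the statistics behave as
designed under their own assumptions — not that those assumptions hold
in any particular tissue dataset.

## Numerical and design choices

- Trigamma inversion by Newton iteration with asymptotic fallbacks at
  y < 1e-6 and y > 1e7; convergence tolerance 1e-10 relative.
- Genes with zero residual variance are excluded from the moment fit but
  still shrunk through the posterior formula.
- BH ties: stable sort by p preserves input order; adjusted p is capped
  at 1 and is never below raw p.
- TMM degenerate guard: if all |M| < 1e-6 the factor is exactly 1.
- Reference level defaults to the lexicographically first group label
  ("C" before "E"); log₂FC is always treatment − reference.
- Determinism: all simulation randomness flows from one
  `numpy.random.default_rng(seed)`; identical seeds give byte-identical
  TSVs.
- Problem sizes in the calibration suites — 1,000 null simulations of
  200-gene datasets for the set-score type-I check, 100 replicates of
  500-gene datasets for power, one 25,000-gene null dataset for per-gene
  calibration — were chosen so each check has the sampling precision its
  99% binomial acceptance band requires while the whole suite stays
  fast.

## Known limitations

- Two-group designs only; no blocking, covariates, or multi-factor
  models.
- No quasi-likelihood NB GLMs; inference is normal-theory on log-CPM,
  adequate at moderate counts but anti-conservative for very low ones
  (mitigated by the expression filter).
- The set statistic's independence assumption (above) is the main
  caveat for interpreting small p-values on real co-expressed panels.
- The packaged worked-example tables are fixtures of published derived
  results; the package does not re-derive them from raw sequence data.
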