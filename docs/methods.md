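# Methods

## The model

`paleotwas` treats a dated genotype panel — ancient diploid genomes merged
with a modern cohort — as a time series and asks three related questions.

**1. Did any gene's predicted expression change directionally over time?**
Predicted expression for sample *j* and gene *g* is the usual TWAS linear
score ŷ_gj = Σ_i β_i d_ij, where β_i are published cis-eQTL weights and
d_ij effect-allele dosages. Each gene is tested by OLS of ŷ on date *t*
(years before present, intercept included):

    ŷ = α + β t + ε.

Under neutrality the slope is zero in expectation, but drift makes the
per-gene slopes overdispersed relative to the OLS sampling variance (each
gene's regulatory variants follow real, autocorrelated trajectories). No
ancestry covariates are used; instead genomic control rescales the test
statistics: each P-value is mapped to a χ²₁ statistic, λ is the observed
median over 0.45494 (the χ²₁ median), statistics are divided by λ and
mapped back. Because drift inflates all genes by a roughly common factor
(both the drift and the sampling variance of a slope scale with the same
allele-frequency variance terms), this restores calibration — the package's
null-simulation tests verify uniformity of post-GC P-values. BH-FDR at
q < 0.05 is the significance criterion; a single global date permutation
re-runs the identical pipeline to give the empirical null for QQ plots.

Only genes passing an imputation-quality filter are tested. Gene quality
is the |β|-weighted mean of per-SNP imputation R²:
R²_gene = Σ|β_i| R²_i / Σ|β_i|; the lowest 20% of genes are removed.
Absolute weights are used in both numerator and denominator — with signed
weights the score would not be a convex combination and could leave [0,1].

**2. Which SNP windows show excess frequency change?** Per SNP, a
constant-s estimator: allele counts (each diploid = 2 Bernoulli trials;
fractional dosages enter as fractional successes) are regressed on
generations before present with a logistic link, by Newton/IRLS
(tolerance 1e-8, ≤100 iterations). The per-generation slope b gives
ŝ = e^(−b) − 1, so ŝ > 0 means the ALT allele rose toward the present;
under genic selection the favored allele's logit frequency grows by
log(1+s) per generation, making this the exact MLE of the deterministic
model. Estimates are aggregated as RMS over 20-SNP windows stepping by 10;
a two-parameter gamma (location 0) fitted genome-wide by maximum
likelihood supplies upper-tail P-values; windows under 5 Mb apart merge
into peaks padded by 0.1 Mb. The estimator sits behind a small interface
(`estimate_s_batch`) so a time-varying trajectory-likelihood backend can
be substituted without touching the window machinery; the constant-s form
is what heavy temporal smoothing of such estimators converges to.

**3. Do haplotype-based statistics agree?** Pre-computed normalized SDS or
iHS scores are aligned to each weight entry's effect allele (negated when
polarized to the other allele, dropped when the allele pairs cannot be
matched) and combined as score_gene = Σβ_i S_i / √(Σβ_i²) — a z-score
under the null that the S_i are independent standard normal. Both sums run
over scored SNPs only, so missingness does not deflate the variance; genes
with fewer than half their SNPs scored are removed (exactly half is
retained). Two-sided normal P-values get genomic control and BH-FDR. For
direction concordance, TWSS slopes are negated (positive = rising toward
the present) before sign comparison with the scores, whose positive pole
is likewise a recent rise of the expression-raising allele.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the statistical structure the scans assume:
Wright–Fisher trajectories (deterministic genic update
p* = p(1+s)/(1+ps), then binomial resampling of 2Ne gametes, absorbing
boundaries), dated diploids drawn from Hardy–Weinberg proportions at the
generation nearest each sample's date, weight models with Poisson-(12)
SNP counts across multiple tissues with distinct training R², per-variant
imputation R² ~ Beta(8,2) (high-quality-skewed, as imputation of
reasonable-coverage data produces), ancient-read simulation with Poisson
coverage and per-read flip probability ε = error at ordinary sites and
ε = 1 − (1−error)(1−deamination) at damage-prone C/T and G/A pairs, and
the matching binomial genotype likelihoods.

Deliberately not emulated: linkage between SNPs (all sites evolve
independently, so windowed statistics see no LD clustering and gene models
share no variants), demographic change, admixture pulses, recombination
maps, and the imputation process itself (dosages are exact genotypes
unless a jitter is enabled). Passing tests therefore demonstrate the
statistical machinery is correct and calibrated under drift + sampling
noise; they do not show robustness to LD, structure, or reference-panel
bias in real data — genomic control is the only structure defense, as in
the analysis design itself.

## Defaults and their reasons

| parameter | default | why |
|---|---|---|
| Ne | 10,000 | standard European effective size for this era |
| generations × gen_time | 150 × 28 y = 4,200 y | matches a Britain-scale Holocene transect |
| sampling | 600 ancient (evenly spaced dates) + 90 modern | emulates a ~600/90 ancient/modern merge |
| s_selected | 0.02 per SNP | strong but realistic polygenic-regulatory selection |
| error / deamination | 0.01 / 0.05 | typical capture-data rates |
| weight sd | 0.1 | eQTL effects on normalized expression |
| quality filter | drop lowest 20% of R²_gene | standard fraction for imputation filtering |
| MAF / missingness | ≥0.1 / ≤90% | scan filters; MAF on the combined panel, ancient-monomorphic sites dropped separately |
| windows | 20 SNPs, step 10 | window statistic definition |
| peak merging | <5 Mb, 0.1 Mb buffer | locus-level reporting |
| FDR | 0.05 | significance criterion (P<1e-4 / 1e-6 reported as plotted reference lines only) |

## Numerical choices

- OLS for thousands of genes is closed-form and vectorized (shared
  regressor); degenerate genes (zero expression variance) are emitted with
  β = 0, p = 1 and a flag, and excluded from genomic control. Constant
  dates are fatal. A perfect noiseless fit (zero residual) reports p at
  the floating-point floor rather than NaN.
- λ is never clipped below 1: a deflated scan reports λ < 1 as measured.
- IRLS on the logit scale clips the linear predictor at ±30 to avoid
  overflow near fixation; series that fail to converge, or whose |ŝ| ≥ 1,
  are flagged and excluded from windows. Complementing the allele maps
  ŝ → 1/(1+ŝ) − 1 exactly.
- The gamma null is fitted on strictly positive RMS values with location
  pinned at 0; zero-RMS windows get p = 1; an all-equal RMS vector is a
  degenerate input and fatal.
- Quality-filter ties at the cutoff drop the lexicographically smallest
  gene ids; best-tissue ties pick the lexicographically smallest tissue —
  both make reruns byte-identical.
- Strand-ambiguous (A/T, C/G) weight entries whose allele pair appears
  swapped in the panel are dropped, not strand-flipped: the two cases are
  indistinguishable and dropping is conservative.
- Missing dosages are mean-imputed per variant at prediction time (the
  TWAS convention); in the selection estimator they contribute zero trials
  instead.
- Multiallelic VCF records are dropped with a warning (or rejected under
  `on_multiallelic="error"`); splitting DS dosages across ALT alleles has
  no well-defined inverse.

## Design choices that were genuinely open

- **Time sign convention.** t is years before present everywhere, so a
  *negative* TWSS slope means expression rising toward today. The
  concordance report negates slopes before comparing with SDS-like scores
  and says so in its docstring; the orientation is a flag, not a guess.
- **Gene quality timing.** R²_gene is computed over model SNPs present in
  the panel with quality available — the quantity the prediction actually
  used — rather than over the full published model.
- **Score-table polarization.** Whether a public score's sign refers to
  the derived, ancestral or ALT allele varies by source; the table format
  therefore carries an explicit `polarized_allele` column and alignment is
  a stated rule (negate when polarized to the non-effect allele).
- **Windows' gamma fitted genome-wide**, one null for all chromosomes, so
  a chromosome enriched for selection is penalized against the global
  background rather than against itself.

## Problem sizes in the validation suite

Null calibration uses 2,000 drift-only genes on the default 690-sample
design; gene-score normality uses 10,000 genes; selection-coefficient
recovery uses 200 Wright–Fisher replicates; window calibration uses an
all-neutral genome of ~41,000 SNPs (~4,000 windows — the overlap between
adjacent windows makes the significant-fraction estimate noisy, so the
suite measures it above the minimal scale); the end-to-end scenario has
10 selected genes among 2,000. These sizes give Monte-Carlo error
comfortably inside each test's tolerance while keeping the full suite in
the minutes range.

## Known limitations

- The constant-s estimator is biased toward zero when selection truly
  varies over time, and its P-values are not used — only point estimates
  feed the window statistic, as in the window-scan design.
- Without LD simulation, the window scan's null is cleaner than on real
  data, where correlated ŝ within windows fattens the RMS tail; on real
  data the gamma fit absorbs some but not all of this.
- Gene counts and λ from any real dataset depend on the weight database,
  imputation pipeline and cohort; the package asserts calibration
  properties, never dataset-specific counts.
- The read-count/likelihood model is available for building
  pseudohaploid-style pipelines but the default scenarios hand the scans
  exact genotypes; imputation bias at strongly selected sites is therefore
  not reproduced.
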