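# paleotwas

Selection scans on **predicted gene expression** over an ancient-DNA time
transect.

Classic selection scans ask whether individual alleles changed frequency
faster than drift allows. `paleotwas` asks the same question one level up:
using published cis-eQTL weight models (JTI/PredictDB-style), it predicts
each dated individual's normalized expression for every gene as a weighted
sum of allele dosages, then scans for genes whose predicted expression
drifted directionally over thousands of years. Small, coordinated frequency
shifts across a gene's regulatory variants — individually invisible to a
SNP-level scan — become a single testable slope. The package is aimed at
population geneticists working with imputed diploid genotypes from dated
ancient samples merged with a present-day cohort.

## What it computes

**Transcriptome-wide selection scan (TWSS).** For gene *g* with eQTL weights
β<sub>i</sub> and effect-allele dosages d<sub>ij</sub>, predicted expression
is ŷ<sub>gj</sub> = Σ<sub>i</sub> β<sub>i</sub> d<sub>ij</sub>. Per gene, OLS of
ŷ on sample date *t* (years before present) gives a slope β and a two-sided
P-value. Genomic control divides the χ²₁-transformed statistics by
λ = median(χ²)/0.4549 to absorb drift-induced inflation, and
Benjamini–Hochberg FDR is applied to the adjusted P-values. A
date-randomization scan (one global permutation) provides the empirical
null. Genes are pre-filtered by imputation quality
R²<sub>gene</sub> = Σ|β<sub>i</sub>|R²<sub>i</sub> / Σ|β<sub>i</sub>| (the
lowest 20% are dropped).

**SNP-window scan.** After MAF/missingness/ancient-polymorphism filters,
each SNP's selection coefficient is estimated by a binomial logistic
regression of allele counts on generations before present
(ŝ = e<sup>−slope</sup> − 1, a constant-s maximum-likelihood estimator
behind a pluggable interface). Root-mean-square ŝ in 20-SNP windows
(step 10) is compared against a genome-wide maximum-likelihood gamma null;
significant windows under 5 Mb apart merge into peaks with 0.1 Mb buffers.

**Gene-level SDS/iHS.** Pre-computed, normalized SNP scores S<sub>i</sub>
are aligned to each model's effect alleles and aggregated as
score<sub>gene</sub> = Σβ<sub>i</sub>S<sub>i</sub> / √(Σβ<sub>i</sub>²),
a calibrated z-score; genes with scores for under half their SNPs are
removed. A direction-concordance report compares the sign of the gene-level
scores with the time-scan slopes.

**Synthetic data.** A Wright–Fisher generator (genic selection, binomial
drift, HWE sampling of dated diploids, Poisson read counts with 1% error
and 5% deamination at damage-prone sites, Beta-distributed imputation R²)
emits every input format the pipeline consumes, plus truth labels.

## Worked example

```bash
paleotwas all --outdir run1 --seed 5 --n-genes 40 --n-selected 4
cat run1/concordance.json
```

simulates 40 genes (4 under selection, s = 0.02 per SNP) across a
4,200-year transect of 600 ancient + 90 modern diploids, runs every stage,
and prints

```json
{
  "n_same_sign": 4,
  "n_compared": 4,
  "rho": 0.4175219941348973,
  "rho_p": 0.017423858819224095
}
```

All 4 FDR-significant genes in the time scan have gene-level SDS scores
pointing the same way (`n_same_sign`/`n_compared`), and the Spearman ρ over
all tested genes is positive because the synthetic SDS scores were
polarized toward each selected gene's favored alleles. `run1/twss.tsv`
holds the per-gene slopes — for example gene `G00000` (simulated expression
increase toward the present) gets `beta = -2.22e-04` per year BP with
`q = 8.0e-30`: a negative slope on years-before-present means rising
expression toward today. `run1/manifest_twss.json` records the
genomic-control λ (5.4 here — a 40-gene toy run with 4 strongly selected
genes inflates the median χ²; on a 2,000-gene drift-only design λ ≈ 2.2,
the inflation genomic control is there to remove).

Each stage is also a library call (`paleotwas.scan_time.scan`,
`paleotwas.scan_snp.estimate_s_batch`, ...) and a separate subcommand
(`simulate`, `predict`, `twss`, `gwss`, `classic`, `concord`) reading a
shared `--config run.yaml`.

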