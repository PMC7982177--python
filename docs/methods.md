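# Methods

## Model and assumptions

The pipeline assumes the regulatory model of GWAS–eQTL integration: a risk
variant influences the trait through the expression of a specific gene, so a
true risk gene should show *joint* evidence — its eSNPs (SNPs associated
with its expression at the eQTL threshold) should also carry trait
association in the GWAS. Genes are therefore scored on their eSNP sets only;
trait-associated SNPs without expression evidence contribute nothing, which
is what distinguishes this approach from purely positional gene mapping.

### Bayesian eSNP scoring

The per-SNP evidence is the z-based approximate Bayes factor
`log10 BF(z) = ½·log10(1/(1+W)) + (z²/2)·(W/(1+W))·log10(e)` with
`z = Φ⁻¹(1 − p/2)` from the GWAS p-value. This is a reconstruction: the
published Bayesian framework this stage follows integrates genotype-level
quantities that are not recoverable from summary statistics, so we use the
standard normal-approximation Bayes factor, which preserves the qualitative
contract — strictly decreasing in p, negative at z = 0 (evidence against
association), positive for large z, and collapsing to 0 as W → 0. The gene
score adds, per eSNP, the prior log-odds of trait association,
`log10(α/(1−α))`, with α = 1.0×10⁻³ for cis and 5.0×10⁻⁵ for trans eSNPs
(β = 1.0×10⁻³, the eQTL prior, is carried in the configuration for
completeness; for a fixed eSNP set it is a constant and cancels from all
rank-based quantities).

Tunable parameters: `W` (prior effect variance, dimensionless, default
0.1 — a standardized effect SD of ~0.3, appropriate for complex-trait
loci); `esnp_threshold` (eQTL p-value defining an eSNP, default 1e-5 — on
synthetic data this cleanly separates planted signatures from the uniform
background, and it is deliberately configurable because real eQTL resources
publish at many thresholds); `n_sim` (resamples for the simulated P,
default 1000, giving a p-value floor of ~1e-3, sufficient to call the .05
significance rule).

The simulated P resamples GWAS p-values over the gene's eSNP count without
replacement, keeping the cis/trans composition. Composition matching makes
the prior constants cancel under the null (a tested invariance). Resampling
is over the SNP pool, not genomic position, because the synthetic model
makes SNPs exchangeable; with real data exhibiting LD this understates the
null variance for genes with many correlated eSNPs.

### Null-trait GWAS

The negative control randomizes case/control labels i.i.d. Bernoulli(0.5)
and scans every SNP with single-covariate additive logistic regression.
The scan runs a vectorized two-parameter Newton–Raphson across SNPs; the
Wald test is the default (a likelihood-ratio test is available), matching
common GWAS practice, and statsmodels is used as the independent oracle in
the test suite. Monomorphic SNPs are reported p = NA and flagged; fits that
diverge (|log-OR| > 15, the numerical signature of complete separation)
fall back to Fisher's exact test on the carrier-collapsed 2×2 table and are
flagged. No covariates are modelled, matching the null construction this
stage emulates.

### Gene-based association

SNPs map to a gene if they lie in the body or within ±20 kb; coordinates
are 0-based half-open throughout, so the window is `[start−20000,
end+20000)`: a SNP exactly at `start−20000` is in, one at `end+20000` is
out. The gene statistic is the mean over mapped SNPs of the χ²₁ quantile of
1−p; its null distribution is obtained by drawing z ~ MVN(0, R) with R the
Pearson dosage correlation from a reference panel and recomputing the
statistic, with the add-one empirical p `(1+#{stat_sim ≥ stat})/(n_perm+1)`
(default n_perm = 10,000). This is the summary-statistic gene model (the
multiple-regression model on raw genotypes requires individual-level data
the pipeline does not assume). Estimated R matrices that fail PSD (possible
with missing-data panels) are eigenvalue-clipped with a warning;
monomorphic panel columns get zero off-diagonal correlation.

### Enrichment and redundancy clustering

Over-representation uses the upper-tail hypergeometric probability
P(X ≥ k) with BH-FDR across retained sets; sets with universe-intersected
size outside [5, 2000] are excluded before testing. The enrichment
universe is the background of the stage that produced the query — all
genes scored by the discovery stage — rather than the genome, to avoid
selection bias from conditioning on having eSNPs; this is configurable.

Redundancy among enriched sets is summarized on the Jaccard distance
`1 − |A∩B|/|A∪B|`. The 2-D embedding is classical (Torgerson) MDS —
double-centering of squared distances plus eigendecomposition — chosen over
iterative SMACOF because it is deterministic and *exact* (zero stress) on
any distance matrix that is 2-D Euclidean-embeddable, which makes the
embedding testable. Clustering is k-medoids (PAM, seeded restarts with
greedy swap descent) on the original distances, not the embedding, so the
grouping does not inherit embedding distortion; k is user-chosen (the kind
of analysis this reproduces used 5). Each cluster is represented by its
lowest-p member.

### Integration

The overlap permutation draws |set_b| genes uniformly without replacement
from the background universe `n_trials` times (default 100,000) and counts
the overlap with set_a. Both tails are always reported: `empirical_p_ge`
(trials with N_random ≥ N_observation; the enrichment question, and the
default) and `empirical_p_le`. Published prose descriptions of this
procedure sometimes state the counting rule as "N_random ≤ N_observation",
which answers the depletion question and yields p ≈ 1 for an enriched
overlap; reporting both keeps the output unambiguous. The add-one estimator
`(1+count)/(1+trials)` avoids zero p-values; ties count in both tails, so
`p_ge + p_le ≥ 1 + 1/(n_trials+1)` identically.

The comparative analysis computes, at cut points .05/.01/.001, the fraction
of each Bayesian-stage subgroup that is significant in the real-trait
versus null-trait gene-based scan, and applies the paired Student t,
`t = mean(d)/(sd(d)/√m)`, across the table × cut-point rate pairs. One pair
is undefined (error); all-zero differences return t = 0, p = 1.

### Expression validation

Differential expression uses the classical pooled-variance two-sample
Student t (two-sided, signed case − control); "Student t" is taken
literally rather than as Welch, which is available by flag. No
multiple-testing correction is applied on the small focal panel, matching
per-gene reporting at p ≤ .05. Co-expression is the within-group Pearson
matrix on the focal panel with the per-pair case-minus-control change;
groups need ≥ 3 samples for a defined correlation.

## The synthetic-data generator

The generator emulates the four data resources this class of analysis
consumes — a large case/control GWAS, two independent eQTL tables, and a
small case/control expression study — with a planted truth for end-to-end
validation. Defaults (the validation study conditions): 2000 samples, 5000
independent biallelic SNPs (MAF uniform in [0.05, 0.5]), 500 genes laid
100 kb apart on one chromosome with 20 kb bodies (windows disjoint, 10 SNPs
per gene), 4 true genes with 3 cis eSNPs each, per-allele GWAS log-odds 0.4
on the planted eSNPs (phenotype via a logistic model, then the actual
per-SNP scan — the GWAS table is computed, not synthesized), and an eQTL
effect of 0.35 residual-SD per allele converted to a z noncentrality at a
nominal eQTL sample size of 1000 (the scale of the monocyte-cohort class
of eQTL studies). eQTL p-values are generated directly from that
noncentral z rather than from simulated expression-genotype pairs, because
the pipeline consumes association tables, not raw pairs. Non-true genes
receive background eSNPs (significant eQTL, no trait effect) at rate 0.3,
with occasional trans assignments; sub-threshold filler rows exercise the
eSNP filter. The expression arm defaults to 9 cases / 10 controls, the
size of the epicardial-adipose expression study this stage mirrors, with
the focal panel's group-specific correlations assembled into one
correlation matrix per group (unspecified entries 0, nearest-PSD projected
with unit diagonal) and drawn jointly, so genes shared between planted
pairs remain consistent.

An optional block-LD mode (latent Gaussian copula, block-constant latent
correlation ρ, block size b) exists solely to exercise the gene-based
test's LD handling.

What the generator does **not** emulate: realistic human LD maps and
recombination structure, allele-frequency spectra, population
stratification, imputation uncertainty, sex chromosomes, genomic inflation,
probe-level microarray noise, and eQTL effect-size/allele-frequency
coupling. Passing tests therefore demonstrate the *statistical machinery*
(calibration, ranking, determinism) under the stated generative model, not
performance on real cohorts.

## Numerical choices

- All empirical p-values use the add-one estimator with ties counted in the
  observed direction (≥), giving floors of 1/(n+1) and values in (0, 1].
- GWAS p = 0 is clamped to 1e-300 with a warning before z conversion.
- Newton–Raphson runs ≤ 40 iterations to a step tolerance of 1e-10;
  separation is declared at |log-OR| > 15.
- Seeds: every stochastic stage receives a child of the single global seed
  via `numpy.random.SeedSequence`; identical config + seed reproduces every
  output byte-for-byte (tested).
- Degenerate inputs: single-class labels, empty eSNP lists, empty SNP
  lists, k < 1 clusters, single-pair paired t, and sub-minimum group sizes
  all raise informative errors rather than returning sentinel values;
  monomorphic/constant features return flagged NA.

## Validation problem sizes

The test suite validates planted-gene recovery on the default study (5000
SNPs / 500 genes / 4 true genes), null calibration with 500 replicates per
empirical-p family (KS against uniform), type-I error of the gene-based
test over 2000 null genes with block LD (ρ = 0.5, b = 5; observed rate
~0.05), exact-oracle equivalence for the hypergeometric tail (all
configurations with universe ≤ 20, rational arithmetic), pooled and paired
t (closed forms, 1e-12), and the χ²₁ single-SNP statistic. These sizes are
the package's reference conditions and run in well under a minute apiece.

## Known limitations

- The Bayes factor is a summary-statistic approximation; published scores
  from genotype-level implementations of this framework will differ
  numerically (ranks agree under the model assumptions).
- The simulated-P null ignores LD between eSNPs of the same gene.
- k-medoids with greedy restarts is exact only in the tested regimes
  (clear cluster separation); near-degenerate distance matrices may admit
  ties resolved by seed.
- The expression reader expects the two-line-header TSV dialect written by
  this package; arbitrary platform exports (e.g. GEO series matrices) need
  reshaping to it first.
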