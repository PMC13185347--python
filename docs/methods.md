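# Methods

`hologwas` implements an integrated host-genetics × gut-microbiota analysis
of feed efficiency in a segregating cohort: relationship-kernel construction,
REML variance partitioning, mixed-model association scans for the trait and
for taxon abundances, a two-part microbiome-wide association model, and the
intersection logic that nominates trait-associated taxa under host-genetic
control.  A synthetic-cohort generator with retained ground truth provides
the recovery experiments that validate every stage.

## Models

### Relationship kernels

The genomic relationship matrix (GRM) between individuals *i* and *j* is

    g_ij = (1/n) Σ_z (x_iz − 2p_z)(x_jz − 2p_z) / (2 p_z (1 − p_z)),

over n biallelic variants, where x are **reference-allele** dosages and p_z
is the sample reference-allele frequency.  Most GWAS software counts the ALT
allele; only effect signs differ between the conventions.  Missing dosages
are mean-imputed inside kernel and association computations only (storage
keeps the missing marker).

The microbial relationship matrix (MRM) of one gut segment (duodenum,
jejunum, ileum, cecum) is the analogous cross-product of per-taxon
standardized abundances, equal to (1/t)·ZZᵀ for the column-standardized
taxon matrix Z.  Standardization uses the unbiased (n−1) variance — the
denominator convention is not dictated by the estimator itself, and this
choice matches common GREML tooling; it makes the mean MRM diagonal
(n−1)/n rather than exactly 1 (each standardized column satisfies
Σz² = n−1).

Taxa enter the MRM after core filtering (mean relative abundance ≥ 0.05%
and detection in ≥ 30% of samples, both inclusive), centred log-ratio (CLR)
transformation, and z-scoring.  Filtering precedes CLR because prevalence
and relative-abundance thresholds are defined on the compositional scale,
not on log-ratios.  Zeros are replaced before CLR by multiplicative simple
replacement with pseudocount = 0.5 × the smallest nonzero relative abundance
in the table (configurable); rows are re-closed so each CLR row sums to 0.

Genetic principal components come from the eigendecomposition of the
double-centred GRM (scores = eigenvector × √eigenvalue); the top five PCs
plus an intercept are the fixed effects of every downstream model.
Kernels with eigenvalues in [−1e-8·λmax, 0) are bent to PSD by clipping.

### Variance components (REML)

All variance estimation uses the multi-kernel linear mixed model
y = Xb + Σ_k u_k + e with u_k ~ N(0, σ²_k K_k), e ~ N(0, σ²_e I), maximizing
the restricted likelihood

    lR = −½[(n−p) log 2π + log|V| + log|XᵀV⁻¹X| + yᵀPy].

* **Optimizer.**  Average-information (AI) REML with step-halving and an
  EM fallback; components that hit the floor (1e-6 × var(y)) are pinned and
  dropped from the AI solve, and released when their score turns positive.
  Iterations stop when the restricted log-likelihood improves by < 1e-8
  (default max 200 iterations; non-convergence is flagged, never silent).
  The accepted iteration path is monotone non-decreasing by construction.
* **Single-kernel fast path.**  With one kernel the model is solved exactly
  through one eigendecomposition of K and a 1-D profile-likelihood search
  over λ = σ²_k/σ²_e (log-spaced grid + bounded refinement, boundary λ = 0
  checked explicitly).  Both paths evaluate the same criterion; tests
  require their agreement and verify the criterion itself against the exact
  multivariate-normal density of error contrasts Aᵀy (offset ½·log|XᵀX|).
* **Uncertainty.**  Component covariance is the inverse AI matrix at the
  optimum; variance ratios (heritability h² = σ²_g/σ²_p, per-kernel
  explainability) get delta-method standard errors, validated against a
  parametric bootstrap within a factor of 1.5.
* **Significance.**  A single variance component on the boundary is tested
  by LRT with the ½χ²₀ + ½χ²₁ mixture reference (p = ½·P(χ²₁ ≥ LRT); a flag
  restores plain χ²₁ for compatibility with tools that use it).
* **Heritable-taxon screen.**  Every CLR taxon abundance is fitted with the
  genomic kernel (top-5 PC covariates, mirroring the trait model) and
  flagged heritable when h² > 0.2 AND p_LRT < 0.05 jointly.  One GRM
  eigendecomposition is shared across all taxa; fit failures propagate as
  flagged NaN rows.

### Association scans

Per-variant tests use y = Za + xb + g + e with g ~ N(0, σ²_g G).  The null
variance components are estimated once by REML and reused for every variant
(the standard "population parameters previously determined" device): after
rotating by the eigenvectors of G, each variant costs O(n) for the
generalized-least-squares effect, SE, Wald χ²₁ statistic and p-value.
Monomorphic variants are flagged untestable, not dropped.  An `exact` mode
re-estimates the variance ratio per variant for small problems; it agrees
with the fast mode to within a few percent in −log₁₀p away from the largest
effects (the residual difference is the genuine statistical gap between the
two estimators, largest for strong causal variants).  mGWAS reuses the same
scan on the CLR abundance of each taxon that passed the heritability screen.

Per-SNP phenotypic variance explained uses the summary-statistic convention

    PVE = 2f(1−f)β² / (2f(1−f)β² + 2f(1−f)·se²·n),

a function of the association output only.  Note its denominator
approximates var(y) plus the SNP's own variance, so it reports roughly
pve/(1+pve) of the true fraction — a property shared by published values
computed the same way.

Significance thresholds are fixed Bonferroni quantities: genome-wide
0.05/n_tests, suggestive 1/n_tests (exact division internally, 3
significant digits for display).  LD is the squared Pearson correlation of
unphased dosage columns (composite LD, missing pairs dropped); haplotype
blocks are maximal runs of map-consecutive variants whose every **adjacent**
pair exceeds r² > 0.8 (an all-pairs rule is available by flag; singletons
are not blocks; spans are closed base-pair intervals).

### Two-part MWAS and integration

Each core taxon is tested against FCR twice: a binary part regressing the
trait on presence/absence (applicable when prevalence is strictly between 0
and 1 — it equals the equal-variance two-sample t-test), and a quantitative
part regressing the trait on log₁₀ relative abundance over present samples
only (requiring ≥ 10 present to avoid near-degenerate regressions).  Both
models carry an intercept and residual term and test the slope.  P-values
are Benjamini–Hochberg adjusted within part × segment, and a taxon is a
"key" hit at FDR < 0.05 in either part.

Trait-stratified differential abundance compares a taxon's CLR abundance
across genotype classes at each trait-associated SNP by one-way ANOVA plus
exact pairwise Wilcoxon rank-sum tests (exact enumeration when the combined
pair size is ≤ 20); genotype classes with fewer than two observations are
dropped rather than failing the SNP, and a taxon counts as
genotype-differential when ANOVA p < 0.05 at **any** trait-associated SNP
(capped at the 20 strongest hits).  The final integration keeps taxa that
are genotype-differential AND a two-part hit, tracks mGWAS membership as a
fourth set, and annotates every kept taxon with its Pearson correlation (and
sign) against FCR on the CLR scale.

## Synthetic cohort

The generator emulates the study design the analysis assumes: 313
individuals from two lines diverged in feed efficiency, biallelic SNPs at
desk scale (default 5,000 across 5 chromosomes; MAF ~ U(0.05, 0.5), line
frequencies drifting with variance 0.05 truncated to (0.01, 0.99), genotypes
Binomial(2, freq)), four 50-taxon segment microbiomes, and a phenotype built
bottom-up as

    y = fixed + g + m_d + m_j + m_i + m_c + e.

* **Genetic value g** is a weighted sum of standardized causal dosages
  (default 10 causal SNPs), rescaled so its sample variance equals the
  configured fraction v_g.  Causal variants are drawn from QC-stable common
  variants (MAF ≥ 0.05, exact-HWE p ≥ 1e-6 in the pooled sample): simulated
  SNPs are mutually unlinked, so a causal variant that QC removes would
  leave no tagging proxy and its variance would be invisible to every
  analysis by construction rather than by biology.
* **Microbial effects m_k** are random-weight combinations of the segment's
  standardized CLR taxa — exactly the construction the MRM kernelizes — each
  rescaled to its configured fraction.  Defaults mirror the variance
  partition the package targets: genetic 0.3696, duodenum 0.0796, jejunum
  0.0763, ileum 0.0, cecum 0.1390, residual 0.3355.
* **Orthogonalization.**  Each component is centred and residualized
  against the previously built ones before rescaling, so configured
  fractions are realized essentially exactly rather than up to O(n^-1/2)
  sampling covariance (the planted cecal effect keeps its genuine overlap
  with g).
* **Taxon abundances** are log-normal: latent = baseline (N(0, 1.5²); the
  first taxon of each segment is a high-baseline, fully prevalent core
  taxon so rows stay closable) + genetic liability (for 5 driven taxa per
  segment, default fraction 0.4 via 3 causal SNPs) + N(0, 1−fraction)
  noise; observed = presence × exp(latent), rows closed to relative
  abundances.  Zeros default to **detection-limit censoring**: a taxon is
  absent when its latent value falls below its π-quantile, so the marginal
  absence rate is the configured π but zeros are informative.  An
  independent-Bernoulli zero mechanism is available
  (`zero_mechanism="bernoulli"`); under it, presence carries no signal, and
  a zero-inflated taxon cannot be simultaneously heritable on the CLR scale
  and binary-part trait-associated — which is why censoring is the default
  for recovery experiments.
* **Trait scale.**  FCR is an affine recalibration of y to mean 2.3,
  sd 0.25 (a plausible feed-conversion scale for a 22–42-day test period);
  variance ratios are unaffected, so all acceptance checks use ratios.  FI
  and BWG columns are generated so FCR = FI/BWG holds exactly.
* **Planted-taxon scenario.**  One extra cecal taxon with genetic fraction
  0.8 (2 dedicated causal SNPs), absence rate 0.10, and a negative weight
  carrying half of the cecal effect variance; its causal SNPs also receive
  direct trait effects (share 0.25 of v_g each), sign-aligned with the
  microbial route so the genetic and microbial paths reinforce.  This taxon
  is the end-to-end positive control: heritable, mGWAS-detectable,
  two-part-associated and genotype-differential.

What the generator does **not** emulate: linkage disequilibrium, phylogenetic
correlation among taxa, sequencing depth/compositional count noise,
segment-to-segment microbial exchange, or shared environment.  Passing
recovery tests therefore demonstrates correctness of the estimators under
the stated generative model, not robustness to those real-data features —
in particular, the absence of LD makes GREML standard errors scale as
√(2p)/n, so experiment sizes here trade variant count against power in a
way real LD-structured data does not.

## Problem sizes and numerical choices

Recovery experiments (also run by `scripts/acceptance.py`) use: single-kernel
heritability at h² = 0.23, n = 500, 1,000 variants, 100 replicates;
five-kernel partition at the default fractions, n = 500, 50 replicates;
null-scan calibration over 5,000 variants at n = 300 with an infinitesimal
polygenic background; the REML grid oracle at n = 40; per-SNP PVE recovery
at n = 313 with two causal SNPs carrying h² = 0.23; and the planted-taxon
experiment at n = 313, 1,500 variants, 20 seeds.  The planted experiment
uses 1,500 variants because the heritable-taxon screen's power is governed
by se(ĥ²) ≈ √(2p)/n for unlinked SNPs (≈ 0.14 at p = 1,500 versus ≈ 0.25 at
p = 3,000).

Numerical details: variance floor 1e-6·var(y); PSD bending tolerance
−1e-8·λmax; REML convergence 1e-8 in log-likelihood; CLR pseudocount rule as
above; exact HWE test two-sided by summing configuration probabilities ≤ the
observed one (with a 1e-12 relative fudge for float ties); Wilcoxon exact
enumeration switches to the tie-corrected normal approximation above a
combined pair size of 20; BH adjustment delegates to statsmodels and is
property-tested against the literal step-up definition.  All randomness in
the generator and experiments flows from a single integer seed through
spawned child seeds.

## Known limitations

* Heritability on the CLR observation scale is attenuated relative to the
  latent-scale fraction: the taxon's own zero handling and the CLR
  per-sample centring (which mixes in other taxa's detection-limit values)
  both add non-genetic variance.  At default zero-inflation this costs
  roughly 0.05–0.10 in h² for a taxon generated at 0.4.
* The fast association mode shares one null variance fit across variants;
  for variants with large effects it can differ from per-variant REML by
  ~10–15% in −log₁₀p (ranking is essentially unchanged).
* The two-line design places substantial genetic variance along PC1; since
  the top PCs are covariates, line-differentiated causal variance is partly
  absorbed, and single-population configurations are used where recovery of
  a configured fraction is the point.
* Mean imputation of missing dosages is the minimal stand-in for genotype
  imputation, which is out of scope.
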