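# hologwas

Joint host-genetics and gut-microbiota analysis of feed efficiency.

Feed conversion ratio (FCR = feed intake / body-weight gain) is the central
economic trait in poultry and livestock production, and it is shaped both by
the host genome and by the microbial communities along the intestinal tract.
`hologwas` is a tested pipeline for quantifying and dissecting those two
influences in a genotyped cohort with segment-resolved microbiome profiles
(duodenum, jejunum, ileum, cecum).  It is aimed at quantitative geneticists
and microbiome researchers who want the whole chain — kernels, variance
components, association scans, microbiome-wide association, and the
integration of the evidence — in one reproducible package.

## What it computes

* **Relationship kernels.**  A genomic relationship matrix (GRM) from
  reference-allele dosages, `g_ij = (1/n) Σ_z (x_iz − 2p_z)(x_jz − 2p_z) /
  (2p_z(1 − p_z))`, and per-segment microbial relationship matrices (MRM),
  `(1/t)·ZZᵀ` over standardized CLR taxon abundances, plus genetic PCs.
* **Variance components (AI-REML).**  SNP heritability from
  `y = Za + g + e`, `g ~ N(0, G σ²_g)` with `h² = σ²_g/σ²_p`, and the
  five-kernel "omics explainability" partition
  `y = Za + g + m_d + m_j + m_i + m_c + e` with `m_k ~ N(0, M_k σ²_k)`;
  boundary-aware likelihood-ratio tests and delta-method standard errors.
* **Association.**  Mixed-linear-model GWAS (`y = Za + xb + g + e`) with the
  spectral one-eigendecomposition trick, Bonferroni thresholds (0.05/m and
  1/m), per-SNP phenotypic variance explained, LD r² and haplotype blocks
  (adjacent r² > 0.8), and mGWAS of heritable taxa (h² > 0.2, P_LRT < 0.05)
  on CLR abundances.
* **Microbiome-wide association.**  A two-part model per taxon — trait on
  presence/absence, and trait on log₁₀ relative abundance among present
  samples — with Benjamini-Hochberg FDR per part, genotype-stratified
  differential abundance (ANOVA + exact Wilcoxon) at trait-associated SNPs,
  and the set intersection nominating trait-associated taxa under host
  genetic control.
* **Synthetic cohorts.**  A generator producing genotypes for two diverged
  lines, four zero-inflated compositional microbiomes with partially
  host-genetic taxa, and a phenotype with an exact, retained variance
  decomposition — the basis of all recovery tests.

The scientific model and the numerical choices behind each stage are
documented in [docs/methods.md](docs/methods.md).

## Worked example

```python
import hologwas as hg
from hologwas.pipeline import analysis_covariates

cfg = hg.SimulationConfig(n_individuals=313, n_variants=1500,
                          planted_taxon=True, seed=3)
genotypes, tables, phenotypes, truth = hg.simulate_all(cfg)
genotypes = hg.filter_variants(genotypes)          # --geno/--maf/--hwe QC
grm = hg.build_grm(genotypes)
pcs, X = analysis_covariates(grm, n_pcs=5)         # intercept + top 5 PCs

fit = hg.reml_fit(phenotypes.fcr, [grm], X, names=["genetic"])
null = hg.VarianceComponentModel(phenotypes.fcr, [], exog=X).fit()
lrt, p = hg.lrt_component(fit, null)
h = fit.heritability("genetic")
print(f"FCR heritability: h2 = {h.h2:.3f} (se {h.se:.3f}), LRT p = {p:.2e}")

mrms = [hg.build_mrm(hg.clr_transform(hg.filter_core_taxa(tables[s])))
        for s in hg.SEGMENTS]
part = hg.reml_fit(phenotypes.fcr, [grm] + mrms, X,
                   names=["genetic", *hg.SEGMENTS], method="ai")
print(part.summary())

scan = hg.mlm_assoc(phenotypes.fcr, genotypes, grm, X, feature="FCR")
print(scan.summary())
```

prints

```
FCR heritability: h2 = 0.432 (se 0.163), LRT p = 6.41e-03

Variance-component REML results
==============================================
n obs                 313
fixed-effect rank     6
restricted loglik     22.552499
converged             True (7 iterations)
----------------------------------------------
component         sigma2     ratio        se
genetic           0.0176    0.2895    0.0083
duodenum          0.0021    0.0342    0.0017
jejunum           0.0032    0.0531    0.0020
ileum             0.0000    0.0000    0.0015
cecum             0.0181    0.2982    0.0051
residual          0.0197    0.3250    0.0073
----------------------------------------------
sigma2_p          0.0608

Mixed-model association scan: FCR
  n = 313, tested variants = 1238
  null sigma2_g = 0.0271, sigma2_e = 0.0356
  thresholds: genome-wide 4.04e-05, suggestive 0.000808
  hits: 2 genome-wide, 3 suggestive
  mean PVE of suggestive hits: 0.098
```

Reading this: the single-kernel model attributes 43% of FCR variance to the
genome-wide kernel in this draw (the planted scenario deliberately makes one
cecal taxon strongly genetic, so genetics and the cecum share signal — the
five-kernel partition then splits the same variance into a direct genetic
share of 29% and a cecal share of 30%, with the ileum at the boundary).  The
scan finds the planted causal variants: 2 SNPs clear the genome-wide
Bonferroni cut and each explains ~10% of trait variance by the
summary-statistic PVE convention.  On this dataset
`hg.screen_heritable_taxa` then flags 2–6 heritable genera per segment, and
the two-part MWAS + genotype-differential intersection recovers the planted
cecal taxon (see `hologwas.pipeline.run_study` for the one-call version).

The same chain is scriptable from a shell via the `hologwas` CLI
(`simulate`, `kernels`, `reml`, `varpart`, `gwas`, `mgwas`, `mwas`,
`integrate`), each subcommand driven by a single YAML config.

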