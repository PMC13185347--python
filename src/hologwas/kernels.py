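"""Variant/taxon filtering, compositional transforms, and relationship kernels.

The genomic relationship matrix (GRM) between individuals i and j is

    g_ij = (1/n) * sum_z (x_iz - 2 p_z)(x_jz - 2 p_z) / (2 p_z (1 - p_z))

over n variants with reference-allele dosages x and sample reference-allele
frequency p_z.  The microbial relationship matrix (MRM) of a gut segment is the
analogous cross-product of per-taxon standardized abundances,

    m_ij = (1/t) * sum_a (x_ia - mean_a)(x_ja - mean_a) / var_a ,

i.e. (1/t) Z Z' for the column-standardized abundance matrix Z.  Standardization
uses the unbiased (n-1) variance throughout, so the mean MRM diagonal is
(n-1)/n rather than exactly 1.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from skbio.stats.composition import clr as _skbio_clr

from .datatypes import MISSING, AbundanceTable, GenotypeMatrix, KernelMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "hwe_exact_test",
    "filter_variants",
    "filter_core_taxa",
    "clr_transform",
    "standardize_taxa",
    "build_grm",
    "build_mrm",
    "kernel_pca",
]


def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact two-sided Hardy-Weinberg test p-value.

    Enumerates every heterozygote count compatible with the observed allele
    counts, computes each configuration's probability under HWE, and sums the
    probabilities no larger than the observed one (Wigginton-style exact test).
    """
    if min(n_hom_ref, n_het, n_hom_alt) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        raise ValueError("no observed genotypes")
    rare = 2 * min(n_hom_ref, n_hom_alt) + n_het  # minor-allele copies
    # heterozygote counts share the parity of the rare-allele count
    het_values = np.arange(rare % 2, min(rare, 2 * n - rare) + 1, 2)
    # unnormalized log-probabilities: P(het) prop. 2^het * n! / (prod of
    # genotype factorials); allele-count factor is constant across het.
    from scipy.special import gammaln

    hom_rare = (rare - het_values) // 2
    hom_common = n - het_values - hom_rare
    logp = (
        het_values * np.log(2.0)
        - gammaln(hom_rare + 1)
        - gammaln(het_values + 1)
        - gammaln(hom_common + 1)
    )
    prob = np.exp(logp - logp.max())
    prob /= prob.sum()
    obs = prob[np.where(het_values == n_het)[0][0]]
    return float(min(1.0, prob[prob <= obs * (1 + 1e-12)].sum()))


def filter_variants(
    g: GenotypeMatrix,
    max_missing: float = 0.1,
    min_maf: float = 0.05,
    hwe_alpha: float = 1e-6,
) -> GenotypeMatrix:
    """Drop variants by missing rate, minor-allele frequency and exact HWE.

    Mirrors the usual ``--geno / --maf / --hwe`` quality-control trio; each
    criterion's removal count is logged.
    """
    for name, v in (("max_missing", max_missing), ("min_maf", min_maf), ("hwe_alpha", hwe_alpha)):
        if not 0 <= v <= 1:
            raise ValueError(f"{name} must lie in [0, 1]")
    d = g.dosages
    n = g.n_samples
    miss_rate = (d == MISSING).sum(axis=0) / n
    keep_miss = miss_rate <= max_missing

    x = d.astype(float)
    x[d == MISSING] = np.nan
    freq = np.nanmean(x, axis=0) / 2.0
    maf = np.minimum(freq, 1.0 - freq)
    keep_maf = maf >= min_maf

    keep_hwe = np.ones(g.n_variants, dtype=bool)
    for j in np.where(keep_miss & keep_maf)[0]:
        col = d[:, j]
        obs = col[col != MISSING]
        counts = (int((obs == 2).sum()), int((obs == 1).sum()), int((obs == 0).sum()))
        keep_hwe[j] = hwe_exact_test(*counts) >= hwe_alpha

    keep = keep_miss & keep_maf & keep_hwe
    logger.info(
        "variant filter: %d/%d retained (missing>%g: %d, maf<%g: %d, hwe p<%g: %d)",
        keep.sum(), g.n_variants,
        max_missing, (~keep_miss).sum(),
        min_maf, (keep_miss & ~keep_maf).sum(),
        hwe_alpha, (keep_miss & keep_maf & ~keep_hwe).sum(),
    )
    if not keep.any():
        raise ValueError("variant filtering removed every variant; review thresholds")
    return g.take_variants(np.where(keep)[0])


def filter_core_taxa(
    t: AbundanceTable,
    min_total_rel_abund: float = 0.0005,
    min_prevalence: float = 0.30,
) -> AbundanceTable:
    """Keep 'core' taxa: mean relative abundance >= ``min_total_rel_abund``
    (0.05% by default) AND detected (abundance > 0) in >= ``min_prevalence``
    of samples (30% by default, inclusive).  Retained rows are re-closed to 1.
    """
    rel = t.to_relative()
    v = rel.values
    mean_abund = v.mean(axis=0)
    prevalence = (v > 0).mean(axis=0)
    keep = (mean_abund >= min_total_rel_abund) & (prevalence >= min_prevalence)
    logger.info(
        "core-taxon filter (%s): %d/%d retained (abundance fail %d, prevalence fail %d)",
        t.segment, keep.sum(), len(keep),
        (mean_abund < min_total_rel_abund).sum(),
        ((mean_abund >= min_total_rel_abund) & (prevalence < min_prevalence)).sum(),
    )
    if not keep.any():
        raise ValueError("core-taxon filtering removed every taxon")
    kept = rel.data.loc[:, keep]
    sums = kept.to_numpy().sum(axis=1, keepdims=True)
    if (sums <= 0).any():
        raise ValueError("a sample has zero abundance over the retained core taxa")
    return AbundanceTable(kept / sums, t.segment, "relative", t.rank)


def clr_transform(t: AbundanceTable, pseudocount: float | None = None) -> AbundanceTable:
    """Centred log-ratio transform: ln(x) - mean(ln x) per sample.

    Zeros are replaced multiplicatively before the transform: each zero becomes
    ``pseudocount`` (default half the smallest nonzero relative abundance in
    the table) and the nonzero entries of that sample are shrunk to keep the
    row closed.  Each output row sums to 0.
    """
    rel = t.to_relative()
    v = rel.values.copy()
    if (v.sum(axis=1) <= 0).any():
        raise ValueError("all-zero sample row cannot be CLR-transformed")
    if (v == 0).any():
        if pseudocount is None:
            pseudocount = 0.5 * v[v > 0].min()
        n_zero = (v == 0).sum(axis=1, keepdims=True)
        v = np.where(v == 0, pseudocount, v * (1.0 - n_zero * pseudocount))
        if (v <= 0).any():
            raise ValueError("pseudocount too large: replacement left non-positive values")
        v = v / v.sum(axis=1, keepdims=True)
    out = _skbio_clr(v)
    return AbundanceTable(
        pd.DataFrame(out, index=rel.data.index, columns=rel.data.columns),
        t.segment, "clr", t.rank,
    )


def standardize_taxa(t: AbundanceTable) -> AbundanceTable:
    """z-score every taxon column (mean 0, unbiased n-1 variance 1)."""
    v = t.values
    mean = v.mean(axis=0)
    sd = v.std(axis=0, ddof=1)
    bad = np.where(sd == 0)[0]
    if bad.size:
        raise ValueError(f"zero-variance taxa cannot be standardized: {[t.taxa[i] for i in bad]}")
    return AbundanceTable(
        pd.DataFrame((v - mean) / sd, index=t.data.index, columns=t.data.columns),
        t.segment, "zscore", t.rank,
    )


def build_grm(g: GenotypeMatrix) -> KernelMatrix:
    """Genomic relationship matrix from reference-allele dosages.

    Missing dosages are mean-imputed; the allele frequency p_z is the sample
    reference-allele frequency.  Monomorphic variants make the denominator
    vanish and must be filtered out first.
    """
    x = g.imputed()
    p = x.mean(axis=0) / 2.0
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("monomorphic variant present; run filter_variants first")
    w = (x - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
    values = (w @ w.T) / g.n_variants
    return KernelMatrix(g.samples, values, "GRM").bent()


def build_mrm(t: AbundanceTable) -> KernelMatrix:
    """Microbial relationship matrix: (1/t) Z Z' of standardized taxa."""
    z = standardize_taxa(t).values
    values = (z @ z.T) / z.shape[1]
    return KernelMatrix(t.samples, values, "MRM", t.segment).bent()


def kernel_pca(k: KernelMatrix, n_components: int = 5):
    """Principal components of a relationship kernel.

    The kernel is double-centred, eigendecomposed, and the top components
    returned as scores (eigenvector * sqrt(eigenvalue)) alongside
    variance-explained fractions (eigenvalue / trace of the centred kernel).
    """
    if n_components > k.n:
        raise ValueError(f"n_components={n_components} exceeds n={k.n}")
    n = k.n
    j = np.eye(n) - np.ones((n, n)) / n
    c = j @ k.values @ j
    w, u = np.linalg.eigh(c)
    order = np.argsort(w)[::-1][:n_components]
    lam = np.clip(w[order], 0.0, None)
    scores = u[:, order] * np.sqrt(lam)
    fractions = lam / np.clip(np.trace(c), np.finfo(float).tiny, None)
    scores_df = pd.DataFrame(
        scores, index=k.samples, columns=[f"PC{i + 1}" for i in range(len(order))]
    )
    return scores_df, fractions
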