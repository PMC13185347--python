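"""Two-part microbiome-wide association with FCR and the integration logic.

The two-part model treats each taxon twice: a binary part regressing the trait
on presence/absence (abundance > 0), and a quantitative part regressing the
trait on log10 relative abundance over the present samples only.  Within each
part, p-values are Benjamini-Hochberg adjusted across the segment's taxa, and
a taxon is a "key" hit when FDR < 0.05 in either part.

"FCR-associated microbiota affected by host genetics" are then the taxa that
are simultaneously (i) a two-part hit (binary or abundance part) and (ii)
differentially abundant across genotypes at a trait-associated SNP; taxon
membership in the mGWAS-hit set is tracked alongside.  Overlapping taxa are
annotated with their Pearson correlation against the trait on the CLR scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import AbundanceTable

__all__ = [
    "TwoPartResult",
    "bh_adjust",
    "two_part_mwas",
    "genotype_differential",
    "taxon_trait_correlation",
    "integrate_taxa",
]

MIN_PRESENT_QUANTITATIVE = 10  # guard against near-degenerate regressions


@dataclass
class TwoPartResult:
    taxon: str
    segment: str
    beta_binary: float | None
    p_binary: float | None
    q_binary: float | None
    beta_abundance: float | None
    p_abundance: float | None
    q_abundance: float | None
    key: bool


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values), capped at 1."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def two_part_mwas(y, table: AbundanceTable, fdr: float = 0.05) -> pd.DataFrame:
    """Two-part association of every taxon in one segment with the trait.

    Binary part: simple regression of y on the presence indicator, applicable
    when prevalence is strictly between 0 and 1.  Quantitative part: regression
    of y on log10 relative abundance over present samples, applicable with at
    least ``MIN_PRESENT_QUANTITATIVE`` present.  BH adjustment runs within each
    part across the segment's taxa.

    Returns a frame with columns taxon, segment, part betas/p/q and ``key``.
    """
    y = np.asarray(y, dtype=float).ravel()
    rel = table.to_relative()
    if len(rel.samples) != y.size:
        raise ValueError("trait vector does not match the abundance table")
    rows = []
    for taxon in rel.taxa:
        x = rel.data[taxon].to_numpy(dtype=float)
        present = x > 0
        b1 = p1 = b2 = p2 = None
        if 0 < present.sum() < present.size:
            fit = stats.linregress(present.astype(float), y)
            b1, p1 = float(fit.slope), float(fit.pvalue)
        if present.sum() >= MIN_PRESENT_QUANTITATIVE:
            q = np.log10(x[present])
            if np.ptp(q) > 0:
                fit = stats.linregress(q, y[present])
                b2, p2 = float(fit.slope), float(fit.pvalue)
        rows.append([taxon, rel.segment, b1, p1, b2, p2])
    df = pd.DataFrame(rows, columns=["taxon", "segment", "beta_binary", "p_binary",
                                     "beta_abundance", "p_abundance"])
    for part in ("binary", "abundance"):
        pcol, qcol = f"p_{part}", f"q_{part}"
        df[qcol] = np.nan
        mask = df[pcol].notna()
        if mask.any():
            df.loc[mask, qcol] = bh_adjust(df.loc[mask, pcol].to_numpy())
    df["binary_hit"] = df["q_binary"] < fdr
    df["abundance_hit"] = df["q_abundance"] < fdr
    df["key"] = df["binary_hit"] | df["abundance_hit"]
    return df


def genotype_differential(values, genotypes, alpha: float = 0.05) -> dict:
    """Compare a numeric vector across genotype classes at one SNP.

    One-way ANOVA across all classes plus exact pairwise Wilcoxon rank-sum
    tests (exact enumeration when the combined pair size is <= 20, normal
    approximation with tie correction otherwise).  Classes with fewer than two
    observations are dropped with a warning rather than failing the SNP.
    """
    import logging

    values = np.asarray(values, dtype=float).ravel()
    genotypes = np.asarray(genotypes)
    if values.size != genotypes.size:
        raise ValueError("values and genotype classes must align")
    groups = {}
    for cls in pd.unique(genotypes):
        v = values[genotypes == cls]
        if v.size >= 2:
            groups[cls] = v
        else:
            logging.getLogger(__name__).warning(
                "genotype class %r has <2 observations; dropped", cls)
    if len(groups) < 2:
        raise ValueError("fewer than two genotype classes with >= 2 observations")
    fstat, p_anova = stats.f_oneway(*groups.values())
    pairwise = {}
    labels = list(groups)
    for a in range(len(labels)):
        for b in range(a + 1, len(labels)):
            ga, gb = groups[labels[a]], groups[labels[b]]
            method = "exact" if ga.size + gb.size <= 20 else "asymptotic"
            res = stats.mannwhitneyu(ga, gb, alternative="two-sided", method=method)
            pairwise[(labels[a], labels[b])] = float(res.pvalue)
    return {
        "group_sizes": {k: int(v.size) for k, v in groups.items()},
        "anova_f": float(fstat),
        "anova_p": float(p_anova),
        "wilcoxon_p": pairwise,
        "significant": bool(p_anova < alpha),
    }


def taxon_trait_correlation(abundance, y) -> tuple[float, float]:
    """Pearson correlation (r, two-sided p) between a taxon's CLR abundance
    and the trait."""
    abundance = np.asarray(abundance, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if abundance.size != y.size or abundance.size < 3:
        raise ValueError("need aligned vectors with n >= 3")
    if np.ptp(abundance) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input has undefined correlation")
    r, p = stats.pearsonr(abundance, y)
    return float(r), float(p)


def integrate_taxa(
    two_part: pd.DataFrame,
    mgwas_taxa,
    differential: pd.DataFrame,
    y,
    clr_tables,
) -> pd.DataFrame:
    """Intersect the evidence streams into the final taxon table.

    Parameters
    ----------
    two_part : DataFrame
        Concatenated :func:`two_part_mwas` output across segments.
    mgwas_taxa : iterable of (taxon, segment)
        Taxa with at least one mGWAS-significant SNP.
    differential : DataFrame
        Columns (taxon, segment, significant): genotype-differential verdicts
        aggregated over trait-associated SNPs (any significant SNP counts).
    y : array-like
        Trait vector in table sample order.
    clr_tables : sequence of AbundanceTable (scale clr)
        Used to annotate overlapping taxa with their trait correlation.

    A taxon is included when it is genotype-differential AND a two-part hit
    (binary or abundance part); mGWAS membership is recorded as a fourth set.
    """
    y = np.asarray(y, dtype=float).ravel()
    mgwas_set = {tuple(t) for t in mgwas_taxa}
    diff_map = {(r["taxon"], r["segment"]): bool(r["significant"])
                for _, r in differential.iterrows()}
    unmatched = [k for k in diff_map if k not in
                 {(r["taxon"], r["segment"]) for _, r in two_part.iterrows()}]
    if unmatched:
        raise ValueError(f"differential results for taxa absent from MWAS: {unmatched}")
    clr_by_segment = {t.segment: t for t in clr_tables}

    rows = []
    for _, r in two_part.iterrows():
        key = (r["taxon"], r["segment"])
        binary_hit = bool(r["binary_hit"])
        abundance_hit = bool(r["abundance_hit"])
        in_mgwas = key in mgwas_set
        in_diff = diff_map.get(key, False)
        included = in_diff and (binary_hit or abundance_hit)
        corr = pval = np.nan
        direction = ""
        if included:
            table = clr_by_segment[r["segment"]]
            corr, pval = taxon_trait_correlation(
                table.data[r["taxon"]].to_numpy(dtype=float), y)
            direction = "negative" if corr < 0 else "positive"
        rows.append([r["taxon"], r["segment"], binary_hit, abundance_hit,
                     in_mgwas, in_diff, included, corr, pval, direction])
    return pd.DataFrame(rows, columns=[
        "taxon", "segment", "binary_hit", "abundance_hit", "mgwas_hit",
        "genotype_differential", "included", "fcr_r", "fcr_p", "direction",
    ])
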