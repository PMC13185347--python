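"""Mixed-linear-model association scans, per-SNP variance explained, and LD.

Per variant the model is

    y = Z a + x b + g + e,   g ~ N(0, sigma2_g G),  e ~ N(0, sigma2_e I)

with covariates Z (intercept + genetic PCs), reference-allele dosage x, and
the genomic kernel G.  The null variance components are estimated once by
REML and reused for every variant ("population parameters previously
determined"): after one eigendecomposition G = U D U', every per-variant
generalized-least-squares effect, SE and Wald test costs O(n).  An ``exact``
mode re-estimates the variance ratio per variant for small problems.

The same scan serves the trait (GWAS) and heritable taxa's CLR abundances
(mGWAS).  Per-SNP phenotypic variance explained uses the standard
summary-statistic estimator

    PVE = 2f(1-f) b^2 / (2f(1-f) b^2 + 2f(1-f) se^2 n),

a convention built only from the association output, not a quantity with a
unique definition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import MISSING, GenotypeMatrix, KernelMatrix
from .reml import _profile_reml_1d, _profiled_residual_variance

__all__ = [
    "AssociationScan",
    "AssociationScanResults",
    "SignificanceThresholds",
    "LDBlock",
    "mlm_assoc",
    "mgwas_scan",
    "snp_pve",
    "significance_thresholds",
    "ld_r2",
    "ld_blocks",
]


@dataclass(frozen=True)
class SignificanceThresholds:
    """Bonferroni-style thresholds: genome-wide 0.05/m, suggestive 1/m."""

    n_tests: int
    genome_wide: float = field(init=False)
    suggestive: float = field(init=False)

    def __post_init__(self) -> None:
        if self.n_tests < 1:
            raise ValueError("n_tests must be >= 1")
        object.__setattr__(self, "genome_wide", 0.05 / self.n_tests)
        object.__setattr__(self, "suggestive", 1.0 / self.n_tests)

    def display(self) -> tuple[float, float]:
        """Thresholds rounded to 3 significant digits for reporting."""
        return (_round_sig(self.genome_wide, 3), _round_sig(self.suggestive, 3))


def _round_sig(x: float, sig: int) -> float:
    if x == 0:
        return 0.0
    from math import floor, log10

    return round(x, -int(floor(log10(abs(x)))) + sig - 1)


def significance_thresholds(n_tests: int) -> SignificanceThresholds:
    return SignificanceThresholds(n_tests)


def snp_pve(beta: float, se: float, freq: float, n: int) -> float:
    """Phenotypic variance explained by one variant from (b, se, f, n)."""
    if not 0 < freq < 1:
        raise ValueError("allele frequency must lie strictly in (0, 1)")
    if se <= 0 or n <= 1:
        raise ValueError("need se > 0 and n > 1")
    num = 2.0 * freq * (1.0 - freq) * beta**2
    return float(num / (num + 2.0 * freq * (1.0 - freq) * se**2 * n))


class _SpectralScanner:
    """Shared eigendecomposition machinery for one genotype/kernel pair."""

    def __init__(self, genotypes: GenotypeMatrix, grm: KernelMatrix, exog: np.ndarray) -> None:
        if genotypes.samples != grm.samples:
            raise ValueError("genotype and kernel sample order differ")
        self.g = genotypes
        self.n = genotypes.n_samples
        self.exog = exog
        d, U = np.linalg.eigh(grm.values)
        self.d = np.clip(d, 0.0, None)
        self.U = U
        self.Xt = U.T @ exog
        x = genotypes.imputed()
        self.freq = x.mean(axis=0) / 2.0
        self.Gt = U.T @ x

    def scan(self, y, feature: str, method: str = "pcpd", lambda_null=None) -> "AssociationScanResults":
        y = np.asarray(y, dtype=float).ravel()
        if y.size != self.n:
            raise ValueError("trait vector length does not match samples")
        yt = self.U.T @ y
        if lambda_null is None:
            lam, _, _ = _profile_reml_1d(yt, self.Xt, self.d)
        else:
            lam = float(lambda_null)
        s2e = _profiled_residual_variance(yt, self.Xt, self.d, lam)
        s2g = lam * s2e

        w = 1.0 / (lam * self.d + 1.0) / s2e  # diagonal of V^-1, rotated
        WX = w[:, None] * self.Xt
        G_small = self.Xt.T @ WX
        # projection of y and dosages orthogonal to covariates under V^-1
        Py = w * yt - WX @ np.linalg.solve(G_small, WX.T @ yt)
        PG = w[:, None] * self.Gt - WX @ np.linalg.solve(G_small, WX.T @ self.Gt)
        xPx = np.einsum("ij,ij->j", self.Gt, PG)
        xPy = self.Gt.T @ Py

        testable = (self.freq > 0) & (self.freq < 1) & (xPx > 0)
        beta = np.full(self.g.n_variants, np.nan)
        se = np.full(self.g.n_variants, np.nan)
        beta[testable] = xPy[testable] / xPx[testable]
        se[testable] = np.sqrt(1.0 / xPx[testable])

        if method == "exact":
            beta, se = self._exact_refit(yt, beta, se, testable)
        elif method != "pcpd":
            raise ValueError(f"unknown method {method!r}")

        wald = np.full_like(beta, np.nan)
        p = np.full_like(beta, np.nan)
        wald[testable] = (beta[testable] / se[testable]) ** 2
        p[testable] = stats.chi2.sf(wald[testable], 1)
        pve = np.full_like(beta, np.nan)
        for j in np.where(testable)[0]:
            pve[j] = snp_pve(beta[j], se[j], self.freq[j], self.n)

        frame = pd.DataFrame({
            "chrom": [v.chrom for v in self.g.variants],
            "pos": [v.pos for v in self.g.variants],
            "ref": [v.ref for v in self.g.variants],
            "alt": [v.alt for v in self.g.variants],
            "freq": self.freq,
            "beta": beta,
            "se": se,
            "wald": wald,
            "p": p,
            "pve": pve,
            "feature": feature,
            "testable": testable,
        })
        return AssociationScanResults(frame, feature, s2g, s2e, self.n)

    def _exact_refit(self, yt, beta, se, testable):
        """Re-estimate the variance ratio per variant (small problems only)."""
        beta = beta.copy()
        se = se.copy()
        for j in np.where(testable)[0]:
            Xj = np.column_stack([self.Xt, self.Gt[:, j]])
            lam_j, _, _ = _profile_reml_1d(yt, Xj, self.d)
            s2e_j = _profiled_residual_variance(yt, Xj, self.d, lam_j)
            w = 1.0 / (lam_j * self.d + 1.0) / s2e_j
            WX = w[:, None] * Xj
            Gj = Xj.T @ WX
            coef = np.linalg.solve(Gj, WX.T @ yt)
            cov = np.linalg.inv(Gj)
            beta[j] = coef[-1]
            se[j] = np.sqrt(cov[-1, -1])
        return beta, se


class AssociationScan:
    """Per-variant mixed-model association scan for one feature.

    Parameters
    ----------
    endog : array-like, shape (n,)
        Trait (FCR) or taxon CLR abundance, in genotype sample order.
    genotypes : GenotypeMatrix
    grm : KernelMatrix
        Genomic kernel controlling for polygenic background/structure.
    exog : array-like, optional
        Fixed covariates; defaults to an intercept.
    feature : str
        Label carried into the result rows.
    """

    def __init__(self, endog, genotypes, grm, exog=None, feature: str = "trait") -> None:
        n = genotypes.n_samples
        if exog is None:
            exog = np.ones((n, 1))
        else:
            exog = np.atleast_2d(np.asarray(exog, dtype=float))
        self.endog = np.asarray(endog, dtype=float).ravel()
        self.feature = feature
        self._scanner = _SpectralScanner(genotypes, grm, exog)

    def fit(self, method: str = "pcpd", lambda_null=None) -> "AssociationScanResults":
        """Run the scan.  ``method="pcpd"`` reuses the null variance
        components for every variant; ``"exact"`` re-fits them per variant.
        ``lambda_null`` overrides the null variance ratio (0 recovers OLS)."""
        return self._scanner.scan(self.endog, self.feature, method=method,
                                  lambda_null=lambda_null)


class AssociationScanResults:
    """Scan output: a tidy per-variant frame plus the null variance fit."""

    def __init__(self, frame: pd.DataFrame, feature: str, s2g: float, s2e: float, n: int) -> None:
        self.frame = frame
        self.feature = feature
        self.null_sigma2_g = float(s2g)
        self.null_sigma2_e = float(s2e)
        self.nobs = int(n)

    @property
    def thresholds(self) -> SignificanceThresholds:
        return SignificanceThresholds(int(self.frame["testable"].sum()))

    def significant(self, level: str = "suggestive") -> pd.DataFrame:
        cut = getattr(self.thresholds, level)
        f = self.frame
        return f[f["testable"] & (f["p"] < cut)]

    def mean_significant_pve(self, level: str = "suggestive") -> float:
        sig = self.significant(level)
        return float(sig["pve"].mean()) if len(sig) else float("nan")

    def summary(self) -> str:
        thr = self.thresholds
        gw, sg = thr.display()
        lines = [
            f"Mixed-model association scan: {self.feature}",
            f"  n = {self.nobs}, tested variants = {thr.n_tests}",
            f"  null sigma2_g = {self.null_sigma2_g:.4f}, sigma2_e = {self.null_sigma2_e:.4f}",
            f"  thresholds: genome-wide {gw:.3g}, suggestive {sg:.3g}",
            f"  hits: {len(self.significant('genome_wide'))} genome-wide, "
            f"{len(self.significant('suggestive'))} suggestive",
        ]
        sig = self.significant("suggestive")
        if len(sig):
            lines.append(f"  mean PVE of suggestive hits: {self.mean_significant_pve():.3f}")
        return "\n".join(lines)

    def plot_manhattan(self, ax=None):
        """Minimal diagnostic Manhattan plot."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(8, 3))
        f = self.frame[self.frame["testable"]]
        offset = 0
        for i, (_, grp) in enumerate(f.groupby("chrom", sort=False)):
            ax.scatter(grp["pos"] + offset, -np.log10(grp["p"]), s=4,
                       color=["#444444", "#999999"][i % 2])
            offset += grp["pos"].max()
        thr = self.thresholds
        ax.axhline(-np.log10(thr.genome_wide), color="red", lw=0.8)
        ax.axhline(-np.log10(thr.suggestive), color="black", lw=0.8, ls="--")
        ax.set_xlabel("position")
        ax.set_ylabel("-log10 p")
        return ax


def mlm_assoc(y, genotypes, grm, covariates=None, feature: str = "trait",
              method: str = "pcpd", lambda_null=None) -> AssociationScanResults:
    """Functional wrapper around :class:`AssociationScan`."""
    return AssociationScan(y, genotypes, grm, exog=covariates, feature=feature).fit(
        method=method, lambda_null=lambda_null
    )


def mgwas_scan(tables, heritable: pd.DataFrame, genotypes, grm, covariates=None) -> dict:
    """mGWAS: association scans for every taxon flagged heritable.

    ``heritable`` is the frame from :func:`hologwas.reml.screen_heritable_taxa`;
    only rows with ``heritable == True`` are scanned.  Returns a dict mapping
    (taxon, segment) to :class:`AssociationScanResults`.  The genotype
    eigendecomposition is shared across taxa.
    """
    n = genotypes.n_samples
    exog = np.ones((n, 1)) if covariates is None else np.atleast_2d(
        np.asarray(covariates, dtype=float))
    scanner = _SpectralScanner(genotypes, grm, exog)
    by_segment = {t.segment: t for t in (tables if not hasattr(tables, "segment") else [tables])}
    out = {}
    for _, row in heritable[heritable["heritable"] == True].iterrows():  # noqa: E712
        table = by_segment[row["segment"]]
        y = table.data[row["feature"]].to_numpy(dtype=float)
        out[(row["feature"], row["segment"])] = scanner.scan(
            y, feature=f"{row['feature']}({row['segment']})"
        )
    return out


# ---------------------------------------------------------------------- LD

@dataclass
class LDBlock:
    """A run of consecutive variants in strong mutual LD."""

    chrom: str
    start: int
    end: int
    indices: list
    min_adjacent_r2: float


def ld_r2(g: GenotypeMatrix, i: int, j: int) -> float:
    """Squared Pearson correlation of two dosage columns (composite LD on
    unphased genotypes); sample pairs with a missing value are dropped."""
    xi = g.dosages[:, i].astype(float)
    xj = g.dosages[:, j].astype(float)
    keep = (g.dosages[:, i] != MISSING) & (g.dosages[:, j] != MISSING)
    xi, xj = xi[keep], xj[keep]
    if np.ptp(xi) == 0 or np.ptp(xj) == 0:
        raise ValueError("zero-variance dosage vector in LD computation")
    r = np.corrcoef(xi, xj)[0, 1]
    return float(r * r)


def ld_blocks(
    g: GenotypeMatrix,
    chrom: str | None = None,
    start: int | None = None,
    end: int | None = None,
    r2_threshold: float = 0.8,
    rule: str = "adjacent",
) -> list[LDBlock]:
    """Haplotype blocks from pairwise r2 along the variant map.

    Default rule: maximal runs of consecutive map-ordered variants in which
    every ADJACENT pair has r2 strictly above the threshold; singletons are
    not blocks.  ``rule="all_pairs"`` additionally requires every pair within
    the block to clear the threshold.  Block span is the closed interval
    [first member position, last member position].
    """
    idx = [
        k for k, v in enumerate(g.variants)
        if (chrom is None or v.chrom == chrom)
        and (start is None or v.pos >= start)
        and (end is None or v.pos <= end)
    ]
    if len(idx) < 2:
        return []
    blocks: list[LDBlock] = []
    run: list[int] = [idx[0]]
    adj: list[float] = []
    for prev, cur in zip(idx, idx[1:]):
        contiguous = g.variants[prev].chrom == g.variants[cur].chrom
        r2 = ld_r2(g, prev, cur) if contiguous else 0.0
        extend = contiguous and r2 > r2_threshold
        if extend and rule == "all_pairs":
            extend = all(ld_r2(g, m, cur) > r2_threshold for m in run)
        if extend:
            run.append(cur)
            adj.append(r2)
        else:
            if len(run) >= 2:
                blocks.append(_make_block(g, run, adj))
            run, adj = [cur], []
    if len(run) >= 2:
        blocks.append(_make_block(g, run, adj))
    return blocks


def _make_block(g: GenotypeMatrix, run, adj) -> LDBlock:
    return LDBlock(
        chrom=g.variants[run[0]].chrom,
        start=g.variants[run[0]].pos,
        end=g.variants[run[-1]].pos,
        indices=list(run),
        min_adjacent_r2=float(min(adj)),
    )
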