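"""Synthetic cohort generator with retained ground truth.

Emulates the data structure the analysis assumes: a diploid cohort (optionally
two diverged lines), biallelic autosomal SNPs, four gut-segment compositional
microbiomes with zero inflation and partially host-genetic taxon abundances,
and a phenotype assembled bottom-up as

    y = fixed + g + m_d + m_j + m_i + m_c + e

where g is a polygenic value over a configurable number of causal SNPs and
each m_k is a weighted combination of that segment's standardized
(CLR + z-score) taxa.  Every component is rescaled to its configured share of
the phenotypic variance, so the same dataset exercises GWAS (causal SNPs
exist), the heritability screen, and five-kernel variance partitioning.

Taxon abundances are log-normal with Bernoulli zero inflation: latent
log-abundance = baseline + genetic liability + Gaussian noise, observed
abundance = presence * exp(latent), rows closed to relative abundances.  The
trait column FCR is an affine recalibration of y to a plausible
feed-conversion scale (mean 2.3, sd 0.25 by default); variance ratios are
unaffected by this affine map.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import SEGMENTS, AbundanceTable, GenotypeMatrix, PhenotypeTable, VariantInfo
from .kernels import clr_transform, standardize_taxa

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "simulate_genotypes",
    "simulate_microbiota",
    "simulate_phenotype",
    "simulate_all",
    "generate_dataset",
]

PLANTED_TAXON = "planted_key_taxon"


@dataclass
class SimulationConfig:
    """Study-design knobs for the synthetic cohort.

    Defaults mirror the study conditions the analysis targets: 313
    individuals from two diverged lines, genome-wide biallelic SNPs at
    desk scale, four 50-taxon segment microbiomes, and phenotype variance
    fractions (genetic 0.3696; duodenum 0.0796; jejunum 0.0763; ileum 0.0;
    cecum 0.1390) with the residual absorbing the remainder.
    """

    n_individuals: int = 313
    n_variants: int = 5000
    n_chromosomes: int = 5
    n_lines: int = 2
    line_divergence: float = 0.05  # variance of line allele-frequency drift
    maf_range: tuple = (0.05, 0.5)
    taxa_per_segment: int = 50
    zero_inflation_range: tuple = (0.05, 0.6)
    driven_zero_inflation_range: tuple = (0.0, 0.2)
    n_genetically_driven_taxa: int = 5
    taxon_genetic_fraction: float = 0.4
    n_taxon_causal_snps: int = 3
    zero_mechanism: str = "censoring"  # "censoring" (detection limit) or "bernoulli"
    variance_fractions: dict = field(default_factory=lambda: {
        "genetic": 0.3696, "duodenum": 0.0796, "jejunum": 0.0763,
        "ileum": 0.0, "cecum": 0.1390,
    })
    n_causal_snps: int = 10
    fixed_intercept: float = 0.0
    line_effect: float = 0.0  # fixed FCR-scale offset of line 2 vs line 1
    fcr_mean: float = 2.3
    fcr_sd: float = 0.25
    # planted jointly-heritable / trait-associated cecal taxon
    planted_taxon: bool = False
    planted_genetic_fraction: float = 0.8
    planted_n_causal_snps: int = 2
    planted_snp_trait_share: float = 0.25  # share of v_g per planted causal SNP
    planted_taxon_weight_share: float = 0.5  # share of cecal effect variance
    seed: int = 0

    def validate(self) -> None:
        if self.n_individuals < 3:
            raise ValueError("need at least 3 individuals")
        if self.n_variants < 1:
            raise ValueError("n_variants must be >= 1")
        if self.n_lines not in (1, 2):
            raise ValueError("n_lines must be 1 or 2")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must be within (0, 0.5]")
        fr = self.variance_fractions
        if set(fr) != {"genetic", *SEGMENTS}:
            raise ValueError(f"variance_fractions must key genetic plus {SEGMENTS}")
        vals = np.array(list(fr.values()))
        if (vals < 0).any() or vals.sum() > 1:
            raise ValueError("variance fractions must be >= 0 and sum <= 1")
        if not 0 <= self.taxon_genetic_fraction < 1:
            raise ValueError("taxon_genetic_fraction must lie in [0, 1)")
        if self.zero_mechanism not in ("censoring", "bernoulli"):
            raise ValueError("zero_mechanism must be 'censoring' or 'bernoulli'")


@dataclass
class SimulationTruth:
    """Ground truth retained for recovery experiments."""

    causal_indices: list
    causal_effects: list
    fixed: np.ndarray
    g: np.ndarray
    m: dict          # segment -> per-individual microbial effect
    e: np.ndarray
    y: np.ndarray
    realized_fractions: dict
    taxon_truth: dict  # segment -> {taxon: {"fraction":…, "causal":[…]}}
    lines: list
    planted: str | None = None

    def reconstruction_error(self) -> float:
        rebuilt = self.fixed + self.g + sum(self.m.values()) + self.e
        return float(np.max(np.abs(self.y - rebuilt)))

    def to_json(self) -> str:
        def conv(x):
            if isinstance(x, np.ndarray):
                return x.tolist()
            if isinstance(x, (np.floating, np.integer)):
                return x.item()
            if isinstance(x, dict):
                return {str(k): conv(v) for k, v in x.items()}
            if isinstance(x, (list, tuple)):
                return [conv(v) for v in x]
            return x

        return json.dumps({k: conv(v) for k, v in dataclasses.asdict(self).items()},
                          indent=1, sort_keys=True)


def _rescale(x: np.ndarray, target_var: float, orthogonal_to=()) -> np.ndarray:
    """Centre a component, optionally project out previously built components,
    and rescale to an exact sample variance.

    Successive orthogonalization keeps in-sample covariances between the
    phenotype's building blocks at zero, so the configured variance fractions
    are realized essentially exactly rather than up to O(1/sqrt(n)) sampling
    covariance."""
    if target_var <= 0:
        return np.zeros_like(x)
    x = x - x.mean()
    basis = [b for b in orthogonal_to if b.var() > 0]
    if basis:
        B = np.column_stack(basis)
        coef, *_ = np.linalg.lstsq(B, x, rcond=None)
        x = x - B @ coef
    v = x.var()
    if v == 0:
        raise ValueError("cannot rescale a constant component to positive variance")
    return x * np.sqrt(target_var / v)


def simulate_genotypes(config: SimulationConfig, rng=None):
    """Draw genotypes for one or two diverged lines.

    Per variant an ancestral reference-allele frequency is drawn from
    ``maf_range``; line frequencies drift around it with the configured
    variance (truncated to (0.01, 0.99)) and genotypes are Binomial(2, freq).
    Returns (GenotypeMatrix, line labels).
    """
    config.validate()
    rng = np.random.default_rng(config.seed if rng is None else rng)
    n, p = config.n_individuals, config.n_variants
    anc = rng.uniform(*config.maf_range, size=p)
    if config.n_lines == 2:
        n1 = n // 2
        lines = ["line1"] * n1 + ["line2"] * (n - n1)
        freqs = np.clip(
            anc + rng.normal(0.0, np.sqrt(config.line_divergence), size=(2, p)),
            0.01, 0.99,
        )
        line_idx = np.array([0] * n1 + [1] * (n - n1))
    else:
        lines = ["line1"] * n
        freqs = anc[None, :]
        line_idx = np.zeros(n, dtype=int)
    dosages = rng.binomial(2, freqs[line_idx, :]).astype(np.int8)

    per_chrom = int(np.ceil(p / config.n_chromosomes))
    variants = []
    j = 0
    for c in range(1, config.n_chromosomes + 1):
        k = min(per_chrom, p - j)
        if k <= 0:
            break
        pos = np.cumsum(rng.integers(1, 10_000, size=k))  # strictly increasing bp
        for q in range(k):
            variants.append(VariantInfo(str(c), int(pos[q]), "A", "G", f"snp{j + q + 1}"))
        j += k
    samples = [f"duck{i + 1:04d}" for i in range(n)]
    return GenotypeMatrix(samples, variants, dosages), lines


def _causal_candidate_indices(g: GenotypeMatrix, min_maf: float = 0.05,
                              hwe_alpha: float = 1e-6) -> np.ndarray:
    """Variants eligible to carry causal effects: common and HWE-stable.

    The simulated SNPs are mutually unlinked, so a causal variant that the
    standard QC trio would remove (rare, or Wahlund-distorted in a two-line
    cohort) leaves no tagging proxy behind and its contribution would be
    invisible to every downstream analysis by construction rather than by
    biology.  Restricting causal draws to QC-stable common variants keeps the
    generator's configured fractions estimable."""
    cached = getattr(g, "_causal_candidates", None)
    if cached is not None:
        return cached
    from .kernels import hwe_exact_test

    freq = g.ref_allele_frequency()
    maf = np.minimum(freq, 1.0 - freq)
    keep = []
    for j in np.where(maf >= min_maf)[0]:
        col = g.dosages[:, j]
        obs = col[col != -1]
        counts = (int((obs == 2).sum()), int((obs == 1).sum()), int((obs == 0).sum()))
        if hwe_exact_test(*counts) >= hwe_alpha:
            keep.append(j)
    out = np.asarray(keep if keep else np.where(maf > 0)[0])
    g._causal_candidates = out
    return out


def _standardized_dosages(g: GenotypeMatrix, idx) -> np.ndarray:
    x = g.imputed()[:, idx]
    sd = x.std(axis=0, ddof=1)
    if (sd == 0).any():
        # resample monomorphic picks upstream; here just guard
        sd = np.where(sd == 0, 1.0, sd)
    return (x - x.mean(axis=0)) / sd


def simulate_microbiota(config: SimulationConfig, genotypes: GenotypeMatrix, rng):
    """Four segment-specific zero-inflated log-normal abundance tables.

    Each taxon's latent log-abundance is baseline + genetic liability (a
    weighted sum of its causal standardized dosages, scaled to the taxon's
    genetic variance fraction) + Gaussian noise.  Zeros arise either from a
    detection limit (default: absent when the latent value falls below its
    pi-quantile, so zeros are informative) or from an independent Bernoulli
    process (``zero_mechanism="bernoulli"``); the marginal absence rate is
    the configured zero-inflation probability under both mechanisms.  The
    first taxon of each segment is a ubiquitous core taxon (no zero
    inflation) so every sample row remains closable.
    Returns ({segment: AbundanceTable(relative)}, taxon_truth dict).
    """
    n = genotypes.n_samples
    polymorphic = _causal_candidate_indices(genotypes)
    tables: dict[str, AbundanceTable] = {}
    taxon_truth: dict[str, dict] = {}
    for segment in SEGMENTS:
        t = config.taxa_per_segment
        extra = 1 if (config.planted_taxon and segment == "cecum") else 0
        labels = [f"{segment[:3]}_g{a + 1:03d}" for a in range(t)]
        fractions = np.zeros(t + extra)
        driven = rng.choice(np.arange(1, t), size=min(config.n_genetically_driven_taxa, t - 1),
                            replace=False)
        fractions[driven] = config.taxon_genetic_fraction
        pi = rng.uniform(*config.zero_inflation_range, size=t + extra)
        pi[driven] = rng.uniform(*config.driven_zero_inflation_range, size=driven.size)
        pi[0] = 0.0  # ubiquitous core taxon keeps rows closable
        if extra:
            labels.append(PLANTED_TAXON)
            fractions[t] = config.planted_genetic_fraction
            pi[t] = 0.10  # some absences so the presence/absence part applies

        baseline = rng.normal(0.0, 1.5, size=t + extra)
        baseline[0] = 2.0  # core taxon sits higher in the composition
        latent = np.empty((n, t + extra))
        truth_seg: dict[str, dict] = {}
        for a in range(t + extra):
            f_a = fractions[a]
            causal: list[int] = []
            liability = np.zeros(n)
            if f_a > 0:
                if labels[a] == PLANTED_TAXON:
                    causal = list(rng.choice(polymorphic, size=config.planted_n_causal_snps,
                                             replace=False))
                else:
                    causal = list(rng.choice(polymorphic, size=min(
                        config.n_taxon_causal_snps, polymorphic.size), replace=False))
                w = rng.normal(size=len(causal))
                liability = _rescale(_standardized_dosages(genotypes, causal) @ w, f_a)
            noise = rng.normal(0.0, np.sqrt(max(1.0 - f_a, 1e-12)), size=n)
            latent[:, a] = baseline[a] + liability + noise
            truth_seg[labels[a]] = {"fraction": float(f_a),
                                    "causal": [int(c) for c in causal],
                                    "liability_weights": [float(v) for v in
                                                          (w if f_a > 0 else [])],
                                    "zero_inflation": float(pi[a])}
        if config.zero_mechanism == "censoring":
            # detection limit: a taxon is absent when its latent abundance
            # falls below the pi-quantile of its latent distribution, so the
            # marginal absence rate is pi but zeros are informative
            from scipy.stats import norm

            cut = baseline[None, :] + norm.ppf(np.clip(pi, 0.0, 1 - 1e-12))[None, :]
            presence = latent >= cut
        else:
            presence = rng.random((n, t + extra)) >= pi[None, :]
        observed = presence * np.exp(latent)
        rel = observed / observed.sum(axis=1, keepdims=True)
        tables[segment] = AbundanceTable(
            pd.DataFrame(rel, index=genotypes.samples, columns=labels),
            segment, "relative",
        )
        taxon_truth[segment] = truth_seg
    return tables, taxon_truth


def simulate_phenotype(config: SimulationConfig, genotypes: GenotypeMatrix,
                       tables: dict, taxon_truth: dict, lines, rng):
    """Assemble the phenotype from individual-level effects.

    Returns (PhenotypeTable, SimulationTruth).  The raw trait y has unit-scale
    variance fractions as configured; FCR is an affine recalibration of y.
    """
    fr = config.variance_fractions
    if sum(fr.values()) > 1:
        raise ValueError("variance fractions sum above 1")
    n = genotypes.n_samples
    v_e = 1.0 - sum(fr.values())
    polymorphic = _causal_candidate_indices(genotypes)

    # polygenic value over the causal SNPs; planted shared SNPs get a fixed
    # share of the genetic variance so they are detectable by GWAS
    causal_idx: list[int] = []
    shares: list[float] = []
    forced_signs: list[float] = []
    if config.planted_taxon:
        planted = taxon_truth["cecum"][PLANTED_TAXON]
        causal_idx.extend(planted["causal"])
        shares.extend([config.planted_snp_trait_share] * len(planted["causal"]))
        # the planted taxon enters m_c with a NEGATIVE weight (lower FCR =
        # better feed efficiency); its SNPs' direct trait effects are aligned
        # so the genetic and microbial routes reinforce instead of cancelling
        forced_signs.extend([-np.sign(a) if a != 0 else 1.0
                             for a in planted["liability_weights"]])
    remaining = [i for i in rng.choice(polymorphic, size=min(config.n_causal_snps,
                                                             polymorphic.size),
                                       replace=False) if i not in causal_idx]
    rest_share = max(1.0 - sum(shares), 0.0)
    causal_idx.extend(remaining)
    if remaining:
        shares.extend([rest_share / len(remaining)] * len(remaining))
    signs = np.concatenate([forced_signs,
                            rng.choice([-1.0, 1.0], size=len(remaining))])
    effects = signs * np.sqrt(np.array(shares))
    if fr["genetic"] > 0 and causal_idx:
        g_comp = _rescale(_standardized_dosages(genotypes, causal_idx) @ effects,
                          fr["genetic"])
        effect_scale = np.sqrt(fr["genetic"])
    else:
        g_comp = np.zeros(n)
        effect_scale = 0.0

    m_comp: dict[str, np.ndarray] = {}
    built = [g_comp]
    for segment in SEGMENTS:
        v_k = fr[segment]
        table = tables[segment]
        z = standardize_taxa(clr_transform(table)).values
        t = z.shape[1]
        w = rng.normal(0.0, 1.0 / np.sqrt(t), size=t)
        if config.planted_taxon and segment == "cecum":
            j = table.taxa.index(PLANTED_TAXON)
            w = w * np.sqrt((1.0 - config.planted_taxon_weight_share) /
                            max(np.sum(np.delete(w, j) ** 2), 1e-12))
            w[j] = -np.sqrt(config.planted_taxon_weight_share)
        # a planted cecal taxon is genuinely genetic: keep its overlap with g;
        # otherwise remove in-sample overlap so configured fractions realize
        ortho = () if (config.planted_taxon and segment == "cecum") else tuple(built)
        m_comp[segment] = (_rescale(z @ w, v_k, orthogonal_to=ortho)
                           if v_k > 0 else np.zeros(n))
        built.append(m_comp[segment])

    e_comp = (_rescale(rng.normal(size=n), v_e, orthogonal_to=built)
              if v_e > 0 else np.zeros(n))
    line_arr = np.asarray([1.0 if l == "line2" else 0.0 for l in lines])
    fixed = config.fixed_intercept + (config.line_effect / config.fcr_sd) * line_arr
    y = fixed + g_comp + sum(m_comp.values()) + e_comp

    fcr = config.fcr_mean + config.fcr_sd * (y - y.mean()) / y.std()
    bwg = rng.normal(1800.0, 150.0, size=n).clip(min=500.0)
    fi = fcr * bwg
    pheno = PhenotypeTable(pd.DataFrame({
        "FI": fi, "BWG": bwg, "FCR": fcr, "line": lines,
    }, index=genotypes.samples))

    vary = y.var()
    realized = {k: float(v.var() / vary) for k, v in
                {"genetic": g_comp, **m_comp, "residual": e_comp}.items()}
    truth = SimulationTruth(
        causal_indices=[int(i) for i in causal_idx],
        causal_effects=[float(b * effect_scale) for b in effects],
        fixed=np.broadcast_to(fixed, (n,)).astype(float).copy(),
        g=g_comp, m=m_comp, e=e_comp, y=y,
        realized_fractions=realized,
        taxon_truth=taxon_truth,
        lines=list(lines),
        planted=PLANTED_TAXON if config.planted_taxon else None,
    )
    return pheno, truth


def simulate_all(config: SimulationConfig, seed=None):
    """Genotypes, four microbiome tables, phenotype and truth in one call."""
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    genotypes, lines = simulate_genotypes(config, rng)
    tables, taxon_truth = simulate_microbiota(config, genotypes, rng)
    pheno, truth = simulate_phenotype(config, genotypes, tables, taxon_truth, lines, rng)
    return genotypes, tables, pheno, truth


def generate_dataset(config: SimulationConfig, outdir) -> dict:
    """Write a full synthetic dataset (VCF, abundance TSVs, phenotype TSV,
    truth JSON, manifest) and return the file map."""
    from . import io as hio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genotypes, tables, pheno, truth = simulate_all(config)
    files = {"genotypes": outdir / "genotypes.vcf"}
    hio.write_genotypes(genotypes, files["genotypes"], format="vcf")
    for segment, table in tables.items():
        files[segment] = outdir / f"abundance_{segment}.tsv"
        hio.write_abundance(table, files[segment])
    files["phenotypes"] = outdir / "phenotypes.tsv"
    hio.write_phenotypes(pheno, files["phenotypes"])
    files["truth"] = outdir / "truth.json"
    files["truth"].write_text(truth.to_json())
    manifest = {
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in dataclasses.asdict(config).items()},
        "realized_fractions": truth.realized_fractions,
        "n_variants_written": genotypes.n_variants,
        "files": {k: str(v) for k, v in files.items()},
    }
    files["manifest"] = outdir / "manifest.json"
    files["manifest"].write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return files
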