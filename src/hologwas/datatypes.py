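"""Core in-memory containers for the host-genetics / gut-microbiota pipeline.

The pipeline revolves around four objects: a genotype dosage matrix (reference
allele counts per individual per variant), per-gut-segment taxon abundance
tables, a phenotype table carrying feed-efficiency traits, and symmetric
relationship kernels (genomic or microbial) consumed by the REML machinery.

Allele orientation: dosages count the REFERENCE allele, so a VCF genotype 0/0
maps to dosage 2.  Most GWAS stacks count the ALT allele; effect signs flip
between the two conventions but test statistics and variance components do not.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "MISSING",
    "SEGMENTS",
    "VariantInfo",
    "GenotypeMatrix",
    "AbundanceTable",
    "PhenotypeTable",
    "KernelMatrix",
]

#: Sentinel for a missing dosage in :attr:`GenotypeMatrix.dosages`.
MISSING: int = -1

#: Canonical gut-segment labels, proximal to distal.
SEGMENTS: tuple[str, ...] = ("duodenum", "jejunum", "ileum", "cecum")

_SCALES = ("counts", "relative", "clr", "log10", "zscore")


@dataclass(frozen=True)
class VariantInfo:
    """A biallelic variant: chromosome, 1-based position and its two alleles."""

    chrom: str
    pos: int
    ref: str
    alt: str
    id: str | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"variant position must be >= 1, got {self.pos}")

    @property
    def label(self) -> str:
        return self.id if self.id else f"{self.chrom}:{self.pos}"


class GenotypeMatrix:
    """n_individuals x n_variants reference-allele dosage matrix.

    Parameters
    ----------
    samples : sequence of str
        Unique individual identifiers, row order of ``dosages``.
    variants : sequence of VariantInfo
        Column order of ``dosages``; sorted by position within chromosome.
    dosages : ndarray of int8, shape (n, p)
        Reference-allele counts in {0, 1, 2}; :data:`MISSING` marks a missing
        genotype.
    """

    def __init__(self, samples, variants, dosages) -> None:
        samples = list(samples)
        variants = list(variants)
        dosages = np.asarray(dosages, dtype=np.int8)
        if dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D matrix")
        if dosages.shape != (len(samples), len(variants)):
            raise ValueError(
                f"dosage shape {dosages.shape} does not match "
                f"{len(samples)} samples x {len(variants)} variants"
            )
        if len(set(samples)) != len(samples):
            raise ValueError("duplicated sample identifiers")
        bad = ~np.isin(dosages, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("dosages must lie in {0, 1, 2} or be MISSING")
        for k in range(1, len(variants)):
            a, b = variants[k - 1], variants[k]
            if a.chrom == b.chrom and b.pos < a.pos:
                raise ValueError("variants must be position-sorted within chromosome")
        self.samples = samples
        self.variants = variants
        self.dosages = dosages

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def imputed(self) -> np.ndarray:
        """Float dosage matrix with missing entries set to the variant mean."""
        x = self.dosages.astype(float)
        x[self.dosages == MISSING] = np.nan
        col_mean = np.nanmean(x, axis=0)
        idx = np.where(np.isnan(x))
        x[idx] = col_mean[idx[1]]
        return x

    def ref_allele_frequency(self) -> np.ndarray:
        """Per-variant sample frequency of the reference allele (missing excluded)."""
        x = self.dosages.astype(float)
        x[self.dosages == MISSING] = np.nan
        return np.nanmean(x, axis=0) / 2.0

    def take_variants(self, index) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            self.samples,
            [self.variants[i] for i in index],
            self.dosages[:, index],
        )

    def __repr__(self) -> str:
        return f"GenotypeMatrix({self.n_samples} samples, {self.n_variants} variants)"


class AbundanceTable:
    """Samples x taxa abundance matrix for one gut segment.

    ``scale`` tags the numeric meaning of the values: raw ``counts``,
    ``relative`` abundances closed to 1 per sample, centred log-ratios
    (``clr``), ``log10`` abundances, or per-taxon z-scores (``zscore``).
    Non-negativity is enforced unless the scale is a transform that can go
    negative.
    """

    def __init__(self, data: pd.DataFrame, segment: str, scale: str, rank: str = "genus") -> None:
        if segment not in SEGMENTS:
            raise ValueError(f"segment must be one of {SEGMENTS}, got {segment!r}")
        if scale not in _SCALES:
            raise ValueError(f"scale must be one of {_SCALES}, got {scale!r}")
        data = pd.DataFrame(data).astype(float)
        if data.index.has_duplicates:
            raise ValueError("duplicated sample identifiers")
        if data.columns.has_duplicates:
            raise ValueError("duplicated taxon labels")
        if scale in ("counts", "relative") and (data.to_numpy() < 0).any():
            raise ValueError(f"negative abundances are invalid on scale {scale!r}")
        if scale == "relative":
            sums = data.to_numpy().sum(axis=1)
            if not np.allclose(sums, 1.0, atol=1e-9):
                raise ValueError("relative-scale rows must sum to 1 within 1e-9")
        self.data = data
        self.segment = segment
        self.scale = scale
        self.rank = rank

    @property
    def samples(self) -> list[str]:
        return list(self.data.index)

    @property
    def taxa(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    def to_relative(self) -> "AbundanceTable":
        """Close each sample's row to sum 1 (valid from counts or relative)."""
        if self.scale == "relative":
            return self
        if self.scale != "counts":
            raise ValueError(f"cannot re-close a table on scale {self.scale!r}")
        v = self.data.to_numpy()
        sums = v.sum(axis=1, keepdims=True)
        if (sums <= 0).any():
            bad = [self.samples[i] for i in np.where(sums.ravel() <= 0)[0]]
            raise ValueError(f"all-zero samples cannot be closed: {bad}")
        return AbundanceTable(
            pd.DataFrame(v / sums, index=self.data.index, columns=self.data.columns),
            self.segment, "relative", self.rank,
        )

    def __repr__(self) -> str:
        return (
            f"AbundanceTable({self.data.shape[0]} samples x {self.data.shape[1]} taxa, "
            f"segment={self.segment}, scale={self.scale})"
        )


class PhenotypeTable:
    """Feed-efficiency phenotypes: feed intake (FI, g), body-weight gain
    (BWG, g), feed conversion ratio (FCR = FI / BWG), optional covariates and
    a line label."""

    REQUIRED = ("FI", "BWG", "FCR")

    def __init__(self, data: pd.DataFrame) -> None:
        data = pd.DataFrame(data)
        if data.index.has_duplicates:
            raise ValueError("duplicated sample identifiers")
        for col in self.REQUIRED:
            if col not in data.columns:
                raise ValueError(f"phenotype table must carry column {col!r}")
            vals = data[col].to_numpy(dtype=float)
            if np.any(vals[~np.isnan(vals)] <= 0):
                raise ValueError(f"{col} must be strictly positive where present")
        self.data = data

    @property
    def samples(self) -> list[str]:
        return list(self.data.index)

    @property
    def fcr(self) -> np.ndarray:
        return self.data["FCR"].to_numpy(dtype=float)

    def covariate_matrix(self, names) -> np.ndarray:
        return self.data[list(names)].to_numpy(dtype=float)

    def __repr__(self) -> str:
        return f"PhenotypeTable({len(self.data)} samples, columns={list(self.data.columns)})"


class KernelMatrix:
    """Symmetric positive-semidefinite n x n relationship matrix.

    ``kind`` is ``"GRM"`` (genomic) or ``"MRM"`` (microbial); an MRM carries
    the gut segment it was built from.  Slightly negative eigenvalues within
    ``-1e-8 * lambda_max`` are tolerated (and may be bent to zero by
    :meth:`bent`); anything worse fails validation.
    """

    def __init__(self, samples, values, kind: str, segment: str | None = None) -> None:
        if kind not in ("GRM", "MRM"):
            raise ValueError("kind must be 'GRM' or 'MRM'")
        if kind == "MRM" and segment is not None and segment not in SEGMENTS:
            raise ValueError(f"unknown segment {segment!r}")
        samples = list(samples)
        values = np.asarray(values, dtype=float)
        n = len(samples)
        if values.shape != (n, n):
            raise ValueError(f"kernel shape {values.shape} does not match {n} samples")
        if not np.allclose(values, values.T, atol=1e-10):
            raise ValueError("kernel is not symmetric within 1e-10")
        self.samples = samples
        self.values = 0.5 * (values + values.T)
        self.kind = kind
        self.segment = segment

    @property
    def n(self) -> int:
        return len(self.samples)

    def eigenvalues(self) -> np.ndarray:
        return np.linalg.eigvalsh(self.values)

    def validate_psd(self) -> None:
        w = self.eigenvalues()
        lo, hi = w[0], max(w[-1], 0.0)
        if lo < -1e-8 * max(hi, 1.0):
            raise ValueError(f"kernel is not PSD: min eigenvalue {lo:.3e}")

    def bent(self) -> "KernelMatrix":
        """Clip tolerably-negative eigenvalues to zero (kernel 'bending')."""
        w, U = np.linalg.eigh(self.values)
        hi = max(w[-1], 0.0)
        if w[0] < -1e-8 * max(hi, 1.0):
            raise ValueError(f"kernel is not PSD: min eigenvalue {w[0]:.3e}")
        if w[0] >= 0:
            return self
        w = np.clip(w, 0.0, None)
        return KernelMatrix(self.samples, (U * w) @ U.T, self.kind, self.segment)

    def reordered(self, samples) -> "KernelMatrix":
        idx = [self.samples.index(s) for s in samples]
        return KernelMatrix(
            [self.samples[i] for i in idx],
            self.values[np.ix_(idx, idx)],
            self.kind,
            self.segment,
        )

    def __repr__(self) -> str:
        seg = f", segment={self.segment}" if self.segment else ""
        return f"KernelMatrix({self.kind}, n={self.n}{seg})"
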