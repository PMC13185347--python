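"""Readers and writers for the standard file formats, plus phenotype derivation.

Genotypes travel as VCF (read with cyvcf2, written with pysam) or as
PLINK-style transposed-raw text (``.traw``).  Abundance, phenotype, kernel and
result tables are TSV.  Kernels are additionally written in the GCTA
lower-triangle text layout for interoperability with GREML tooling.

Dosages count the reference allele (VCF GT allele 0), so a 0/0 genotype is
dosage 2 and a 1/1 genotype is dosage 0.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import (
    MISSING,
    AbundanceTable,
    GenotypeMatrix,
    KernelMatrix,
    PhenotypeTable,
    VariantInfo,
)

logger = logging.getLogger(__name__)

__all__ = [
    "read_genotypes",
    "write_genotypes",
    "read_abundance",
    "write_abundance",
    "read_phenotypes",
    "write_phenotypes",
    "read_kernel",
    "write_kernel",
    "write_kernel_gcta",
    "compute_fcr",
    "check_normality",
]


# ---------------------------------------------------------------- genotypes

def read_genotypes(path, format: str = "vcf") -> GenotypeMatrix:
    """Read a genotype matrix from ``vcf`` or ``plink_text`` (.traw).

    Multiallelic records are dropped with a logged count; anything malformed
    raises.  Dosages are reference-allele counts.
    """
    if format == "vcf":
        return _read_vcf(path)
    if format == "plink_text":
        return _read_traw(path)
    raise ValueError(f"unknown genotype format {format!r}")


def _read_vcf(path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if len(set(samples)) != len(samples):
        raise ValueError("duplicated sample id in VCF header")
    variants: list[VariantInfo] = []
    columns: list[np.ndarray] = []
    n_multi = 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            n_multi += 1
            continue
        col = np.empty(len(samples), dtype=np.int8)
        for i, gt in enumerate(rec.genotypes):
            a, b = gt[0], gt[1]
            if a < 0 or b < 0:
                col[i] = MISSING
            else:
                col[i] = int(a == 0) + int(b == 0)  # reference-allele count
        variants.append(
            VariantInfo(str(rec.CHROM), int(rec.POS), rec.REF, rec.ALT[0],
                        rec.ID if rec.ID not in (None, ".") else None)
        )
        columns.append(col)
    vcf.close()
    if n_multi:
        logger.warning("dropped %d multiallelic record(s) from %s", n_multi, path)
    if not variants:
        raise ValueError(f"no biallelic records in {path}")
    dosages = np.column_stack(columns)
    return GenotypeMatrix(samples, variants, dosages)


def write_genotypes(g: GenotypeMatrix, path, format: str = "vcf") -> None:
    if format == "vcf":
        _write_vcf(g, path)
    elif format == "plink_text":
        _write_traw(g, path)
    else:
        raise ValueError(f"unknown genotype format {format!r}")


def _write_vcf(g: GenotypeMatrix, path) -> None:
    import pysam

    header = pysam.VariantHeader()
    chrom_max: dict[str, int] = {}
    for v in g.variants:
        chrom_max[v.chrom] = max(chrom_max.get(v.chrom, 0), v.pos)
    for chrom, mx in chrom_max.items():
        header.contigs.add(chrom, length=mx + 1000)
    header.formats.add("GT", 1, "String", "Genotype")
    for s in g.samples:
        header.add_sample(s)
    # dosage -> unphased GT under reference-allele counting
    gt_of = {2: (0, 0), 1: (0, 1), 0: (1, 1), MISSING: (None, None)}
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for j, v in enumerate(g.variants):
            rec = out.new_record(
                contig=v.chrom, start=v.pos - 1, stop=v.pos,
                alleles=(v.ref, v.alt), id=v.id,
            )
            for i, s in enumerate(g.samples):
                rec.samples[s]["GT"] = gt_of[int(g.dosages[i, j])]
                rec.samples[s].phased = False
            out.write(rec)


_TRAW_META = ["CHR", "SNP", "(C)M", "POS", "COUNTED", "ALT"]


def _write_traw(g: GenotypeMatrix, path) -> None:
    # COUNTED is the reference allele, so values stay reference dosages.
    meta = pd.DataFrame({
        "CHR": [v.chrom for v in g.variants],
        "SNP": [v.label for v in g.variants],
        "(C)M": 0,
        "POS": [v.pos for v in g.variants],
        "COUNTED": [v.ref for v in g.variants],
        "ALT": [v.alt for v in g.variants],
    })
    dos = g.dosages.T.astype(object)
    dos[dos == MISSING] = "NA"
    body = pd.DataFrame(dos, columns=[f"0_{s}" for s in g.samples])
    pd.concat([meta, body], axis=1).to_csv(path, sep="\t", index=False)


def _read_traw(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"CHR": str})
    for col in _TRAW_META:
        if col not in df.columns:
            raise ValueError(f"not a .traw file: missing column {col!r}")
    sample_cols = [c for c in df.columns if c not in _TRAW_META]
    samples = [c.split("_", 1)[1] if "_" in c else c for c in sample_cols]
    if len(set(samples)) != len(samples):
        raise ValueError("duplicated sample id in .traw header")
    variants = [
        VariantInfo(str(r.CHR), int(r.POS), str(r.COUNTED), str(r.ALT),
                    None if str(r.SNP) == "." else str(r.SNP))
        for r in df.itertuples()
    ]
    vals = df[sample_cols].to_numpy()
    dosages = np.where(pd.isna(vals.astype(float)), MISSING, vals).astype(np.int8)
    return GenotypeMatrix(samples, variants, dosages.T)


# ---------------------------------------------------------------- abundance

def read_abundance(path, segment: str, rank: str = "genus") -> AbundanceTable:
    """Read a samples x taxa TSV; scale inferred as counts if all integral."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    try:
        vals = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise ValueError(f"non-numeric abundance entry in {path}: {exc}") from exc
    if np.isnan(vals).any():
        raise ValueError(f"missing/ragged entries in abundance table {path}")
    if (vals < 0).any():
        raise ValueError(f"negative abundance in {path}")
    scale = "counts" if np.allclose(vals, np.round(vals)) else "relative"
    if scale == "relative" and not np.allclose(vals.sum(axis=1), 1.0, atol=1e-9):
        # fractional but unclosed: close it so the invariant holds
        vals = vals / vals.sum(axis=1, keepdims=True)
        df = pd.DataFrame(vals, index=df.index, columns=df.columns)
    return AbundanceTable(df, segment=segment, scale=scale, rank=rank)


def write_abundance(t: AbundanceTable, path) -> None:
    t.data.to_csv(path, sep="\t", index_label="sample")


# ---------------------------------------------------------------- phenotype

def read_phenotypes(path) -> PhenotypeTable:
    return PhenotypeTable(pd.read_csv(path, sep="\t", index_col=0))


def write_phenotypes(p: PhenotypeTable, path) -> None:
    p.data.to_csv(path, sep="\t", index_label="sample")


# ---------------------------------------------------------------- kernels

def read_kernel(path, kind: str = "GRM", segment: str | None = None) -> KernelMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return KernelMatrix(list(df.index), df.to_numpy(dtype=float), kind, segment)


def write_kernel(k: KernelMatrix, path) -> None:
    pd.DataFrame(k.values, index=k.samples, columns=k.samples).to_csv(
        path, sep="\t", index_label="sample"
    )


def write_kernel_gcta(k: KernelMatrix, prefix, n_features: int = 0) -> None:
    """GCTA-compatible lower-triangle text: ``<prefix>.grm`` + ``<prefix>.grm.id``."""
    prefix = str(prefix)
    with open(prefix + ".grm", "w") as fh:
        for i in range(k.n):
            for j in range(i + 1):
                fh.write(f"{i + 1}\t{j + 1}\t{n_features}\t{k.values[i, j]:.10g}\n")
    with open(prefix + ".grm.id", "w") as fh:
        for s in k.samples:
            fh.write(f"{s}\t{s}\n")


# ---------------------------------------------------------------- phenotype math

def compute_fcr(fi, bwg):
    """Feed conversion ratio FCR = FI / BWG (dimensionless; lower = more
    feed-efficient).  ``bwg`` must be strictly positive."""
    fi = np.asarray(fi, dtype=float)
    bwg = np.asarray(bwg, dtype=float)
    if np.any(bwg <= 0):
        raise ValueError("body-weight gain must be > 0 to define FCR")
    out = fi / bwg
    return float(out) if out.ndim == 0 else out


def check_normality(values) -> tuple[float, float]:
    """Shapiro-Wilk test of normality; returns (W, p).

    Requires 3 <= n <= 5000 and a non-constant vector.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or not 3 <= values.size <= 5000:
        raise ValueError("Shapiro-Wilk requires a 1-D vector with 3 <= n <= 5000")
    if np.ptp(values) == 0:
        raise ValueError("Shapiro-Wilk statistic undefined for a constant vector")
    w, p = stats.shapiro(values)
    return float(w), float(p)
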