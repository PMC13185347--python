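import logging

import matplotlib
import numpy as np
import pandas as pd
import pytest

matplotlib.use("Agg")
logging.getLogger("hologwas").setLevel(logging.ERROR)

from hologwas.datatypes import AbundanceTable, GenotypeMatrix, VariantInfo


def make_genotypes(dosages, chrom="1", start_pos=100, spacing=100, samples=None):
    """GenotypeMatrix from a plain dosage array (n x p)."""
    dosages = np.asarray(dosages, dtype=np.int8)
    n, p = dosages.shape
    if samples is None:
        samples = [f"s{i}" for i in range(n)]
    variants = [VariantInfo(chrom, start_pos + j * spacing, "A", "G", f"v{j}")
                for j in range(p)]
    return GenotypeMatrix(samples, variants, dosages)


def make_table(values, segment="cecum", scale="relative", taxa=None, samples=None):
    values = np.asarray(values, dtype=float)
    n, t = values.shape
    samples = samples or [f"s{i}" for i in range(n)]
    taxa = taxa or [f"t{j}" for j in range(t)]
    return AbundanceTable(pd.DataFrame(values, index=samples, columns=taxa),
                          segment, scale)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def random_genotypes(rng):
    """120 individuals x 60 common variants in approximate HWE."""
    freqs = rng.uniform(0.1, 0.5, size=60)
    return make_genotypes(rng.binomial(2, freqs, size=(120, 60)))
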