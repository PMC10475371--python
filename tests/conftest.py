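import numpy as np
import pandas as pd
import pytest

from herdgen.dataset import GenotypeDataset, LOCUS_COLUMNS, MISSING, SAMPLE_COLUMNS


def make_dataset(
    dosages,
    chromosomes=None,
    positions=None,
    sample_sexes=None,
) -> GenotypeDataset:
    """Build a small dataset from a dosage matrix with sensible defaults."""
    d = np.asarray(dosages, dtype=np.int8)
    n, m = d.shape
    if chromosomes is None:
        chromosomes = ["1"] * m
    if positions is None:
        positions = [1000 * (j + 1) for j in range(m)]
    loci = pd.DataFrame(
        {
            "locus_id": [f"snp{j}" for j in range(m)],
            "chromosome": [str(c) for c in chromosomes],
            "position_bp": positions,
            "allele_a": ["A"] * m,
            "allele_b": ["C"] * m,
        },
        columns=LOCUS_COLUMNS,
    )
    samples = pd.DataFrame(
        {
            "sample_id": [f"s{i}" for i in range(n)],
            "sex": sample_sexes or ["unknown"] * n,
        },
        columns=SAMPLE_COLUMNS,
    )
    return GenotypeDataset(d, loci, samples)


def random_dataset(rng, n=None, m=None, missing_rate=0.1) -> GenotypeDataset:
    """Random small dataset (n, m <= 20 by default) with missingness."""
    n = n or int(rng.integers(2, 21))
    m = m or int(rng.integers(1, 21))
    p = rng.uniform(0.05, 0.95, size=m)
    d = rng.binomial(2, p, size=(n, m)).astype(np.int8)
    mask = rng.random((n, m)) < missing_rate
    d[mask] = MISSING
    # guarantee at least one call per locus, and one locus fully called
    # so every sample pair shares a genotyped locus
    for j in range(m):
        if (d[:, j] == MISSING).all():
            d[rng.integers(0, n), j] = 1
    fully = d[:, 0] == MISSING
    d[fully, 0] = rng.binomial(2, p[0], size=int(fully.sum()))
    return make_dataset(d)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
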