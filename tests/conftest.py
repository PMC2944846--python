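import numpy as np
import pytest

from snplca import GenotypeMatrix, SnpInfo


def make_gm(values, status=None, ids=None, snp_ids=None) -> GenotypeMatrix:
    """Quick genotype-matrix constructor for fixtures."""
    values = np.asarray(values, dtype=np.int8)
    n, m = values.shape
    if ids is None:
        ids = [f"ind{i}" for i in range(n)]
    if snp_ids is None:
        snp_ids = [f"snp{j}" for j in range(m)]
    return GenotypeMatrix(
        individual_ids=list(ids),
        snps=[SnpInfo(snp_id=s) for s in snp_ids],
        values=values,
        status=None if status is None else np.asarray(status, dtype=object),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_genotypes(rng, n, m, missing_rate=0.1):
    values = rng.integers(0, 3, size=(n, m)).astype(np.int8)
    values[rng.random((n, m)) < missing_rate] = -1
    return values
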