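import numpy as np
import pandas as pd
import pytest

from snpherit import GenotypeMatrix, MISSING


def make_genotypes(n: int, m: int, seed: int, missing_rate: float = 0.0,
                   maf_range=(0.05, 0.5), n_chroms: int = 2) -> GenotypeMatrix:
    """Random homogeneous-population genotype matrix for unit tests."""
    rng = np.random.default_rng(seed)
    p = rng.uniform(*maf_range, size=m)
    dosages = rng.binomial(2, p, size=(n, m)).astype(np.int8)
    if missing_rate > 0:
        dosages[rng.random((n, m)) < missing_rate] = MISSING
    chroms = np.repeat([str(c + 1) for c in range(n_chroms)],
                       np.diff(np.linspace(0, m, n_chroms + 1).astype(int)))
    meta = pd.DataFrame({
        "chrom": chroms,
        "snp_id": [f"s{i + 1}" for i in range(m)],
        "pos": np.arange(1, m + 1) * 500,
        "a1": "A", "a2": "C",
    })
    ids = pd.DataFrame({"fid": [f"F{i}" for i in range(n)],
                        "iid": [f"I{i}" for i in range(n)]})
    return GenotypeMatrix(dosages=dosages, snp_meta=meta, sample_ids=ids)


@pytest.fixture
def small_genotypes() -> GenotypeMatrix:
    return make_genotypes(30, 80, seed=7, missing_rate=0.05)
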