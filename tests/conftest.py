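import numpy as np
import pandas as pd
import pytest

from phytomer.types import GenotypeMatrix, InternodeProfile


@pytest.fixture
def profile_213() -> InternodeProfile:
    """Hand-OLS fixture: slope 0.5, intercept 1, |residuals| sum 2, AMP 1/3."""
    return InternodeProfile("p1", "g1", [2.0, 1.0, 3.0])


@pytest.fixture
def linear_profile() -> InternodeProfile:
    return InternodeProfile("p2", "g1", [1.0, 2.0, 3.0, 4.0])


@pytest.fixture
def replicated_trait_frame() -> pd.DataFrame:
    """Balanced 200-genotype, 4-replicate trait table with sigma_g = sigma_e = 1."""
    rng = np.random.default_rng(42)
    g = rng.normal(0.0, 1.0, 200)
    rows = [
        {"genotype": f"g{i:03d}", "replicate": f"r{j}", "value": 10.0 + g[i] + rng.normal(0.0, 1.0)}
        for i in range(200)
        for j in range(4)
    ]
    return pd.DataFrame(rows)


def make_geno(dosage, pos=None, chrom="1H", ids=None) -> GenotypeMatrix:
    dosage = np.asarray(dosage, dtype=float)
    n_acc, n_snp = dosage.shape
    return GenotypeMatrix(
        accession_ids=ids or [f"a{k}" for k in range(n_acc)],
        chrom=np.full(n_snp, chrom, dtype=object),
        pos=np.arange(1, n_snp + 1) * 1000 if pos is None else np.asarray(pos),
        dosage=dosage,
    )
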