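import numpy as np
import pandas as pd
import pytest

from petalgwas.datatypes import GenotypeMatrix
from petalgwas.simulate import PopSimConfig, simulate_genotypes


def make_matrix(calls, chrom="Chr01", start=100, step=100, samples=None):
    """GenotypeMatrix from a literal samples x variants code array."""
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    samples = samples or [f"S{i:03d}" for i in range(n)]
    pos = start + step * np.arange(m)
    variants = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": pos,
            "id": [f"{chrom}_{p}" for p in pos],
            "ref": "A",
            "alt": "T",
        }
    )
    return GenotypeMatrix(samples=samples, variants=variants, calls=calls)


@pytest.fixture(scope="session")
def structured_panel():
    """A small three-subpopulation panel shared across tests."""
    cfg = PopSimConfig(
        n_per_subpop=(40, 30, 30), n_variants=500, missing_rate=0.02, seed=42
    )
    G, labels = simulate_genotypes(cfg)
    return G, labels


@pytest.fixture(scope="session")
def gwas_panel():
    """A GWAS-sized panel (n=300, 3000 markers) for variance-component tests."""
    cfg = PopSimConfig(n_per_subpop=(100, 100, 100), n_variants=3000, seed=7)
    return simulate_genotypes(cfg)[0]


@pytest.fixture(scope="session")
def clean_panel():
    """A fully-called panel (no missing data)."""
    cfg = PopSimConfig(n_per_subpop=(40, 30, 30), n_variants=400, seed=7)
    G, labels = simulate_genotypes(cfg)
    return G, labels
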