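import numpy as np
import pandas as pd
import pytest

from greml import GenotypeMatrix, SimConfig, simulate_genotypes


def make_genotype_matrix(calls, chrom=None, annotations=None, maf_meta=None):
    """Build a GenotypeMatrix directly from a call matrix (tests' workhorse)."""
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    samples = pd.DataFrame(
        {"fid": [f"F{i}" for i in range(n)], "iid": [f"I{i}" for i in range(n)]}
    )
    snps = pd.DataFrame(
        {
            "snp": [f"rs{j}" for j in range(m)],
            "chrom": np.ones(m, dtype=int) if chrom is None else np.asarray(chrom),
            "pos": np.arange(1, m + 1) * 100,
            "a1": "A",
            "a2": "C",
            "cm": 0.0,
        }
    )
    meta = {} if maf_meta is None else {"true_maf": np.asarray(maf_meta, float)}
    return GenotypeMatrix(samples=samples, snps=snps, calls=calls,
                         annotations=annotations or {}, meta=meta)


@pytest.fixture(scope="session")
def small_panel():
    """600 samples x 1,500 SNPs HWE panel, default MAF spectrum."""
    cfg = SimConfig(n_snps=1500, n_cases=100, n_controls=500, seed=42)
    return simulate_genotypes(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
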