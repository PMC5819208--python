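import numpy as np
import pandas as pd
import pytest

from pleioscan.sumstats import TraitSumStats


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


def make_records(n=5, chrom="1", seed=0, **overrides):
    """Small well-formed summary-statistics table."""
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(
        {
            "snp_id": [f"rs{i}" for i in range(n)],
            "chrom": chrom,
            "pos": 1000 + 100 * np.arange(n),
            "effect_allele": ["A", "G", "C", "T", "A"][:n] if n <= 5 else ["A"] * n,
            "ref_allele": ["G", "A", "T", "C", "C"][:n] if n <= 5 else ["G"] * n,
            "eaf": rng.uniform(0.05, 0.95, n),
            "beta": rng.normal(0, 0.1, n),
            "se": rng.uniform(0.02, 0.2, n),
        }
    )
    for k, v in overrides.items():
        df[k] = v
    return df


@pytest.fixture
def trait_pair():
    """Two traits sharing the same SNPs and orientation."""
    a = TraitSumStats("NP", make_records(seed=1))
    b = TraitSumStats("NFT", make_records(seed=2))
    return a, b
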