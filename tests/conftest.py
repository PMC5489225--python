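import numpy as np
import pandas as pd
import pytest

from vqscreen import ArchitectureSpec, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """300 individuals x 60 common SNPs, some marginal and interaction
    effects; shared across read-only tests."""
    spec = ArchitectureSpec(
        m_snps=60, maf_range=(0.15, 0.5), prop_effect=0.2, beta_scale=0.1,
        prop_interaction=0.1, delta_scale=0.3, exposure_main_effect=0.1, seed=42,
    )
    return simulate_cohort(spec, 300)


@pytest.fixture
def truth_maker():
    """Build a truth table with explicit per-SNP MAF/beta/delta."""

    def make(mafs, betas=None, deltas=None):
        m = len(mafs)
        return pd.DataFrame(
            {
                "snp_id": [f"snp{j + 1}" for j in range(m)],
                "chrom": "1",
                "pos": np.arange(1, m + 1) * 10_000,
                "ea": "A",
                "oa": "G",
                "maf": np.asarray(mafs, float),
                "beta": np.zeros(m) if betas is None else np.asarray(betas, float),
                "delta": np.zeros(m) if deltas is None else np.asarray(deltas, float),
            }
        )

    return make
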