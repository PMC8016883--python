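import numpy as np
import pandas as pd
import pytest

from logoscan import ld_core
from logoscan import synthetic_data as sd


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_panel():
    """Session-wide panel: ~300 SNPs with realistic decaying LD."""
    raw, meta, founders, positions = sd.simulate_panel(300, 300, seed=42)
    panel = ld_core.standardize_genotypes(raw, meta, maf_min=0.0)
    return panel


@pytest.fixture(scope="session")
def panel_with_founders():
    raw, meta, founders, positions = sd.simulate_panel(400, 400, seed=7)
    panel = ld_core.standardize_genotypes(raw, meta, maf_min=0.0)
    return panel, founders, positions


def independent_panel(m=500, n_ref=400, seed=0, spacing_bp=5_000_000):
    """Panel of essentially independent SNPs (far apart, free recombination)."""
    rng = np.random.default_rng(seed)
    freqs = rng.uniform(0.2, 0.8, m)
    raw = rng.binomial(2, freqs[None, :], size=(n_ref, m)).astype(float)
    meta = pd.DataFrame(
        {
            "snp": [f"rs{i}" for i in range(m)],
            "chrom": "1",
            "pos": np.arange(m, dtype=np.int64) * spacing_bp + 1,
            "a1": "A",
            "a2": "G",
        }
    )
    return ld_core.standardize_genotypes(raw, meta, maf_min=0.0)


@pytest.fixture(scope="session")
def indep_panel():
    return independent_panel()
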