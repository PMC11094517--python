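"""Shared fixtures: small synthetic panels kept cheap enough for unit tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from prsconv.panel import GenotypePanel

# keep runs reproducible and the working tree free of example databases
settings.register_profile("default", database=None, derandomize=True)
settings.load_profile("default")
from prsconv.simulate import QcViolationRates, SimConfig, simulate_genotypes


def make_panel(dosage, positions=None, a1="G", a2="A", chrom="1"):
    """Hand-built panel from a dosage matrix (helper, not a fixture)."""
    dosage = np.asarray(dosage, dtype=float)
    n, m = dosage.shape
    if positions is None:
        positions = 10_000 * (np.arange(m) + 1)
    variants = pd.DataFrame(
        {
            "variant_id": [f"v{j + 1}" for j in range(m)],
            "chrom": chrom,
            "pos": positions,
            "a1": a1 if isinstance(a1, list) else [a1] * m,
            "a2": a2 if isinstance(a2, list) else [a2] * m,
        }
    )
    return GenotypePanel(dosage, variants, [f"s{i + 1}" for i in range(n)])


@pytest.fixture(scope="session")
def small_cfg():
    return SimConfig(
        n_target=150,
        n_discovery=500,
        n_variants=300,
        n_blocks=15,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_panel(small_cfg):
    return simulate_genotypes(small_cfg)


@pytest.fixture(scope="session")
def independent_panel():
    """5,000 independent variants for relatedness nulls."""
    cfg = SimConfig(
        n_target=60, n_variants=5000, n_blocks=5000, ld_copy_prob=0.0,
        missing_rate=0.0, seed=23,
    )
    return simulate_genotypes(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(2026)
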