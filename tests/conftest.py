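import numpy as np
import pytest

from ecmassembly.io import AsvTable
from ecmassembly.simulate import SyntheticConfig, generate_study


@pytest.fixture
def toy_table() -> AsvTable:
    """3 ASVs x 3 samples; ASV_a occurs in a single sample."""
    return AsvTable(
        np.array([[5, 0, 0], [3, 2, 0], [1, 1, 1]]),
        ["ASV_a", "ASV_b", "ASV_c"],
        ["S1", "S2", "S3"],
    )


@pytest.fixture(scope="session")
def small_study():
    """Reduced synthetic study shared by read-only tests.

    4 replicates x 6 species x 2 stages = 48 samples at depth 3000 with 100
    EcM ASVs (+ decoys); keeps per-test runtime low.
    """
    cfg = SyntheticConfig(n_replicates=4, depth=3000, n_asvs=100, seed=11)
    table, metadata, taxonomy, truth = generate_study(cfg)
    return cfg, table, metadata, taxonomy, truth


def random_table(rng: np.random.Generator, n_asvs=12, n_samples=6, lam=20) -> AsvTable:
    counts = rng.poisson(lam, size=(n_asvs, n_samples))
    counts[0] += 1  # guard against an all-zero sample
    return AsvTable(
        counts,
        [f"A{i}" for i in range(n_asvs)],
        [f"S{j}" for j in range(n_samples)],
    )
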