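import numpy as np
import pandas as pd
import pytest

from tgrm.genotypes import GenotypeMatrix
from tgrm.simdata import SimConfig, simulate_genotypes


@pytest.fixture(scope="session")
def small_panel():
    """Two related sub-panels with overlap, ~60+50 lines x 150 markers."""
    cfg = SimConfig(
        n_lines_discovery=60, n_lines_elite=50, n_overlap=6,
        n_markers=150, n_ld_blocks=30, seed=42,
    )
    G, record = simulate_genotypes(cfg)
    return G, record, cfg


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_dosages(rng, n, p, het=0.0, missing=0.0):
    """Inbred-style random dosage matrix with optional het/missing calls."""
    d = rng.choice([0.0, 2.0], size=(n, p), p=[0.55, 0.45])
    if het:
        d[rng.random((n, p)) < het] = 1.0
    if missing:
        d[rng.random((n, p)) < missing] = np.nan
    return GenotypeMatrix(
        d, [f"L{i:03d}" for i in range(n)], [f"M{j:04d}" for j in range(p)]
    )
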