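import numpy as np
import pandas as pd
import pytest

from stockid import GenotypeMatrix, SampleTable
from stockid.genotype_io import MISSING


@pytest.fixture
def two_group_matrix() -> tuple[GenotypeMatrix, SampleTable]:
    """4+4 samples, 3 loci: a fixed difference, a shared-polymorphism
    locus, and a locus with missing calls."""
    calls = np.array([
        [0, 1, 0],
        [0, 0, 1],
        [0, 1, MISSING],
        [0, 2, 0],
        [2, 1, 1],
        [2, 0, MISSING],
        [2, 1, 2],
        [2, 2, 1],
    ], dtype=np.int8)
    g = GenotypeMatrix([f"s{i}" for i in range(8)], ["L1", "L2", "L3"], calls)
    s = SampleTable(pd.DataFrame({
        "sample_id": g.sample_ids,
        "cluster": ["Northern"] * 4 + ["Southern"] * 4,
        "site_id": ["1_S", "1_S", "1_W", "1_W", "6", "6", "7", "7"],
    }))
    return g, s


def random_dataset(rng: np.random.Generator, n_groups=None, n_samples=None,
                   n_loci=None, missing_rate=0.1):
    """A small random genotype dataset for oracle comparisons."""
    n_groups = n_groups or rng.integers(2, 5)
    n_samples = n_samples or rng.integers(n_groups * 2, 21)
    n_loci = n_loci or rng.integers(1, 11)
    calls = rng.integers(0, 3, size=(n_samples, n_loci)).astype(np.int8)
    mask = rng.random(calls.shape) < missing_rate
    calls[mask] = MISSING
    labels = rng.integers(0, n_groups, size=n_samples)
    # guarantee every group is inhabited
    labels[:n_groups] = np.arange(n_groups)
    g = GenotypeMatrix([f"s{i}" for i in range(n_samples)],
                       [f"L{j}" for j in range(n_loci)], calls)
    s = SampleTable(pd.DataFrame({
        "sample_id": g.sample_ids,
        "cluster": [f"G{k}" for k in labels],
        "site_id": [f"G{k}_1" for k in labels],
    }))
    return g, s
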