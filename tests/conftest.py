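import numpy as np
import pandas as pd
import pytest

from glialseq import CountMatrix, SampleDesign, SimConfig, generate_counts


@pytest.fixture
def small_counts():
    rng = np.random.default_rng(7)
    df = pd.DataFrame(
        rng.poisson(50, size=(20, 6)),
        index=[f"G{i:03d}" for i in range(20)],
        columns=[f"C{i}" for i in range(3)] + [f"E{i}" for i in range(3)],
    )
    return CountMatrix(df)


@pytest.fixture
def small_design(small_counts):
    return SampleDesign(
        pd.Series(["C"] * 3 + ["E"] * 3, index=small_counts.sample_ids), reference="C"
    )


@pytest.fixture
def sim_null():
    """A null (no planted effect) simulated experiment, 5 vs 5."""
    cfg = SimConfig(n_genes=400, n_per_group=5, dispersion=0.1, seed=11)
    return generate_counts(cfg)
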