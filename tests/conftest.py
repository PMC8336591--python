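import numpy as np
import pytest

from internof1 import CountMatrix, PairedSample, SimulationConfig, generate_dataset


@pytest.fixture
def tiny_matrix() -> CountMatrix:
    """3 genes x 4 samples (two subjects' baseline/case pairs)."""
    counts = np.array(
        [
            [2.0, 3.0, 10.0, 20.0],
            [8.0, 8.0, 8.0, 8.0],
            [0.0, 6.0, 12.0, 30.0],
        ]
    )
    return CountMatrix(
        ["gA", "gB", "gC"], ["s1_base", "s1_case", "s2_base", "s2_case"], counts
    )


@pytest.fixture
def tiny_pairs() -> list[PairedSample]:
    return [
        PairedSample("s1", "s1_base", "s1_case"),
        PairedSample("s2", "s2_base", "s2_case"),
    ]


@pytest.fixture(scope="session")
def small_dataset():
    """A small but complete simulated study (3vs3, 5000 genes)."""
    return generate_dataset(SimulationConfig(n_genes=5000, cohort_size=3, seed=11))
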