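import numpy as np
import pytest

from ldscape.genotype_io import GenotypeMatrix, make_marker_map
from ldscape.synthetic_data import SimulationConfig, simulate_wright_fisher


@pytest.fixture
def tiny_genotypes():
    """4 individuals x 5 markers on two chromosomes, with one missing call."""
    dosages = np.array(
        [
            [2, 1, 0, 2, 1],
            [1, 1, 1, 2, 0],
            [0, 1, 2, 2, -1],
            [2, 0, 0, 2, 1],
        ],
        dtype=np.int8,
    )
    markers = make_marker_map(
        ["1", "1", "1", "2", "2"],
        [f"m{i}" for i in range(1, 6)],
        [100, 200, 300, 100, 250],
        ["A", "A", "C", "G", "T"],
        ["G", "C", "T", "A", "C"],
    )
    return GenotypeMatrix(dosages, ["s1", "s2", "s3", "s4"], markers)


@pytest.fixture(scope="session")
def wf_dataset():
    """A small two-chromosome Wright-Fisher panel shared across tests."""
    cfg = SimulationConfig(
        n_diploid=100,
        n_chromosomes=2,
        markers_per_chromosome=60,
        spacing_bp=100_000,
        generations=100,
        freq_range=(0.2, 0.8),
        sample_size=80,
        seed=11,
    )
    return simulate_wright_fisher(cfg)
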