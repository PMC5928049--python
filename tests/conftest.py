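import numpy as np
import pytest

from slapenrich import (
    GeneLengthTable,
    GeneSet,
    MutationDataset,
    PathwayCollection,
    PlantedPathway,
    SimConfig,
    simulate_cohort,
)


@pytest.fixture
def toy_dataset():
    """3 genes x 3 samples: s1 has A; s2 has A and B; s3 has nothing."""
    ind = np.array(
        [
            [1, 1, 0],  # A
            [0, 1, 0],  # B
            [0, 0, 0],  # C
        ]
    )
    return MutationDataset(["A", "B", "C"], ["s1", "s2", "s3"], ind)


@pytest.fixture
def toy_lengths():
    return GeneLengthTable({"A": 1000, "B": 2000, "C": 3000})


@pytest.fixture
def toy_collection():
    return PathwayCollection(
        [
            GeneSet("P1", "pathway one", frozenset({"A", "B"})),
            GeneSet("P2", "pathway two", frozenset({"C"})),
        ]
    )


@pytest.fixture(scope="session")
def planted_sim():
    """A medium cohort with one mutually exclusive planted pathway."""
    config = SimConfig(
        n_samples=80,
        n_genes=1000,
        n_pathways=60,
        planted=(PlantedPathway("PLANTED00", n_genes=8, effect=5.0),),
        seed=11,
    )
    return simulate_cohort(config)
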