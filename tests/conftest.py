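import numpy as np
import pytest

from cbg3d.core_io import Genome, load_packaged_genome, make_bins
from cbg3d.scab import scab_matrix
from cbg3d.synthetic_data import (
    default_cohort_design,
    make_compartment_track,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def human_genome():
    return load_packaged_genome("human")


@pytest.fixture(scope="session")
def mouse_genome():
    return load_packaged_genome("mouse")


@pytest.fixture
def toy_genome():
    return Genome(
        species="toy",
        names=("chrA", "chrB", "chrX"),
        lengths=(10_000_000, 10_500_000, 5_000_000),
        x_name="chrX",
    )


@pytest.fixture(scope="session")
def human_track(human_genome):
    return make_compartment_track(human_genome, 1_000_000, seed=1)


@pytest.fixture(scope="session")
def cohort(human_genome):
    """Default five-stage cohort: 100 cells/stage at 20,000 contacts/cell."""
    design = default_cohort_design(genome=human_genome, n_per_stage=100, n_contacts=20_000, seed=5)
    return simulate_cohort(design)


@pytest.fixture(scope="session")
def cohort_scab(cohort):
    return scab_matrix(cohort.cells, cohort.track.bin_index, cohort.track)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
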