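import numpy as np
import pytest

from melroot import synthetic as syn
from melroot import validation


@pytest.fixture(scope="session")
def study_ds():
    """One full synthetic study at the emulated design, shared read-only."""
    return syn.study_dataset(seed=0)


@pytest.fixture(scope="session")
def study_fpkm(study_ds):
    return validation.fpkm_of(study_ds)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_spec():
    """A fast 60-gene simulation spec with planted up/down effects."""
    return syn.SimulationSpec(
        n_genes=60,
        chrom_length=400_000,
        seed=7,
        de_spec=(
            syn.DEPattern(8, "up", 2.0, ("M10", "M20")),
            syn.DEPattern(4, "down", 2.0, ("M10", "M20")),
        ),
    )
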