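import numpy as np
import pytest

from thalascreen import regions, simulate


@pytest.fixture(scope="session")
def default_bins() -> regions.BinSet:
    return regions.make_uniform_bins(regions.DEFAULT_REGION, 66)


@pytest.fixture(scope="session")
def study_table() -> dict:
    """Genotype tallies of the 68,885-sample screening cohort."""
    return dict(simulate.STUDY_GENOTYPE_COUNTS)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260930)
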