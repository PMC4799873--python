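import pytest

from founderage.datasets import load_cohort, load_marker_map
from founderage.haplotypes import infer_ancestral


@pytest.fixture(scope="session")
def marker_map():
    return load_marker_map()


@pytest.fixture(scope="session")
def cohort():
    return load_cohort()


@pytest.fixture(scope="session")
def ancestral(cohort):
    return infer_ancestral(cohort)
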