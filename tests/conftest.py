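import numpy as np
import pytest

from olfnet.cohort import CohortSpec, simulate_cohort
from olfnet.paradigm import build_paradigm
from olfnet.templates import default_templates


@pytest.fixture(scope="session")
def design():
    return build_paradigm()


@pytest.fixture(scope="session")
def templates():
    return default_templates()


@pytest.fixture(scope="session")
def spec():
    return CohortSpec()


@pytest.fixture(scope="session")
def cn_cohort(spec):
    """Small CN-only cohort table used by simulation-level tests."""
    return simulate_cohort(spec.with_sizes(8, 0, 0), seed=11)


def planted_series(cohort, design, spec, seed):
    """Network series for every subject of a cohort table."""
    from olfnet.bold import simulate_network_series

    rng = np.random.default_rng(seed)
    return [
        simulate_network_series(row, design, spec, rng)
        for _, row in cohort.iterrows()
    ]
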