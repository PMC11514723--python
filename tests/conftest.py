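import numpy as np
import pytest

from lipasym import (
    TABLE_BILAYERS,
    ScenarioSpec,
    simulate_timecourse,
    synthetic_curvature_table,
)


@pytest.fixture(scope="session")
def curvature_table():
    """Full synthetic curvature table (POPE/POPC flat, POPG saturating)."""
    return synthetic_curvature_table()


@pytest.fixture
def pe_pg():
    return TABLE_BILAYERS["PE/PG"]


@pytest.fixture
def noiseless_timecourse():
    """Clean exponential decay at k = 0.01 /s, known plateau."""
    spec = ScenarioSpec(
        bilayer=TABLE_BILAYERS["PE/PG"], k_true=0.01, noise_sigma=0.0, seed=1
    )
    return spec, simulate_timecourse(spec)
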