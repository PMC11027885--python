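import numpy as np
import pytest

from pgpflux.reference import DEFAULT_PHASES, DEMO_RATES
from pgpflux.transport import ObservableParams, PhaseSchedule


@pytest.fixture(scope="session")
def phases() -> PhaseSchedule:
    return DEFAULT_PHASES


@pytest.fixture(scope="session")
def short_phases() -> PhaseSchedule:
    """Compressed injection cycle for cheap simulations."""
    return PhaseSchedule(association_end=300.0, trace_end=500.0)


@pytest.fixture(scope="session")
def obs() -> ObservableParams:
    return ObservableParams(k=1e6, c=0.0)
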