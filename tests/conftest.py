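import numpy as np
import pandas as pd
import pytest

from binbat.events import EventTable, StimulationCondition
from binbat.synthetic import ResponseModel, default_populations, simulate_events

GLUTEN_400 = StimulationCondition("allergen", allergen="gluten", concentration=400.0)
NEG_CTRL = StimulationCondition("negative_control")
ANTI_IGE = StimulationCondition("anti_IgE")
FMLP = StimulationCondition("fMLP")


@pytest.fixture(scope="session")
def stimulated_sample() -> EventTable:
    """One 100k-event whole-blood sample, gluten 400 ug/mL, allergic responder."""
    return simulate_events(default_populations(), ResponseModel(), GLUTEN_400,
                           100_000, seed=42)


@pytest.fixture(scope="session")
def control_sample() -> EventTable:
    """Matching unstimulated negative control."""
    return simulate_events(default_populations(), ResponseModel(), NEG_CTRL,
                           100_000, seed=43)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2026)


@pytest.fixture()
def small_table(rng) -> EventTable:
    """Small generic 2-channel-plus-target table for binning tests."""
    n = 500
    return EventTable(pd.DataFrame({
        "x": rng.uniform(0, 4, n),
        "y": rng.uniform(0, 4, n),
        "t": rng.uniform(0, 3, n),
    }))
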