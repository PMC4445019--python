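import numpy as np
import pytest

from probank.grm import ItemBank, ItemParameters
from probank.simulate import SimulationDesign, make_bank, simulate_responses


@pytest.fixture(scope="session")
def small_bank() -> ItemBank:
    """Five hand-picked 5-category items spanning the trait range."""
    items = (
        ItemParameters("a1", 1.8, (-2.0, -1.0, 0.0, 1.0)),
        ItemParameters("a2", 1.2, (-1.5, -0.5, 0.5, 1.5)),
        ItemParameters("a3", 2.4, (-1.0, 0.0, 1.0, 2.0)),
        ItemParameters("a4", 0.9, (-0.5, 0.3, 1.1, 1.9)),
        ItemParameters("a5", 1.5, (-2.2, -1.2, 0.2, 1.2)),
    )
    return ItemBank(items, metric_name="reference")


@pytest.fixture(scope="session")
def default_bank() -> ItemBank:
    """The 30-item PROMIS-like synthetic bank used across modules."""
    return make_bank(n_items=30, seed=0)


@pytest.fixture(scope="session")
def calibration_data(default_bank):
    """One calibration-sized sample (n=877) on a 20-item bank."""
    bank = make_bank(n_items=20, seed=3)
    design = SimulationDesign(bank=bank, n_persons=877, seed=11)
    return bank, simulate_responses(design)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
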