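import numpy as np
import pytest

from impactlevels import ItemBank, ItemParameters, SimulationConfig, simulate_bank
from impactlevels.vignettes import build_vignette_set


@pytest.fixture(scope="session")
def example_item() -> ItemParameters:
    """The worked item: a = 2, b = (-2, -1, 1, 2), symmetric about theta = 0."""
    return ItemParameters(item_id="ex1", text="example", subdomain="chores",
                          a=2.0, b=(-2.0, -1.0, 1.0, 2.0))


@pytest.fixture(scope="session")
def symmetric_bank(example_item) -> ItemBank:
    return ItemBank(items=(example_item,), name="symmetric")


@pytest.fixture(scope="session")
def reference_bank() -> ItemBank:
    """Synthetic 12-item reference bank used across modules (seed 4)."""
    return simulate_bank(SimulationConfig(seed=4))


@pytest.fixture(scope="session")
def reference_vignettes(reference_bank):
    return build_vignette_set(reference_bank, t_min=45.0, t_max=80.0,
                              n_vignettes=8, n_items=6)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260903)


def random_item(rng: np.random.Generator, item_id: str = "rnd") -> ItemParameters:
    """Random valid GRM item for property checks."""
    a = float(rng.uniform(0.4, 3.0))
    b1 = float(rng.uniform(-2.5, 0.5))
    gaps = rng.uniform(0.2, 1.5, size=3)
    b = tuple(b1 + np.concatenate([[0.0], np.cumsum(gaps)]))
    return ItemParameters(item_id=item_id, text="", subdomain="x", a=a, b=b)
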