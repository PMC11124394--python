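import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import isobind as ib

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def binding_matrix() -> ib.IsotypeBindingMatrix:
    """Bundled 9-compound × 9-isotype docking energy table."""
    return ib.load_fixture("binding")


@pytest.fixture(scope="session")
def weighted_table() -> ib.WeightedEnergyTable:
    """Bundled 9-compound × 7-cell-line published BE_w table."""
    return ib.load_fixture("weighted")


@pytest.fixture(scope="session")
def potency_table() -> ib.CensoredPotencyTable:
    """Bundled IC50 table with '>100' right-censoring."""
    return ib.load_fixture("ic50")


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240508)
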