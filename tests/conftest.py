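import numpy as np
import pytest

from csfpk.pk_model import PKParameters, Regimen
from csfpk.reference import (
    HUMAN_PARAMETERS,
    MONKEY_HUMAN_SCALE,
    monkey_typical_parameters,
)


@pytest.fixture(scope="session")
def human_params() -> PKParameters:
    """Published human-scale parameter set."""
    return HUMAN_PARAMETERS


@pytest.fixture(scope="session")
def monkey_params() -> PKParameters:
    """Monkey typical values from inverting the published scaling."""
    return monkey_typical_parameters()


@pytest.fixture(scope="session")
def monkey_human_scale():
    return MONKEY_HUMAN_SCALE


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


def random_params(rng: np.random.Generator) -> PKParameters:
    """Log-uniform random but physiologically shaped parameter sets."""
    return PKParameters(
        V=10 ** rng.uniform(1.5, 4),
        Cl=10 ** rng.uniform(-1, 2),
        V2=10 ** rng.uniform(1.5, 4),
        Cl2=10 ** rng.uniform(-1, 2),
        Vcsf=10 ** rng.uniform(1, 3.5),
        Qcsf=10 ** rng.uniform(-3, 0),
    )


@pytest.fixture(scope="session")
def monkey_1000_regimen() -> Regimen:
    return Regimen.single_iv_infusion(1000.0, 4.42, 0.5)
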