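import numpy as np
import pytest

from cagrna.thermo import MeltingParameters
from cagrna.tjump import JumpProtocol
from cagrna.synthetic import gen_cag_hairpin


@pytest.fixture(scope="session")
def dpbs_params() -> MeltingParameters:
    """In vitro (buffer) melting parameters: T_m = 349 K, dG37 = 20.7 kJ/mol."""
    return MeltingParameters(tm=349.0, g1=-20.7 / 39.0)


@pytest.fixture(scope="session")
def ladder() -> JumpProtocol:
    """19-jump consecutive ladder spanning 303-358 K, 25 s dwell."""
    return JumpProtocol(target_temperatures=tuple(np.linspace(303.0, 358.0, 19)),
                       start_temperature=300.0)


@pytest.fixture(scope="session")
def hairpin20():
    return gen_cag_hairpin(20)


@pytest.fixture(scope="session")
def hairpin4():
    return gen_cag_hairpin(4)
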