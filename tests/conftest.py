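import numpy as np
import pytest

from calfscape import MaxEntParams, generate_study


@pytest.fixture(scope="session")
def two_component_params() -> MaxEntParams:
    """The enumerable two-component system J12=1, h=(-0.1, -0.1)."""
    return MaxEntParams(h=np.array([-0.1, -0.1]),
                        J=np.array([[0.0, 1.0], [1.0, 0.0]]),
                        g_a=np.zeros(2), g_s=np.zeros(2))


@pytest.fixture(scope="session")
def dysbiosis_study():
    return generate_study(n_animals=12, seed=7, effect_profile="dysbiosis")


@pytest.fixture(scope="session")
def null_study():
    return generate_study(n_animals=12, seed=7, effect_profile="null")
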