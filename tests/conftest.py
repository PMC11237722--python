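import numpy as np
import pytest

from phagecomm.model_core import preset_params


@pytest.fixture(scope="session")
def competition():
    return preset_params("competition")


@pytest.fixture(scope="session")
def mutualism():
    return preset_params("mutualism")


@pytest.fixture(scope="session")
def mutualism_prey_roots():
    """Closed-form phage-free symmetric equilibria of the mutualism preset.

    Setting the prey equation to zero under E = S = x gives
    0.5 x (x/(x+1)) (1-x) = 0.03 x, i.e. x^2 - 0.94 x + 0.06 = 0.
    """
    disc = np.sqrt(0.94**2 - 4 * 0.06)
    return (0.94 - disc) / 2, (0.94 + disc) / 2  # (unstable Allee root, stable root)
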