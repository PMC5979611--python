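import numpy as np
import pytest

from uiexplore.space import ReactionSpace, angular_space


@pytest.fixture
def flat2d():
    """Non-periodic 2D space at beta = 1."""
    return ReactionSpace(dim=2, periodic=(False, False), beta=1.0)


@pytest.fixture
def torus2d():
    """Periodic (-pi, pi]^2 dihedral space at 298 K."""
    return angular_space(2)


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)
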