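import numpy as np
import pytest

from hgtest.models import SubstitutionModel, two_state_model, parse_model


@pytest.fixture(scope="session")
def model2():
    """Symmetric binary model (closed forms available)."""
    return two_state_model()


@pytest.fixture(scope="session")
def model4():
    """4-state reversible toy model with unequal frequencies."""
    s = np.array([
        [0.0, 1.0, 2.0, 1.0],
        [1.0, 0.0, 1.0, 3.0],
        [2.0, 1.0, 0.0, 1.0],
        [1.0, 3.0, 1.0, 0.0],
    ])
    pi = np.array([0.1, 0.2, 0.3, 0.4])
    return SubstitutionModel("ACGT", s, pi)


@pytest.fixture(scope="session")
def lg_model():
    return parse_model("LG+I+G4", alpha=1.0, p_inv=0.1)
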