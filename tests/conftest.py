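import numpy as np
import pytest

from lhigp import find_attractor, solve_equilibrium
from lhigp.scenarios import default_parameters

#: Closed-form consumer-resource equilibrium at the default constants:
#: R* from nu_c = mu_c, C* from the resource balance delta*(R_max - R*) = I_c*C.
CR_R = 1.1 / 3.9
CR_C = (3.0 - CR_R) / 2.2


@pytest.fixture
def params():
    """Factory for parameter sets at the standard constants."""
    def make(a_jr, a_ar=0.0, beta=0.0, **overrides):
        return default_parameters(a_jr=a_jr, a_ar=a_ar, beta=beta, **overrides)
    return make


@pytest.fixture(scope="session")
def cr_equilibrium():
    p = default_parameters(a_jr=4.0, a_ar=0.0, beta=0.0)
    return solve_equilibrium([0.3, 1.2, 0.0, 0.0], p, absent={"Pj", "Pa"})


@pytest.fixture(scope="session")
def pcr_equilibrium():
    """Stable three-species coexistence state (diet shift, no cannibalism)."""
    p = default_parameters(a_jr=4.5, a_ar=0.0, beta=0.0)
    rep = find_attractor(np.array([1.5, 0.5, 0.3, 0.3]), p)
    assert rep.status == "equilibrium" and rep.equilibrium.label == "PCR"
    return rep.equilibrium
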