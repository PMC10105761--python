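import numpy as np
import pytest

from pyrosc import kinetics as K


@pytest.fixture
def neutral_params():
    """Unit-everything parameter set: all k = Km = 1, n = 1, a = 0, Vmax = 4."""
    return K.ModelParameters(
        k1=1, k2=1, k3=1, Km1=1, Km2=1, Km3=1, Km4=1, Km5=1,
        n1=1, n2=1, n3=1, a1=0, a2=0, a3=0, flux_ratio=0.5,
        Vmax1=4, Vmax2=4, Vmax3=4, Vmax4=4, Vmax5=4, Vmax6=4,
    )


@pytest.fixture
def calibrated_sets():
    """Twenty calibrated stable full-structure sets, fixed seed."""
    sets, _ = K.sample_stable_ensemble(K.FULL_STRUCTURE, 20, rng=123)
    return sets


@pytest.fixture
def random_calibrated_params(calibrated_sets):
    return calibrated_sets[0]


def random_state(rng):
    return K.MetaboliteState(*np.exp(rng.uniform(-1.5, 1.5, 4)))
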