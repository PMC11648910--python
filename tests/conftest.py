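import numpy as np
import pytest

from foldcest import synthetic
from foldcest.bloch import CESTExperiment, CESTProfile
from foldcest.exchange import make_ff_model


@pytest.fixture(scope="session")
def scenario_a_network():
    return synthetic.scenario("A").network()


@pytest.fixture(scope="session")
def small_two_state():
    """Compact noiseless two-state dataset for fast fitting tests.

    3 spins x 2 B1 fields x 31 offsets generated under the glucose-buffer
    ground truth (kex = 587 s^-1, p_I2 = 2.1%).
    """
    scn = synthetic.scenario("B", n_spins=3)
    spins = synthetic.make_spin_set(3, minor_states=("I2",), seed=0)
    profiles, truth = synthetic.generate_profiles(scn, spins=spins)
    return thin_profiles(profiles, 2), truth


def thin_profiles(profiles, step):
    """Subsample every profile's offset grid by ``step`` (runtime control)."""
    out = []
    for p in profiles:
        e = p.experiment
        idx = np.arange(0, e.offsets.size, step)
        exp = CESTExperiment(e.b1, e.t_ex, e.spectrometer_1h_freq, e.carrier,
                             e.offsets[idx], e.nucleus, e.temperature,
                             e.b1_inhomogeneity)
        err = p.errors[idx] if p.errors is not None else None
        out.append(CESTProfile(exp, p.spin_id, p.intensities[idx], err))
    return out


@pytest.fixture
def two_state_net():
    return make_ff_model("two_state", {"kex_FI2": 587.0, "p_I2": 0.021},
                         temperature=293.15)
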