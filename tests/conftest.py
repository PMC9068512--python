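import numpy as np
import pytest

from porestate.synthetic import ToyGateSpec, gen_gate_geometry


@pytest.fixture(scope="session")
def clean_gate():
    """Noise-free toy tetramer with 5-Angstrom rings and chi1 = 60 deg."""
    return gen_gate_geometry(ToyGateSpec(chi1_targets=(60.0, 60.0, 60.0, 60.0)))


@pytest.fixture(scope="session")
def bent_gate():
    """Toy tetramer with subunits B and D kinked at the hinge (+1.5 A at top)."""
    return gen_gate_geometry(ToyGateSpec(bend_flags=(False, True, False, True)))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
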