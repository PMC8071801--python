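import numpy as np
import pytest

from poremech.nucleation import NucleationParams

#: Table of (label, line tension in N, spreading pressure in N/m) for the
#: three experimental conditions of the supported POPC:POPG 1:1 bilayer
#: study: bare bilayer, with dodeca-arginine, with the side-chain mimic.
CONDITIONS = [
    ("popc_popg", 6.93e-12, 9.49e-3),
    ("r12", 8.49e-12, 3.65e-3),
    ("r_side", 4.91e-12, 4.30e-3),
]


@pytest.fixture
def bare_bilayer_params():
    """Nucleation parameters of the bare POPC:POPG 1:1 condition."""
    return NucleationParams(gamma=6.93e-12, spreading_pressure=9.49e-3)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
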