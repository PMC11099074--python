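import numpy as np
import pytest

from llcroe import RelaxationModel, SpinSystem
from llcroe.synthetic_data import default_three_spin_system

R_IS = 1.77  # methylene H-H distance (A)


@pytest.fixture(scope="session")
def equivalent_pair() -> SpinSystem:
    """Magnetically equivalent proton pair (free glycine limit)."""
    return SpinSystem(
        labels=("I", "S"),
        offsets_hz=(0.0, 0.0),
        j_couplings_hz={("I", "S"): 17.5},
        coordinates_angstrom=((0.0, 0.0, 0.0), (0.0, 0.0, R_IS)),
        b0_T=22.3,
    )


@pytest.fixture(scope="session")
def gly117_pair() -> SpinSystem:
    """Gly117-like pair: J = 17.5 Hz, shift difference 140 Hz at 950 MHz."""
    return SpinSystem(
        labels=("I", "S"),
        offsets_hz=(70.0, -70.0),
        j_couplings_hz={("I", "S"): 17.5},
        coordinates_angstrom=((0.0, 0.0, 0.0), (0.0, 0.0, R_IS)),
        b0_T=22.3,
    )


@pytest.fixture(scope="session")
def three_spin() -> SpinSystem:
    """Default glycine-like three-spin geometry (K at 2.5 A from S,
    3.6 A from I, in the IS plane)."""
    return default_three_spin_system()


@pytest.fixture(scope="session")
def model_10ns() -> RelaxationModel:
    """Protein-like tumbling at the experiment's field."""
    return RelaxationModel(tau_c_s=10e-9, b0_T=22.3)


def make_three_spin(
    k_xyz, b0_T: float = 22.3, j_is: float = 17.5, dnu_hz: float = 140.0
) -> SpinSystem:
    return SpinSystem(
        labels=("I", "S", "K"),
        offsets_hz=(dnu_hz / 2.0, -dnu_hz / 2.0, 300.0),
        j_couplings_hz={("I", "S"): j_is},
        coordinates_angstrom=(
            (0.0, 0.0, 0.0),
            (0.0, 0.0, R_IS),
            tuple(float(v) for v in k_xyz),
        ),
        b0_T=b0_T,
    )
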