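import numpy as np
import pytest

from carapace_pheno.calibration import GreyStandardLadder
from carapace_pheno.colour import CHANNELS
from carapace_pheno.synthetic import LADDER_REFLECTANCES


@pytest.fixture
def rng():
    return np.random.default_rng(20250901)


def ladder_from_response(exponent: float = 1.0, scale: float = 255.0) -> GreyStandardLadder:
    """Ladder measured under a noiseless power-law camera response."""
    refl = LADDER_REFLECTANCES.copy()
    vals = scale * refl ** (1.0 / exponent)
    return GreyStandardLadder(
        reflectances=refl, measured={ch: vals.copy() for ch in CHANNELS}
    )


@pytest.fixture
def identity_ladder():
    return ladder_from_response(exponent=1.0)


@pytest.fixture
def gamma_ladder():
    return ladder_from_response(exponent=2.2)
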