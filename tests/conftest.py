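import numpy as np
import pytest

from fluorbind import GroundTruth, QuenchTitration
from fluorbind.synthetic import default_concentrations, generate_titration


@pytest.fixture
def noiseless_titration() -> QuenchTitration:
    """Exact static-quenching titration with the reference ground truth."""
    return generate_titration(GroundTruth(noise_sd_relative=0.0, seed=0))


@pytest.fixture
def linear_sv_titration() -> QuenchTitration:
    """Noiseless titration following the linear quench law with K_SV = 8.5e3."""
    q = default_concentrations()
    f0 = 1.0e4
    return QuenchTitration(
        quencher_concentrations=q,
        intensities=f0 / (1.0 + 8.5e3 * q),
        F0=f0,
        temperature=298.0,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260919)
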