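import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mrsynth import make_axes, make_toy_basis

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

SW, NPTS, F0, PPM_REF = 2000.0, 4096, 127.7, 4.65


@pytest.fixture(scope="session")
def axes():
    return make_axes(SW, NPTS, F0, PPM_REF)


@pytest.fixture(scope="session")
def singlet_basis():
    """One metabolite singlet at 2.01 ppm."""
    return make_toy_basis([("NAA", "metabolite", [(2.01, 1.0)])], SW, NPTS, F0, PPM_REF)


@pytest.fixture(scope="session")
def multi_basis():
    """Two metabolites plus one macromolecule resonance."""
    return make_toy_basis(
        [
            ("NAA", "metabolite", [(2.01, 2.0)]),
            ("Cr", "metabolite", [(3.03, 1.0)]),
            ("MM09", "mm_lipid", [(0.9, 0.5)]),
        ],
        SW,
        NPTS,
        F0,
        PPM_REF,
    )
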