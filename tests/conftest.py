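import numpy as np
import pytest

from pdlmech import (
    FractionalKernel,
    PDLMaterial,
    RootGeometry,
    assemble_stiffness,
)

# Reference human-incisor-like parameter set (the "reference" preset):
# paraboloid root h = 13 mm, b = 3.9 mm, e = 0.6; PDL 0.229 mm thick,
# relaxed modulus 680 kPa, nu = 0.49; kernel gamma = 0.35, tau_sigma = 550 s,
# nu_sigma = 1.3e3.


@pytest.fixture(scope="session")
def ref_geom() -> RootGeometry:
    return RootGeometry(h=13.0e-3, b=3.9e-3, e=0.6, delta=0.229e-3)


@pytest.fixture(scope="session")
def ref_material() -> PDLMaterial:
    return PDLMaterial(e_inf=680e3, nu=0.49)


@pytest.fixture(scope="session")
def ref_kernel() -> FractionalKernel:
    return FractionalKernel(gamma=0.35, tau_sigma=550.0, nu_sigma=1.3e3)


@pytest.fixture(scope="session")
def ref_stiffness(ref_geom, ref_material):
    return assemble_stiffness(ref_geom, ref_material)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)


# Published coefficient table for the reference parameter set (SI units).
PUBLISHED_STIFFNESS = {
    "a11": 5.043e6,
    "a22": 1.090e6,
    "a33": 6.997e6,
    "a44": 578.9,
    "a55": 6.137,
    "a66": 445.6,
    "a16": -44.168e3,
    "a34": 59.060e3,
}


@pytest.fixture(scope="session")
def published_stiffness() -> dict:
    return dict(PUBLISHED_STIFFNESS)
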