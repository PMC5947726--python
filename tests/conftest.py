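import numpy as np
import pytest

from diffusemap.geometry import CrystalFrame, DetectorGeometry, DiffractionFrame
from diffusemap.mapping import MapGrid
from diffusemap.synthetic import ToyCrystalSpec, make_toy_crystal


@pytest.fixture(scope="session")
def small_geometry():
    return DetectorGeometry(distance=100.0, pixel_size=0.5, n_fast=128,
                            n_slow=128, beam_center=(63.5, 63.5),
                            wavelength=1.0)


@pytest.fixture(scope="session")
def p1_toy():
    """Five constant-form-factor atoms in a triclinic-friendly P1 box."""
    spec = ToyCrystalSpec(n_atoms=5, cell=(20.0, 22.0, 24.0, 90, 90, 90),
                          elements=("X",), seed=3)
    return make_toy_crystal(spec)


@pytest.fixture(scope="session")
def p1_grid(p1_toy):
    return MapGrid(p1_toy.crystal_frame(), oversampling=3, extent=2)


@pytest.fixture(scope="session")
def ortho_toy():
    spec = ToyCrystalSpec(n_atoms=3, cell=(20.0, 24.0, 28.0, 90, 90, 90),
                          spacegroup="P212121", seed=2)
    return make_toy_crystal(spec)


@pytest.fixture(scope="session")
def ortho_grid(ortho_toy):
    return MapGrid(ortho_toy.crystal_frame(), oversampling=3, extent=3)


@pytest.fixture
def flat_frame():
    pixels = np.full((64, 64), 7.0)
    return DiffractionFrame(pixels, np.ones_like(pixels, dtype=bool),
                            phi_start=0.0, phi_width=1.0)


@pytest.fixture(scope="session")
def p1_crystal():
    return CrystalFrame((25.0, 25.0, 25.0, 90.0, 90.0, 90.0))
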