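import numpy as np
import pytest

from singlehit.geomio import DetectorGeometry
from singlehit.simdata import SimulationConfig


@pytest.fixture(scope="session")
def psd_geometry():
    """Fully live square detector with enough q range for ~10 sphere fringes."""
    mask = np.ones((128, 128), dtype=bool)
    return DetectorGeometry(
        distance=0.046, pixel_size=75e-6, wavelength=0.729,
        beam_center=(63.5, 63.5), panel_mask=mask,
    )


@pytest.fixture(scope="session")
def train_geometry():
    """Small half-dead two-panel detector at the experiment's q sampling."""
    return DetectorGeometry.two_panel(
        shape=(64, 64), distance=0.130, pixel_size=75e-6, wavelength=0.729,
    )


@pytest.fixture()
def mono_sphere_config():
    """Noise-controlled monodisperse sphere source (R = 35 nm)."""
    return SimulationConfig(
        particle_radius_range=(35.0, 35.0), contaminant_fraction=0.0,
        fluence_jitter=0.0, mean_photon_scale=50.0, background_level=0.01,
        seed=3,
    )
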