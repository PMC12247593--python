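import numpy as np
import pytest
from hypothesis import settings

import qbrm

settings.register_profile("ci", deadline=None, derandomize=True,
                          max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def ideal_train():
    return qbrm.OpticalTrain(angles_deg=(0.0, 60.0, 120.0), seed=7)


@pytest.fixture
def small_phantom():
    """A few axons and one vesicle on a 96x96 raster."""
    spec = qbrm.PhantomSpec(
        shape=(96, 96),
        structures=(
            qbrm.LongitudinalAxon(center=(30, 48), length=80,
                                  direction_deg=0.0, outer_radius=6,
                                  sheath_thickness=2, delta_peak=0.08),
            qbrm.LongitudinalAxon(center=(60, 48), length=70,
                                  direction_deg=30.0, outer_radius=5,
                                  sheath_thickness=2, delta_peak=0.06),
            qbrm.TransverseAxon(center=(75, 20), radius=7, thickness=2,
                                delta_peak=0.07),
            qbrm.Vesicle(center=(20, 75), radius=5, thickness=2,
                         delta_peak=0.05),
        ),
        seed=3,
    )
    return qbrm.generate_phantom(spec)


def jones_retarder(phi_deg, retardance_waves):
    """Brute-force 2x2 complex Jones matrix of a linear retarder (oracle)."""
    phi = np.deg2rad(phi_deg)
    g2 = np.pi * retardance_waves
    c, s = np.cos(g2), np.sin(g2)
    return np.array([
        [c + 1j * s * np.cos(2 * phi), 1j * s * np.sin(2 * phi)],
        [1j * s * np.sin(2 * phi), c - 1j * s * np.cos(2 * phi)],
    ])
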