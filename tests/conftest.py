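import numpy as np
import pytest

from fajtrace import (Beam, ControlPoint, PhaseSpaceStore, SourceModel,
                      default_geometry, generate_phspA)


@pytest.fixture
def geom():
    return default_geometry()


@pytest.fixture
def four_radii_store():
    """Four photons at radii 1, 2, 3, 4 cm on the z=26 plane."""
    r = np.array([1.0, 2.0, 3.0, 4.0])
    zeros = np.zeros(4)
    return PhaseSpaceStore(np.ones(4, np.int8), np.full(4, 2.0), r, zeros,
                           np.full(4, 26.0), zeros, zeros, np.ones(4),
                           z_plane=26.0)


@pytest.fixture
def point_source_store():
    """2e5 photons from a point source with a cone covering ~12x12 at iso."""
    model = SourceModel(seed=101, focal_spot_sigma=0.0, cone_half_angle=0.1)
    return generate_phspA(model, 200_000)


def square_beam(half=5.0, total_mu=100.0, modality="static", n_cp=1,
                jaw_tracking=False, mlc=None, gantry=0.0):
    jaws = (-half, half, -half, half)
    if n_cp == 1:
        cps = [ControlPoint(0, 0.0, jaws, mlc, gantry)]
    else:
        cps = [ControlPoint(i, i / (n_cp - 1), jaws, mlc, gantry)
               for i in range(n_cp)]
    return Beam(cps, total_mu, modality, jaw_tracking)


@pytest.fixture
def static_10x10():
    return square_beam()
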