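"""Synthetic photon source standing in for a validated linac phase space.

Vendor-supplied phase spaces (e.g. for a 6 MV TrueBeam) are proprietary, so
the package ships a parameterized stand-in: photons emitted from a Gaussian
focal spot at the target plane (z = 0), directions uniform in solid angle
within a cone about +z, energies from a tabulated spectrum, transported in
vacuum to the PhspA scoring plane above the jaws.  The default spectrum is a
coarse 10-bin fixture with the qualitative shape of a 6 MV bremsstrahlung
beam; it is a test fixture, not fitted beam data.

Coordinate convention: beam axis +z, target at z = 0, isocenter at
z = SAD = 100 cm, all plane positions in cm from the target.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from .phasespace import KIND_PHOTON, PhaseSpaceStore

DEFAULT_Z_SCORE = 26.0  # cm, above the first jaw pair in the default geometry


def default_spectrum() -> np.ndarray:
    """The shipped 6 MV-like spectrum fixture as an (n, 2) array of
    (energy MeV, probability)."""
    with resources.files("fajtrace.data").joinpath("spectrum_6mv.csv").open() as f:
        return load_spectrum(f)


def load_spectrum(path_or_file) -> np.ndarray:
    arr = np.loadtxt(path_or_file, delimiter=",", comments="#")
    arr = np.atleast_2d(arr)
    if arr.shape[1] != 2:
        raise ValueError("spectrum CSV must have two columns: energy_MeV,probability")
    return arr


@dataclass
class SourceModel:
    """Parameterized point/Gaussian-focal-spot photon source.

    Parameters
    ----------
    focal_spot_sigma : cm
        Gaussian lateral spread of emission points at the target plane.
    spectrum : (n, 2) array
        (energy MeV, probability) bins; probabilities must sum to 1.
    cone_half_angle : radians
        Maximum polar angle of emission (uniform in solid angle within the
        cone).  The default covers a 40x40 cm field at isocenter.
    z_score : cm
        Scoring plane of the generated PhspA.
    """

    focal_spot_sigma: float = 0.1
    spectrum: np.ndarray = field(default_factory=default_spectrum)
    cone_half_angle: float = 0.29
    z_score: float = DEFAULT_Z_SCORE
    seed: int = 0

    def __post_init__(self):
        self.spectrum = np.asarray(self.spectrum, dtype=float)
        p = self.spectrum[:, 1]
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("spectrum probabilities must be >= 0 and sum to 1")
        if not (0 < self.cone_half_angle < np.pi / 2):
            raise ValueError("cone_half_angle must lie in (0, pi/2)")
        if self.focal_spot_sigma < 0:
            raise ValueError("focal_spot_sigma must be >= 0")


def generate_phspA(model: SourceModel, n: int) -> PhaseSpaceStore:
    """Generate ``n`` source photons scored at ``model.z_score``.

    Each photon is one primary history (weight 1, new_history True);
    ``n_original_histories`` equals ``n``.
    """
    if n <= 0:
        raise ValueError("n must be > 0")
    rng = np.random.default_rng(model.seed)
    x0 = rng.normal(0.0, model.focal_spot_sigma, n) if model.focal_spot_sigma else np.zeros(n)
    y0 = rng.normal(0.0, model.focal_spot_sigma, n) if model.focal_spot_sigma else np.zeros(n)
    # uniform in solid angle within the cone: cos(theta) ~ U[cos(theta_max), 1]
    cos_t = rng.uniform(np.cos(model.cone_half_angle), 1.0, n)
    sin_t = np.sqrt(1.0 - cos_t ** 2)
    phi = rng.uniform(0.0, 2 * np.pi, n)
    u = sin_t * np.cos(phi)
    v = sin_t * np.sin(phi)
    w = cos_t
    energies = model.spectrum[:, 0]
    probs = model.spectrum[:, 1]
    e = rng.choice(energies, size=n, p=probs / probs.sum())
    # vacuum transport from the target plane to the scoring plane
    t = model.z_score / w
    x = x0 + u * t
    y = y0 + v * t
    z = np.full(n, model.z_score)
    return PhaseSpaceStore(np.full(n, KIND_PHOTON, np.int8), e, x, y, z, u, v, w,
                           z_plane=model.z_score, n_original_histories=n)


def parallel_beam(n: int, half_width: float, energy: float = 1.0,
                  z_score: float = DEFAULT_Z_SCORE, seed: int = 0) -> PhaseSpaceStore:
    """A parallel beam: ``n`` photons uniformly distributed laterally within
    +/- ``half_width`` cm, all travelling along +z.  The extreme case where
    the choice of absorbing-plane depth within a jaw matters most."""
    if n <= 0 or half_width <= 0:
        raise ValueError("n and half_width must be > 0")
    rng = np.random.default_rng(seed)
    x = rng.uniform(-half_width, half_width, n)
    y = rng.uniform(-half_width, half_width, n)
    z = np.full(n, z_score)
    zero = np.zeros(n)
    return PhaseSpaceStore(np.full(n, KIND_PHOTON, np.int8), np.full(n, energy),
                           x, y, z, zero, zero, np.ones(n),
                           z_plane=z_score, n_original_histories=n)
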