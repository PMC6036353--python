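"""Voxel phantoms for the desk-scale dose engine.

The machine frame has the target at the origin, beam axis +z at gantry 0,
and the isocenter at z = SAD.  Phantoms are axis-aligned boxes of voxels in
the machine frame at gantry 0, laterally centered on the beam axis, with the
entrance surface placed at z = SSD.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

AIR_DENSITY = 0.0012  # g/cm^3


@dataclass
class VoxelPhantom:
    dims: tuple              # (nx, ny, nz) voxels
    voxel_size: tuple        # cm per axis
    origin: tuple            # cm, corner in machine frame at gantry 0
    density: np.ndarray      # g/cm^3, shape dims
    ssd: float = 90.0

    def __post_init__(self):
        self.density = np.asarray(self.density, dtype=np.float64)
        if self.density.shape != tuple(self.dims):
            raise ValueError("density shape does not match dims")
        if np.any(self.density < 0):
            raise ValueError("density must be >= 0")

    @property
    def extent(self) -> tuple:
        return tuple(o + n * s for o, n, s in
                     zip(self.origin, self.dims, self.voxel_size))

    def voxel_centers(self, axis: int) -> np.ndarray:
        return (self.origin[axis] +
                (np.arange(self.dims[axis]) + 0.5) * self.voxel_size[axis])

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.voxel_size))


def make_water_cube(n: int, voxel: float, ssd: float) -> VoxelPhantom:
    """Uniform water cube of ``n`` voxels per axis, ``voxel`` cm resolution,
    entrance surface at z = ssd, laterally centered on the beam axis."""
    if n < 1:
        raise ValueError("n must be >= 1")
    half = n * voxel / 2.0
    return VoxelPhantom((n, n, n), (float(voxel),) * 3,
                        (-half, -half, float(ssd)),
                        np.ones((n, n, n)), ssd=float(ssd))


def make_water_cylinder(diameter: float, length: float, voxel: float,
                        ssd: float | None = None) -> VoxelPhantom:
    """Water cylinder with its axis along the couch axis (y), air outside.

    The cylinder cross-section lies in the x-z plane; by default it is
    centered on the isocenter depth-wise (ssd = 100 - diameter/2)."""
    if diameter <= 0:
        raise ValueError("diameter must be > 0")
    r = diameter / 2.0
    if ssd is None:
        ssd = 100.0 - r
    nx = nz = int(np.ceil(diameter / voxel))
    ny = int(np.ceil(length / voxel))
    # grid centered on the cylinder axis (axis at depth z = ssd + r)
    ox, oy = -nx * voxel / 2.0, -ny * voxel / 2.0
    oz = ssd + r - nz * voxel / 2.0
    xc = ox + (np.arange(nx) + 0.5) * voxel
    zc = oz + (np.arange(nz) + 0.5) * voxel
    zc_rel = zc - (ssd + r)
    inside = (xc[:, None] ** 2 + zc_rel[None, :] ** 2) <= r ** 2
    density = np.where(inside[:, None, :], 1.0, AIR_DENSITY)
    density = np.broadcast_to(density, (nx, ny, nz)).copy()
    return VoxelPhantom((nx, ny, nz), (float(voxel),) * 3, (ox, oy, oz),
                        density, ssd=float(ssd))
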