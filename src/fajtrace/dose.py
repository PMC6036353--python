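"""Desk-scale kerma ray-trace dose engine.

A deliberately simple stand-in for a full Monte Carlo phantom code: photons
are ray-traced through the voxel grid with the exact incremental
grid-crossing walk, the energy fluence attenuates as ``exp(-mu * rho * l)``
along the radiological path, and each traversed voxel receives a
track-length kerma deposit ``weight * E * (mu_en/rho) * surviving_fraction *
dl / V``.  There is no electron transport and no scatter dose; charged
particles deposit their full energy in the entry voxel.  The engine's
accuracy envelope is therefore kerma-level — the package's claims concern
collimation, not transport.

Dose is normalized per primary-history-equivalent, and a per-voxel variance
is accumulated from per-particle deposits so that statistical uncertainty
can be reported and propagated.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
from numba import njit

from .phasespace import KIND_PHOTON, PhaseSpaceStore
from .phantom import VoxelPhantom


class AttenuationModel:
    """Log-log interpolated mass attenuation / energy-absorption tables
    (cm^2/g) over the beam's energy range."""

    def __init__(self, energy_mev, mu_over_rho, muen_over_rho):
        self.energy = np.asarray(energy_mev, dtype=float)
        self.mu = np.asarray(mu_over_rho, dtype=float)
        self.muen = np.asarray(muen_over_rho, dtype=float)
        if not np.all(np.diff(self.energy) > 0):
            raise ValueError("energies must ascend")

    def lookup(self, e):
        e = np.asarray(e, dtype=float)
        loge = np.log(e)
        mu = np.exp(np.interp(loge, np.log(self.energy), np.log(self.mu)))
        muen = np.exp(np.interp(loge, np.log(self.energy), np.log(self.muen)))
        return mu, muen


def water_attenuation() -> AttenuationModel:
    """The shipped coarse water attenuation fixture table."""
    with resources.files("fajtrace.data").joinpath("attenuation_water.csv").open() as f:
        arr = np.loadtxt(f, delimiter=",", comments="#")
    return AttenuationModel(arr[:, 0], arr[:, 1], arr[:, 2])


@dataclass
class DoseGrid:
    """Voxel dose per primary-history-equivalent with per-voxel variance."""
    dose: np.ndarray
    variance: np.ndarray
    n_histories_equivalent: float
    voxel_size: tuple
    origin: tuple

    def __post_init__(self):
        self.dose = np.asarray(self.dose, dtype=np.float64)
        self.variance = np.asarray(self.variance, dtype=np.float64)
        if self.dose.shape != self.variance.shape:
            raise ValueError("dose and variance shapes differ")

    @property
    def sigma(self) -> np.ndarray:
        return np.sqrt(self.variance)

    def rel_sigma(self, threshold_frac: float = 0.1) -> np.ndarray:
        """Relative sigma of voxels above ``threshold_frac`` of max dose."""
        mask = self.dose > threshold_frac * self.dose.max()
        return self.sigma[mask] / self.dose[mask]

    def save_text(self, path) -> None:
        """Plain 3D text dump (header + one voxel value per line)."""
        with open(path, "w") as f:
            f.write(f"# fajtrace dose grid {self.dose.shape} voxel_size="
                    f"{self.voxel_size} origin={self.origin} "
                    f"n_hist={self.n_histories_equivalent}\n")
            np.savetxt(f, np.c_[self.dose.ravel(), self.variance.ravel()],
                       fmt="%.10e")

    def save(self, path) -> None:
        np.savez(path, dose=self.dose, variance=self.variance,
                 n_histories_equivalent=self.n_histories_equivalent,
                 voxel_size=self.voxel_size, origin=self.origin)

    @classmethod
    def load(cls, path) -> "DoseGrid":
        d = np.load(path)
        return cls(d["dose"], d["variance"], float(d["n_histories_equivalent"]),
                   tuple(d["voxel_size"]), tuple(d["origin"]))


@njit(cache=False)
def _deposit_kernel(px, py, pz, dx, dy, dz, energy, weight, charged,
                    mu, muen, density, ox, oy, oz, vx, vy, vz, s1, s2):
    nx, ny, nz = density.shape
    n_miss = 0
    for p in range(px.size):
        # slab intersection with the phantom box
        tmin = -1e30
        tmax = 1e30
        pos = (px[p], py[p], pz[p])
        d = (dx[p], dy[p], dz[p])
        o = (ox, oy, oz)
        hi = (ox + nx * vx, oy + ny * vy, oz + nz * vz)
        miss = False
        for a in range(3):
            if d[a] == 0.0:
                if pos[a] <= o[a] or pos[a] >= hi[a]:
                    miss = True
                    break
            else:
                t0 = (o[a] - pos[a]) / d[a]
                t1 = (hi[a] - pos[a]) / d[a]
                if t0 > t1:
                    t0, t1 = t1, t0
                if t0 > tmin:
                    tmin = t0
                if t1 < tmax:
                    tmax = t1
        if miss or tmax <= tmin or tmax <= 0.0:
            n_miss += 1
            continue
        t = tmin if tmin > 0.0 else 0.0
        eps = 1e-9 * (vx + vy + vz)
        ex = px[p] + d[0] * (t + eps)
        ey = py[p] + d[1] * (t + eps)
        ez = pz[p] + d[2] * (t + eps)
        ix = int(np.floor((ex - ox) / vx))
        iy = int(np.floor((ey - oy) / vy))
        iz = int(np.floor((ez - oz) / vz))
        if ix < 0: ix = 0
        if iy < 0: iy = 0
        if iz < 0: iz = 0
        if ix > nx - 1: ix = nx - 1
        if iy > ny - 1: iy = ny - 1
        if iz > nz - 1: iz = nz - 1

        if charged[p]:
            if density[ix, iy, iz] > 0.0:
                dep = weight[p] * energy[p]
                s1[ix, iy, iz] += dep
                s2[ix, iy, iz] += dep * dep
            continue

        stepx = 1 if d[0] > 0 else -1
        stepy = 1 if d[1] > 0 else -1
        stepz = 1 if d[2] > 0 else -1
        big = 1e30
        tdx = vx / abs(d[0]) if d[0] != 0.0 else big
        tdy = vy / abs(d[1]) if d[1] != 0.0 else big
        tdz = vz / abs(d[2]) if d[2] != 0.0 else big
        # parametric distance to the next voxel face per axis
        if d[0] > 0:
            tnx = ((ix + 1) * vx + ox - px[p]) / d[0]
        elif d[0] < 0:
            tnx = (ix * vx + ox - px[p]) / d[0]
        else:
            tnx = big
        if d[1] > 0:
            tny = ((iy + 1) * vy + oy - py[p]) / d[1]
        elif d[1] < 0:
            tny = (iy * vy + oy - py[p]) / d[1]
        else:
            tny = big
        if d[2] > 0:
            tnz = ((iz + 1) * vz + oz - pz[p]) / d[2]
        elif d[2] < 0:
            tnz = (iz * vz + oz - pz[p]) / d[2]
        else:
            tnz = big

        tau = 0.0
        ke = weight[p] * energy[p] * muen[p]
        while t < tmax - 1e-12:
            tnext = tnx
            axis = 0
            if tny < tnext:
                tnext = tny
                axis = 1
            if tnz < tnext:
                tnext = tnz
                axis = 2
            if tnext > tmax:
                tnext = tmax
            dl = tnext - t
            if dl > 0.0:
                rho = density[ix, iy, iz]
                if rho > 0.0:  # no medium, no kerma
                    dtau = mu[p] * rho * dl
                    dep = ke * np.exp(-(tau + 0.5 * dtau)) * dl
                    s1[ix, iy, iz] += dep
                    s2[ix, iy, iz] += dep * dep
                    tau += dtau
            t = tnext
            if axis == 0:
                ix += stepx
                tnx += tdx
                if ix < 0 or ix >= nx:
                    break
            elif axis == 1:
                iy += stepy
                tny += tdy
                if iy < 0 or iy >= ny:
                    break
            else:
                iz += stepz
                tnz += tdz
                if iz < 0 or iz >= nz:
                    break
    return n_miss


def _rotate_gantry(x, y, z, u, v, w, gantry_deg, sad):
    """Map particle coordinates at gantry angle g into the fixed phantom
    frame (rotation about the couch axis y through the isocenter)."""
    g = np.deg2rad(gantry_deg)
    c, s = np.cos(g), np.sin(g)
    zr = z - sad
    xn = c * x + s * zr
    zn = -s * x + c * zr + sad
    un = c * u + s * w
    wn = -s * u + c * w
    return xn, y, zn, un, v, wn


def deposit(phsp: PhaseSpaceStore, phantom: VoxelPhantom,
            attenuation: AttenuationModel | None = None,
            gantry_deg: float | None = None, sad: float = 100.0,
            n_histories_equivalent: float | None = None) -> DoseGrid:
    """Deposit a phase space into a phantom and return the normalized dose.

    ``gantry_deg`` overrides any per-particle gantry annotation on the
    store; when both are absent, gantry 0 is assumed.  The normalization
    denominator defaults to the store's ``n_original_histories`` (the
    recycling-aware history-equivalent count set by the collimator).
    """
    if attenuation is None:
        attenuation = water_attenuation()
    n = len(phsp)
    x, y, z = phsp.x, phsp.y, phsp.z
    u, v, w = phsp.u, phsp.v, phsp.w
    if gantry_deg is not None:
        gd = np.full(n, float(gantry_deg))
    elif phsp.gantry is not None:
        gd = phsp.gantry
    else:
        gd = None
    if gd is not None and np.any(gd != 0.0):
        x, y, z, u, v, w = _rotate_gantry(x, y, z, u, v, w, gd, sad)

    mu, muen = attenuation.lookup(phsp.energy)
    charged = phsp.kind != KIND_PHOTON
    s1 = np.zeros(phantom.dims)
    s2 = np.zeros(phantom.dims)
    _deposit_kernel(np.ascontiguousarray(x), np.ascontiguousarray(y),
                    np.ascontiguousarray(z), np.ascontiguousarray(u),
                    np.ascontiguousarray(v), np.ascontiguousarray(w),
                    phsp.energy, phsp.weight, charged, mu, muen,
                    phantom.density,
                    *(float(o) for o in phantom.origin),
                    *(float(v) for v in phantom.voxel_size),
                    s1, s2)
    nh = float(n_histories_equivalent if n_histories_equivalent is not None
               else phsp.n_original_histories)
    vol = phantom.voxel_volume
    dose = s1 / (vol * nh)
    if nh > 1:
        var = (s2 - s1 ** 2 / nh) / (vol ** 2 * nh * (nh - 1.0))
        var = np.clip(var, 0.0, None)
    else:
        var = np.zeros_like(dose)
    return DoseGrid(dose, var, nh, phantom.voxel_size, phantom.origin)


def sum_dose(grids, weights=None) -> DoseGrid:
    """Weighted voxelwise sum of dose grids; variances combine assuming
    independence (sigma adds in quadrature)."""
    if not grids:
        raise ValueError("no grids to sum")
    if weights is None:
        weights = [1.0] * len(grids)
    shape = grids[0].dose.shape
    for g in grids:
        if g.dose.shape != shape:
            raise ValueError("dose grid shape mismatch")
    dose = sum(wt * g.dose for wt, g in zip(weights, grids))
    var = sum(wt ** 2 * g.variance for wt, g in zip(weights, grids))
    return DoseGrid(dose, var, grids[0].n_histories_equivalent,
                    grids[0].voxel_size, grids[0].origin)


def estimate_required_histories(pilot: DoseGrid, target_rel_sigma: float,
                                threshold_frac: float = 0.1) -> int:
    """Histories needed so the median relative sigma of voxels above
    ``threshold_frac`` of the maximum dose reaches ``target_rel_sigma``,
    by inverse-square scaling of the pilot run."""
    if pilot.dose.max() <= 0:
        raise ValueError("pilot dose grid is all zero")
    med = float(np.median(pilot.rel_sigma(threshold_frac)))
    return int(np.ceil(pilot.n_histories_equivalent * (med / target_rel_sigma) ** 2))
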