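"""Closed-form fluence/kerma oracles for validating the collimator + engine.

For a point source at the target with directions uniform in solid angle
within a cone, the expected kerma at a point in a uniform water phantom is

    D(r) = sum_E p_E * E * (mu_en/rho)(E) * exp(-mu_E * t(r)) / (Omega * r^2)

inside the aperture projection and zero outside, where ``t`` is the depth
from the phantom entry point along the ray and ``Omega`` the emission cone's
solid angle.  This is exactly what the track-length kerma estimator in
:mod:`fajtrace.dose` converges to, so the two routes (Monte Carlo collimation
+ deposition vs direct integration through the same apertures) can be
compared with the gamma machinery without sharing any code path.
"""

from __future__ import annotations

import numpy as np

from .collimate import CollimatorGeometry, StaticAperture
from .dose import AttenuationModel, DoseGrid, water_attenuation
from .phantom import VoxelPhantom
from .source import SourceModel


def _ray_passes(cx, cy, cz, geom: CollimatorGeometry, aperture: StaticAperture):
    """Vectorized pass test for rays from the origin through points (c)."""
    ok = cz > 0
    x1, x2, y1, y2 = aperture.jaws
    for pair in geom.jaw_pairs:
        s = pair.z_top / geom.sad
        if pair.axis == "X":
            coord = np.where(ok, cx / np.where(ok, cz, 1.0), 0.0) * pair.z_top
            ok &= (coord > x1 * s) & (coord < x2 * s)
        else:
            coord = np.where(ok, cy / np.where(ok, cz, 1.0), 0.0) * pair.z_top
            ok &= (coord > y1 * s) & (coord < y2 * s)
    if aperture.mlc is not None:
        bnd, a, b = (np.asarray(m, dtype=float) for m in aperture.mlc)
        s = geom.mlc_plane_z / geom.sad
        xm = np.where(ok, cx / np.where(ok, cz, 1.0), 0.0) * geom.mlc_plane_z
        ym = np.where(ok, cy / np.where(ok, cz, 1.0), 0.0) * geom.mlc_plane_z
        leaf = np.searchsorted(bnd * s, ym, side="right") - 1
        in_span = (leaf >= 0) & (leaf < a.size)
        leaf_c = np.clip(leaf, 0, a.size - 1)
        ok &= in_span & (xm > a[leaf_c] * s) & (xm < b[leaf_c] * s)
    return ok


def analytic_open_field_dose(model: SourceModel, geom: CollimatorGeometry,
                             aperture: StaticAperture, phantom: VoxelPhantom,
                             attenuation: AttenuationModel | None = None,
                             supersample: int = 3) -> DoseGrid:
    """Direct integration of the point-source kerma through the aperture
    into a uniform water phantom (the independent oracle for the end-to-end
    open-field comparison).  The focal spot is treated as a point.

    The Monte Carlo estimator measures the *voxel-averaged* dose, so the
    oracle averages too.  For jaws-only apertures the admitted rays form an
    exact rectangle at every depth plane (the isocenter projection scaled by
    z/SAD), so the voxel coverage fraction is computed analytically from
    rectangle overlaps — edge voxels get their exact partial coverage — and
    only the smooth 1/r^2-attenuation field is midpoint-sampled.  With an
    MLC aperture the oracle falls back to a ``supersample``-per-axis
    midpoint grid over the full integrand.
    """
    if attenuation is None:
        attenuation = water_attenuation()
    if not np.allclose(phantom.density, 1.0):
        raise ValueError("the analytic oracle supports uniform water phantoms")
    if aperture.mlc is None:
        return _open_field_exact_coverage(model, geom, aperture, phantom,
                                          attenuation, max(supersample, 3))
    mu, muen = attenuation.lookup(model.spectrum[:, 0])
    probs = model.spectrum[:, 1]
    omega = 2.0 * np.pi * (1.0 - np.cos(model.cone_half_angle))
    ns = int(supersample)
    sub = (np.arange(ns) + 0.5) / ns - 0.5  # offsets in voxel units

    dose = np.zeros(phantom.dims)
    for ox in sub:
        for oy in sub:
            for oz in sub:
                xc = phantom.voxel_centers(0) + ox * phantom.voxel_size[0]
                yc = phantom.voxel_centers(1) + oy * phantom.voxel_size[1]
                zc = phantom.voxel_centers(2) + oz * phantom.voxel_size[2]
                cx, cy, cz = np.meshgrid(xc, yc, zc, indexing="ij")
                r = np.sqrt(cx ** 2 + cy ** 2 + cz ** 2)
                in_cone = cz / r >= np.cos(model.cone_half_angle)
                ok = in_cone & _ray_passes(cx, cy, cz, geom, aperture)
                # distance along the ray to the phantom entrance (z = ssd face)
                t_entry = r * (phantom.origin[2] / cz)
                depth = np.clip(r - t_entry, 0.0, None)
                acc = np.zeros(phantom.dims)
                for e, p, m, men in zip(model.spectrum[:, 0], probs, mu, muen):
                    acc += p * e * men * np.exp(-m * depth)
                dose += np.where(ok, acc / (omega * r ** 2), 0.0)
    dose /= ns ** 3
    return DoseGrid(dose, np.zeros_like(dose), 1.0,
                    phantom.voxel_size, phantom.origin)


def _open_field_exact_coverage(model, geom, aperture, phantom, attenuation,
                               nz: int) -> DoseGrid:
    """Jaws-only oracle: exact per-voxel lateral coverage fractions times a
    midpoint-sampled smooth field, averaged over ``nz`` depth sub-planes."""
    x1, x2, y1, y2 = aperture.jaws
    mu, muen = attenuation.lookup(model.spectrum[:, 0])
    probs = model.spectrum[:, 1]
    omega = 2.0 * np.pi * (1.0 - np.cos(model.cone_half_angle))
    vx, vy, vz = phantom.voxel_size
    xc = phantom.voxel_centers(0)
    yc = phantom.voxel_centers(1)
    sub = (np.arange(nz) + 0.5) / nz - 0.5

    def overlap(centers, width, lo, hi):
        a = np.maximum(centers - width / 2.0, lo)
        b = np.minimum(centers + width / 2.0, hi)
        return np.clip(b - a, 0.0, None) / width

    dose = np.zeros(phantom.dims)
    tan_cone = np.tan(model.cone_half_angle)
    for oz in sub:
        zc = phantom.voxel_centers(2) + oz * vz
        for k, z in enumerate(zc):
            s = z / geom.sad
            fx = overlap(xc, vx, x1 * s, x2 * s)
            fy = overlap(yc, vy, y1 * s, y2 * s)
            # smooth field at the clamped-to-aperture lateral position
            xs = np.clip(xc, x1 * s, x2 * s)
            ys = np.clip(yc, y1 * s, y2 * s)
            r2 = xs[:, None] ** 2 + ys[None, :] ** 2 + z ** 2
            r = np.sqrt(r2)
            depth = np.clip(r - r * (phantom.origin[2] / z), 0.0, None)
            acc = np.zeros_like(r)
            for e, p, m, men in zip(model.spectrum[:, 0], probs, mu, muen):
                acc += p * e * men * np.exp(-m * depth)
            in_cone = np.sqrt(xs[:, None] ** 2 + ys[None, :] ** 2) <= z * tan_cone
            dose[:, :, k] += np.where(in_cone,
                                      fx[:, None] * fy[None, :] * acc / (omega * r2),
                                      0.0)
    dose /= nz
    return DoseGrid(dose, np.zeros_like(dose), 1.0,
                    phantom.voxel_size, phantom.origin)


def aperture_pass_fraction(geom: CollimatorGeometry, aperture: StaticAperture,
                           cone_half_angle: float, n_theta: int = 400,
                           n_phi: int = 800) -> float:
    """Fraction of the emission cone's solid angle admitted by the aperture
    (point source), by midpoint quadrature uniform in (cos theta, phi)."""
    cos_min = np.cos(cone_half_angle)
    ct = cos_min + (np.arange(n_theta) + 0.5) / n_theta * (1.0 - cos_min)
    ph = (np.arange(n_phi) + 0.5) / n_phi * 2.0 * np.pi
    ctg, phg = np.meshgrid(ct, ph, indexing="ij")
    st = np.sqrt(1.0 - ctg ** 2)
    ok = _ray_passes(st * np.cos(phg), st * np.sin(phg), ctg, geom, aperture)
    return float(np.mean(ok))
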