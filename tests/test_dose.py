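"""Kerma ray-trace engine: traversal, attenuation, normalization algebra."""

import numpy as np
import pytest

from fajtrace import (AttenuationModel, DoseGrid, PhaseSpaceStore,
                      deposit, estimate_required_histories, make_water_cube,
                      make_water_cylinder, parallel_beam, sum_dose,
                      water_attenuation)


def _single_ray(x=0.0, y=0.0, u=0.0, v=0.0, w=1.0, e=1.0):
    n = np.sqrt(u * u + v * v + w * w)
    return PhaseSpaceStore([1], [e], [x], [y], [26.0], [u / n], [v / n], [w / n],
                           z_plane=26.0, n_original_histories=1)


def _no_attenuation():
    # mu ~ 0: deposits become pure track-length x muen
    e = np.array([0.01, 10.0])
    return AttenuationModel(e, np.full(2, 1e-12), np.ones(2))


# ---------------------------------------------------------------- phantoms

def test_water_cube_dimensions():
    ph = make_water_cube(82, 0.5, 90.0)
    assert ph.dims == (82, 82, 82)
    assert ph.origin[2] == 90.0
    assert np.all(ph.density == 1.0)
    assert ph.extent[0] == pytest.approx(-20.5 + 41.0)
    assert make_water_cube(1, 0.5, 90.0).dims == (1, 1, 1)


def test_water_cylinder_mask():
    ph = make_water_cylinder(20.4, 10.0, 0.25)
    water = ph.density > 0.5
    # in-cylinder voxel count close to pi r^2 l / v^3, within one shell
    expect = np.pi * 10.2 ** 2 * 10.0 / 0.25 ** 3
    shell = 2 * np.pi * 10.2 * 10.0 / 0.25 ** 2  # one voxel-thick shell
    assert abs(water.sum() - expect) < shell
    # voxel centers beyond the radius are air
    xc = ph.voxel_centers(0)
    zc = ph.voxel_centers(2) - (ph.ssd + 10.2)
    r = np.sqrt(xc[:, None] ** 2 + zc[None, :] ** 2)
    assert np.all(ph.density[:, 0, :][r > 10.2] < 0.01)
    # reflection symmetry through the axis
    np.testing.assert_array_equal(water, water[::-1, :, :])
    np.testing.assert_array_equal(water, water[:, :, ::-1])


# ---------------------------------------------------------------- deposit

def test_zero_density_deposits_nothing():
    ph = make_water_cube(5, 1.0, 90.0)
    ph.density[:] = 0.0
    d = deposit(_single_ray(), ph, water_attenuation())
    assert d.dose.max() == 0.0


def test_radiological_path_closed_form():
    """With mu -> 0 the voxel-summed deposit equals E * muen * path length:
    an axial ray through the cube recovers the geometric column length."""
    ph = make_water_cube(11, 0.5, 90.0)
    d = deposit(_single_ray(), ph, _no_attenuation())
    total = d.dose.sum() * ph.voxel_volume  # back to summed track length
    assert total == pytest.approx(11 * 0.5, rel=1e-9)
    # slightly oblique ray staying inside: path = depth / cos(theta)
    d2 = deposit(_single_ray(x=-0.1, u=0.002, w=1.0), ph, _no_attenuation())
    cos_t = 1.0 / np.sqrt(1.0 + 0.002 ** 2)
    assert d2.dose.sum() * ph.voxel_volume == pytest.approx(5.5 / cos_t, rel=1e-9)


def test_exponential_depth_curve():
    """A single axial monoenergetic ray: successive voxel deposits fall by
    exactly exp(-mu rho dz) (midpoint attenuation, uniform water)."""
    att = water_attenuation()
    mu, _ = att.lookup(np.array([2.0]))
    ph = make_water_cube(9, 1.0, 90.0)
    d = deposit(_single_ray(e=2.0), ph, att)
    col = d.dose[4, 4, :]
    ratios = col[1:] / col[:-1]
    np.testing.assert_allclose(ratios, np.exp(-mu[0]), rtol=5e-3)


def test_charged_particle_deposits_in_entry_voxel():
    s = PhaseSpaceStore([2], [3.0], [0.0], [0.0], [26.0], [0.0], [0.0], [1.0],
                        z_plane=26.0, n_original_histories=1)
    ph = make_water_cube(5, 1.0, 90.0)
    d = deposit(s, ph, water_attenuation())
    nz = np.nonzero(d.dose)
    assert len(nz[0]) == 1
    assert nz[2][0] == 0  # entry voxel
    assert d.dose[nz][0] == pytest.approx(3.0 / ph.voxel_volume)


def test_gantry_180_mirrors_dose():
    ph = make_water_cube(11, 1.0, 100.0 - 5.5)  # centered on the isocenter
    att = water_attenuation()
    s = _single_ray(u=0.01)
    d0 = deposit(s, ph, att, gantry_deg=0.0)
    d180 = deposit(s, ph, att, gantry_deg=180.0)
    np.testing.assert_allclose(d180.dose, d0.dose[::-1, :, ::-1], rtol=1e-9,
                               atol=d0.dose.max() * 1e-9)


def test_energy_bookkeeping():
    beam = parallel_beam(5000, half_width=2.0, energy=2.0, seed=3)
    ph = make_water_cube(9, 0.5, 90.0)
    d = deposit(beam, ph, water_attenuation(), n_histories_equivalent=1.0)
    att = water_attenuation()
    _, muen = att.lookup(np.array([2.0]))
    deposited = d.dose.sum() * ph.voxel_volume
    incident = 2.0 * 5000  # total energy times weight entering
    # kerma deposits are bounded by muen-weighted incident fluence
    assert deposited <= incident * muen[0] * 9 * 0.5


# ---------------------------------------------------------------- algebra

def test_sum_dose_variance_algebra():
    d = DoseGrid(np.ones((2, 2, 2)), np.full((2, 2, 2), 0.04), 10,
                 (1, 1, 1), (0, 0, 0))
    s = sum_dose([d, d], [1.0, 1.0])
    np.testing.assert_allclose(s.dose, 2.0)
    np.testing.assert_allclose(np.sqrt(s.variance), 0.2 * np.sqrt(2))
    s0 = sum_dose([d, d], [1.0, 0.0])
    np.testing.assert_allclose(s0.dose, d.dose)
    other = DoseGrid(np.ones((3, 2, 2)), np.zeros((3, 2, 2)), 1, (1, 1, 1), (0, 0, 0))
    with pytest.raises(ValueError, match="mismatch"):
        sum_dose([d, other])


def test_deposit_linearity_under_partition(point_source_store):
    """Splitting the particle set in four and summing the four grids equals
    depositing the whole set (all normalized to the same denominator)."""
    s = point_source_store.select(np.arange(20_000))
    ph = make_water_cube(11, 1.0, 90.0)
    att = water_attenuation()
    whole = deposit(s, ph, att, n_histories_equivalent=20_000)
    parts = [deposit(s.select(np.arange(i * 5000, (i + 1) * 5000)), ph, att,
                     n_histories_equivalent=20_000) for i in range(4)]
    summed = sum_dose(parts, [1.0] * 4)
    np.testing.assert_allclose(summed.dose, whole.dose, rtol=1e-12,
                               atol=whole.dose.max() * 1e-14)


def test_estimate_required_histories_scaling():
    dose = np.full((3, 3, 3), 1.0)
    var = np.full((3, 3, 3), 0.04 ** 2)  # rel sigma 4%
    pilot = DoseGrid(dose, var, 10_000, (1, 1, 1), (0, 0, 0))
    assert estimate_required_histories(pilot, 0.01) == 160_000
    assert estimate_required_histories(pilot, 0.04) == 10_000
    empty = DoseGrid(np.zeros((2, 2, 2)), np.zeros((2, 2, 2)), 10, (1, 1, 1),
                     (0, 0, 0))
    with pytest.raises(ValueError):
        estimate_required_histories(empty, 0.01)


def test_required_histories_rerun_achieves_target(point_source_store, geom):
    """The recommended N, re-simulated, lands within 1.1x of the target
    median uncertainty."""
    from fajtrace import (CollimationConfig, CyclicReader, StaticAperture,
                          collimate_static)
    ph = make_water_cube(21, 1.0, 90.0)
    att = water_attenuation()
    ap = StaticAperture((-5, 5, -5, 5))
    cfg = CollimationConfig(n_requested=20_000, n_recycle=20, seed=3)
    pilot_phsp, _ = collimate_static(CyclicReader(point_source_store, 4),
                                     geom, cfg, ap)
    pilot = deposit(pilot_phsp, ph, att)
    target = np.median(pilot.rel_sigma(0.1)) / 2.0
    n = estimate_required_histories(pilot, target)
    scale = n / pilot.n_histories_equivalent
    cfg2 = CollimationConfig(n_requested=int(20_000 * scale), n_recycle=20, seed=5)
    phsp2, _ = collimate_static(CyclicReader(point_source_store, 6), geom,
                                cfg2, ap)
    d2 = deposit(phsp2, ph, att)
    assert np.median(d2.rel_sigma(0.1)) <= 1.1 * target
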