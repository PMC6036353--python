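"""FAJT collimator: APR, projection, jaw/MLC transmission, exact-count
contracts, jaw-tracking synchronization."""

import numpy as np
import pytest

from fajtrace import (Beam, CollimationConfig, ControlPoint, CyclicReader,
                      JawPair, Particle, StaticAperture, apr_rotate,
                      collimate_dynamic, collimate_static, jaw_transmit,
                      mlc_transmit, parallel_beam, project_to_plane)
from fajtrace.analytic import aperture_pass_fraction
from fajtrace.collimate import CollimatorGeometry
from fajtrace.phasespace import fluence_map
from conftest import square_beam


def _photon(x=0.0, y=0.0, z=0.0, u=0.0, v=0.0, w=1.0, e=6.0, wt=1.0):
    n = np.sqrt(u * u + v * v + w * w)
    return Particle(1, e, x, y, z, u / n, v / n, w / n, wt)


# ---------------------------------------------------------------- APR

def test_apr_identity_and_quarter_turn():
    p = _photon(x=3.0, y=4.0, u=0.0998, v=0.0, w=0.995)
    assert apr_rotate(p, 0.0) == p
    q = apr_rotate(p, np.pi / 2)
    assert (q.x, q.y) == pytest.approx((-4.0, 3.0))
    assert (q.u, q.v) == pytest.approx((0.0, p.u), abs=1e-12)
    assert np.hypot(q.x, q.y) == pytest.approx(5.0)
    assert q.u ** 2 + q.v ** 2 == pytest.approx(p.u ** 2 + p.v ** 2)
    assert (q.w, q.energy, q.weight) == (p.w, p.energy, p.weight)


def test_apr_azimuth_uniform_radius_preserved():
    from scipy import stats
    rng = np.random.default_rng(12)
    p = _photon(x=2.0, y=1.0, u=0.05, v=-0.02, w=0.998)
    phis = rng.uniform(0, 2 * np.pi, 100_000)
    c, s = np.cos(phis), np.sin(phis)
    xs, ys = c * p.x - s * p.y, s * p.x + c * p.y
    np.testing.assert_allclose(np.hypot(xs, ys), np.hypot(p.x, p.y), atol=1e-12)
    az = np.mod(np.arctan2(ys, xs), 2 * np.pi)
    assert stats.kstest(az, stats.uniform(0, 2 * np.pi).cdf).pvalue > 0.01


# ---------------------------------------------------------------- projection

def test_projection_similar_triangles_and_associativity():
    assert project_to_plane(_photon(x=1.5, z=26.0), 80.0).x == 1.5
    p = _photon(u=0.05, w=1.0)  # u/w = 0.05 after normalization keeps ratio
    assert project_to_plane(p, 100.0).x == pytest.approx(5.0)
    q1 = project_to_plane(project_to_plane(p, 28.0), 100.0)
    q2 = project_to_plane(p, 100.0)
    assert q1.x == pytest.approx(q2.x, abs=1e-12)
    with pytest.raises(ValueError):
        project_to_plane(_photon(w=-1.0), 10.0)


# ---------------------------------------------------------------- jaws

def test_jaw_transmit_hand_computed_edge():
    """10x10 at iso, plane at 28 cm: physical half-opening 1.4 cm."""
    pair = JawPair("X", 28.0, -5.0, 5.0)
    assert jaw_transmit(_photon(u=0.049), pair) == "pass"
    assert jaw_transmit(_photon(u=0.051), pair) == "absorb"
    # exactly on the edge is absorbed (closed-jaw tie-break); built with
    # exactly-representable arithmetic: 0.125 * 25 = 12.5 * 25/100 = 3.125
    tie = Particle(1, 6.0, 0.0, 0.0, 0.0, 0.125, 0.0, 1.0, 1.0)
    assert jaw_transmit(tie, JawPair("X", 25.0, -12.5, 12.5)) == "absorb"


def test_jaw_open_edges_pass_everything():
    pair = JawPair("Y", 28.0, -1e9, 1e9)
    rng = np.random.default_rng(0)
    for _ in range(50):
        u, v = rng.uniform(-0.2, 0.2, 2)
        assert jaw_transmit(_photon(u=u, v=v, w=1.0), pair) == "pass"


def test_jaw_parallel_beam_counting_oracle():
    """Parallel beam, half-width 3, physical opening +/-1.4 at the plane:
    exactly the rays within +/-1.4 cm pass."""
    pair = JawPair("X", 28.0, -5.0, 5.0)  # 1.4 cm physical at 28
    xs = np.linspace(-2.99, 2.99, 200)
    passed = sum(jaw_transmit(_photon(x=x, z=26.0), pair) == "pass" for x in xs)
    assert passed == np.count_nonzero(np.abs(xs) < 1.4)


# ---------------------------------------------------------------- MLC

def test_mlc_zero_transmission_is_absorbing_aperture():
    bnd, a, b = [-1.0, 1.0], [-2.0], [2.0]
    status, q = mlc_transmit(_photon(u=0.005), 50.0, bnd, a, b)
    assert status == "pass" and q.weight == 1.0
    status, q = mlc_transmit(_photon(u=0.05), 50.0, bnd, a, b)
    assert status == "absorb" and q is None


def test_mlc_transmission_scales_weight_only():
    bnd, a, b = [-1.0, 1.0], [-2.0], [2.0]
    p = _photon(u=0.05)
    status, q = mlc_transmit(p, 50.0, bnd, a, b, transmission=0.015)
    assert status == "pass_attenuated"
    assert q.weight == pytest.approx(0.015)
    assert (q.u, q.v, q.w) == (p.u, p.v, p.w)


def test_mlc_gap_profile_counting_oracle():
    """Uniform fan across a 2 cm gap: in-gap level 1, under-leaf level =
    transmission, transition at the projected tip +/- tip_offset."""
    bnd, a, b = [-10.0, 10.0], [-1.0], [1.0]  # 2 cm gap at isocenter
    scale = 0.5  # mlc plane 50 / sad 100
    tip = 0.1
    xs = np.linspace(-2.0, 2.0, 801)  # positions at the MLC plane
    got = []
    for x in xs:
        p = _photon(x=x, z=50.0)  # already on the plane
        status, q = mlc_transmit(p, 50.0, bnd, a, b, transmission=0.1,
                                 tip_offset=tip)
        got.append(q.weight if q is not None else 0.0)
    got = np.array(got)
    lo, hi = a[0] * scale - tip, b[0] * scale + tip
    expect = np.where((xs > lo) & (xs < hi), 1.0, 0.1)
    np.testing.assert_array_equal(got, expect)


# ---------------------------------------------------------------- static

def test_wide_open_counting_no_rejection(point_source_store):
    cfg = CollimationConfig(n_requested=1000, n_recycle=20, seed=1)
    reader = CyclicReader(point_source_store, 2, r_max=np.inf)
    geom = CollimatorGeometry([JawPair("Y", 28.0), JawPair("X", 36.0)],
                              50.0, 100.0, 55.0)
    phspB, rep = collimate_static(reader, geom, cfg,
                                  StaticAperture((-1e3, 1e3, -1e3, 1e3)))
    assert len(phspB) == 1000
    assert rep.n_read == 50  # ceil(1000 / 20): every particle passes
    assert rep.n_absorbed_jaws == 0
    rep.check()


def test_exact_count_contract_random_apertures(point_source_store, geom):
    rng = np.random.default_rng(5)
    for i in range(10):
        x1, y1 = -rng.uniform(0.5, 6, 2)
        x2, y2 = rng.uniform(0.5, 6, 2)
        cfg = CollimationConfig(n_requested=int(rng.integers(100, 3000)),
                                n_recycle=20, seed=i)
        reader = CyclicReader(point_source_store, i)
        phspB, rep = collimate_static(reader, geom, cfg,
                                      StaticAperture((x1, x2, y1, y2)))
        assert len(phspB) == cfg.n_requested
        assert rep.n_scored == cfg.n_requested
        rep.check()


def test_collimation_determinism(point_source_store, geom):
    out = []
    for _ in range(2):
        cfg = CollimationConfig(n_requested=5000, n_recycle=20, seed=11)
        reader = CyclicReader(point_source_store, 17)
        phspB, rep = collimate_static(reader, geom, cfg,
                                      StaticAperture((-4, 4, -4, 4)))
        out.append((phspB, rep))
    a, b = out
    np.testing.assert_array_equal(a[0].x, b[0].x)
    np.testing.assert_array_equal(a[0].energy, b[0].energy)
    assert a[1] == b[1]


def test_scored_fraction_matches_solid_angle_oracle(geom):
    """Point source, 10x10: the fraction of examined copies scored equals
    the aperture's share of the emission cone's solid angle (computed by an
    independent direction-grid quadrature)."""
    from fajtrace import SourceModel, generate_phspA
    model = SourceModel(seed=31, focal_spot_sigma=0.0, cone_half_angle=0.1)
    store = generate_phspA(model, 300_000)
    ap = StaticAperture((-5, 5, -5, 5))
    # n_recycle=1: copies are then independent draws from the cone
    cfg = CollimationConfig(n_requested=50_000, n_recycle=1, seed=3)
    reader = CyclicReader(store, 4, r_max=np.inf)
    phspB, rep = collimate_static(reader, geom, cfg, ap)
    p = aperture_pass_fraction(geom, ap, 0.1, n_theta=1200, n_phi=2400)
    n = rep.n_examined
    sigma = np.sqrt(n * p * (1 - p))
    assert abs(rep.n_scored - n * p) < 4 * sigma


def test_top_surface_vs_midplane_semantics():
    """With a parallel beam the absorbing-plane depth changes the passing
    set: the physical opening scales with the plane height."""
    beam = parallel_beam(20_000, half_width=3.0, z_score=26.0, seed=2)
    ap = StaticAperture((-5, 5, -5, 5))
    passed = {}
    for z_top in (28.0, 33.0):  # top surface vs a mid-plane variant
        geom = CollimatorGeometry([JawPair("Y", z_top), JawPair("X", z_top + 3)],
                                  50.0, 100.0, 55.0)
        cfg = CollimationConfig(n_requested=100, n_recycle=1, seed=1)
        reader = CyclicReader(beam, 3, r_max=np.inf)
        _, rep = collimate_static(reader, geom, cfg, ap)
        passed[z_top] = rep.n_scored / rep.n_examined
    # opening at 28 cm is 1.4 cm; at 33 cm it is 1.65 cm
    assert passed[33.0] > passed[28.0] * 1.2


# ---------------------------------------------------------------- dynamic

def _two_segment_plan(jaw_tracking):
    cps = [ControlPoint(0, 0.0, (-2, 2, -2, 2)),
           ControlPoint(1, 0.5, (-2, 2, -2, 2)),
           ControlPoint(2, 0.5, (-5, 5, -5, 5)),
           ControlPoint(3, 1.0, (-5, 5, -5, 5))]
    return Beam(cps, 100.0, "imrt_dynamic", jaw_tracking)


def test_two_aperture_mixture_fluence(point_source_store, geom):
    """Half the MU in a 4x4, half in a 10x10: the 4x4 core collects both
    segments while the annulus collects only the second, so the expected
    annulus/core fluence-density ratio is 0.5."""
    cfg = CollimationConfig(n_requested=400_000, n_recycle=20, seed=31)
    phspB, _ = collimate_dynamic(CyclicReader(point_source_store, 32), geom,
                                 cfg, _two_segment_plan(jaw_tracking=True))
    h, xe, _ = fluence_map(phspB, 5.5, 22, z_plane=100.0)  # 0.5 cm bins
    centers = (xe[:-1] + xe[1:]) / 2
    cx, cy = np.meshgrid(centers, centers, indexing="ij")
    core = (np.abs(cx) < 1.5) & (np.abs(cy) < 1.5)
    annulus = (np.abs(cx) < 4.5) & (np.abs(cy) < 4.5) & \
              ((np.abs(cx) > 2.5) | (np.abs(cy) > 2.5))
    core_n, ann_n = h[core].sum(), h[annulus].sum()
    core_density = core_n / core.sum()
    ann_density = ann_n / annulus.sum()
    ratio = ann_density / core_density
    # 4 sigma on the ratio via Poisson counts
    sigma = ratio * np.sqrt(1 / core_n + 1 / ann_n)
    assert abs(ratio - 0.5) < 4 * sigma + 0.02


def test_mixture_without_jaw_tracking_raises_annulus(point_source_store, geom):
    """Jaws parked at the maximum opening: the annulus now sees both
    segments (no MLC in this plan), so the ratio climbs to ~1."""
    cfg = CollimationConfig(n_requested=400_000, n_recycle=20, seed=41)
    phspB, _ = collimate_dynamic(CyclicReader(point_source_store, 42), geom,
                                 cfg, _two_segment_plan(jaw_tracking=False))
    h, xe, _ = fluence_map(phspB, 5.5, 22, z_plane=100.0)
    centers = (xe[:-1] + xe[1:]) / 2
    cx, cy = np.meshgrid(centers, centers, indexing="ij")
    core = (np.abs(cx) < 1.5) & (np.abs(cy) < 1.5)
    annulus = (np.abs(cx) < 4.5) & (np.abs(cy) < 4.5) & \
              ((np.abs(cx) > 2.5) | (np.abs(cy) > 2.5))
    ratio = (h[annulus].sum() / annulus.sum()) / (h[core].sum() / core.sum())
    assert ratio > 0.9


def test_dynamic_scored_particles_carry_gantry(point_source_store, geom):
    cps = [ControlPoint(0, 0.0, (-4, 4, -4, 4), None, 0.0),
           ControlPoint(1, 1.0, (-4, 4, -4, 4), None, 90.0)]
    beam = Beam(cps, 10.0, "vmat_arc")
    cfg = CollimationConfig(n_requested=2000, n_recycle=20, seed=5)
    phspB, _ = collimate_dynamic(CyclicReader(point_source_store, 6), geom,
                                 cfg, beam)
    assert phspB.gantry is not None
    assert phspB.gantry.min() >= 0.0 and phspB.gantry.max() <= 90.0
    assert phspB.gantry.std() > 5.0
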