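"""Plan model: loading, normalization, delivery sampling, splitting."""

import json

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fajtrace import (Beam, ControlPoint, load_plan, sample_delivery,
                      save_plan, split_imrt_nsplit, split_vmat_subfields,
                      interpolate_apertures)
from fajtrace.plan import PlanValidationError, derive_seed


def _plan_dict(cps, modality="imrt_dynamic", total_mu=100.0, jaw_tracking=True):
    return {"beams": [{"modality": modality, "total_mu": total_mu,
                       "jaw_tracking": jaw_tracking, "control_points": cps}]}


def _cp(mu_raw, jaws=(-5, 5, -5, 5), gantry=0.0, mlc=None):
    d = {"mu_cum_raw": mu_raw,
         "jaws": dict(zip(("X1", "X2", "Y1", "Y2"), jaws)),
         "gantry_deg": gantry}
    if mlc:
        d["mlc"] = mlc
    return d


def test_minimal_static_plan(tmp_path):
    p = tmp_path / "p.json"
    p.write_text(json.dumps(_plan_dict([_cp(0), _cp(1)], modality="static")))
    beam = load_plan(p)[0]
    assert list(beam.mu_cum) == [0.0, 1.0]
    assert all(cp.jaws == (-5, 5, -5, 5) for cp in beam.control_points)


def test_meterset_normalization(tmp_path):
    p = tmp_path / "p.json"
    p.write_text(json.dumps(_plan_dict([_cp(0), _cp(50), _cp(200)])))
    beam = load_plan(p)[0]
    np.testing.assert_allclose(beam.mu_cum, [0.0, 0.25, 1.0])


def test_jaw_tracking_plan_roundtrip(tmp_path):
    mlc = {"boundaries": [-3.0, -1.0, 1.0, 3.0],
           "bankA": [-2.0, -3.0, -1.5], "bankB": [2.0, 3.0, 1.0]}
    cps = [_cp(0, (-2, 2, -2, 2), 0.0, mlc), _cp(30, (-3, 4, -2, 3), 0.0, mlc),
           _cp(100, (-5, 5, -5, 5), 0.0, mlc)]
    src = tmp_path / "a.json"
    src.write_text(json.dumps(_plan_dict(cps)))
    beams = load_plan(src)
    save_plan(beams, tmp_path / "b.json")
    again = load_plan(tmp_path / "b.json")
    for cp1, cp2 in zip(beams[0].control_points, again[0].control_points):
        assert cp1.jaws == cp2.jaws and cp1.mu_cum == cp2.mu_cum
        np.testing.assert_array_equal(cp1.mlc[1], cp2.mlc[1])


def test_validation_errors_cite_control_point(tmp_path):
    p = tmp_path / "p.json"
    p.write_text(json.dumps(_plan_dict([_cp(0), _cp(60), _cp(50), _cp(100)])))
    with pytest.raises(PlanValidationError, match="control point 2"):
        load_plan(p)
    mlc = {"boundaries": [-1.0, 0.0, 1.0], "bankA": [0.5, -1.0],
           "bankB": [-0.5, 1.0]}
    p.write_text(json.dumps(_plan_dict([_cp(0, mlc=mlc), _cp(1, mlc=mlc)])))
    with pytest.raises(PlanValidationError, match="overlapping leaf pair"):
        load_plan(p)


def test_sample_delivery_boundaries_and_midpoint():
    cps = [ControlPoint(0, 0.0, (-5, 5, -5, 5)),
           ControlPoint(1, 1.0, (-5, 7, -5, 5))]
    beam = Beam(cps, 100.0, "imrt_dynamic")
    s0 = sample_delivery(beam, 0.0)
    assert s0.jaws_t == (-5, 5, -5, 5) and s0.segment == 0
    s_mid = sample_delivery(beam, 0.5)
    assert s_mid.jaws_t[1] == pytest.approx(6.0)


def test_segment_frequencies_match_mu_weights():
    """Over 1e5 uniform draws the segment visit frequencies follow the
    delta-MU weights within 4 sigma."""
    weights = [0.2, 0.3, 0.1, 0.4]
    mu = np.concatenate([[0], np.cumsum(weights)])
    cps = [ControlPoint(i, m, (-5, 5, -5, 5)) for i, m in enumerate(mu)]
    beam = Beam(cps, 100.0, "imrt_dynamic")
    draws = np.random.default_rng(4).random(100_000)
    seg, _, _, _ = interpolate_apertures(beam, draws)
    for i, p in enumerate(weights):
        k = np.count_nonzero(seg == i)
        sigma = np.sqrt(len(draws) * p * (1 - p))
        assert abs(k - len(draws) * p) < 4 * sigma


def test_interpolation_consistency_scalar_vs_vectorized():
    cps = [ControlPoint(0, 0.0, (-2, 2, -3, 3), None, 10.0),
           ControlPoint(1, 0.4, (-3, 3, -2, 4), None, 50.0),
           ControlPoint(2, 1.0, (-5, 5, -5, 5), None, 170.0)]
    beam = Beam(cps, 50.0, "vmat_arc")
    mus = np.linspace(0, 0.999, 17)
    seg, jaws, _, gantry = interpolate_apertures(beam, mus)
    for i, m in enumerate(mus):
        s = sample_delivery(beam, float(m))
        np.testing.assert_allclose(s.jaws_t, jaws[i])
        assert s.gantry_t == pytest.approx(gantry[i])


@settings(deadline=None, max_examples=50)
@given(mu=st.floats(0.0, 1.0, exclude_max=True))
def test_interpolated_apertures_preserve_invariants(mu):
    mlc = ([-2.0, 0.0, 2.0], [-1.0, -2.0], [1.0, 2.0])
    cps = [ControlPoint(0, 0.0, (-1, 1, -2, 2), mlc, 0.0),
           ControlPoint(1, 0.5, (-4, 2, -3, 3), mlc, 30.0),
           ControlPoint(2, 1.0, (-2, 5, -1, 4), mlc, 90.0)]
    beam = Beam(cps, 10.0, "vmat_arc")
    s = sample_delivery(beam, mu)
    x1, x2, y1, y2 = s.jaws_t
    assert x1 < x2 and y1 < y2
    assert np.all(s.mlc_t[1] <= s.mlc_t[2])


def test_vmat_split_counts_and_mu_conservation():
    cps = [ControlPoint(0, 0.0, (-5, 5, -5, 5), None, 180.0),
           ControlPoint(1, 0.3, (-5, 5, -5, 5), None, 120.0),
           ControlPoint(2, 1.0, (-5, 5, -5, 5), None, 0.0)]
    beam = Beam(cps, 200.0, "vmat_arc")
    subs = split_vmat_subfields(beam)
    assert len(subs) == 2
    np.testing.assert_allclose([s.total_mu for s in subs], [60.0, 140.0])
    assert sum(s.total_mu for s in subs) == pytest.approx(beam.total_mu)
    for s in subs:
        assert list(s.mu_cum) == [0.0, 1.0]


def test_pooled_subfield_sampling_matches_parent():
    """Sampling sub-fields in proportion to their MU shares reproduces the
    parent's segment frequencies within 4 sigma."""
    weights = np.array([0.25, 0.45, 0.3])
    mu = np.concatenate([[0], np.cumsum(weights)])
    cps = [ControlPoint(i, m, (-5, 5, -5, 5)) for i, m in enumerate(mu)]
    beam = Beam(cps, 100.0, "vmat_arc")
    subs = split_vmat_subfields(beam)
    rng = np.random.default_rng(9)
    n = 100_000
    shares = np.array([s.total_mu for s in subs]) / beam.total_mu
    counts = rng.multinomial(n, shares)
    for i, (sub, k, p) in enumerate(zip(subs, counts, weights)):
        sigma = np.sqrt(n * p * (1 - p))
        assert abs(k - n * p) < 4 * sigma


def test_nsplit_identity_and_distinct_seeds():
    cps = [ControlPoint(0, 0.0, (-5, 5, -5, 5)), ControlPoint(1, 1.0, (-5, 5, -5, 5))]
    beam = Beam(cps, 100.0, "imrt_dynamic")
    only, = split_imrt_nsplit(beam, 1, 42)
    assert only[0] is beam and only[1] == derive_seed(42, 0)
    seeds = [s for _, s in split_imrt_nsplit(beam, 64, 42)]
    assert len(set(seeds)) == 64
    assert all(0 <= s < 2 ** 31 for s in seeds)
    assert seeds == [s for _, s in split_imrt_nsplit(beam, 64, 42)]
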