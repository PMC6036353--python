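"""Treatment-plan representation and delivery sampling.

A beam is an ordered list of control points, each a delivery snapshot:
cumulative fractional monitor units (MU), jaw edges (X1, X2, Y1, Y2, cm
projected to the isocenter plane), two banks of MLC leaf positions (cm at
isocenter, with a shared leaf-boundary list on the perpendicular axis), and
gantry angle.  Dynamic delivery is modeled by sampling the fractional MU
uniformly and interpolating apertures between the bounding control points —
linear-in-MU by default, matching dynamic delivery semantics (a
``nearest``-control-point mode is available).

The module also implements the two splitting strategies used for
parallelization: VMAT arcs split into per-control-point-pair sub-fields
(each carrying its MU share and gantry span), and IMRT fields split into
``nsplit`` identical copies with independently derived seeds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

MODALITIES = ("static", "imrt_dynamic", "vmat_arc")


class PlanValidationError(ValueError):
    pass


@dataclass
class ControlPoint:
    index: int
    mu_cum: float                       # cumulative fractional MU in [0, 1]
    jaws: tuple                         # (X1, X2, Y1, Y2) cm at isocenter
    mlc: tuple | None = None            # (boundaries, bankA, bankB) cm at isocenter
    gantry_deg: float = 0.0

    def __post_init__(self):
        x1, x2, y1, y2 = self.jaws
        if not (x1 < x2 and y1 < y2):
            raise PlanValidationError(
                f"control point {self.index}: jaw edges must satisfy X1<X2, Y1<Y2")
        if self.mlc is not None:
            b, a, bb = (np.asarray(m, dtype=float) for m in self.mlc)
            if b.size != a.size + 1 or a.size != bb.size:
                raise PlanValidationError(
                    f"control point {self.index}: boundaries must have one more "
                    "entry than each leaf bank")
            if np.any(np.diff(b) <= 0):
                raise PlanValidationError(
                    f"control point {self.index}: leaf boundaries must ascend")
            if np.any(a > bb):
                raise PlanValidationError(
                    f"control point {self.index}: overlapping leaf pair "
                    f"(bankA > bankB at leaf {int(np.argmax(a > bb))})")
            self.mlc = (b, a, bb)


@dataclass
class Beam:
    control_points: list
    total_mu: float
    modality: str = "static"
    jaw_tracking: bool = False
    name: str = ""

    def __post_init__(self):
        if self.modality not in MODALITIES:
            raise PlanValidationError(f"unknown modality {self.modality!r}")
        n = len(self.control_points)
        if self.modality == "static":
            if n < 1:
                raise PlanValidationError("static beam needs >= 1 control point")
        elif n < 2:
            raise PlanValidationError("dynamic beam needs >= 2 control points")
        mu = self.mu_cum
        if n >= 2:
            if np.any(np.diff(mu) < 0):
                i = int(np.argmax(np.diff(mu) < 0)) + 1
                raise PlanValidationError(
                    f"non-monotone cumulative MU at control point {i}")
            if abs(mu[0]) > 1e-12 or abs(mu[-1] - 1.0) > 1e-9:
                raise PlanValidationError("mu_cum must start at 0 and end at 1")

    @property
    def mu_cum(self) -> np.ndarray:
        return np.array([cp.mu_cum for cp in self.control_points])

    @property
    def max_jaws(self) -> tuple:
        """Per-beam maximum jaw opening (used when jaw-tracking is off)."""
        j = np.array([cp.jaws for cp in self.control_points])
        return (float(j[:, 0].min()), float(j[:, 1].max()),
                float(j[:, 2].min()), float(j[:, 3].max()))


@dataclass
class DeliverySample:
    mu_frac: float
    segment: int
    jaws_t: tuple
    mlc_t: tuple | None
    gantry_t: float


# ---------------------------------------------------------------------------
# JSON plan dialect
# ---------------------------------------------------------------------------

def _beam_from_dict(d: dict, beam_index: int) -> Beam:
    cps_raw = d["control_points"]
    raw_mu = np.array([cp["mu_cum_raw"] for cp in cps_raw], dtype=float)
    if len(raw_mu) >= 2:
        if raw_mu[-1] <= 0:
            raise PlanValidationError(f"beam {beam_index}: final meterset must be > 0")
        mu = raw_mu / raw_mu[-1]
        mu[0] = 0.0 if abs(mu[0]) < 1e-12 else mu[0]
    else:
        mu = np.zeros(1)
    cps = []
    for i, (cp, m) in enumerate(zip(cps_raw, mu)):
        jaws = (cp["jaws"]["X1"], cp["jaws"]["X2"], cp["jaws"]["Y1"], cp["jaws"]["Y2"])
        mlc = None
        if cp.get("mlc") is not None:
            mlc = (cp["mlc"]["boundaries"], cp["mlc"]["bankA"], cp["mlc"]["bankB"])
        cps.append(ControlPoint(i, float(m), jaws, mlc, float(cp.get("gantry_deg", 0.0))))
    return Beam(cps, float(d["total_mu"]), d.get("modality", "static"),
                bool(d.get("jaw_tracking", False)), d.get("name", f"beam{beam_index}"))


def load_plan(path) -> list:
    """Load a list of beams from the JSON plan dialect, normalizing each
    beam's cumulative meterset to [0, 1] and validating all invariants."""
    data = json.loads(Path(path).read_text())
    return [_beam_from_dict(b, i) for i, b in enumerate(data["beams"])]


def save_plan(beams, path) -> None:
    out = {"beams": []}
    for b in beams:
        cps = []
        for cp in b.control_points:
            d = {"mu_cum_raw": cp.mu_cum,
                 "jaws": dict(zip(("X1", "X2", "Y1", "Y2"), map(float, cp.jaws))),
                 "gantry_deg": cp.gantry_deg}
            if cp.mlc is not None:
                bnd, a, bb = cp.mlc
                d["mlc"] = {"boundaries": list(map(float, bnd)),
                            "bankA": list(map(float, a)),
                            "bankB": list(map(float, bb))}
            cps.append(d)
        out["beams"].append({"name": b.name, "modality": b.modality,
                             "total_mu": b.total_mu, "jaw_tracking": b.jaw_tracking,
                             "control_points": cps})
    Path(path).write_text(json.dumps(out, indent=1))


def load_dicom_plan(path) -> list:
    """Optional adapter: import a DICOM RT Plan subset into the dialect.

    Maps BeamSequence/ControlPointSequence cumulative meterset weights, jaw
    (ASYMX/ASYMY) and MLCX positions.  Leaf boundaries are taken from the
    BeamLimitingDeviceSequence.  Couch and collimator rotations are ignored.
    """
    import pydicom

    ds = pydicom.dcmread(path)
    beams = []
    for bi, b in enumerate(ds.BeamSequence):
        boundaries = None
        for dev in b.BeamLimitingDeviceSequence:
            if dev.RTBeamLimitingDeviceType.startswith("MLC"):
                boundaries = [float(v) / 10.0 for v in dev.LeafPositionBoundaries]
        cps_raw = []
        jaws = mlc = None
        for cp in b.ControlPointSequence:
            for dev in getattr(cp, "BeamLimitingDevicePositionSequence", []):
                t = dev.RTBeamLimitingDeviceType
                pos = [float(v) / 10.0 for v in dev.LeafJawPositions]
                if t in ("X", "ASYMX"):
                    jaws = (pos[0], pos[1]) + (jaws[2:] if jaws else (-20.0, 20.0))
                elif t in ("Y", "ASYMY"):
                    jaws = ((jaws[:2] if jaws else (-20.0, 20.0)) + (pos[0], pos[1]))
                elif t.startswith("MLC"):
                    nl = len(pos) // 2
                    mlc = {"boundaries": boundaries, "bankA": pos[:nl], "bankB": pos[nl:]}
            cps_raw.append({"mu_cum_raw": float(cp.CumulativeMetersetWeight),
                            "jaws": dict(zip(("X1", "X2", "Y1", "Y2"), jaws)),
                            "mlc": mlc,
                            "gantry_deg": float(getattr(cp, "GantryAngle", 0.0))})
        modality = "vmat_arc" if getattr(b, "BeamType", "") == "DYNAMIC" and \
            len({c["gantry_deg"] for c in cps_raw}) > 1 else "imrt_dynamic"
        beams.append(_beam_from_dict(
            {"control_points": cps_raw, "total_mu": float(b.FinalCumulativeMetersetWeight)
             if hasattr(b, "FinalCumulativeMetersetWeight") else 1.0,
             "modality": modality, "name": getattr(b, "BeamName", f"beam{bi}")}, bi))
    return beams


# ---------------------------------------------------------------------------
# delivery sampling
# ---------------------------------------------------------------------------

def _segment_of(mu_cum: np.ndarray, mu: np.ndarray) -> np.ndarray:
    """Segment index i such that mu_cum[i] <= mu <= mu_cum[i+1].

    A draw landing exactly on an interior node belongs to the following
    segment; zero-width segments (repeated mu_cum) are skipped.
    """
    seg = np.searchsorted(mu_cum, mu, side="right") - 1
    return np.clip(seg, 0, len(mu_cum) - 2)


def interpolate_apertures(beam: Beam, mu: np.ndarray, interp: str = "linear"):
    """Vectorized aperture interpolation at fractional MU values ``mu``.

    Returns ``(segment, jaws, mlc, gantry)`` where ``jaws`` is (n, 4),
    ``mlc`` is None or ``(boundaries, bankA, bankB)`` with banks of shape
    (n, n_leaves), and ``gantry`` is (n,).
    """
    mu = np.atleast_1d(np.asarray(mu, dtype=float))
    mu_cum = beam.mu_cum
    seg = _segment_of(mu_cum, mu)
    lo, hi = mu_cum[seg], mu_cum[seg + 1]
    width = hi - lo
    f = np.where(width > 0, (mu - lo) / np.where(width > 0, width, 1.0), 0.0)
    if interp == "nearest":
        f = np.where(f < 0.5, 0.0, 1.0)
    elif interp != "linear":
        raise ValueError("interp must be 'linear' or 'nearest'")

    jaws_all = np.array([cp.jaws for cp in beam.control_points])
    jaws = jaws_all[seg] * (1 - f)[:, None] + jaws_all[seg + 1] * f[:, None]
    gantry_all = np.array([cp.gantry_deg for cp in beam.control_points])
    gantry = gantry_all[seg] * (1 - f) + gantry_all[seg + 1] * f
    mlc = None
    if beam.control_points[0].mlc is not None:
        boundaries = beam.control_points[0].mlc[0]
        a_all = np.array([cp.mlc[1] for cp in beam.control_points])
        b_all = np.array([cp.mlc[2] for cp in beam.control_points])
        bank_a = a_all[seg] * (1 - f)[:, None] + a_all[seg + 1] * f[:, None]
        bank_b = b_all[seg] * (1 - f)[:, None] + b_all[seg + 1] * f[:, None]
        mlc = (boundaries, bank_a, bank_b)
    return seg, jaws, mlc, gantry


def sample_delivery(beam: Beam, rng_draw: float, interp: str = "linear") -> DeliverySample:
    """Map one uniform draw in [0, 1) to an interpolated delivery state."""
    if len(beam.control_points) < 2:
        raise PlanValidationError("sampling requires >= 2 control points")
    seg, jaws, mlc, gantry = interpolate_apertures(beam, [rng_draw], interp)
    mlc_t = None if mlc is None else (mlc[0], mlc[1][0], mlc[2][0])
    return DeliverySample(float(rng_draw), int(seg[0]), tuple(jaws[0]),
                          mlc_t, float(gantry[0]))


# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------

def split_vmat_subfields(beam: Beam) -> list:
    """Split an arc into one sub-beam per adjacent control-point pair.

    Each sub-beam has two control points with mu_cum renormalized to [0, 1],
    carries its MU share (total_mu x deltaMU) and its own gantry span.
    Pooled delivery over the sub-beams, weighted by MU share, is
    statistically identical to sampling the parent.
    """
    if beam.modality != "vmat_arc":
        raise PlanValidationError("sub-field splitting applies to vmat_arc beams")
    if len(beam.control_points) < 2:
        raise PlanValidationError("arc needs >= 2 control points")
    subs = []
    for i in range(len(beam.control_points) - 1):
        a, b = beam.control_points[i], beam.control_points[i + 1]
        dmu = b.mu_cum - a.mu_cum
        cps = [replace(a, index=0, mu_cum=0.0), replace(b, index=1, mu_cum=1.0)]
        subs.append(Beam(cps, beam.total_mu * dmu, "vmat_arc",
                         beam.jaw_tracking, f"{beam.name}/sub{i}"))
    return subs


def derive_seed(base_seed: int, split_index: int) -> int:
    """Stable per-split seed: SeedSequence(base_seed).spawn-style derivation,
    folded below 2**31 so downstream consumers can treat it as a C int."""
    ss = np.random.SeedSequence(entropy=int(base_seed), spawn_key=(int(split_index),))
    return int(ss.generate_state(1, np.uint64)[0] % (2 ** 31))


def split_imrt_nsplit(beam: Beam, nsplit: int, base_seed: int) -> list:
    """``nsplit`` identical copies of the beam, each with a distinct derived
    seed; running each with Nrequested/nsplit particles and summing the dose
    grids is the parallelization contract."""
    if nsplit < 1:
        raise PlanValidationError("nsplit must be >= 1")
    return [(beam, derive_seed(base_seed, i)) for i in range(nsplit)]
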