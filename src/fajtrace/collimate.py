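"""The flat-absorbing jaw-tracking (FAJT) collimator core.

Jaws are modeled as perfectly absorbing planes at the *top* surface of each
jaw pair: a particle ray-traced to the plane is absorbed if it lands on the
jaw side of the projected edge and passes untouched otherwise — no
transmission through, and no scatter from, the collimator material.  The top
surface (rather than the vertical midpoint) removes diverging and
downward-aimed particles most effectively; a parallel beam is the extreme
case where the choice matters.

Efficiency comes from azimuthal particle redistribution (APR): each source
particle is recycled ``n_recycle`` times (default 20), each copy rotated by
an independent uniform azimuth about the beam axis, which suppresses the
latent variance of reusing a finite phase space.  The collimated output
phase space (PhspB, scored below the MLC) is generated to contain *exactly*
``n_requested`` particles; the number of source particles read (``n_read``)
is determined on the fly from the rejection rate.

For dynamic (IMRT/VMAT) beams each APR copy independently samples the
fractional MU delivered; the sampled state supplies both the jaw edges and
the MLC leaf positions, synchronizing jaw and MLC motion for jaw-tracking.
The MLC stage is a deliberate first-order model: a projected aperture at a
single plane with a bulk transmission factor and a leaf-tip offset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .phasespace import CyclicReader, Particle, PhaseSpaceStore, default_r_max
from .plan import Beam, interpolate_apertures

_CHUNK_SRC = 2048  # source particles per vectorized chunk (fixed for determinism)


@dataclass
class JawPair:
    """One pair of opposing jaws sharing a top-surface absorbing plane."""
    axis: str                 # 'X' or 'Y'
    z_top: float              # cm from target, top surface
    e_neg: float | None = None  # default projected edges at isocenter (cm)
    e_pos: float | None = None

    def __post_init__(self):
        if self.axis not in ("X", "Y"):
            raise ValueError("jaw axis must be 'X' or 'Y'")
        if self.e_neg is not None and self.e_pos is not None and not self.e_neg < self.e_pos:
            raise ValueError("jaw edges must satisfy e_neg < e_pos")


@dataclass
class CollimatorGeometry:
    jaw_pairs: list            # ordered along the beam direction
    mlc_plane_z: float
    sad: float = 100.0
    phspB_z: float = 55.0

    def __post_init__(self):
        zs = [p.z_top for p in self.jaw_pairs]
        seq = zs + [self.mlc_plane_z, self.phspB_z]
        if any(a >= b for a, b in zip(seq, seq[1:])) or (zs and zs[0] <= 0) \
                or self.phspB_z > self.sad:
            raise ValueError("geometry planes must satisfy 0 < z_top(jaws...) "
                             "< mlc_plane_z < phspB_z <= sad")


def default_geometry() -> CollimatorGeometry:
    """Declared geometry fixture (real linac head geometry is proprietary):
    Y pair at 28 cm, X pair at 36 cm, MLC plane at 50 cm, PhspB at 55 cm,
    SAD 100 cm."""
    return CollimatorGeometry([JawPair("Y", 28.0), JawPair("X", 36.0)],
                              mlc_plane_z=50.0, sad=100.0, phspB_z=55.0)


@dataclass
class StaticAperture:
    """A fixed aperture: jaw edges at isocenter and an optional MLC shape
    (boundaries, bankA, bankB, all cm projected to isocenter)."""
    jaws: tuple
    mlc: tuple | None = None

    def __post_init__(self):
        x1, x2, y1, y2 = self.jaws
        if not (x1 < x2 and y1 < y2):
            raise ValueError("aperture jaws must satisfy X1<X2, Y1<Y2")
        if self.mlc is not None:
            self.mlc = tuple(np.asarray(m, dtype=float) for m in self.mlc)


@dataclass
class CollimationConfig:
    n_requested: int
    n_recycle: int = 20
    seed: int = 0
    mlc_transmission: float = 0.0
    leaf_tip_offset: float = 0.0   # cm at the MLC plane
    interp: str = "linear"         # aperture interpolation within a segment
    apr: bool = True               # azimuthal redistribution of copies

    def __post_init__(self):
        if self.n_requested < 1 or self.n_recycle < 1:
            raise ValueError("n_requested and n_recycle must be >= 1")
        if not 0.0 <= self.mlc_transmission <= 1.0:
            raise ValueError("mlc_transmission must lie in [0, 1]")


@dataclass
class CollimationReport:
    """Bookkeeping counters for one collimation run.

    The accounting identity
    ``n_examined = n_discarded_upward + n_absorbed_jaws + n_absorbed_mlc +
    n_scored`` holds exactly; ``n_attenuated`` counts the subset of scored
    particles that passed under a leaf with reduced weight.
    """
    n_read: int = 0
    n_examined: int = 0
    n_discarded_upward: int = 0
    n_absorbed_jaws: int = 0
    n_absorbed_mlc: int = 0
    n_attenuated: int = 0
    n_scored: int = 0
    wrapped: bool = False
    n_histories_equivalent: float = 0.0

    def check(self) -> None:
        total = (self.n_discarded_upward + self.n_absorbed_jaws +
                 self.n_absorbed_mlc + self.n_scored)
        if total != self.n_examined:
            raise AssertionError("collimation accounting identity violated")


# ---------------------------------------------------------------------------
# single-particle operations (the vectorized pipeline mirrors these)
# ---------------------------------------------------------------------------

def apr_rotate(p: Particle, phi: float) -> Particle:
    """Rotate position and direction by the same azimuth about the beam
    axis; radius, polar angle, energy and weight are preserved exactly."""
    c, s = math.cos(phi), math.sin(phi)
    return Particle(p.kind, p.energy,
                    c * p.x - s * p.y, s * p.x + c * p.y, p.z,
                    c * p.u - s * p.v, s * p.u + c * p.v, p.w,
                    p.weight, p.new_history)


def project_to_plane(p: Particle, z_plane: float) -> Particle:
    """Straight-line vacuum transport to ``z_plane`` (requires w > 0)."""
    if p.w <= 0:
        raise ValueError("cannot project a particle with w <= 0")
    t = (z_plane - p.z) / p.w
    return Particle(p.kind, p.energy, p.x + p.u * t, p.y + p.v * t, z_plane,
                    p.u, p.v, p.w, p.weight, p.new_history)


def jaw_transmit(p: Particle, pair: JawPair, sad: float = 100.0) -> str:
    """Project to the pair's top surface and test against the physical
    edges ``e * z_top / sad``.  Returns ``"pass"`` iff the coordinate lies
    strictly inside the opening; a particle exactly on an edge is absorbed
    (closed-jaw tie-break)."""
    if pair.e_neg is None or pair.e_pos is None:
        raise ValueError("jaw pair has no edges set")
    q = project_to_plane(p, pair.z_top)
    c = q.x if pair.axis == "X" else q.y
    scale = pair.z_top / sad
    return "pass" if pair.e_neg * scale < c < pair.e_pos * scale else "absorb"


def mlc_transmit(p: Particle, mlc_plane_z: float, boundaries, bank_a, bank_b,
                 sad: float = 100.0, transmission: float = 0.0,
                 tip_offset: float = 0.0):
    """First-order MLC stage at a single plane.

    Projects the particle to the MLC plane, locates the leaf pair by the
    cross-leaf coordinate (y), and returns ``(status, particle)`` where
    status is ``"pass"`` (inside the tip_offset-widened opening),
    ``"pass_attenuated"`` (under a leaf, weight scaled by ``transmission``)
    or ``"absorb"`` (under a leaf with zero transmission, or outside the
    leaf-boundary span)."""
    q = project_to_plane(p, mlc_plane_z)
    scale = mlc_plane_z / sad
    boundaries = np.asarray(boundaries, dtype=float) * scale
    leaf = int(np.searchsorted(boundaries, q.y, side="right")) - 1
    if leaf < 0 or leaf >= len(bank_a):
        return "absorb", None
    lo = bank_a[leaf] * scale - tip_offset
    hi = bank_b[leaf] * scale + tip_offset
    if lo < q.x < hi:
        return "pass", q
    if transmission > 0.0:
        q.weight = q.weight * transmission
        return "pass_attenuated", q
    return "absorb", None


# ---------------------------------------------------------------------------
# vectorized collimation
# ---------------------------------------------------------------------------

_SCORED, _UPWARD, _JAW, _MLC = 0, 1, 2, 3


def _jaw_indices(geom: CollimatorGeometry):
    # column indices into a (n, 4) jaws array (X1, X2, Y1, Y2)
    return [(0, 1) if p.axis == "X" else (2, 3) for p in geom.jaw_pairs]


def _collimate(reader: CyclicReader, geom: CollimatorGeometry,
               cfg: CollimationConfig, *, static_aperture: StaticAperture | None,
               beam: Beam | None):
    dynamic = beam is not None
    ss = np.random.SeedSequence(cfg.seed)
    phi_rng, mu_rng = (np.random.default_rng(s) for s in ss.spawn(2))

    if reader.r_max is None and reader.n_delivered == 0:
        jaws_for_rmax = beam.max_jaws if dynamic else static_aperture.jaws
        reader.set_r_max(default_r_max(jaws_for_rmax, reader.store.z_plane, geom.sad))

    nr = cfg.n_recycle
    cols: list = []
    report = CollimationReport()
    src_frac = reader.store.n_original_histories / len(reader.store)
    jaw_cols = _jaw_indices(geom)
    cycles_without_score = 0

    while report.n_scored < cfg.n_requested:
        src = reader.take(_CHUNK_SRC)
        k = _CHUNK_SRC * nr
        x = np.repeat(src.x, nr)
        y = np.repeat(src.y, nr)
        z = np.repeat(src.z, nr)
        u = np.repeat(src.u, nr)
        v = np.repeat(src.v, nr)
        w = np.repeat(src.w, nr)
        e = np.repeat(src.energy, nr)
        wt = np.repeat(src.weight, nr)
        kind = np.repeat(src.kind, nr)
        newh = np.repeat(src.new_history, nr)

        if cfg.apr:
            # APR: independent azimuth per copy, rotating (x,y) and (u,v) alike
            phi = phi_rng.uniform(0.0, 2.0 * np.pi, k)
            c, s = np.cos(phi), np.sin(phi)
            x, y = c * x - s * y, s * x + c * y
            u, v = c * u - s * v, s * u + c * v

        if dynamic:
            mu = mu_rng.random(k)
            _, jaws_t, mlc_t, gantry_t = interpolate_apertures(beam, mu, cfg.interp)
            if not beam.jaw_tracking:
                jaws_t = np.broadcast_to(np.asarray(beam.max_jaws), (k, 4))
        else:
            jaws_t = np.broadcast_to(np.asarray(static_aperture.jaws), (k, 4))
            mlc_t = None
            if static_aperture.mlc is not None:
                bnd, a, b = static_aperture.mlc
                mlc_t = (bnd, np.broadcast_to(a, (k, a.size)),
                         np.broadcast_to(b, (k, b.size)))
            gantry_t = None

        status = np.full(k, _SCORED, dtype=np.int8)
        status[w <= 0] = _UPWARD
        alive = status == _SCORED

        for pair, (i_neg, i_pos) in zip(geom.jaw_pairs, jaw_cols):
            t = np.where(alive, (pair.z_top - z) / np.where(alive, w, 1.0), 0.0)
            x = x + u * t
            y = y + v * t
            z = np.where(alive, pair.z_top, z)
            coord = x if pair.axis == "X" else y
            scale = pair.z_top / geom.sad
            inside = (coord > jaws_t[:, i_neg] * scale) & (coord < jaws_t[:, i_pos] * scale)
            status[alive & ~inside] = _JAW
            alive = status == _SCORED

        if mlc_t is not None:
            bnd, bank_a, bank_b = mlc_t
            t = np.where(alive, (geom.mlc_plane_z - z) / np.where(alive, w, 1.0), 0.0)
            x = x + u * t
            y = y + v * t
            z = np.where(alive, geom.mlc_plane_z, z)
            scale = geom.mlc_plane_z / geom.sad
            bphys = np.asarray(bnd, dtype=float) * scale
            leaf = np.searchsorted(bphys, y, side="right") - 1
            in_span = (leaf >= 0) & (leaf < bank_a.shape[1])
            leaf_c = np.clip(leaf, 0, bank_a.shape[1] - 1)
            rows = np.arange(k)
            lo = bank_a[rows, leaf_c] * scale - cfg.leaf_tip_offset
            hi = bank_b[rows, leaf_c] * scale + cfg.leaf_tip_offset
            open_mask = in_span & (x > lo) & (x < hi)
            under_leaf = alive & in_span & ~open_mask
            out_span = alive & ~in_span
            if cfg.mlc_transmission > 0.0:
                wt = np.where(under_leaf, wt * cfg.mlc_transmission, wt)
                attenuated = under_leaf
                status[out_span] = _MLC
            else:
                attenuated = np.zeros(k, dtype=bool)
                status[under_leaf | out_span] = _MLC
            alive = status == _SCORED
        else:
            attenuated = np.zeros(k, dtype=bool)

        # exact-count truncation: stop at the copy that completes n_requested
        survivor_pos = np.flatnonzero(alive)
        need = cfg.n_requested - report.n_scored
        if survivor_pos.size >= need:
            cut = int(survivor_pos[need - 1]) + 1  # copies examined this chunk
            n_src_used = (cut - 1) // nr + 1
            reader.rollback(_CHUNK_SRC - n_src_used)
            sel = slice(0, cut)
        else:
            cut = k
            sel = slice(0, k)

        st = status[sel]
        report.n_examined += cut
        report.n_discarded_upward += int(np.count_nonzero(st == _UPWARD))
        report.n_absorbed_jaws += int(np.count_nonzero(st == _JAW))
        report.n_absorbed_mlc += int(np.count_nonzero(st == _MLC))
        report.n_attenuated += int(np.count_nonzero(attenuated[sel] & (st == _SCORED)))
        keep = np.flatnonzero(st == _SCORED)
        report.n_scored += keep.size

        if keep.size:
            # project survivors to the PhspB scoring plane
            t = (geom.phspB_z - z[keep]) / w[keep]
            rec = dict(kind=kind[keep], energy=e[keep],
                       x=x[keep] + u[keep] * t, y=y[keep] + v[keep] * t,
                       z=np.full(keep.size, geom.phspB_z),
                       u=u[keep], v=v[keep], w=w[keep], weight=wt[keep],
                       new_history=newh[keep],
                       gantry=None if gantry_t is None else gantry_t[keep])
            cols.append(rec)
            cycles_without_score = 0
        else:
            cycles_without_score += cut
            if cycles_without_score > 2 * len(reader.store) * nr:
                raise RuntimeError(
                    "aperture admits no particles: two full passes over the "
                    "source yielded no survivors")

    report.n_read = reader.n_read
    report.wrapped = reader.wrapped
    report.n_histories_equivalent = report.n_read * nr * src_frac
    report.check()

    def cat(name):
        parts = [c[name] for c in cols]
        if any(p is None for p in parts):
            return None
        return np.concatenate(parts) if parts else np.zeros(0)

    out = PhaseSpaceStore(
        cat("kind"), cat("energy"), cat("x"), cat("y"), cat("z"),
        cat("u"), cat("v"), cat("w"), cat("weight"), cat("new_history"),
        z_plane=geom.phspB_z, n_original_histories=report.n_histories_equivalent,
        gantry=cat("gantry"))
    return out, report


def collimate_static(reader: CyclicReader, geom: CollimatorGeometry,
                     cfg: CollimationConfig, aperture: StaticAperture):
    """Collimate through a fixed jaw (+ optional MLC) aperture until PhspB
    holds exactly ``cfg.n_requested`` particles."""
    return _collimate(reader, geom, cfg, static_aperture=aperture, beam=None)


def collimate_dynamic(reader: CyclicReader, geom: CollimatorGeometry,
                      cfg: CollimationConfig, beam: Beam):
    """Collimate a dynamic beam: each APR copy samples a fresh fractional MU
    which sets both the jaw edges and the MLC leaves (jaw-tracking).  With
    ``beam.jaw_tracking`` False the jaws are held at the per-beam maximum
    opening while the MLC still moves.  Scored particles carry the sampled
    gantry angle as an annotation."""
    if len(beam.control_points) < 2:
        raise ValueError("dynamic collimation requires >= 2 control points")
    return _collimate(reader, geom, cfg, static_aperture=None, beam=beam)
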