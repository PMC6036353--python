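"""Phase-space particle containers and the cyclic recycling reader.

A phase space is the particle fluence crossing a scoring plane, stored as a
columnar table so that millions of records fit comfortably in RAM and can be
processed with vectorized arithmetic.  ``PhaseSpaceStore`` holds the upstream
source (PhspA, scored above the jaws) as well as the collimated output
(PhspB, scored below the MLC).  ``CyclicReader`` provides the recycling
access pattern used by the collimator: a random start index, strictly
sequential reads with wraparound, and an optional radius pre-filter that
discards particles which could never enter the largest collimator opening.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

log = logging.getLogger(__name__)

KIND_PHOTON = 1
KIND_ELECTRON = 2
KIND_POSITRON = 3

KIND_NAMES = {KIND_PHOTON: "photon", KIND_ELECTRON: "electron", KIND_POSITRON: "positron"}
KIND_CODES = {v: k for k, v in KIND_NAMES.items()}


class PhaseSpaceExhausted(RuntimeError):
    """Raised when the radius pre-filter rejects every particle in the store."""


@dataclass
class Particle:
    """A single phase-space record.

    Positions are in cm on the scoring plane, ``u, v, w`` are direction
    cosines (unit norm), energy is in MeV, and ``weight`` is the statistical
    weight.  ``new_history`` marks the first particle scored from a new
    primary history.
    """

    kind: int
    energy: float
    x: float
    y: float
    z: float
    u: float
    v: float
    w: float
    weight: float = 1.0
    new_history: bool = True

    def validate(self) -> None:
        norm = self.u ** 2 + self.v ** 2 + self.w ** 2
        if abs(norm - 1.0) > 1e-6:
            raise ValueError(f"direction cosines not normalized: |u,v,w|^2={norm}")
        if self.energy <= 0:
            raise ValueError("energy must be > 0")
        if self.weight <= 0:
            raise ValueError("weight must be > 0")


_COLUMNS = ("kind", "energy", "x", "y", "z", "u", "v", "w", "weight", "new_history")


class PhaseSpaceStore:
    """Ordered in-RAM collection of phase-space particles on one plane.

    Parameters
    ----------
    kind, energy, x, y, z, u, v, w, weight, new_history
        Columnar particle data (1-D arrays of equal length).
    z_plane
        Nominal scoring-plane position in cm; every particle's z must agree
        within 1e-4 cm.
    n_original_histories
        Number of primary histories the store represents (may exceed the
        particle count, and may be fractional after recycling bookkeeping).
    gantry
        Optional per-particle gantry angle annotation (degrees), attached by
        dynamic collimation so the dose engine can rotate each particle into
        the phantom frame.
    """

    def __init__(self, kind, energy, x, y, z, u, v, w, weight=None,
                 new_history=None, *, z_plane=None, n_original_histories=None,
                 gantry=None, extra_floats=None, extra_longs=None):
        self.kind = np.asarray(kind, dtype=np.int8)
        n = self.kind.size
        self.energy = np.asarray(energy, dtype=np.float64)
        self.x = np.asarray(x, dtype=np.float64)
        self.y = np.asarray(y, dtype=np.float64)
        self.z = np.asarray(z, dtype=np.float64)
        self.u = np.asarray(u, dtype=np.float64)
        self.v = np.asarray(v, dtype=np.float64)
        self.w = np.asarray(w, dtype=np.float64)
        self.weight = (np.ones(n) if weight is None
                       else np.asarray(weight, dtype=np.float64))
        self.new_history = (np.ones(n, dtype=bool) if new_history is None
                            else np.asarray(new_history, dtype=bool))
        if z_plane is None:
            z_plane = float(self.z[0]) if n else 0.0
        self.z_plane = float(z_plane)
        self.n_original_histories = (float(n_original_histories)
                                     if n_original_histories is not None else float(n))
        self.gantry = None if gantry is None else np.asarray(gantry, dtype=np.float64)
        # opaque IAEA extras, preserved through round-trips
        self.extra_floats = extra_floats
        self.extra_longs = extra_longs
        self._check()

    def _check(self) -> None:
        n = len(self)
        for name in _COLUMNS:
            if getattr(self, name).shape != (n,):
                raise ValueError(f"column {name!r} has wrong shape")
        if n and np.any(np.abs(self.z - self.z_plane) > 1e-4):
            raise ValueError("particle z deviates from z_plane by more than 1e-4 cm")

    def __len__(self) -> int:
        return int(self.kind.size)

    @property
    def counts_by_kind(self) -> dict:
        return {name: int(np.count_nonzero(self.kind == code))
                for code, name in KIND_NAMES.items()}

    @property
    def radius(self) -> np.ndarray:
        return np.hypot(self.x, self.y)

    def particle(self, i: int) -> Particle:
        return Particle(int(self.kind[i]), float(self.energy[i]),
                        float(self.x[i]), float(self.y[i]), float(self.z[i]),
                        float(self.u[i]), float(self.v[i]), float(self.w[i]),
                        float(self.weight[i]), bool(self.new_history[i]))

    @classmethod
    def from_particles(cls, particles, *, z_plane=None, n_original_histories=None):
        cols = {c: [getattr(p, c) for p in particles] for c in _COLUMNS}
        return cls(**cols, z_plane=z_plane, n_original_histories=n_original_histories)

    def select(self, idx) -> "PhaseSpaceStore":
        return PhaseSpaceStore(
            self.kind[idx], self.energy[idx], self.x[idx], self.y[idx],
            self.z[idx], self.u[idx], self.v[idx], self.w[idx],
            self.weight[idx], self.new_history[idx],
            z_plane=self.z_plane, n_original_histories=self.n_original_histories,
            gantry=None if self.gantry is None else self.gantry[idx])

    # ------------------------------------------------------------------
    # native columnar container: raw float64 columns + JSON metadata
    # ------------------------------------------------------------------
    def save(self, prefix) -> None:
        """Write the native container: ``<prefix>.phsp`` (binary columns) and
        ``<prefix>.json`` (metadata sidecar)."""
        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        cols = ["energy", "x", "y", "z", "u", "v", "w", "weight"]
        has_gantry = self.gantry is not None
        if has_gantry:
            cols.append("gantry")
        with open(prefix.with_suffix(".phsp"), "wb") as f:
            self.kind.astype(np.int8).tofile(f)
            self.new_history.astype(np.int8).tofile(f)
            for c in cols:
                getattr(self, c).astype("<f8").tofile(f)
        meta = {
            "format": "fajtrace-phsp-v1",
            "n_particles": len(self),
            "z_plane": self.z_plane,
            "n_original_histories": self.n_original_histories,
            "counts_by_kind": self.counts_by_kind,
            "columns": cols,
        }
        prefix.with_suffix(".json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, prefix) -> "PhaseSpaceStore":
        prefix = Path(prefix)
        meta = json.loads(prefix.with_suffix(".json").read_text())
        if meta.get("format") != "fajtrace-phsp-v1":
            raise ValueError(f"unrecognized container format: {meta.get('format')!r}")
        n = meta["n_particles"]
        raw = np.fromfile(prefix.with_suffix(".phsp"), dtype=np.int8)
        kind = raw[:n]
        new_history = raw[n:2 * n].astype(bool)
        floats = raw[2 * n:].view("<f8")
        cols = {}
        for i, c in enumerate(meta["columns"]):
            cols[c] = floats[i * n:(i + 1) * n].astype(np.float64)
        return cls(kind, cols["energy"], cols["x"], cols["y"], cols["z"],
                   cols["u"], cols["v"], cols["w"], cols["weight"], new_history,
                   z_plane=meta["z_plane"],
                   n_original_histories=meta["n_original_histories"],
                   gantry=cols.get("gantry"))


def fluence_map(store: PhaseSpaceStore, half_width: float, nbins: int,
                z_plane: float | None = None):
    """Weighted 2D lateral fluence histogram, optionally projected to
    another plane first.  Returns ``(H, xedges, yedges)`` with H indexed
    [ix, iy]."""
    x, y = store.x, store.y
    if z_plane is not None and abs(z_plane - store.z_plane) > 1e-9:
        t = (z_plane - store.z) / store.w
        x = x + store.u * t
        y = y + store.v * t
    edges = np.linspace(-half_width, half_width, nbins + 1)
    h, xe, ye = np.histogram2d(x, y, bins=(edges, edges), weights=store.weight)
    return h, xe, ye


def default_r_max(jaws, z_plane: float, sad: float = 100.0) -> float:
    """Radius pre-filter default: the most distant corner of the jaw opening
    (X1, X2, Y1, Y2 at isocenter) projected to the source scoring plane, plus
    a 10% margin."""
    x1, x2, y1, y2 = jaws
    rx = max(abs(x1), abs(x2))
    ry = max(abs(y1), abs(y2))
    return float(np.hypot(rx, ry) * (z_plane / sad) * 1.1)


class CyclicReader:
    """Sequential cyclic reader over a :class:`PhaseSpaceStore`.

    The first particle is chosen uniformly at random from ``seed`` (so that
    parallel runs with different seeds consume independent portions of the
    store) and subsequent particles are read sequentially with wraparound.
    An optional radius pre-filter ``r_max`` silently discards particles whose
    lateral radius exceeds the largest collimator opening; discarded
    particles still count toward ``n_read``.
    """

    def __init__(self, store: PhaseSpaceStore, seed: int, r_max: float | None = None):
        if len(store) == 0:
            raise ValueError("cannot read from an empty store")
        self.store = store
        self.seed = int(seed)
        self.r_max = None if r_max is None else float(r_max)
        rng = np.random.default_rng(self.seed)
        self.start_index = int(rng.integers(len(store)))
        self._rebuild()
        self.n_delivered = 0
        self._warned_wrap = False

    def _rebuild(self) -> None:
        n = len(self.store)
        cyc = (self.start_index + np.arange(n)) % n
        if self.r_max is None:
            good = np.arange(n)
        else:
            mask = self.store.radius[cyc] <= self.r_max
            good = np.flatnonzero(mask)
        if good.size == 0:
            # detected lazily on first take() so construction stays cheap
            self._good_pos = good
        self._good_pos = good          # positions within the cyclic order
        self._cyc = cyc

    def set_r_max(self, r_max: float | None) -> None:
        if self.n_delivered:
            raise RuntimeError("cannot change r_max after reading has begun")
        self.r_max = None if r_max is None else float(r_max)
        self._rebuild()

    # counters ----------------------------------------------------------
    @property
    def n_read(self) -> int:
        """Particles examined so far, including radius-rejected ones."""
        return self._n_read_for(self.n_delivered)

    def _n_read_for(self, m: int) -> int:
        n = len(self.store)
        ng = self._good_pos.size
        if m == 0:
            return 0
        full = (m - 1) // ng          # completed cycles before the last delivery
        rem = m - full * ng           # deliveries within the current cycle, >= 1
        return full * n + int(self._good_pos[rem - 1]) + 1

    @property
    def wrapped(self) -> bool:
        return self.n_read >= len(self.store)

    @property
    def cursor(self) -> int:
        return int(self._cyc[self.n_read % len(self.store)])

    # reading -----------------------------------------------------------
    def take(self, k: int) -> PhaseSpaceStore:
        """Deliver the next ``k`` particles passing the radius filter."""
        if self._good_pos.size == 0:
            raise PhaseSpaceExhausted(
                f"r_max={self.r_max} cm excludes every particle in the store")
        n = len(self.store)
        ng = self._good_pos.size
        m0 = self.n_delivered
        j = (np.arange(m0, m0 + k)) % ng
        idx = self._cyc[self._good_pos[j]]
        self.n_delivered += int(k)
        if self.wrapped and not self._warned_wrap:
            log.warning("phase-space store wrapped: particles are being "
                        "recycled a second time (latent variance grows)")
            self._warned_wrap = True
        return self.store.select(idx)

    def next_particle(self) -> Particle:
        return self.take(1).particle(0)

    def rollback(self, k: int) -> None:
        """Un-deliver the last ``k`` particles (used when a vectorized
        consumer over-reads past an exact-count target)."""
        if k > self.n_delivered:
            raise ValueError("cannot roll back past the beginning")
        self.n_delivered -= int(k)
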