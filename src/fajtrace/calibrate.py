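"""Absolute dose conversion and monitor-backscatter (Sb) weighting.

Monte Carlo dose comes out in relative units of Gy per primary history.
Conversion to Gy for a delivered number of monitor units MU follows the
SAD-calibration relation

    D' = Do * TMR(dref, 10x10) * Dcal(dmax, 10x10) / DMC(dref, 10x10) * MU * Sb

where Dcal is the clinic calibration dose per MU at dmax for a 10x10 cm
field (SSD 90, dref = 10 cm), TMR carries it to the reference depth, DMC is
the simulated reference dose per history at dref for the same setup, and Sb
corrects for radiation backscattered from the jaws into the monitor chamber
— an effect a collimator model without jaw scatter cannot produce, so Sb
comes from a measurement-based lookup table indexed by jaw opening.

For dynamic deliveries Sb is MU-weighted: IMRT fields average Sb over
control-point segments weighted by each segment's fractional MU; VMAT arcs
apply a separate Sb to each per-control-point-pair sub-field.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .dose import DoseGrid
from .plan import Beam


class SbTable:
    """Bilinear Sb lookup on an (X field size, Y field size) grid, cm at
    isocenter, normalized so Sb(10, 10) = 1 in the shipped fixture."""

    def __init__(self, x_sizes, y_sizes, values):
        self.x_sizes = np.asarray(x_sizes, dtype=float)
        self.y_sizes = np.asarray(y_sizes, dtype=float)
        self.values = np.asarray(values, dtype=float)
        if self.values.shape != (self.x_sizes.size, self.y_sizes.size):
            raise ValueError("Sb grid shape mismatch")
        if np.any(self.values <= 0):
            raise ValueError("Sb values must be > 0")
        self._interp = RegularGridInterpolator(
            (self.x_sizes, self.y_sizes), self.values, method="linear",
            bounds_error=False, fill_value=None)

    @classmethod
    def from_csv(cls, path_or_file) -> "SbTable":
        rows = []
        header = None
        if isinstance(path_or_file, (str, Path)):
            lines = Path(path_or_file).read_text().splitlines()
        elif hasattr(path_or_file, "read_text"):
            lines = path_or_file.read_text().splitlines()
        else:
            lines = path_or_file.read().splitlines()
        for line in lines:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(",")
            if header is None:
                header = [float(v) for v in parts[1:]]
            else:
                rows.append([float(v) for v in parts])
        arr = np.array(rows)
        return cls(arr[:, 0], header, arr[:, 1:])


def default_sb_table() -> SbTable:
    return SbTable.from_csv(resources.files("fajtrace.data").joinpath("sb_table.csv"))


def sb_lookup(table: SbTable, x_size: float, y_size: float) -> float:
    """Bilinear interpolation of Sb at the given jaw opening; queries
    outside the table hull are clamped to the edge."""
    if x_size <= 0 or y_size <= 0:
        raise ValueError("field sizes must be > 0")
    xq = float(np.clip(x_size, table.x_sizes[0], table.x_sizes[-1]))
    yq = float(np.clip(y_size, table.y_sizes[0], table.y_sizes[-1]))
    return float(table._interp((xq, yq)))


def _segment_sb(beam: Beam, table: SbTable, node_mode: bool):
    """Per-segment (deltaMU, Sb) pairs.  The aperture entering the lookup is
    the segment-midpoint jaw opening by default (consistent with linear
    interpolation of jaws in MU); ``node_mode`` uses the leading node."""
    mu = beam.mu_cum
    jaws = np.array([cp.jaws for cp in beam.control_points])
    dmu = np.diff(mu)
    if node_mode:
        j = jaws[:-1]
    else:
        j = 0.5 * (jaws[:-1] + jaws[1:])
    sb = np.array([sb_lookup(table, x2 - x1, y2 - y1) for x1, x2, y1, y2 in j])
    return dmu, sb


def sb_weighted_imrt(beam: Beam, table: SbTable, node_mode: bool = False) -> float:
    """MU-weighted average Sb over control-point segments:
    Sb = sum_i dMU_i Sb_i / sum_i dMU_i."""
    if len(beam.control_points) < 2:
        raise ValueError("need >= 2 control points")
    dmu, sb = _segment_sb(beam, table, node_mode)
    total = dmu.sum()
    if total <= 0:
        raise ValueError("zero total MU")
    return float(np.sum(dmu * sb) / total)


def sb_per_subfield(subfields, table: SbTable, node_mode: bool = False) -> list:
    """One Sb per VMAT sub-field via its (narrow) MU-weighted aperture."""
    return [sb_weighted_imrt(sf, table, node_mode) for sf in subfields]


@dataclass
class CalibrationConfig:
    """Clinic calibration constants for the absolute-dose relation.

    ``dcal``: Gy per MU at dmax for 10x10 (machine calibration);
    ``dref``: reference depth, cm;
    ``tmr_ref``: TMR(dref, 10x10);
    ``dmc_ref``: simulated Gy per primary-history-equivalent at dref for the
    10x10 reference setup (ties the MC normalization to the calibration).
    """
    dcal: float = 0.01
    dref: float = 10.0
    tmr_ref: float = 0.739
    dmc_ref: float = 1.0

    def __post_init__(self):
        if self.dcal <= 0 or self.dmc_ref <= 0:
            raise ValueError("dcal and dmc_ref must be > 0")
        if not 0 < self.tmr_ref <= 1.2:
            raise ValueError("tmr_ref out of range (0, 1.2]")


def load_tmr_table(path_or_file=None):
    """Load a TMR(depth, equivalent square) CSV table; returns
    (depths, eq_squares, values).  Only the (dref, 10x10) entry enters the
    conversion but the full table is kept for future use."""
    if path_or_file is None:
        path_or_file = resources.files("fajtrace.data").joinpath("tmr.csv")
    lines = (Path(path_or_file).read_text().splitlines()
             if isinstance(path_or_file, (str, Path)) else
             path_or_file.read_text().splitlines())
    header, rows = None, []
    for line in lines:
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split(",")
        if header is None:
            header = [float(v) for v in parts[1:]]
        else:
            rows.append([float(v) for v in parts])
    arr = np.array(rows)
    return arr[:, 0], np.array(header), arr[:, 1:]


def default_calibration(dmc_ref: float = 1.0) -> CalibrationConfig:
    depths, sizes, tmr = load_tmr_table()
    i = int(np.argmin(np.abs(depths - 10.0)))
    j = int(np.argmin(np.abs(sizes - 10.0)))
    return CalibrationConfig(dcal=0.01, dref=10.0, tmr_ref=float(tmr[i, j]),
                             dmc_ref=dmc_ref)


def to_gray(do: DoseGrid, calib: CalibrationConfig, mu: float, sb: float = 1.0) -> DoseGrid:
    """Apply the absolute-dose relation voxelwise; the variance scales by
    the square of the (deterministic) conversion constant."""
    if mu <= 0:
        raise ValueError("MU must be > 0")
    k = calib.tmr_ref * calib.dcal / calib.dmc_ref * mu * sb
    return DoseGrid(do.dose * k, do.variance * k ** 2,
                    do.n_histories_equivalent, do.voxel_size, do.origin)
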