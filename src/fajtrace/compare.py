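"""3D dose-comparison stack: gamma index, chi index, RMSD, isodose bands.

All metrics use the global percent-of-maximum convention: the dose tolerance
is a percent of the maximum *reference* dose, and voxels below a percent
threshold of that maximum are excluded from evaluation.  (A local-difference
gamma mode is available behind a flag.)

The gamma search is restricted, per reference voxel, to evaluation points
whose pure distance term cannot beat the current best — an exact pruning, so
the result equals exhaustive brute force.  No sub-voxel interpolation is
performed (voxel-center search only), a conservative bias that keeps the
pruned search exactly equivalent to its brute-force oracle.

The chi index is the standard gradient-weighted signed dose difference

    chi = (D_eval - D_ref) / sqrt((tol * Dmax)^2 + dta^2 * |grad D_ref|^2)

with the reference gradient from central differences; it coincides with
gamma's value on zero-gradient fields and is less susceptible to statistical
noise than the minimum-search gamma.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .dose import DoseGrid


@dataclass
class ComparisonCriteria:
    dose_tol: float = 2.0       # percent of global max reference dose
    dta: float = 2.0            # mm, distance to agreement
    threshold: float = 10.0     # percent of max reference dose
    bands: tuple | None = None  # descending band edges in percent, e.g. (80, 40, 20)
    local: bool = False         # local (per-voxel) dose-difference normalization

    def __post_init__(self):
        if self.dose_tol <= 0 or self.dta <= 0:
            raise ValueError("dose_tol and dta must be > 0")
        if not 0 <= self.threshold < 100:
            raise ValueError("threshold must lie in [0, 100)")


@dataclass
class ComparisonResult:
    gamma_pass: float
    chi_pass: float
    rmsd: float
    n_voxels_evaluated: int
    per_band: dict | None = None


def _as_array(grid):
    if isinstance(grid, DoseGrid):
        return grid.dose, tuple(10.0 * s for s in grid.voxel_size)  # cm -> mm
    raise TypeError("expected a DoseGrid")


@njit(cache=False)
def _gamma_kernel(ref, ev, eval_mask, off, off_dist2, tol_abs, dta, local, out):
    nx, ny, nz = ref.shape
    inv_dta2 = 1.0 / (dta * dta)
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                if not eval_mask[i, j, k]:
                    out[i, j, k] = -1.0
                    continue
                denom = tol_abs if not local else max(tol_abs * ref[i, j, k], 1e-300)
                dd = (ev[i, j, k] - ref[i, j, k]) / denom
                best = dd * dd
                for m in range(off.shape[0]):
                    dist_term = off_dist2[m] * inv_dta2
                    if dist_term >= best:
                        break
                    ii = i + off[m, 0]
                    jj = j + off[m, 1]
                    kk = k + off[m, 2]
                    if ii < 0 or ii >= nx or jj < 0 or jj >= ny or kk < 0 or kk >= nz:
                        continue
                    dd = (ev[ii, jj, kk] - ref[i, j, k]) / denom
                    g2 = dd * dd + dist_term
                    if g2 < best:
                        best = g2
                out[i, j, k] = np.sqrt(best)


def _sorted_offsets(shape, spacing_mm, max_dist_mm):
    """Integer voxel offsets (excluding zero) sorted by physical distance,
    limited to ``max_dist_mm``."""
    rng = []
    for n, s in zip(shape, spacing_mm):
        m = min(n - 1, int(np.floor(max_dist_mm / s)))
        rng.append(np.arange(-m, m + 1))
    oi, oj, ok = np.meshgrid(*rng, indexing="ij")
    off = np.column_stack([oi.ravel(), oj.ravel(), ok.ravel()])
    d2 = (off.astype(float) * np.asarray(spacing_mm)) ** 2
    d2 = d2.sum(axis=1)
    keep = (d2 > 0) & (d2 <= max_dist_mm ** 2)
    off, d2 = off[keep], d2[keep]
    order = np.argsort(d2, kind="stable")
    return np.ascontiguousarray(off[order].astype(np.int64)), np.ascontiguousarray(d2[order])


def _prep(reference, evaluation, criteria):
    ref, spacing = _as_array(reference)
    ev, spacing_e = _as_array(evaluation)
    if ref.shape != ev.shape or not np.allclose(spacing, spacing_e):
        raise ValueError("reference and evaluation grids must share a lattice")
    dmax = float(ref.max())
    if dmax <= 0:
        raise ValueError("reference dose is all zero")
    mask = ref > criteria.threshold / 100.0 * dmax
    if not mask.any():
        raise ValueError("empty evaluation set: all voxels below threshold")
    return ref, ev, spacing, dmax, mask


def gamma3d(reference, evaluation, criteria: ComparisonCriteria):
    """Gamma index per reference voxel above threshold.

    Returns ``(gamma, pass_rate)`` where ``gamma`` is -1 at excluded voxels
    and the pass rate is the percentage of evaluated voxels with gamma <= 1.
    """
    ref, ev, spacing, dmax, mask = _prep(reference, evaluation, criteria)
    tol_abs = criteria.dose_tol / 100.0 * dmax
    # a search beyond best_init * dta cannot win: distance term alone exceeds it
    if criteria.local:
        denom = np.maximum(criteria.dose_tol / 100.0 * ref[mask], 1e-300)
        best_init = np.max(np.abs(ev[mask] - ref[mask]) / denom)
    else:
        best_init = np.max(np.abs(ev[mask] - ref[mask])) / tol_abs
    max_dist = max(criteria.dta * best_init, 1e-9)
    diag = np.sqrt(sum((n * s) ** 2 for n, s in zip(ref.shape, spacing)))
    off, d2 = _sorted_offsets(ref.shape, spacing, min(max_dist, diag))
    out = np.empty_like(ref)
    _gamma_kernel(ref, ev, mask, off, d2, tol_abs, criteria.dta,
                  criteria.local, out)
    evaluated = out[mask]
    pass_rate = 100.0 * np.count_nonzero(evaluated <= 1.0) / evaluated.size
    return out, float(pass_rate)


def chi3d(reference, evaluation, criteria: ComparisonCriteria):
    """Signed gradient-weighted dose difference per voxel above threshold."""
    ref, ev, spacing, dmax, mask = _prep(reference, evaluation, criteria)
    tol_abs = criteria.dose_tol / 100.0 * dmax
    grads = np.gradient(ref, *spacing)
    gmag2 = sum(g ** 2 for g in grads)
    chi = (ev - ref) / np.sqrt(tol_abs ** 2 + criteria.dta ** 2 * gmag2)
    chi = np.where(mask, chi, np.nan)
    evaluated = chi[mask]
    pass_rate = 100.0 * np.count_nonzero(np.abs(evaluated) <= 1.0) / evaluated.size
    return chi, float(pass_rate)


def rmsd_percent(reference, evaluation, threshold: float = 10.0) -> float:
    """Root-mean-square deviation over voxels above threshold, as percent of
    the maximum reference dose."""
    crit = ComparisonCriteria(threshold=threshold)
    ref, ev, _, dmax, mask = _prep(reference, evaluation, crit)
    return float(np.sqrt(np.mean((ev[mask] - ref[mask]) ** 2)) / dmax * 100.0)


def compare(reference, evaluation, criteria: ComparisonCriteria) -> ComparisonResult:
    """Full comparison: gamma, chi, RMSD and optional per-band breakdown."""
    gamma, gpass = gamma3d(reference, evaluation, criteria)
    chi, cpass = chi3d(reference, evaluation, criteria)
    rmsd = rmsd_percent(reference, evaluation, criteria.threshold)
    ref, _, _, dmax, mask = _prep(reference, evaluation, criteria)
    n_eval = int(mask.sum())
    per_band = None
    if criteria.bands:
        per_band = band_report(reference, evaluation, criteria,
                               _gamma=gamma, _chi=chi)
    return ComparisonResult(gpass, cpass, rmsd, n_eval, per_band)


def band_report(reference, evaluation, criteria: ComparisonCriteria,
                _gamma=None, _chi=None) -> dict:
    """Gamma/chi pass rates within isodose bands of the reference dose.

    ``criteria.bands`` gives descending edges in percent of maximum, e.g.
    (80, 40, 20) produces bands '>80', '40-80' and '20-40'.
    """
    if not criteria.bands:
        raise ValueError("criteria.bands must be set")
    edges = tuple(criteria.bands)
    if any(a <= b for a, b in zip(edges, edges[1:])):
        raise ValueError("bands must be strictly descending")
    ref, _ = _as_array(reference)
    dmax = float(ref.max())
    if _gamma is None:
        _gamma, _ = gamma3d(reference, evaluation, criteria)
    if _chi is None:
        _chi, _ = chi3d(reference, evaluation, criteria)
    pct = ref / dmax * 100.0
    report = {}
    bounds = [(edges[0], np.inf)] + [(lo, hi) for hi, lo in zip(edges, edges[1:])]
    labels = [f">{edges[0]:g}"] + [f"{lo:g}-{hi:g}" for hi, lo in zip(edges, edges[1:])]
    for label, (lo, hi) in zip(labels, bounds):
        m = (pct > lo) & (pct <= hi) if np.isfinite(hi) else pct > lo
        n = int(m.sum())
        if n == 0:
            report[label] = ComparisonResult(np.nan, np.nan, np.nan, 0)
            continue
        g = _gamma[m]
        g = g[g >= 0]
        c = _chi[m]
        c = c[~np.isnan(c)]
        gp = 100.0 * np.count_nonzero(g <= 1.0) / g.size if g.size else np.nan
        cp = 100.0 * np.count_nonzero(np.abs(c) <= 1.0) / c.size if c.size else np.nan
        ev, _ = _as_array(evaluation)
        rmsd = float(np.sqrt(np.mean((ev[m] - ref[m]) ** 2)) / dmax * 100.0)
        report[label] = ComparisonResult(gp, cp, rmsd, n)
    return report
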