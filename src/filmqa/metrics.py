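"""Dose-comparison statistics for film QA.

Implements the comparison chain applied to a measured (film) and a
calculated dose image on the common grid: relative normalization against
the median dose in the center of the high-dose region, a bounded rigid
shift correction, global gamma analysis (default 2% / 2 mm), voxel-wise
dose deviation, distance to agreement (DTA) within a local dose tolerance,
center dose profiles in percentage points, and ionization-chamber point
comparison against a sphere-averaged calculated dose.

Conventions
-----------
* The measured film is the *reference* distribution; the calculated dose is
  the *evaluated* (searched) distribution.
* Global gamma: the dose tolerance is a fraction of the normalization dose
  (1.0 in relative units), not of each local dose.  The DTA tolerance alone
  is local (0.5% of the local reference dose).
* Threshold doses (10% / 90%) are fractions of D_max of the calculated
  relative plane by default (configurable via ``dmax_source``).
* The evaluated distribution is interpolated bilinearly on a fine lattice
  whose pitch is the requested subsample rounded to an integer divisor of
  the grid spacing, so displacement candidates land exactly on lattice
  nodes.
* Voxels flagged invalid upstream are excluded from every statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import (ConsistencyError, DomainError, ExtentError,
                     NormalizationError, SpecError)
from .grids import DoseGrid3D, DosePlane2D, same_geometry


@dataclass
class GammaCriteria:
    dose_tol: float = 0.02          # fraction of the normalization dose (global)
    dist_tol: float = 2.0           # mm
    search_radius: float = 6.0      # mm, cap on the displacement search
    eval_subsample: float = 0.2     # mm, evaluated-grid interpolation pitch

    def __post_init__(self):
        if min(self.dose_tol, self.dist_tol, self.search_radius,
               self.eval_subsample) <= 0:
            raise SpecError("gamma criteria must be strictly positive")
        if self.search_radius < self.dist_tol:
            raise SpecError("search_radius must be >= dist_tol")


@dataclass
class AnalysisThresholds:
    low: float = 0.10
    high: float = 0.90

    def __post_init__(self):
        if not 0 < self.low < self.high <= 1:
            raise SpecError("thresholds must satisfy 0 < low < high <= 1")


@dataclass
class DtaSpec:
    local_tol: float = 0.005        # fraction of the local reference dose
    band: tuple = (0.10, 0.90)      # threshold window for summary statistics
    search_radius: float = 10.0     # mm cap; saturated voxels carry this value
    eval_subsample: float = 0.2     # mm

    def __post_init__(self):
        if self.local_tol <= 0 or self.search_radius <= 0 or self.eval_subsample <= 0:
            raise SpecError("DTA spec parameters must be strictly positive")


@dataclass
class ShiftSearchSpec:
    max_shift: float = 1.5          # mm per axis
    step: float = 0.1               # mm search pitch

    def __post_init__(self):
        if not 0 < self.step <= self.max_shift:
            raise SpecError("require 0 < step <= max_shift")


@dataclass
class ChamberSpec:
    position: np.ndarray = field(default_factory=lambda: np.zeros(3))
    radius: float = 3.0             # mm averaging sphere (0.3 cm)

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float).reshape(3)
        if self.radius <= 0:
            raise SpecError("chamber radius must be positive")


# ---------------------------------------------------------------------------
# helpers


def _require_common(measured: DosePlane2D, calculated: DosePlane2D,
                    relative: bool = True):
    if not same_geometry(measured, calculated):
        raise ConsistencyError("measured and calculated planes must share geometry")
    if relative and not (measured.is_relative and calculated.is_relative):
        raise ConsistencyError("comparison requires relative planes")
    if abs(measured.spacing[0] - measured.spacing[1]) > 1e-9:
        raise ConsistencyError("comparison requires an isotropic common grid")


def _fine_lattice(plane: DosePlane2D, subsample: float):
    """Bilinear upsampling of a plane onto a lattice aligned with its grid.

    Returns (fine array with NaN at invalid/out-of-support, refinement
    factor k, effective pitch).  The effective pitch is spacing/k with
    k = round(spacing/subsample) so that every coarse node is a fine node.
    """
    sp = float(plane.spacing[0])
    k = max(1, int(round(sp / subsample)))
    sub = sp / k
    n0, n1 = plane.shape
    src = plane.masked()
    if k == 1:
        return src.copy(), 1, sub
    f0 = np.arange((n0 - 1) * k + 1) / k          # in coarse-index units
    f1 = np.arange((n1 - 1) * k + 1) / k
    i0 = np.minimum(f0.astype(int), n0 - 2)
    j0 = np.minimum(f1.astype(int), n1 - 2)
    wi = (f0 - i0)[:, None]
    wj = (f1 - j0)[None, :]
    a = src[np.ix_(i0, j0)]
    b = src[np.ix_(i0 + 1, j0)]
    c = src[np.ix_(i0, j0 + 1)]
    d = src[np.ix_(i0 + 1, j0 + 1)]
    fine = (a * (1 - wi) * (1 - wj) + b * wi * (1 - wj)
            + c * (1 - wi) * wj + d * wi * wj)
    return fine, k, sub


def _disk_offsets(radius_mm: float, sub: float):
    """Integer lattice offsets within the search disk, sorted by distance
    (ties broken lexicographically for determinism)."""
    m = int(np.floor(radius_mm / sub + 1e-9))
    di, dj = np.meshgrid(np.arange(-m, m + 1), np.arange(-m, m + 1), indexing="ij")
    di, dj = di.ravel(), dj.ravel()
    r2 = (di * di + dj * dj) * sub * sub
    keep = r2 <= radius_mm**2 + 1e-9
    di, dj, r2 = di[keep], dj[keep], r2[keep]
    order = np.lexsort((dj, di, r2))
    return di[order], dj[order], r2[order]


def _shifted_values(fine, ii, jj, di, dj):
    """Evaluated values at reference nodes displaced by (di, dj) fine steps;
    NaN where the displaced node leaves the lattice."""
    si, sj = ii + di, jj + dj
    out = np.full(ii.shape, np.nan)
    inb = (si >= 0) & (si < fine.shape[0]) & (sj >= 0) & (sj < fine.shape[1])
    out[inb] = fine[si[inb], sj[inb]]
    return out


def _dmax(measured: DosePlane2D, calculated: DosePlane2D, dmax_source: str) -> float:
    plane = calculated if dmax_source == "calculated" else measured
    vals = plane.masked()
    if not np.isfinite(vals).any():
        raise DomainError("cannot determine D_max: no valid voxels")
    return float(np.nanmax(vals))


# ---------------------------------------------------------------------------
# operations


def locate_high_dose_center(plane: DosePlane2D) -> np.ndarray:
    """Centroid (mm) of the largest connected component of voxels >= 90% of
    the plane maximum — the package's construction of "the center of the
    high dose region"."""
    vals = plane.masked()
    if not np.isfinite(vals).any() or np.nanmax(vals) <= 0:
        raise DomainError("plane has no positive high-dose region")
    vmax = np.nanmax(vals)
    mask = np.where(np.isfinite(vals), vals >= 0.9 * vmax * (1 - 1e-12), False)
    labels, n = ndimage.label(mask)
    if n == 0:
        raise DomainError("empty high-dose region")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    largest = int(np.argmax(sizes)) + 1
    idx = np.argwhere(labels == largest)
    centroid_idx = idx.mean(axis=0)
    return plane.origin + centroid_idx * plane.spacing


def normalize_relative(plane: DosePlane2D, center=None,
                       radius_mm: float = 10.0) -> DosePlane2D:
    """Divide by the median dose within ``radius_mm`` of the high-dose
    center; marks the plane relative and records the normalization dose."""
    if center is None:
        center = locate_high_dose_center(plane)
    center = np.asarray(center, dtype=float).reshape(2)
    for ax in range(2):
        c = plane.coords(ax)
        if center[ax] - radius_mm < c[0] - 1e-9 or center[ax] + radius_mm > c[-1] + 1e-9:
            raise DomainError("normalization disk extends beyond the plane")
    cx = plane.coords(0)[:, None] - center[0]
    cy = plane.coords(1)[None, :] - center[1]
    disk = (cx * cx + cy * cy) <= radius_mm**2 + 1e-9
    sel = disk & plane.valid
    if not sel.any():
        raise DomainError("no valid voxels inside the normalization disk")
    med = float(np.median(plane.values[sel]))
    if med <= 0:
        raise NormalizationError(f"non-positive normalization dose {med}")
    norm_gy = med * (plane.norm_dose if plane.is_relative else 1.0)
    vals = plane.values / med
    vals = np.where(plane.valid, vals, np.nan)
    return DosePlane2D(vals, plane.spacing.copy(), plane.origin.copy(),
                       True, norm_gy, plane.valid.copy())


def optimize_shift(measured: DosePlane2D, calculated: DosePlane2D,
                   spec: ShiftSearchSpec | None = None,
                   thr: AnalysisThresholds | None = None,
                   dmax_source: str = "calculated"):
    """Bounded grid search for the residual setup/post-processing shift.

    Minimizes the mean squared relative dose difference over voxels above
    10% of D_max, over shifts up to ``max_shift`` per axis at ``step``
    pitch; the measured plane is shifted bilinearly.  Ties are broken in
    favour of the smallest |shift|.  Returns ``(shift_mm, shifted_measured)``
    with the convention ``shifted(r) = measured(r - shift)``.
    """
    spec = spec or ShiftSearchSpec()
    thr = thr or AnalysisThresholds()
    _require_common(measured, calculated)
    sp = float(measured.spacing[0])
    k = max(1, int(round(sp / spec.step)))
    sub = sp / k
    fine, k, sub = _fine_lattice(measured, spec.step)
    calc = calculated.masked()
    dmax = _dmax(measured, calculated, dmax_source)
    mask = calculated.valid & (calc >= thr.low * dmax)
    n0, n1 = measured.shape
    ii, jj = np.meshgrid(np.arange(n0) * k, np.arange(n1) * k, indexing="ij")
    m = int(np.floor(spec.max_shift / sub + 1e-9))
    cand = np.arange(-m, m + 1)
    best_obj, best_shift, best_vals = np.inf, None, None
    order = sorted(((di, dj) for di in cand for dj in cand),
                   key=lambda s: (s[0] * s[0] + s[1] * s[1], s[0], s[1]))
    for di, dj in order:
        # shifted(r) = measured(r - s) -> fine node index minus (di, dj)
        vals = _shifted_values(fine, ii, jj, -di, -dj)
        sel = mask & np.isfinite(vals) & np.isfinite(calc)
        if not sel.any():
            continue
        obj = float(np.mean((vals[sel] - calc[sel]) ** 2))
        if obj < best_obj - 1e-15:
            best_obj, best_shift, best_vals = obj, (di, dj), vals
    if best_shift is None:
        raise DomainError("no shift candidate leaves a usable overlap")
    shift_mm = np.array([best_shift[0] * sub, best_shift[1] * sub])
    shifted = DosePlane2D(best_vals, measured.spacing.copy(), measured.origin.copy(),
                          measured.is_relative, measured.norm_dose,
                          np.isfinite(best_vals))
    return shift_mm, shifted


def compute_gamma(measured: DosePlane2D, calculated: DosePlane2D,
                  crit: GammaCriteria | None = None,
                  thr: AnalysisThresholds | None = None,
                  dmax_source: str = "calculated"):
    """Global gamma analysis; measured film is the reference.

    gamma(r) = min over displacements |s| <= search_radius of
    sqrt(|s|^2/dist_tol^2 + (D_meas(r) - D_calc(r+s))^2 / (dose_tol*D_norm)^2)
    with the calculated plane interpolated bilinearly at ``eval_subsample``
    pitch.  Returns ``(gamma map, pass rates in % keyed by threshold)``.
    Displacements are enumerated by increasing distance with an early exit
    once the distance term alone exceeds every current best value.
    """
    crit = crit or GammaCriteria()
    thr = thr or AnalysisThresholds()
    _require_common(measured, calculated)
    ref = measured.masked()
    fine, k, sub = _fine_lattice(calculated, crit.eval_subsample)
    denom = crit.dose_tol * 1.0     # relative planes: D_norm = 1
    n0, n1 = measured.shape
    ii, jj = np.meshgrid(np.arange(n0) * k, np.arange(n1) * k, indexing="ij")
    di, dj, r2 = _disk_offsets(crit.search_radius, sub)
    best = np.full(measured.shape, np.inf)
    relevant = measured.valid
    for a, b, rr in zip(di, dj, r2):
        dist2 = rr / crit.dist_tol**2
        cur = best[relevant]
        if cur.size and not np.any(np.isinf(cur)) and dist2 >= cur.max():
            break
        vals = _shifted_values(fine, ii, jj, int(a), int(b))
        g2 = dist2 + ((ref - vals) / denom) ** 2
        np.fmin(best, g2, out=best)
    gamma = np.sqrt(best)
    gamma[~relevant] = np.nan
    gamma[np.isinf(gamma)] = np.nan
    dmax = _dmax(measured, calculated, dmax_source)
    pass_rates = {}
    for t in (thr.low, thr.high):
        sel = np.isfinite(gamma) & np.where(np.isfinite(ref), ref >= t * dmax, False)
        pass_rates[t] = 100.0 * float(np.mean(gamma[sel] <= 1.0)) if sel.any() else np.nan
    return gamma, pass_rates


def compute_dose_deviation(measured: DosePlane2D, calculated: DosePlane2D,
                           thr: AnalysisThresholds | None = None,
                           dmax_source: str = "calculated"):
    """Voxel-wise dose difference in % of the normalization dose (no DTA
    correction): 100*(D_meas - D_calc).  Returns ``(map, {threshold:
    (mean, sd)})`` with statistics over voxels above each threshold."""
    thr = thr or AnalysisThresholds()
    _require_common(measured, calculated)
    ref, calc = measured.masked(), calculated.masked()
    dev = 100.0 * (ref - calc)
    dmax = _dmax(measured, calculated, dmax_source)
    stats = {}
    for t in (thr.low, thr.high):
        sel = np.isfinite(dev) & np.where(np.isfinite(ref), ref >= t * dmax, False)
        if sel.any():
            stats[t] = (float(np.mean(dev[sel])), float(np.std(dev[sel])))
        else:
            stats[t] = (np.nan, np.nan)
    return dev, stats


def compute_dta(measured: DosePlane2D, calculated: DosePlane2D,
                spec: DtaSpec | None = None,
                thr: AnalysisThresholds | None = None,
                dmax_source: str = "calculated"):
    """Distance to agreement within a local dose tolerance.

    For each reference voxel above the low threshold, the smallest
    displacement |s| <= search_radius with
    |D_calc(r+s) - D_meas(r)| <= local_tol * D_meas(r), found on the
    subsampled evaluated lattice by radially ordered search.  Voxels with no
    solution carry the cap value and a saturation flag.  Summary mean/SD is
    taken over the ``band`` threshold window (default 10%-90% of D_max).

    Returns ``(dta map, (mean, sd), saturated mask)``.
    """
    spec = spec or DtaSpec()
    thr = thr or AnalysisThresholds()
    _require_common(measured, calculated)
    ref = measured.masked()
    fine, k, sub = _fine_lattice(calculated, spec.eval_subsample)
    dmax = _dmax(measured, calculated, dmax_source)
    lo, hi = spec.band
    region = measured.valid & np.where(np.isfinite(ref), ref >= lo * dmax, False)
    tol = spec.local_tol * np.abs(ref)
    n0, n1 = measured.shape
    ii, jj = np.meshgrid(np.arange(n0) * k, np.arange(n1) * k, indexing="ij")
    di, dj, r2 = _disk_offsets(spec.search_radius, sub)
    dta = np.full(measured.shape, np.nan)
    unresolved = region.copy()
    for a, b, rr in zip(di, dj, r2):
        if not unresolved.any():
            break
        vals = _shifted_values(fine, ii, jj, int(a), int(b))
        hit = unresolved & (np.abs(vals - ref) <= tol)
        dta[hit] = np.sqrt(rr)
        unresolved &= ~hit
    saturated = unresolved
    dta[saturated] = spec.search_radius
    band = region & np.where(np.isfinite(ref), ref <= hi * dmax, False)
    if band.any():
        stats = (float(np.mean(dta[band])), float(np.std(dta[band])))
    else:
        stats = (np.nan, np.nan)
    return dta, stats, saturated


def extract_center_profiles(measured: DosePlane2D, calculated: DosePlane2D,
                            center) -> dict:
    """Inline and crossline profiles through the high-dose center, with
    differences in percentage points: 100*(measured - calculated)."""
    _require_common(measured, calculated, relative=False)
    center = np.asarray(center, dtype=float).reshape(2)
    idx = np.round((center - measured.origin) / measured.spacing).astype(int)
    if not (0 <= idx[0] < measured.shape[0] and 0 <= idx[1] < measured.shape[1]):
        raise DomainError(f"profile center {center} outside the plane")
    out = {}
    m, c = measured.masked(), calculated.masked()
    for name, (msel, csel, coord) in {
        "inline": (m[idx[0], :], c[idx[0], :], measured.coords(1)),
        "crossline": (m[:, idx[1]], c[:, idx[1]], measured.coords(0)),
    }.items():
        diff = 100.0 * (msel - csel)
        ok = np.isfinite(diff)
        out[name] = {
            "coord_mm": coord,
            "measured": msel,
            "calculated": csel,
            "diff_pp": diff,
            "mean_pp": float(np.mean(diff[ok])) if ok.any() else np.nan,
            "max_abs_pp": float(np.max(np.abs(diff[ok]))) if ok.any() else np.nan,
        }
    return out


def compare_chamber(measured_gy: float, grid: DoseGrid3D,
                    spec: ChamberSpec | None = None,
                    refine_mm: float = 0.5) -> float:
    """Chamber reading vs sphere-averaged calculated dose, in % of the
    calculated value.  The sphere mean is taken over a trilinearly refined
    sub-lattice (default 0.5 mm) restricted to the sphere."""
    spec = spec or ChamberSpec()
    c, r = spec.position, spec.radius
    for ax in range(3):
        lo, hi = grid.extent(ax)
        if c[ax] - r < lo - 1e-9 or c[ax] + r > hi + 1e-9:
            raise ExtentError("averaging sphere extends beyond the dose grid")
    off = np.arange(-r, r + 1e-9, refine_mm)
    px, py, pz = np.meshgrid(off, off, off, indexing="ij")
    pts = np.stack([px, py, pz], axis=-1).reshape(-1, 3)
    keep = np.sum(pts * pts, axis=1) <= r * r + 1e-9
    pts = pts[keep] + c
    vals = grid.interpolator()(pts)
    calc = float(np.mean(vals))
    if calc == 0:
        raise DomainError("calculated sphere mean dose is zero")
    return 100.0 * (measured_gy - calc) / calc


@dataclass
class ComparisonResult:
    """One Table-style QA row plus the underlying maps."""

    dataset_id: str
    gamma_map: np.ndarray
    deviation_map: np.ndarray
    dta_map: np.ndarray
    saturated: np.ndarray
    pass_rate_by_threshold: dict
    deviation_mean_sd: dict
    dta_mean_sd: tuple
    applied_shift: np.ndarray
    norm_dose_measured: float
    norm_dose_calculated: float
    excluded_voxels: int = 0
    chamber_diff_pct: float | None = None

    def to_row(self) -> dict:
        th = sorted(self.pass_rate_by_threshold)
        lo, hi = th[0], th[-1]
        return {
            "dataset": self.dataset_id,
            f"gamma_pass_{int(100*lo)}_pct": self.pass_rate_by_threshold[lo],
            f"gamma_pass_{int(100*hi)}_pct": self.pass_rate_by_threshold[hi],
            f"dev_mean_{int(100*lo)}_pct": self.deviation_mean_sd[lo][0],
            f"dev_sd_{int(100*lo)}_pct": self.deviation_mean_sd[lo][1],
            f"dev_mean_{int(100*hi)}_pct": self.deviation_mean_sd[hi][0],
            f"dev_sd_{int(100*hi)}_pct": self.deviation_mean_sd[hi][1],
            "dta_mean_mm": self.dta_mean_sd[0],
            "dta_sd_mm": self.dta_mean_sd[1],
            "shift_crossline_mm": float(self.applied_shift[0]),
            "shift_inline_mm": float(self.applied_shift[1]),
            "norm_dose_measured_gy": self.norm_dose_measured,
            "norm_dose_calculated_gy": self.norm_dose_calculated,
            "chamber_diff_pct": self.chamber_diff_pct,
        }


def summarize_comparison(dataset_id: str, gamma_map, pass_rates, deviation_map,
                         deviation_stats, dta_map, dta_stats, saturated,
                         applied_shift, norm_dose_measured, norm_dose_calculated,
                         excluded_voxels: int = 0,
                         chamber_diff_pct: float | None = None) -> ComparisonResult:
    """Assemble the per-dataset summary row; all maps must share geometry."""
    shapes = {np.asarray(m).shape for m in (gamma_map, deviation_map, dta_map, saturated)}
    if len(shapes) != 1:
        raise ConsistencyError(f"component maps disagree in shape: {shapes}")
    return ComparisonResult(
        dataset_id, np.asarray(gamma_map), np.asarray(deviation_map),
        np.asarray(dta_map), np.asarray(saturated), dict(pass_rates),
        dict(deviation_stats), tuple(dta_stats),
        np.asarray(applied_shift, dtype=float).reshape(2),
        float(norm_dose_measured), float(norm_dose_calculated),
        int(excluded_voxels), chamber_diff_pct,
    )
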