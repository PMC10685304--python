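"""Radiochromic film dosimetry: calibration, daily rescaling, conversion,
and landmark-based scanner registration.

The film response is assumed already netted against the unexposed base
value, so it decreases strictly monotonically with dose.  Dose is fitted as
a rational function of net response,

    dose(x) = (a + b x) / (1 + c x),

the standard functional form for radiochromic film calibration; a monotone
piecewise-cubic (PCHIP) interpolant is available as a fallback.  Day-to-day
response drift is corrected by scaling the batch calibration curve against
three to five daily correction films scanned together with the measurement
films.  The default correction is a single multiplicative factor on the
dose axis; a response-axis variant is available via ``mode="response"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import PchipInterpolator, RegularGridInterpolator
from scipy.optimize import least_squares, minimize_scalar

from .errors import (CalibrationError, ConversionError, DesignError, DomainError,
                     FitError, GeometryError)
from .grids import CommonGridSpec, DosePlane2D


@dataclass
class FilmScan:
    """A scanned film image: net response on a square-pixel scanner grid.

    ``response[i, j]`` sits at scanner coordinates
    ``origin + spacing * (i, j)``;  ``landmarks`` are the three detected
    cassette-pin positions (mm, scanner frame).
    """

    response: np.ndarray
    spacing: float
    landmarks: np.ndarray
    origin: np.ndarray = field(default_factory=lambda: np.zeros(2))
    valid: np.ndarray | None = None

    def __post_init__(self):
        self.response = np.asarray(self.response, dtype=float)
        if self.response.ndim != 2:
            raise DomainError("FilmScan response must be a 2D array")
        self.spacing = float(self.spacing)
        if self.spacing <= 0:
            raise DomainError("scan pitch must be positive")
        self.origin = np.asarray(self.origin, dtype=float).reshape(2)
        lm = np.asarray(self.landmarks, dtype=float)
        if lm.shape != (3, 2):
            raise GeometryError("FilmScan requires exactly three 2D landmarks")
        _check_noncollinear(lm, "scan landmarks")
        self.landmarks = lm
        if self.valid is None:
            self.valid = np.isfinite(self.response)
        else:
            self.valid = np.asarray(self.valid, dtype=bool) & np.isfinite(self.response)
        if np.any(self.response[self.valid] < -1e-9):
            raise DomainError("net film response must be non-negative")

    def coords(self, axis: int) -> np.ndarray:
        return self.origin[axis] + self.spacing * np.arange(self.response.shape[axis])


def _check_noncollinear(pts: np.ndarray, what: str, tol: float = 1e-6):
    if len(np.unique(pts.round(9), axis=0)) != len(pts):
        raise GeometryError(f"{what}: duplicate points")
    e1, e2 = pts[1] - pts[0], pts[2] - pts[0]
    area = e1[0] * e2[1] - e1[1] * e2[0]
    if abs(area) < tol:
        raise GeometryError(f"{what}: points are collinear")


@dataclass
class CalibrationDesign:
    """Batch/daily calibration layout: 20-point batch curve, 3-5 daily films."""

    n_points: int = 20
    daily_range: tuple = (0.0, 10.0)
    n_daily: int = 4

    def __post_init__(self):
        if not 3 <= self.n_daily <= 5:
            raise DesignError("n_daily must be between 3 and 5")
        if self.n_points < 4:
            raise DesignError("batch calibration needs at least 4 points")
        lo, hi = self.daily_range
        if not hi > lo >= 0:
            raise DesignError("daily_range must be an increasing dose interval")


@dataclass
class CalibrationCurve:
    """Fitted monotone response->dose mapping with a daily scale factor.

    ``dose_from_response`` applies ``daily_scale * f(daily_response_scale*x)``
    where ``f`` is the fitted batch curve.
    """

    points: np.ndarray                     # (n, 2) columns: dose_gy, response
    params: tuple                          # (a, b, c) of the rational form
    daily_scale: float = 1.0
    daily_response_scale: float = 1.0
    form: str = "rational"
    residual_rms: float = 0.0
    _pchip: object = None

    def __post_init__(self):
        if self.daily_scale <= 0 or self.daily_response_scale <= 0:
            raise CalibrationError("daily scale factors must be positive")

    # --- batch curve (no daily correction) ---
    def base_dose(self, response):
        x = np.asarray(response, dtype=float)
        if self.form == "rational":
            a, b, c = self.params
            return (a + b * x) / (1.0 + c * x)
        return self._pchip(x)

    def base_response(self, dose):
        d = np.asarray(dose, dtype=float)
        if self.form == "rational":
            a, b, c = self.params
            return (a - d) / (c * d - b)
        lo, hi = self.response_range
        from scipy.optimize import brentq
        return np.vectorize(lambda dd: brentq(lambda x: self._pchip(x) - dd, lo, hi))(d)

    # --- scaled curve ---
    def dose_from_response(self, response):
        return self.daily_scale * self.base_dose(
            np.asarray(response, dtype=float) * self.daily_response_scale)

    def response_from_dose(self, dose):
        return self.base_response(np.asarray(dose, dtype=float) / self.daily_scale) \
            / self.daily_response_scale

    @property
    def dose_range(self):
        d = self.points[:, 0]
        return float(d.min()), float(d.max())

    @property
    def response_range(self):
        r = self.points[:, 1]
        return float(r.min()), float(r.max())

    def check_monotone(self, n: int = 512) -> bool:
        lo, hi = self.response_range
        x = np.linspace(lo, hi, n)
        d = self.base_dose(x)
        steps = np.diff(d)
        return bool(np.all(steps < 0) or np.all(steps > 0))


def fit_calibration_curve(points, form: str = "rational") -> CalibrationCurve:
    """Fit the monotone calibration mapping to (dose Gy, net response) pairs.

    Rational-form fitting: the relation ``d (1 + c x) = a + b x`` is linear
    in (a, b, c), solved by least squares and refined by Levenberg-Marquardt
    on the dose residuals.  Raises ``CalibrationError`` if the responses are
    not strictly monotone in dose and ``FitError`` on rank deficiency.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 4:
        raise CalibrationError("need at least 4 (dose, response) pairs")
    order = np.argsort(pts[:, 0])
    pts = pts[order]
    d, x = pts[:, 0], pts[:, 1]
    if np.any(np.diff(d) <= 0):
        raise CalibrationError("calibration doses must be distinct")
    steps = np.diff(x)
    if not (np.all(steps < 0) or np.all(steps > 0)):
        raise CalibrationError("calibration responses are not strictly monotone in dose")

    if form == "pchip":
        xs = np.argsort(x)
        interp = PchipInterpolator(x[xs], d[xs])
        curve = CalibrationCurve(pts, (), form="pchip", _pchip=interp)
        curve.residual_rms = 0.0
        return curve
    if form != "rational":
        raise DomainError(f"unknown calibration form {form!r}")

    design = np.column_stack([np.ones_like(x), x, -x * d])
    sol, _, rank, _ = np.linalg.lstsq(design, d, rcond=None)
    if rank < 3:
        raise FitError("rank-deficient calibration fit")

    def residuals(p):
        a, b, c = p
        return (a + b * x) / (1.0 + c * x) - d

    refined = least_squares(residuals, sol, method="lm")
    if not refined.success:
        raise FitError(f"calibration refinement failed: {refined.message}")
    curve = CalibrationCurve(pts, tuple(refined.x))
    curve.residual_rms = float(np.sqrt(np.mean(residuals(refined.x) ** 2)))
    if not curve.check_monotone():
        raise FitError("fitted calibration curve is not monotone over its range")
    return curve


def rescale_daily(curve: CalibrationCurve, daily_points, mode: str = "dose") -> CalibrationCurve:
    """Scale the batch curve against 3-5 daily correction films.

    ``mode="dose"`` (default): find the single factor ``s`` minimizing
    ``sum_i (D_i - s * f(x_i))^2`` (closed form).  ``mode="response"``:
    scale the response axis instead.  Returns a new curve; the batch fit is
    untouched.
    """
    pts = np.asarray(daily_points, dtype=float).reshape(-1, 2)
    if not 3 <= len(pts) <= 5:
        raise DesignError(f"daily correction requires 3-5 films, got {len(pts)}")
    dlo, dhi = curve.dose_range
    span = dhi - dlo
    if np.any(pts[:, 0] < dlo - 0.05 * span) or np.any(pts[:, 0] > dhi + 0.05 * span):
        raise DesignError("daily film doses fall outside the batch calibration range")
    d, x = pts[:, 0], pts[:, 1]
    if mode == "dose":
        f = curve.base_dose(x)
        denom = float(np.sum(f * f))
        if denom <= 0:
            raise DesignError("daily films carry no usable dose signal")
        s = float(np.sum(d * f) / denom)
        if s <= 0:
            raise DesignError("non-positive daily scale factor")
        new = CalibrationCurve(curve.points, curve.params, s, 1.0,
                               curve.form, curve.residual_rms, curve._pchip)
        return new
    if mode == "response":
        def cost(t):
            return float(np.sum((curve.base_dose(x * t) - d) ** 2))
        res = minimize_scalar(cost, bounds=(0.5, 2.0), method="bounded",
                              options={"xatol": 1e-10})
        new = CalibrationCurve(curve.points, curve.params, 1.0, float(res.x),
                               curve.form, curve.residual_rms, curve._pchip)
        return new
    raise DomainError(f"unknown daily rescale mode {mode!r}")


def convert_response_to_dose(scan: FilmScan, curve: CalibrationCurve,
                             range_tol: float = 0.02,
                             max_out_of_range: float = 0.05) -> DosePlane2D:
    """Apply the scaled calibration curve pixel-wise; returns absolute Gy.

    Pixels whose response falls outside the calibrated range (widened by
    ``range_tol`` of the response span) are flagged invalid; if more than
    ``max_out_of_range`` of previously valid pixels are out of range a
    ``ConversionError`` is raised.
    """
    rlo, rhi = curve.response_range
    band = range_tol * (rhi - rlo)
    x = np.asarray(scan.response, dtype=float) * curve.daily_response_scale
    in_range = (x >= rlo - band) & (x <= rhi + band)
    usable = scan.valid
    n_usable = int(usable.sum())
    if n_usable == 0:
        raise ConversionError("film scan has no valid pixels")
    frac_out = 1.0 - in_range[usable].mean()
    if frac_out > max_out_of_range:
        raise ConversionError(
            f"{100*frac_out:.1f}% of film pixels outside the calibrated response range")
    dose = curve.daily_scale * curve.base_dose(np.clip(x, rlo, rhi))
    valid = usable & in_range
    dose = np.where(valid, dose, np.nan)
    return DosePlane2D(dose, np.array([scan.spacing, scan.spacing]),
                       scan.origin.copy(), False, None, valid)


def save_film_tiff(path, scan: FilmScan):
    """Write a scan as 16-bit TIFF plus a JSON sidecar (spacing, origin,
    landmarks, quantization scale).  Invalid pixels are stored as 0 and
    restored from the sidecar-free mask on load (response 0 stays valid)."""
    import json
    from pathlib import Path

    import tifffile

    path = Path(path).with_suffix(".tif")
    rmax = float(np.nanmax(scan.response[scan.valid])) if scan.valid.any() else 1.0
    scale = rmax / 65535.0 if rmax > 0 else 1.0
    img = np.zeros(scan.response.shape, dtype=np.uint16)
    img[scan.valid] = np.round(scan.response[scan.valid] / scale).astype(np.uint16)
    tifffile.imwrite(path, img)
    meta = {"spacing": scan.spacing, "origin": scan.origin.tolist(),
            "landmarks": scan.landmarks.tolist(), "response_scale": scale,
            "invalid": np.argwhere(~scan.valid).tolist()}
    path.with_suffix(".json").write_text(json.dumps(meta, sort_keys=True))
    return path


def load_film_tiff(path) -> FilmScan:
    """Read a scan written by :func:`save_film_tiff`."""
    import json
    from pathlib import Path

    import tifffile

    from .errors import ParseError

    path = Path(path).with_suffix(".tif")
    sidecar = path.with_suffix(".json")
    try:
        meta = json.loads(sidecar.read_text())
    except FileNotFoundError:
        raise ParseError(f"missing film scan sidecar {sidecar}")
    try:
        img = tifffile.imread(path)
    except Exception as e:
        raise ParseError(f"cannot read film TIFF {path}: {e}")
    try:
        response = img.astype(float) * meta["response_scale"]
        valid = np.ones(img.shape, dtype=bool)
        for i, j in meta["invalid"]:
            valid[i, j] = False
        return FilmScan(response, meta["spacing"], meta["landmarks"],
                        meta["origin"], valid)
    except KeyError as e:
        raise ParseError(f"{sidecar}: missing field {e}")


@dataclass
class RigidTransform2D:
    """Rotation (degrees, counter-clockwise) followed by a translation (mm)."""

    rotation: float = 0.0
    translation: np.ndarray = field(default_factory=lambda: np.zeros(2))
    residual_rms: float = 0.0

    def __post_init__(self):
        self.translation = np.asarray(self.translation, dtype=float).reshape(2)

    @property
    def matrix(self) -> np.ndarray:
        th = np.deg2rad(self.rotation)
        return np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])

    def apply(self, points) -> np.ndarray:
        p = np.asarray(points, dtype=float)
        return p @ self.matrix.T + self.translation

    def inverse(self) -> "RigidTransform2D":
        rinv = self.matrix.T
        return RigidTransform2D(-self.rotation, -(rinv @ self.translation))


def solve_landmark_transform(detected, nominal) -> RigidTransform2D:
    """Least-squares rigid transform (Procrustes without scaling) mapping the
    three detected cassette-pin landmarks onto their nominal film-frame
    positions.  Exactly invariant under relabeling of the point pairs."""
    det = np.asarray(detected, dtype=float).reshape(-1, 2)
    nom = np.asarray(nominal, dtype=float).reshape(-1, 2)
    if det.shape != (3, 2) or nom.shape != (3, 2):
        raise GeometryError("landmark registration needs exactly three point pairs")
    _check_noncollinear(det, "detected landmarks")
    _check_noncollinear(nom, "nominal landmarks")
    dc, nc = det.mean(axis=0), nom.mean(axis=0)
    h = (det - dc).T @ (nom - nc)
    u, _, vt = np.linalg.svd(h)
    sign = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, sign]) @ u.T
    t = nc - r @ dc
    angle = float(np.rad2deg(np.arctan2(r[1, 0], r[0, 0])))
    out = RigidTransform2D(angle, t)
    out.residual_rms = float(np.sqrt(np.mean(np.sum((out.apply(det) - nom) ** 2, axis=1))))
    return out


def apply_transform(scan: FilmScan, t: RigidTransform2D,
                    spec: CommonGridSpec | None = None) -> FilmScan:
    """Resample a scan under the rigid scanner correction onto the film-frame
    post-processing grid (bilinear).  Pixels whose source location falls
    outside the scan support are invalid."""
    spec = spec or CommonGridSpec()
    if abs(spec.spacing[0] - spec.spacing[1]) > 1e-12:
        raise DomainError("post-processing grid must have square pixels for film scans")
    cx, cy = spec.film_coords(0), spec.film_coords(1)
    pts = np.stack(np.meshgrid(cx, cy, indexing="ij"), axis=-1).reshape(-1, 2)
    src_pts = t.inverse().apply(pts)
    resp = np.where(scan.valid, scan.response, np.nan)
    interp = RegularGridInterpolator((scan.coords(0), scan.coords(1)), resp,
                                     method="linear", bounds_error=False,
                                     fill_value=np.nan)
    vals = interp(src_pts).reshape(cx.size, cy.size)
    new_landmarks = t.apply(scan.landmarks)
    valid = np.isfinite(vals)
    vals = np.where(valid, np.clip(vals, 0.0, None), np.nan)
    return FilmScan(vals, float(spec.spacing[0]), new_landmarks, np.zeros(2), valid)
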