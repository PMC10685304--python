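"""Dose-grid data model and geometry operations.

The package works in a phantom-attached, right-handed coordinate frame with
axes named ``crossline`` (lateral, the film's short 60 mm axis), ``inline``
(longitudinal/bore direction, the film's long 165 mm axis) and ``depth``
(anterior-posterior, normal to the coronal film plane).  All positions are
voxel-center based and in millimetres.

:class:`DoseGrid3D` holds a calculated 3D dose distribution on a regular
lattice; :class:`DosePlane2D` holds a 2D dose image on the film plane.  A
plane carries a boolean ``valid`` mask: pixels that fell outside an
interpolation support or outside the calibrated film range are marked
invalid (values NaN) and are excluded from every downstream statistic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .errors import ConsistencyError, DomainError, ExtentError, GeometryError, ParseError

AXES = ("crossline", "inline", "depth")

_GEOM_ATOL = 1e-9


def _as_float_array(x, n: int, name: str) -> np.ndarray:
    a = np.asarray(x, dtype=float).reshape(-1)
    if a.size != n:
        raise DomainError(f"{name} must have {n} components, got {a.size}")
    return a


@dataclass
class DoseGrid3D:
    """Absorbed dose (Gy) on a regular 3D lattice.

    ``values`` is stored in canonical (crossline, inline, depth) axis order;
    a permuted ``axes`` argument is transposed into canonical order on
    construction.  ``origin`` is the physical position of the first voxel
    center, ``spacing`` the voxel pitch per axis (both mm, phantom frame).
    """

    values: np.ndarray
    origin: np.ndarray
    spacing: np.ndarray
    axes: tuple = AXES

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise DomainError("DoseGrid3D values must be a 3D array")
        self.origin = _as_float_array(self.origin, 3, "origin")
        self.spacing = _as_float_array(self.spacing, 3, "spacing")
        axes = tuple(self.axes)
        if sorted(axes) != sorted(AXES):
            raise DomainError(f"axes must be a permutation of {AXES}, got {axes}")
        if axes != AXES:
            perm = [axes.index(a) for a in AXES]
            self.values = np.transpose(self.values, perm)
            self.origin = self.origin[perm]
            self.spacing = self.spacing[perm]
            self.axes = AXES
        if np.any(self.spacing <= 0):
            raise DomainError("spacing must be strictly positive per axis")
        if np.any(self.values < -1e-9):
            raise DomainError("dose values must be non-negative")
        np.clip(self.values, 0.0, None, out=self.values)

    @property
    def shape(self):
        return self.values.shape

    def coords(self, axis: int) -> np.ndarray:
        """Voxel-center coordinates along ``axis`` (mm)."""
        return self.origin[axis] + self.spacing[axis] * np.arange(self.shape[axis])

    def extent(self, axis: int):
        c = self.coords(axis)
        return float(c[0]), float(c[-1])

    def interpolator(self) -> RegularGridInterpolator:
        """Trilinear interpolator over the grid; NaN outside the extent."""
        return RegularGridInterpolator(
            (self.coords(0), self.coords(1), self.coords(2)),
            self.values,
            method="linear",
            bounds_error=False,
            fill_value=np.nan,
        )


@dataclass
class DosePlane2D:
    """A crossline x inline dose image on the film plane.

    ``values[i, j]`` sits at crossline ``origin[0] + i*spacing[0]`` and
    inline ``origin[1] + j*spacing[1]``.  When ``is_relative`` the values are
    absolute dose divided by ``norm_dose`` (Gy).
    """

    values: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray
    is_relative: bool = False
    norm_dose: float | None = None
    valid: np.ndarray | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DomainError("DosePlane2D values must be a 2D array")
        self.spacing = _as_float_array(self.spacing, 2, "spacing")
        self.origin = _as_float_array(self.origin, 2, "origin")
        if np.any(self.spacing <= 0):
            raise DomainError("plane spacing must be strictly positive")
        if self.valid is None:
            self.valid = np.isfinite(self.values)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
            if self.valid.shape != self.values.shape:
                raise DomainError("valid mask shape must match values")
            self.valid = self.valid & np.isfinite(self.values)
        if self.is_relative and (self.norm_dose is None or self.norm_dose <= 0):
            raise DomainError("relative plane requires norm_dose > 0")

    @property
    def shape(self):
        return self.values.shape

    def coords(self, axis: int) -> np.ndarray:
        return self.origin[axis] + self.spacing[axis] * np.arange(self.shape[axis])

    def masked(self) -> np.ndarray:
        """Values with invalid pixels set to NaN."""
        out = self.values.copy()
        out[~self.valid] = np.nan
        return out

    def copy(self) -> "DosePlane2D":
        return DosePlane2D(
            self.values.copy(), self.spacing.copy(), self.origin.copy(),
            self.is_relative, self.norm_dose, self.valid.copy(),
        )


def same_geometry(a: DosePlane2D, b: DosePlane2D, atol: float = 1e-6) -> bool:
    return (
        a.shape == b.shape
        and np.allclose(a.spacing, b.spacing, atol=atol)
        and np.allclose(a.origin, b.origin, atol=atol)
    )


@dataclass
class CassettePose:
    """Placement of the film cassette inside the phantom.

    ``plane_offset`` is the signed depth of the film plane relative to the
    phantom mid-coronal plane (mm); ``in_plane_origin`` locates the film
    frame's lower-left pin-defined corner in phantom (crossline, inline)
    coordinates; ``nominal_landmarks`` are the three cassette-pin positions
    in the film frame (mm), required non-collinear.
    """

    plane_offset: float = 0.0
    in_plane_origin: np.ndarray = field(default_factory=lambda: np.array([-30.0, -82.5]))
    nominal_landmarks: np.ndarray = field(
        default_factory=lambda: np.array([[2.0, 4.0], [2.0, 161.0], [57.0, 82.5]])
    )

    def __post_init__(self):
        self.in_plane_origin = _as_float_array(self.in_plane_origin, 2, "in_plane_origin")
        lm = np.asarray(self.nominal_landmarks, dtype=float)
        if lm.shape != (3, 2):
            raise GeometryError("nominal_landmarks must be three 2D points")
        e1, e2 = lm[1] - lm[0], lm[2] - lm[0]
        area = e1[0] * e2[1] - e1[1] * e2[0]
        if abs(area) < 1e-6:
            raise GeometryError("cassette pin landmarks are collinear")
        self.nominal_landmarks = lm


@dataclass
class CommonGridSpec:
    """Common post-processing grid: 1x1 mm pitch, 61x166 mm extent, 1-voxel
    edge trim (final analysis grid 59x164 mm)."""

    spacing: np.ndarray = field(default_factory=lambda: np.array([1.0, 1.0]))
    post_size: np.ndarray = field(default_factory=lambda: np.array([61.0, 166.0]))
    edge_trim: int = 1

    def __post_init__(self):
        self.spacing = _as_float_array(self.spacing, 2, "spacing")
        self.post_size = _as_float_array(self.post_size, 2, "post_size")
        if np.any(self.spacing <= 0) or np.any(self.post_size <= 0):
            raise DomainError("CommonGridSpec spacing and post_size must be positive")
        if self.edge_trim < 0:
            raise DomainError("edge_trim must be >= 0")

    @property
    def post_shape(self):
        return tuple(int(round(s / p)) for s, p in zip(self.post_size, self.spacing))

    def film_coords(self, axis: int) -> np.ndarray:
        """Film-frame voxel-center coordinates of the post-processing grid."""
        return self.spacing[axis] * np.arange(self.post_shape[axis])


# ---------------------------------------------------------------------------
# operations


def extract_film_plane(grid: DoseGrid3D, pose: CassettePose,
                       spec: CommonGridSpec | None = None) -> DosePlane2D:
    """Trilinearly sample the coronal film plane out of a 3D dose grid.

    Returns absolute dose (Gy) on the post-processing grid in the film
    frame.  The film plane depth must lie inside the grid's depth extent;
    in-plane samples outside the grid are marked invalid.
    """
    spec = spec or CommonGridSpec()
    zlo, zhi = grid.extent(2)
    z = pose.plane_offset
    if not (zlo - _GEOM_ATOL <= z <= zhi + _GEOM_ATOL):
        raise ExtentError(
            f"film plane depth {z} mm outside grid depth extent [{zlo}, {zhi}] mm"
        )
    cx = pose.in_plane_origin[0] + spec.film_coords(0)
    cy = pose.in_plane_origin[1] + spec.film_coords(1)
    gx, gy = np.meshgrid(cx, cy, indexing="ij")
    pts = np.stack([gx, gy, np.full_like(gx, z)], axis=-1)
    vals = grid.interpolator()(pts.reshape(-1, 3)).reshape(cx.size, cy.size)
    return DosePlane2D(vals, spec.spacing.copy(), np.zeros(2))


def resample_plane(plane: DosePlane2D, spec: CommonGridSpec | None = None) -> DosePlane2D:
    """Bilinearly resample a plane onto the common (default 1x1 mm) grid.

    The target lattice starts at the source origin; no extrapolation is
    performed — target pixels whose bilinear support includes an invalid or
    out-of-extent source pixel are marked invalid.
    """
    spec = spec or CommonGridSpec()
    if plane.values.size == 0:
        raise DomainError("cannot resample an empty plane")
    new_sp = spec.spacing
    if np.allclose(plane.spacing, new_sp, atol=_GEOM_ATOL):
        return plane.copy()
    src = plane.masked()
    cs = [plane.coords(i) for i in range(2)]
    tgt = []
    for i in range(2):
        span = cs[i][-1] - cs[i][0]
        n = int(np.floor(span / new_sp[i] + _GEOM_ATOL)) + 1
        tgt.append(cs[i][0] + new_sp[i] * np.arange(n))
    interp = RegularGridInterpolator(cs, src, method="linear",
                                     bounds_error=False, fill_value=np.nan)
    pts = np.stack(np.meshgrid(*tgt, indexing="ij"), axis=-1)
    vals = interp(pts.reshape(-1, 2)).reshape(len(tgt[0]), len(tgt[1]))
    return DosePlane2D(vals, new_sp.copy(), np.array([tgt[0][0], tgt[1][0]]),
                       plane.is_relative, plane.norm_dose)


def crop_edge_voxels(plane: DosePlane2D, spec: CommonGridSpec | None = None) -> DosePlane2D:
    """Delete ``edge_trim`` rows/columns from every border (edge-effect removal)."""
    spec = spec or CommonGridSpec()
    t = spec.edge_trim
    if t == 0:
        return plane.copy()
    if any(s - 2 * t < 1 for s in plane.shape):
        raise DomainError(f"plane shape {plane.shape} too small for edge trim {t}")
    return DosePlane2D(
        plane.values[t:-t, t:-t].copy(),
        plane.spacing.copy(),
        plane.origin + t * plane.spacing,
        plane.is_relative,
        plane.norm_dose,
        plane.valid[t:-t, t:-t].copy(),
    )


def sum_planes(planes) -> DosePlane2D:
    """Voxel-wise sum of absolute per-fraction dose planes (total dose)."""
    planes = list(planes)
    if not planes:
        raise DomainError("sum_planes requires at least one plane")
    first = planes[0]
    total = np.zeros(first.shape)
    valid = np.ones(first.shape, dtype=bool)
    for p in planes:
        if p.is_relative:
            raise ConsistencyError("sum_planes requires absolute (not relative) planes")
        if not same_geometry(first, p):
            raise ConsistencyError("sum_planes requires identical plane geometry")
        total += np.where(p.valid, p.values, 0.0)
        valid &= p.valid
    total[~valid] = np.nan
    return DosePlane2D(total, first.spacing.copy(), first.origin.copy(),
                       False, None, valid)


# ---------------------------------------------------------------------------
# portable container I/O (.npz arrays + .json metadata sidecar)


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def save_portable(path, obj) -> Path:
    """Write a DoseGrid3D / DosePlane2D / FilmScan losslessly as
    ``<path>.npz`` plus a ``<path>.json`` metadata sidecar."""
    from .film import FilmScan  # local import to avoid a cycle

    path = Path(path).with_suffix(".npz")
    if isinstance(obj, DoseGrid3D):
        meta = {"type": "DoseGrid3D", "origin": obj.origin.tolist(),
                "spacing": obj.spacing.tolist(), "axes": list(obj.axes)}
        np.savez_compressed(path, values=obj.values)
    elif isinstance(obj, DosePlane2D):
        meta = {"type": "DosePlane2D", "origin": obj.origin.tolist(),
                "spacing": obj.spacing.tolist(), "is_relative": obj.is_relative,
                "norm_dose": obj.norm_dose}
        np.savez_compressed(path, values=obj.values, valid=obj.valid)
    elif isinstance(obj, FilmScan):
        meta = {"type": "FilmScan", "spacing": obj.spacing,
                "origin": obj.origin.tolist(), "landmarks": obj.landmarks.tolist()}
        np.savez_compressed(path, response=obj.response, valid=obj.valid)
    else:
        raise DomainError(f"cannot serialize object of type {type(obj).__name__}")
    _sidecar(path).write_text(json.dumps(meta, indent=1, sort_keys=True))
    return path


def load_portable(path):
    """Load an object written by :func:`save_portable`."""
    from .film import FilmScan

    path = Path(path).with_suffix(".npz")
    try:
        meta = json.loads(_sidecar(path).read_text())
    except FileNotFoundError:
        raise ParseError(f"missing metadata sidecar {_sidecar(path)}")
    except json.JSONDecodeError as e:
        raise ParseError(f"malformed sidecar {_sidecar(path)}: {e}")
    try:
        with np.load(path) as z:
            arrays = {k: z[k] for k in z.files}
    except Exception as e:  # truncated / corrupt archive
        raise ParseError(f"cannot read array container {path}: {e}")
    try:
        kind = meta["type"]
        if kind == "DoseGrid3D":
            return DoseGrid3D(arrays["values"], meta["origin"], meta["spacing"],
                              tuple(meta["axes"]))
        if kind == "DosePlane2D":
            return DosePlane2D(arrays["values"], meta["spacing"], meta["origin"],
                               meta["is_relative"], meta["norm_dose"], arrays["valid"])
        if kind == "FilmScan":
            return FilmScan(arrays["response"], meta["spacing"], meta["landmarks"],
                            meta["origin"], arrays["valid"])
    except KeyError as e:
        raise ParseError(f"{path}: missing field {e}")
    raise ParseError(f"{path}: unknown object type {meta.get('type')!r}")


# ---------------------------------------------------------------------------
# DICOM RTDOSE (optional at runtime; requires pydicom)

_RTDOSE_CLASS_UID = "1.2.840.10008.5.1.4.1.1.481.2"


def write_rtdose(path, grid: DoseGrid3D) -> Path:
    """Write a grid as a minimal DICOM RTDOSE file (GY, 32-bit, scaled).

    Axis convention: frames = depth, rows = inline, columns = crossline;
    ImagePositionPatient carries (crossline, inline, depth) of the first
    voxel center.  Not clinical-grade metadata — intended for round-tripping
    and interoperability tests.
    """
    import pydicom
    from pydicom.dataset import FileDataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, generate_uid

    path = Path(path)
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = _RTDOSE_CLASS_UID
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = _RTDOSE_CLASS_UID
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "RTDOSE"
    ds.DoseUnits = "GY"
    ds.DoseType = "PHYSICAL"
    ds.DoseSummationType = "FRACTION"
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 32
    ds.BitsStored = 32
    ds.HighBit = 31
    ds.PixelRepresentation = 0
    nx, ny, nz = grid.shape
    ds.Columns = nx
    ds.Rows = ny
    ds.NumberOfFrames = nz
    ds.PixelSpacing = [float(grid.spacing[1]), float(grid.spacing[0])]
    ds.GridFrameOffsetVector = [float(grid.spacing[2] * k) for k in range(nz)]
    ds.ImagePositionPatient = [float(grid.origin[0]), float(grid.origin[1]),
                               float(grid.origin[2])]
    ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
    vmax = float(grid.values.max())
    scaling = vmax / (2**32 - 1) if vmax > 0 else 1.0
    ds.DoseGridScaling = scaling
    pixels = np.round(grid.values / scaling).astype(np.uint32)
    ds.PixelData = np.ascontiguousarray(np.transpose(pixels, (2, 1, 0))).tobytes()
    ds.save_as(path, enforce_file_format=True)
    return path


def read_rtdose(path) -> DoseGrid3D:
    """Read a DICOM RTDOSE file; DoseGridScaling is honored."""
    import pydicom

    path = Path(path)
    try:
        ds = pydicom.dcmread(path)
    except Exception as e:
        raise ParseError(f"cannot parse DICOM file {path}: {e}")
    for attr in ("DoseGridScaling", "PixelSpacing", "ImagePositionPatient",
                 "GridFrameOffsetVector"):
        if not hasattr(ds, attr):
            raise ParseError(f"{path}: RTDOSE missing field {attr}")
    values = ds.pixel_array.astype(float) * float(ds.DoseGridScaling)
    if values.ndim == 2:
        values = values[None]
    values = np.transpose(values, (2, 1, 0))  # -> (crossline, inline, depth)
    offsets = np.asarray(ds.GridFrameOffsetVector, dtype=float)
    dz = float(offsets[1] - offsets[0]) if offsets.size > 1 else 1.0
    spacing = np.array([float(ds.PixelSpacing[1]), float(ds.PixelSpacing[0]), dz])
    origin = np.asarray(ds.ImagePositionPatient, dtype=float)
    return DoseGrid3D(values, origin, spacing)
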