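"""Synthetic QUASAR-style phantom and five-fraction treatment simulator.

Generates complete treatment datasets with known ground truth — per-fraction
calculated 3D dose grids, an accumulated film scan, daily calibration films
and chamber readings — so the full film-QA analysis chain can be exercised
without physical measurements.

Physics model
-------------
The phantom is an elliptical water cylinder (long axis along ``inline``)
containing a film cassette on the mid-coronal plane, an air-filled lung
cylinder and a chamber/ball-bearing point at the body center.  Each of the
13 beams of the plan contributes a square field with an error-function
lateral penumbra and exponential attenuation along its axis through the
body; contributions are summed and rescaled so the prescription point (on
the ~70% isodose of the inline profile) receives exactly the fraction dose.
This is a parametric stand-in for a Monte-Carlo engine: it reproduces the
features the QA pipeline is sensitive to (field edges, penumbra widths,
attenuation gradients, fraction summation) and nothing else.

Adaptive replanning is emulated by working in the phantom-attached frame:
an inter-fraction variation transforms the *machine* (beam directions)
by the inverse rigid transform, and body modifications rescale the body
ellipse and attenuation.  For a pure translation with rigid replanning the
per-fraction dose in this frame is exactly the original dose — attenuation
geometry is unchanged — so translation fractions differ from the original
plan only through the delivery/measurement noise channels.

All randomness flows through one seeded NumPy generator; every injected
perturbation is recorded in a ground-truth ledger sufficient to reconstruct
the simulation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import brentq
from scipy.special import erf

from .errors import ConfigError, GeometryError, SimulationError
from .film import CalibrationCurve, FilmScan, RigidTransform2D, save_film_tiff
from .grids import (CassettePose, CommonGridSpec, DoseGrid3D, DosePlane2D,
                    extract_film_plane, save_portable, sum_planes)
from .metrics import ChamberSpec


# ---------------------------------------------------------------------------
# models


@dataclass
class BeamModel:
    gantry_deg: float
    weight: float = 1.0
    field_size: float = 32.0        # mm, square field side
    penumbra_sigma: float = 3.0     # mm
    mu: float = 0.004               # linear attenuation per mm

    def __post_init__(self):
        if self.weight < 0:
            raise ConfigError("beam weight must be non-negative")
        if self.field_size <= 0 or self.penumbra_sigma <= 0 or self.mu < 0:
            raise ConfigError("beam geometry parameters must be positive")


def _edge_profile(t, half, sigma):
    """Flat-top lateral profile with error-function penumbra (1.0 on axis)."""
    s = sigma * np.sqrt(2.0)
    return 0.5 * (erf((half - t) / s) + erf((half + t) / s))


def penumbra_width_20_80(sigma: float) -> float:
    """Closed-form 20-80% penumbra width of the erf edge: 2*sqrt(2)*erfinv(0.6)*sigma."""
    from scipy.special import erfinv
    return 2.0 * np.sqrt(2.0) * erfinv(0.6) * sigma


@dataclass
class PlanModel:
    """13-beam plan, five fractions of 1.2 Gy (6.0 Gy total prescription)."""

    beams: list = field(default_factory=lambda: [
        BeamModel(g) for g in np.linspace(-130.0, 130.0, 13)
    ])
    n_fractions: int = 5
    fraction_dose: float = 1.2      # Gy at the prescription point
    prescription_isodose: float = 0.7

    def __post_init__(self):
        if self.n_fractions < 1 or self.fraction_dose <= 0:
            raise ConfigError("plan requires >= 1 fraction with positive dose")
        if not 0 < self.prescription_isodose <= 1:
            raise ConfigError("prescription isodose must be in (0, 1]")

    @property
    def total_dose(self) -> float:
        return self.n_fractions * self.fraction_dose

    def prescription_offset(self) -> float:
        """Inline offset (mm) from the target where the nominal lateral
        profile equals the prescription isodose level."""
        b = self.beams[0]
        half, sigma = b.field_size / 2.0, b.penumbra_sigma
        level = self.prescription_isodose
        return brentq(lambda t: _edge_profile(t, half, sigma) - level,
                      0.0, half + 6 * sigma)


@dataclass
class PhantomModel:
    """Elliptical-cylinder body with film cassette, lung cylinder and
    chamber/ball-bearing; all positions mm, phantom frame, body center at
    the origin."""

    body_semi_axes: tuple = (140.0, 100.0)     # (crossline, depth)
    body_length: float = 300.0                 # inline extent
    film_cassette: CassettePose = field(default_factory=CassettePose)
    lung_center: tuple = (55.0, 0.0)           # (crossline, depth)
    lung_radius: float = 25.0
    chamber: ChamberSpec = field(default_factory=ChamberSpec)
    ball_bearing: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.ball_bearing = np.asarray(self.ball_bearing, dtype=float).reshape(3)
        a, b = self.body_semi_axes
        if a <= 0 or b <= 0 or self.body_length <= 0 or self.lung_radius <= 0:
            raise ConfigError("phantom dimensions must be positive")
        cx, cz = self.chamber.position[0], self.chamber.position[2]
        if (cx / a) ** 2 + (cz / b) ** 2 >= 1:
            raise ConfigError("chamber must lie inside the body")
        ox = self.film_cassette.in_plane_origin[0]
        if abs(ox) >= a:
            raise ConfigError("film cassette must lie inside the body")


@dataclass
class GridSpec3D:
    """Lattice for calculated dose grids (default 2 mm pitch)."""

    origin: tuple = (-60.0, -95.0, -50.0)
    spacing: tuple = (2.0, 2.0, 2.0)
    shape: tuple = (61, 96, 51)


@dataclass
class InterfractionVariation:
    """One positional/anatomical variation: exactly one kind per fraction."""

    kind: str                       # none | translation | rotation | body_modification
    params: dict = field(default_factory=dict)

    _KINDS = ("none", "translation", "rotation", "body_modification")

    def __post_init__(self):
        if self.kind not in self._KINDS:
            raise ConfigError(f"unknown variation kind {self.kind!r}")

    @classmethod
    def none(cls):
        return cls("none")

    @classmethod
    def translation(cls, vector_mm):
        return cls("translation", {"vector_mm": [float(v) for v in vector_mm]})

    @classmethod
    def rotation(cls, angle_deg: float, axis: str = "depth"):
        if axis not in ("crossline", "inline", "depth"):
            raise ConfigError(f"unknown rotation axis {axis!r}")
        return cls("rotation", {"angle_deg": float(angle_deg), "axis": axis})

    @classmethod
    def body_modification(cls, scale: float = 1.05, attenuation_delta: float = 0.0):
        if scale <= 0:
            raise ConfigError("body scale must be positive")
        return cls("body_modification",
                   {"scale": float(scale), "attenuation_delta": float(attenuation_delta)})

    def rotation_matrix(self) -> np.ndarray:
        if self.kind != "rotation":
            return np.eye(3)
        th = np.deg2rad(self.params["angle_deg"])
        c, s = np.cos(th), np.sin(th)
        axis = self.params["axis"]
        if axis == "depth":
            return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1.0]])
        if axis == "inline":
            return np.array([[c, 0, s], [0, 1.0, 0], [-s, 0, c]])
        return np.array([[1.0, 0, 0], [0, c, -s], [0, s, c]])

    def body_scale(self) -> float:
        return self.params.get("scale", 1.0) if self.kind == "body_modification" else 1.0

    def attenuation_delta(self) -> float:
        return self.params.get("attenuation_delta", 0.0) \
            if self.kind == "body_modification" else 0.0


@dataclass
class NoiseModel:
    """Measurement-chain perturbations.  All SDs are >= 0; ``None`` for a
    fixed quantity means "sample it"."""

    film_response_noise: float = 0.003      # fractional, per pixel
    landmark_jitter_sd: float = 0.3         # mm, manual landmark selection
    daily_drift: float | None = None        # fixed dose-scale factor per day
    daily_drift_sd: float = 0.02
    scanner_transform: RigidTransform2D | None = None
    scanner_rotation_sd: float = 1.0        # deg
    scanner_translation_sd: float = 1.0     # mm
    delivery_dose_scale: float | None = None
    delivery_dose_scale_sd: float = 0.0
    delivery_shift: tuple | None = None     # (crossline, inline) mm
    delivery_shift_sd: float = 0.0
    chamber_noise_sd: float = 0.002         # fractional

    def __post_init__(self):
        for name in ("film_response_noise", "landmark_jitter_sd", "daily_drift_sd",
                     "scanner_rotation_sd", "scanner_translation_sd",
                     "delivery_dose_scale_sd", "delivery_shift_sd", "chamber_noise_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")

    @classmethod
    def null(cls):
        """No perturbations at all — every downstream comparison is identity."""
        return cls(film_response_noise=0.0, landmark_jitter_sd=0.0, daily_drift=1.0,
                   scanner_transform=RigidTransform2D(), scanner_rotation_sd=0.0,
                   scanner_translation_sd=0.0, delivery_dose_scale=1.0,
                   delivery_shift=(0.0, 0.0), chamber_noise_sd=0.0)


# ---------------------------------------------------------------------------
# beam-model dose engine


def _beam_dose_at(points: np.ndarray, beam: BeamModel, target: np.ndarray,
                  rot_inv: np.ndarray, semi_axes, mu_delta: float) -> np.ndarray:
    """Dose contribution of one beam at ``points`` (..., 3), phantom frame."""
    th = np.deg2rad(beam.gantry_deg)
    d_m = np.array([np.sin(th), 0.0, np.cos(th)])      # travel direction
    y_m = np.array([0.0, 1.0, 0.0])
    u_m = np.cross(d_m, y_m)
    d, y, u = rot_inv @ d_m, rot_inv @ y_m, rot_inv @ u_m

    a, b = semi_axes
    # central-axis sanity: the ray through the target must traverse the body
    alpha0 = (d[0] / a) ** 2 + (d[2] / b) ** 2
    gamma0 = (target[0] / a) ** 2 + (target[2] / b) ** 2 - 1.0
    if alpha0 < 1e-12 or gamma0 >= 0:
        raise GeometryError(
            f"beam at gantry {beam.gantry_deg} deg misses the phantom body")

    rel = points - target
    tu = rel @ u
    tv = rel @ y
    half = beam.field_size / 2.0
    lateral = _edge_profile(tu, half, beam.penumbra_sigma) \
        * _edge_profile(tv, half, beam.penumbra_sigma)

    # upstream path length inside the elliptical body (line X(t) = r - t*d)
    x0, z0 = points[..., 0], points[..., 2]
    alpha = alpha0
    beta = 2.0 * (x0 * d[0] / a**2 + z0 * d[2] / b**2)
    gamma = (x0 / a) ** 2 + (z0 / b) ** 2 - 1.0
    disc = beta * beta - 4.0 * alpha * gamma
    sq = np.sqrt(np.clip(disc, 0.0, None))
    t_hi = (beta + sq) / (2.0 * alpha)
    t_lo = (beta - sq) / (2.0 * alpha)
    path = np.where(disc > 0,
                    np.clip(t_hi, 0.0, None) - np.clip(t_lo, 0.0, None), 0.0)
    return beam.weight * lateral * np.exp(-(beam.mu + mu_delta) * path)


def evaluate_plan_dose_at(plan: PlanModel, phantom: PhantomModel,
                          points, variation: InterfractionVariation | None = None
                          ) -> np.ndarray:
    """Scaled analytic dose of the (possibly varied) plan at arbitrary
    points (..., 3) — the same beam model the grid calculation uses, without
    lattice discretization.  The prescription point receives exactly
    ``fraction_dose``."""
    variation = variation or InterfractionVariation.none()
    rot_inv = variation.rotation_matrix().T
    semi = (phantom.body_semi_axes[0] * variation.body_scale(),
            phantom.body_semi_axes[1] * variation.body_scale())
    mu_delta = variation.attenuation_delta()
    target = phantom.ball_bearing
    points = np.asarray(points, dtype=float)
    presc = target + np.array([0.0, plan.prescription_offset(), 0.0])
    accum = np.zeros(points.shape[:-1])
    presc_raw = 0.0
    for beam in plan.beams:
        accum += _beam_dose_at(points, beam, target, rot_inv, semi, mu_delta)
        presc_raw += float(_beam_dose_at(presc[None, :], beam, target,
                                         rot_inv, semi, mu_delta)[0])
    if presc_raw <= 0:
        if np.all(accum == 0):
            return accum
        raise GeometryError("prescription point receives no dose")
    return accum * (plan.fraction_dose / presc_raw)


def compute_plan_dose(plan: PlanModel, phantom: PhantomModel,
                      variation: InterfractionVariation | None = None,
                      grid: GridSpec3D | None = None) -> DoseGrid3D:
    """Calculated per-fraction 3D dose for a (possibly varied) phantom.

    Deterministic: the variation is applied by inverse-transforming the
    beam geometry into the phantom-attached frame (rigid replanning tracks
    the target), and the sum of beam contributions is rescaled so the
    prescription point receives exactly ``fraction_dose``.
    """
    grid = grid or GridSpec3D()
    cs = [np.asarray(grid.origin)[i] + np.asarray(grid.spacing)[i]
          * np.arange(grid.shape[i]) for i in range(3)]
    pts = np.stack(np.meshgrid(*cs, indexing="ij"), axis=-1)
    values = evaluate_plan_dose_at(plan, phantom, pts, variation)
    return DoseGrid3D(values, np.asarray(grid.origin), np.asarray(grid.spacing))


# ---------------------------------------------------------------------------
# measurement-chain simulation


def true_calibration_curve() -> CalibrationCurve:
    """The simulator's ground-truth film batch response: dose(x) =
    12(1-x)/(1+1.5x) Gy, net response x in (0, 1], strictly decreasing."""
    params = (12.0, -12.0, 1.5)
    doses = np.linspace(0.0, 10.0, 20)
    a, b, c = params
    responses = (a - doses) / (c * doses - b)
    return CalibrationCurve(np.column_stack([doses, responses]), params)


def make_calibration_table(curve: CalibrationCurve, n_points: int = 20,
                           max_dose: float = 10.0, noise_sd: float = 0.003,
                           rng: np.random.Generator | None = None) -> np.ndarray:
    """Batch calibration table: (dose_gy, response) with multiplicative noise."""
    rng = rng or np.random.default_rng(0)
    doses = np.linspace(0.0, max_dose, n_points)
    resp = curve.base_response(doses)
    if noise_sd > 0:
        resp = resp * (1.0 + rng.normal(0.0, noise_sd, size=resp.shape))
    return np.column_stack([doses, resp])


def make_daily_table(curve: CalibrationCurve, doses, drift: float,
                     noise_sd: float, rng: np.random.Generator) -> np.ndarray:
    """Daily correction films: the film responds as if the dose were
    ``dose/drift`` (the daily scale the analysis must recover)."""
    doses = np.asarray(doses, dtype=float)
    resp = curve.base_response(doses / drift)
    if noise_sd > 0:
        resp = resp * (1.0 + rng.normal(0.0, noise_sd, size=resp.shape))
    return np.column_stack([doses, resp])


def simulate_fraction_delivery(calculated: DoseGrid3D, pose: CassettePose,
                               spec: CommonGridSpec, dose_scale: float = 1.0,
                               residual_shift=(0.0, 0.0)) -> DosePlane2D:
    """Ground-truth delivered film-plane dose: the calculated plane, scaled
    and rigidly shifted in-plane by the residual delivery error."""
    shift = np.asarray(residual_shift, dtype=float).reshape(2)
    shifted_pose = CassettePose(pose.plane_offset,
                                pose.in_plane_origin - shift,
                                pose.nominal_landmarks)
    plane = extract_film_plane(calculated, shifted_pose, spec)
    vals = plane.values * dose_scale
    return DosePlane2D(vals, plane.spacing, plane.origin, False, None, plane.valid)


def simulate_film_scan(accumulated: DosePlane2D, curve: CalibrationCurve,
                       noise: NoiseModel, rng: np.random.Generator,
                       nominal_landmarks: np.ndarray,
                       drift: float = 1.0,
                       scan_pitch: float = 0.25, scan_margin: float = 6.0):
    """Simulate scanning the accumulated film.

    The film encodes ``dose/drift`` through the inverse calibration curve,
    multiplicative response noise is added per pixel, the image is laid out
    under a rigid scanner transform, and the three pin landmarks are written
    with manual-selection jitter.  Returns ``(FilmScan, truth dict)``.
    """
    dmax_cal = curve.dose_range[1]
    peak = float(np.nanmax(np.where(accumulated.valid, accumulated.values, 0.0)))
    if peak / drift > dmax_cal + 1e-9:
        raise SimulationError(
            f"film dose {peak:.2f} Gy exceeds the calibration range "
            f"({dmax_cal:.2f} Gy) — film saturation")
    if noise.scanner_transform is not None:
        s = noise.scanner_transform
    else:
        s = RigidTransform2D(rng.normal(0.0, noise.scanner_rotation_sd),
                             rng.normal(0.0, noise.scanner_translation_sd, 2))
    film_extent = (np.array(accumulated.shape) - 1) * accumulated.spacing
    c0 = np.arange(-scan_margin, film_extent[0] + scan_margin + 1e-9, scan_pitch)
    c1 = np.arange(-scan_margin, film_extent[1] + scan_margin + 1e-9, scan_pitch)
    q = np.stack(np.meshgrid(c0, c1, indexing="ij"), axis=-1).reshape(-1, 2)
    p = s.inverse().apply(q)
    from scipy.interpolate import RegularGridInterpolator
    dose_src = np.where(accumulated.valid, accumulated.values, 0.0)
    interp = RegularGridInterpolator(
        (accumulated.coords(0), accumulated.coords(1)), dose_src,
        method="linear", bounds_error=False, fill_value=0.0)
    dose = np.clip(interp(p).reshape(c0.size, c1.size), 0.0, None)
    response = np.asarray(curve.base_response(dose / drift), dtype=float)
    if noise.film_response_noise > 0:
        response = response * (1.0 + rng.normal(0.0, noise.film_response_noise,
                                                size=response.shape))
    jitter = rng.normal(0.0, noise.landmark_jitter_sd, size=(3, 2)) \
        if noise.landmark_jitter_sd > 0 else np.zeros((3, 2))
    detected = s.apply(nominal_landmarks) + jitter
    scan = FilmScan(np.clip(response, 0.0, None), scan_pitch, detected,
                    np.array([c0[0], c1[0]]))
    truth = {"scanner_rotation_deg": float(s.rotation),
             "scanner_translation_mm": [float(v) for v in s.translation],
             "landmark_jitter_mm": jitter.tolist(),
             "daily_drift": float(drift)}
    return scan, truth


# ---------------------------------------------------------------------------
# full dataset generation


@dataclass
class SimulationConfig:
    """Everything the simulator needs: phantom, plan, variations per family,
    noise model and experimental layout."""

    phantom: PhantomModel = field(default_factory=PhantomModel)
    plan: PlanModel = field(default_factory=PlanModel)
    grid: GridSpec3D = field(default_factory=GridSpec3D)
    common: CommonGridSpec = field(default_factory=CommonGridSpec)
    noise: NoiseModel = field(default_factory=NoiseModel)
    layout: str = "paper"           # paper (14 datasets) | null
    translations: list = field(default_factory=lambda: [
        (3.0, 0.0, 0.0), (0.0, 5.0, 0.0), (-4.0, 0.0, 2.0),
        (0.0, -6.0, 0.0), (5.0, 3.0, -2.0)])
    rotation_angles: list = field(default_factory=lambda: [2.0, -3.0, 4.0, -2.0, 3.0])
    rotation_axis: str = "depth"
    body_scales: list = field(default_factory=lambda: [1.02, 0.98, 1.05, 0.97, 1.03])
    daily_doses_total: list = field(default_factory=lambda: [0.0, 2.5, 5.0, 7.5, 10.0])
    daily_doses_single: list = field(default_factory=lambda: [0.0, 0.8, 1.6, 2.4])
    batch_noise_sd: float = 0.002

    def variations(self, family: str) -> list:
        if family == "none":
            return [InterfractionVariation.none()] * self.plan.n_fractions
        if family == "translation":
            return [InterfractionVariation.translation(v) for v in self.translations]
        if family == "rotation":
            return [InterfractionVariation.rotation(a, self.rotation_axis)
                    for a in self.rotation_angles]
        if family == "body_modification":
            return [InterfractionVariation.body_modification(s) for s in self.body_scales]
        raise ConfigError(f"unknown variation family {family!r}")

    def dataset_plan(self) -> list:
        """(dataset_id, family, fraction indices, mode) for the layout:
        three totals plus eleven single fractions."""
        if self.layout not in ("paper", "null", "mini"):
            raise ConfigError(f"unknown layout {self.layout!r}")
        ds = [("original_sf", "none", [0], "single_fraction")]
        if self.layout == "mini":
            ds.append(("translation_total", "translation",
                       [0, 1, 2, 3, 4], "total_dose"))
            return ds
        ds.append(("translation_total", "translation", [0, 1, 2, 3, 4], "total_dose"))
        ds += [(f"translation_f{i+1}", "translation", [i], "single_fraction")
               for i in range(5)]
        ds.append(("rotation_total", "rotation", [0, 1, 2, 3, 4], "total_dose"))
        ds += [(f"rotation_f{i+1}", "rotation", [i], "single_fraction")
               for i in (0, 2, 4)]
        ds.append(("body_total", "body_modification", [0, 1, 2, 3, 4], "total_dose"))
        ds += [(f"body_f{i+1}", "body_modification", [i], "single_fraction")
               for i in (0, 4)]
        return ds

    @classmethod
    def null_experiment(cls):
        """Paper layout with zero delivery error and default film noise."""
        noise = NoiseModel()            # delivery error SDs default to 0
        return cls(noise=noise, layout="paper")


CHAMBER_DATASETS = ("original_sf", "translation_f1", "translation_f2",
                    "translation_f3", "translation_f4", "translation_f5")


@dataclass
class DatasetRecord:
    dataset_id: str
    mode: str
    calculated: list                # DoseGrid3D per fraction
    delivered: list                 # DosePlane2D per fraction (ground truth)
    accumulated: DosePlane2D        # ground-truth film-plane dose
    scan: FilmScan
    daily_table: np.ndarray
    truth: dict
    chamber_measured_gy: float | None = None


@dataclass
class TreatmentDataset:
    root: Path
    config: SimulationConfig
    batch_table: np.ndarray
    records: dict
    ledger: dict


def generate_treatment_dataset(config: SimulationConfig,
                               rng: np.random.Generator | int,
                               out_dir) -> TreatmentDataset:
    """Generate and write the full dataset tree for the configured layout.

    Deterministic under a fixed seed: re-running with the same config and
    seed produces a byte-identical tree.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    curve = true_calibration_curve()
    batch = make_calibration_table(curve, 20, 10.0, config.batch_noise_sd, rng)
    _write_table(out / "batch_calibration.csv", batch)

    pose = config.phantom.film_cassette
    # calculated grids are deterministic: compute once per (family, fraction)
    grid_cache: dict = {}

    def calc_grid(family: str, k: int) -> DoseGrid3D:
        var = config.variations(family)[k]
        # cache on the physical effect: rigid translations leave the
        # phantom-frame dose unchanged, so they share the unvaried grid
        key = (tuple(np.round(var.rotation_matrix().ravel(), 12)),
               round(var.body_scale(), 12), round(var.attenuation_delta(), 12))
        if key not in grid_cache:
            grid_cache[key] = compute_plan_dose(config.plan, config.phantom,
                                                var, config.grid)
        return grid_cache[key]

    records, ledger = {}, {"seed_note": "all randomness from one generator",
                           "datasets": {}}
    datasets_dir = out / "datasets"
    for ds_id, family, fracs, mode in config.dataset_plan():
        noise = config.noise
        drift = noise.daily_drift if noise.daily_drift is not None else \
            max(0.5, 1.0 + rng.normal(0.0, noise.daily_drift_sd))
        grids, delivered, frac_truth = [], [], []
        for k in fracs:
            g = calc_grid(family, k)
            scale = noise.delivery_dose_scale if noise.delivery_dose_scale is not None \
                else 1.0 + rng.normal(0.0, noise.delivery_dose_scale_sd)
            shift = np.asarray(noise.delivery_shift, dtype=float) \
                if noise.delivery_shift is not None \
                else rng.normal(0.0, noise.delivery_shift_sd, 2)
            delivered.append(simulate_fraction_delivery(g, pose, config.common,
                                                        scale, shift))
            grids.append(g)
            frac_truth.append({"fraction": k + 1, "dose_scale": float(scale),
                               "residual_shift_mm": [float(v) for v in shift]})
        accumulated = sum_planes(delivered)
        scan, scan_truth = simulate_film_scan(accumulated, curve, noise, rng,
                                              pose.nominal_landmarks, drift)
        daily_doses = config.daily_doses_total if mode == "total_dose" \
            else config.daily_doses_single
        daily = make_daily_table(curve, daily_doses, drift,
                                 noise.film_response_noise, rng)
        chamber = None
        if ds_id in CHAMBER_DATASETS:
            # the chamber sees the delivered dose: sphere-mean of the
            # calculated grid times the fraction's delivery scale, plus
            # chamber reading noise
            calc_mean = _sphere_mean(grids[0], config.phantom.chamber)
            chamber = calc_mean * frac_truth[0]["dose_scale"] * \
                (1.0 + rng.normal(0.0, noise.chamber_noise_sd))
        truth = {"family": family, "fractions": frac_truth, **scan_truth}
        rec = DatasetRecord(ds_id, mode, grids, delivered, accumulated, scan,
                            daily, truth, chamber)
        records[ds_id] = rec
        ledger["datasets"][ds_id] = truth
        _write_dataset(datasets_dir / ds_id, rec, config)

    sim_meta = {
        "cassette": {"plane_offset": pose.plane_offset,
                     "in_plane_origin": pose.in_plane_origin.tolist(),
                     "nominal_landmarks": pose.nominal_landmarks.tolist()},
        "chamber": {"position": config.phantom.chamber.position.tolist(),
                    "radius_mm": config.phantom.chamber.radius},
        "plan": {"n_fractions": config.plan.n_fractions,
                 "fraction_dose_gy": config.plan.fraction_dose,
                 "total_dose_gy": config.plan.total_dose,
                 "n_beams": len(config.plan.beams)},
        "common_grid": {"spacing": config.common.spacing.tolist(),
                        "post_size": config.common.post_size.tolist(),
                        "edge_trim": config.common.edge_trim},
        "layout": config.layout,
        "datasets": [d[0] for d in config.dataset_plan()],
    }
    (out / "simulation.json").write_text(json.dumps(sim_meta, indent=1, sort_keys=True))
    (out / "ledger.json").write_text(json.dumps(ledger, indent=1, sort_keys=True))
    return TreatmentDataset(out, config, batch, records, ledger)


def _sphere_mean(grid: DoseGrid3D, spec: ChamberSpec) -> float:
    """Mean calculated dose over the chamber averaging sphere (shared with
    the analysis-side chamber comparison)."""
    # compare_chamber returns 100*(m-c)/c; invert with m=0 -> c = -c*...,
    # cleaner to recompute directly:
    c, r = spec.position, spec.radius
    off = np.arange(-r, r + 1e-9, 0.5)
    px, py, pz = np.meshgrid(off, off, off, indexing="ij")
    pts = np.stack([px, py, pz], axis=-1).reshape(-1, 3)
    pts = pts[np.sum(pts * pts, axis=1) <= r * r + 1e-9] + c
    return float(np.mean(grid.interpolator()(pts)))


def _write_table(path: Path, table: np.ndarray):
    lines = ["dose_gy,response"]
    lines += [f"{d:.10g},{r:.10g}" for d, r in table]
    path.write_text("\n".join(lines) + "\n")


def _write_dataset(d: Path, rec: DatasetRecord, config: SimulationConfig):
    d.mkdir(parents=True, exist_ok=True)
    for i, g in enumerate(rec.calculated, start=1):
        save_portable(d / f"fraction_{i:02d}", g)
    save_portable(d / "ground_truth_plane", rec.accumulated)
    save_film_tiff(d / "film", rec.scan)
    _write_table(d / "daily_calibration.csv", rec.daily_table)
    meta = {"dataset_id": rec.dataset_id, "mode": rec.mode,
            "n_fractions": len(rec.calculated), "family": rec.truth["family"]}
    if rec.chamber_measured_gy is not None:
        meta["chamber_measured_gy"] = float(rec.chamber_measured_gy)
    (d / "meta.json").write_text(json.dumps(meta, indent=1, sort_keys=True))
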