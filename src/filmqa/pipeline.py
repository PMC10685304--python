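"""QA pipeline orchestration: calibrate -> register -> convert -> extract ->
sum -> normalize -> shift-correct -> compare, with Table-style reports.

Single-fraction and total-dose analyses share every metric implementation;
the only difference is how many calculated fraction grids are summed before
the comparison.  Each report row is a pure function of (inputs, config):
re-running with the same configuration reproduces every number.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import film as fl
from . import grids as gr
from . import metrics as mt
from .errors import ConfigError, FilmQAError


@dataclass
class QaConfig:
    """Paths plus every analysis criterion, loadable from YAML/JSON."""

    dataset_root: Path
    dataset_ids: list | None = None       # None -> all datasets in the tree
    common: gr.CommonGridSpec = field(default_factory=gr.CommonGridSpec)
    gamma: mt.GammaCriteria = field(default_factory=mt.GammaCriteria)
    thresholds: mt.AnalysisThresholds = field(default_factory=mt.AnalysisThresholds)
    dta: mt.DtaSpec = field(default_factory=mt.DtaSpec)
    shift: mt.ShiftSearchSpec = field(default_factory=mt.ShiftSearchSpec)
    dmax_source: str = "calculated"
    calibration_form: str = "rational"
    daily_mode: str = "dose"
    norm_radius_mm: float = 10.0
    require_five_fractions: bool = True   # for total-dose datasets

    def __post_init__(self):
        self.dataset_root = Path(self.dataset_root)

    @classmethod
    def from_yaml(cls, path) -> "QaConfig":
        import yaml
        try:
            raw = yaml.safe_load(Path(path).read_text())
        except FileNotFoundError:
            raise ConfigError(f"config file not found: {path}")
        except yaml.YAMLError as e:
            raise ConfigError(f"malformed config {path}: {e}")
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "QaConfig":
        if "dataset_root" not in raw:
            raise ConfigError("config missing field dataset_root")
        kw = {"dataset_root": raw["dataset_root"],
              "dataset_ids": raw.get("dataset_ids")}
        sections = {"common": gr.CommonGridSpec, "gamma": mt.GammaCriteria,
                    "thresholds": mt.AnalysisThresholds, "dta": mt.DtaSpec,
                    "shift": mt.ShiftSearchSpec}
        for name, klass in sections.items():
            if name in raw:
                try:
                    kw[name] = klass(**raw[name])
                except TypeError as e:
                    raise ConfigError(f"config section {name}: {e}")
        for scalar in ("dmax_source", "calibration_form", "daily_mode",
                       "norm_radius_mm", "require_five_fractions"):
            if scalar in raw:
                kw[scalar] = raw[scalar]
        return cls(**kw)

    def canonical_dict(self) -> dict:
        def enc(o):
            if isinstance(o, (gr.CommonGridSpec, mt.GammaCriteria,
                              mt.AnalysisThresholds, mt.DtaSpec, mt.ShiftSearchSpec)):
                return {k: enc(v) for k, v in vars(o).items()}
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, Path):
                return str(o)
            return o
        return {k: enc(v) for k, v in vars(self).items()}

    def config_hash(self) -> str:
        payload = json.dumps(self.canonical_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def validate(self):
        root = self.dataset_root
        if not root.is_dir():
            raise ConfigError(f"dataset root {root} does not exist")
        for f in ("batch_calibration.csv", "simulation.json"):
            if not (root / f).is_file():
                raise ConfigError(f"missing input file {root / f}")
        for ds in self.resolve_dataset_ids():
            d = root / "datasets" / ds
            for f in ("meta.json", "daily_calibration.csv", "film.tif", "film.json"):
                if not (d / f).is_file():
                    raise ConfigError(f"dataset {ds}: missing input file {d / f}")
            if not list(d.glob("fraction_*.npz")):
                raise ConfigError(f"dataset {ds}: no calculated fraction grids")

    def resolve_dataset_ids(self) -> list:
        if self.dataset_ids is not None:
            return list(self.dataset_ids)
        sim = json.loads((self.dataset_root / "simulation.json").read_text())
        return list(sim["datasets"])


def _read_table(path: Path) -> np.ndarray:
    df = pd.read_csv(path)
    for col in ("dose_gy", "response"):
        if col not in df.columns:
            raise ConfigError(f"{path}: calibration table missing column {col}")
    return df[["dose_gy", "response"]].to_numpy(dtype=float)


@dataclass
class QaReport:
    rows: pd.DataFrame
    results: dict                      # dataset_id -> ComparisonResult
    profiles: dict                     # dataset_id -> profile dict
    provenance: dict

    @property
    def shift_stats(self) -> dict:
        s = self.rows[["shift_crossline_mm", "shift_inline_mm"]]
        return {
            "crossline_mean_mm": float(s["shift_crossline_mm"].mean()),
            "crossline_sd_mm": float(s["shift_crossline_mm"].std(ddof=0)),
            "inline_mean_mm": float(s["shift_inline_mm"].mean()),
            "inline_sd_mm": float(s["shift_inline_mm"].std(ddof=0)),
        }

    def write(self, out_dir) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.rows.to_csv(out / "report.csv", index=False)
        (out / "provenance.json").write_text(
            json.dumps({**self.provenance, "shift_stats": self.shift_stats},
                       indent=1, sort_keys=True))
        for ds, res in self.results.items():
            np.savez_compressed(out / f"maps_{ds}.npz", gamma=res.gamma_map,
                                deviation=res.deviation_map, dta=res.dta_map,
                                saturated=res.saturated)
        for ds, prof in self.profiles.items():
            frames = []
            for direction, p in prof.items():
                frames.append(pd.DataFrame({
                    "direction": direction, "coord_mm": p["coord_mm"],
                    "measured": p["measured"], "calculated": p["calculated"],
                    "diff_pp": p["diff_pp"]}))
            pd.concat(frames).to_csv(out / f"profiles_{ds}.csv", index=False)
        return out / "report.csv"


def _stage(ds_id: str, name: str):
    """Context manager attaching stage/dataset info to pipeline errors."""
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and isinstance(exc, FilmQAError):
                exc.args = (f"[{ds_id}/{name}] {exc}",)
            return False
    return _Ctx()


def analyze_dataset(config: QaConfig, ds_id: str):
    """Run the full comparison chain on one dataset.

    Returns ``(ComparisonResult, profiles dict)``.
    """
    root = config.dataset_root
    d = root / "datasets" / ds_id
    sim = json.loads((root / "simulation.json").read_text())
    meta = json.loads((d / "meta.json").read_text())
    nominal = np.asarray(sim["cassette"]["nominal_landmarks"], dtype=float)

    with _stage(ds_id, "calibrate"):
        curve = fl.fit_calibration_curve(_read_table(root / "batch_calibration.csv"),
                                         form=config.calibration_form)
        curve = fl.rescale_daily(curve, _read_table(d / "daily_calibration.csv"),
                                 mode=config.daily_mode)
    with _stage(ds_id, "register"):
        scan = fl.load_film_tiff(d / "film")
        transform = fl.solve_landmark_transform(scan.landmarks, nominal)
        registered = fl.apply_transform(scan, transform, config.common)
    with _stage(ds_id, "convert"):
        measured_abs = fl.convert_response_to_dose(registered, curve)
    with _stage(ds_id, "extract"):
        pose = gr.CassettePose(sim["cassette"]["plane_offset"],
                               sim["cassette"]["in_plane_origin"],
                               nominal)
        grid_files = sorted(d.glob("fraction_*.npz"))
        grids3d = [gr.load_portable(p) for p in grid_files]
        planes = [gr.extract_film_plane(g, pose, config.common) for g in grids3d]
    with _stage(ds_id, "sum"):
        if meta["mode"] == "total_dose" and config.require_five_fractions \
                and len(planes) != 5:
            raise ConfigError(f"total-dose dataset has {len(planes)} fractions, "
                              "expected 5 (set require_five_fractions=False to override)")
        calc_abs = gr.sum_planes(planes)
    with _stage(ds_id, "crop"):
        measured_abs = gr.crop_edge_voxels(measured_abs, config.common)
        calc_abs = gr.crop_edge_voxels(calc_abs, config.common)
    with _stage(ds_id, "normalize"):
        center = mt.locate_high_dose_center(calc_abs)
        calc_rel = mt.normalize_relative(calc_abs, center, config.norm_radius_mm)
        measured_rel = mt.normalize_relative(measured_abs, center,
                                             config.norm_radius_mm)
    with _stage(ds_id, "shift"):
        shift, measured_shifted = mt.optimize_shift(measured_rel, calc_rel,
                                                    config.shift, config.thresholds,
                                                    config.dmax_source)
    with _stage(ds_id, "compare"):
        gamma_map, pass_rates = mt.compute_gamma(measured_shifted, calc_rel,
                                                 config.gamma, config.thresholds,
                                                 config.dmax_source)
        dev_map, dev_stats = mt.compute_dose_deviation(measured_shifted, calc_rel,
                                                       config.thresholds,
                                                       config.dmax_source)
        dta_map, dta_stats, saturated = mt.compute_dta(measured_shifted, calc_rel,
                                                       config.dta, config.thresholds,
                                                       config.dmax_source)
        profiles = mt.extract_center_profiles(measured_shifted, calc_rel, center)
        chamber_diff = None
        if "chamber_measured_gy" in meta and meta["mode"] == "single_fraction":
            spec = mt.ChamberSpec(sim["chamber"]["position"],
                                  sim["chamber"]["radius_mm"])
            chamber_diff = mt.compare_chamber(meta["chamber_measured_gy"],
                                              grids3d[0], spec)
        excluded = int((~measured_shifted.valid).sum() + (~calc_rel.valid).sum())
        result = mt.summarize_comparison(
            ds_id, gamma_map, pass_rates, dev_map, dev_stats, dta_map, dta_stats,
            saturated, shift, measured_rel.norm_dose, calc_rel.norm_dose,
            excluded, chamber_diff)
    return result, profiles


def _run(config: QaConfig, modes) -> QaReport:
    config.validate()
    root = config.dataset_root
    results, profiles, rows = {}, {}, []
    for ds_id in config.resolve_dataset_ids():
        meta = json.loads((root / "datasets" / ds_id / "meta.json").read_text())
        if meta["mode"] not in modes:
            continue
        res, prof = analyze_dataset(config, ds_id)
        results[ds_id] = res
        profiles[ds_id] = prof
        rows.append(res.to_row())
    if not rows:
        raise ConfigError(f"no datasets with mode in {sorted(modes)} found")
    df = pd.DataFrame(rows)
    provenance = {"config_hash": config.config_hash(),
                  "dataset_root": str(root),
                  "n_datasets": len(rows)}
    return QaReport(df, results, profiles, provenance)


def run_fraction_qa(config: QaConfig) -> QaReport:
    """Single-fraction QA on every single-fraction dataset in the config."""
    return _run(config, {"single_fraction"})


def run_total_qa(config: QaConfig) -> QaReport:
    """Total-dose QA: sums the five per-fraction calculated planes and runs
    the comparison once against the accumulated film."""
    return _run(config, {"total_dose"})


def run_qa(config: QaConfig) -> QaReport:
    """All datasets, single-fraction and total-dose alike."""
    return _run(config, {"single_fraction", "total_dose"})
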