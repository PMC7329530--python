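"""Readers, writers, configuration and the end-to-end pipeline.

All geometry lives in physical millimetres (x rightward along columns,
y downward along rows, origin at the image center); the single pixel<->mm
conversion layer sits at the image boundary. Image stacks are stored as
multi-page TIFF (portable, text-free tests use it round-trip); DICOM series
are read with pydicom. Contours, tracks and curves travel as CSV; torsion,
ground truth, reports and resolved configs as JSON with sorted keys and
fixed float precision so reruns are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml
from shapely import contains_xy
from shapely.geometry import Polygon

from . import ffd as _ffd
from . import harp as _harp
from . import kinematics as _kin
from .phantom import (
    MotionModel,
    PhantomConfig,
    PhantomStudy,
    TaggedCineSeries,
    pixel_grid_mm,
)
from .tracks import MaterialPointTracks

__all__ = [
    "StudyBundle",
    "RunConfig",
    "write_study",
    "read_study",
    "read_dicom_series",
    "read_contours",
    "write_contours",
    "contours_to_mask",
    "mask_seed_points",
    "write_tracks_csv",
    "read_tracks_csv",
    "write_curve_csv",
    "read_curve_csv",
    "write_torsion_json",
    "read_torsion_json",
    "run_pipeline",
]

log = logging.getLogger(__name__)

_FLOAT_DECIMALS = 9


class GeometryError(ValueError):
    """Invalid contour geometry."""


class AmbiguousSeriesError(ValueError):
    """Directory holds more than one DICOM series."""


# ---------------------------------------------------------------------------
# study bundle


@dataclass
class StudyBundle:
    """Two-plane tagged study with contours and inter-slice distance."""

    apical: TaggedCineSeries
    basal: TaggedCineSeries
    contours: dict[str, dict[str, np.ndarray]]
    slice_distance: float | None = None
    subject_id: str = "unknown"
    group_label: str = ""

    def __post_init__(self) -> None:
        if self.slice_distance is None:
            self.slice_distance = abs(self.basal.slice_location - self.apical.slice_location)
        if self.slice_distance <= 0:
            raise ValueError("slice_distance must be > 0")

    def series(self, plane: str) -> TaggedCineSeries:
        return {"apical": self.apical, "basal": self.basal}[plane]


def bundle_from_phantom(study: PhantomStudy, subject_id: str = "phantom",
                        group_label: str = "synthetic") -> StudyBundle:
    return StudyBundle(apical=study.apical, basal=study.basal, contours=study.contours,
                       subject_id=subject_id, group_label=group_label)


# ---------------------------------------------------------------------------
# JSON helpers (deterministic output)


def _round_floats(obj):
    if isinstance(obj, float):
        return round(obj, _FLOAT_DECIMALS)
    if isinstance(obj, dict):
        return {k: _round_floats(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return _round_floats(obj.tolist())
    if isinstance(obj, (np.floating,)):
        return round(float(obj), _FLOAT_DECIMALS)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj


def write_json(path, obj) -> None:
    Path(path).write_text(json.dumps(_round_floats(obj), indent=2, sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# study directory (TIFF stacks + CSV contours + JSON ground truth)


def write_study(study: PhantomStudy, out_dir) -> Path:
    """Write a phantom study as a portable directory: one multi-page TIFF per
    plane, per-plane contour CSVs, ground truth and config echo as JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for plane in ("apical", "basal"):
        series = study.apical if plane == "apical" else study.basal
        tifffile.imwrite(out / f"{plane}.tif", series.frames.astype(np.float32))
        write_contours(out / f"contours_{plane}.csv", study.contours[plane])
    meta = {
        plane: {
            "pixel_spacing": s.pixel_spacing,
            "trigger_times_ms": list(s.trigger_times),
            "tag_spacing": s.tag_spacing,
            "slice_location": s.slice_location,
        }
        for plane, s in (("apical", study.apical), ("basal", study.basal))
    }
    write_json(out / "study.json", meta)
    truth = {
        "rotation_deg": {p: list(study.truth.rotation_deg(p)) for p in ("apical", "basal")},
        "end_systole_index": study.truth.end_systole_index,
        "config": _config_echo(study.config),
    }
    write_json(out / "ground_truth.json", truth)
    return out


def _config_echo(cfg: PhantomConfig) -> dict:
    d = dataclasses.asdict(cfg)
    return d


def read_study(study_dir) -> StudyBundle:
    """Read a study directory written by :func:`write_study`."""
    d = Path(study_dir)
    meta = json.loads((d / "study.json").read_text())
    series = {}
    contours = {}
    for plane in ("apical", "basal"):
        frames = np.asarray(tifffile.imread(d / f"{plane}.tif"), dtype=float)
        m = meta[plane]
        series[plane] = TaggedCineSeries(
            frames=frames,
            pixel_spacing=float(m["pixel_spacing"]),
            trigger_times=np.asarray(m["trigger_times_ms"], dtype=float),
            tag_spacing=float(m["tag_spacing"]),
            plane_label=plane,
            slice_location=float(m["slice_location"]),
        )
        contours[plane] = read_contours(d / f"contours_{plane}.csv")
    return StudyBundle(apical=series["apical"], basal=series["basal"], contours=contours)


# ---------------------------------------------------------------------------
# DICOM


def read_dicom_series(directory, tag_spacing: float, plane_label: str = "unknown") -> TaggedCineSeries:
    """Read one single-slice multi-phase tagged series from a DICOM directory.

    Frames are ordered by trigger time (falling back to instance number with a
    warning when trigger times are absent). Tag spacing is not a DICOM field
    and must be supplied. A directory holding more than one series is
    rejected as ambiguous.
    """
    import pydicom

    files = sorted(p for p in Path(directory).iterdir() if p.is_file())
    datasets = []
    for p in files:
        try:
            datasets.append(pydicom.dcmread(p))
        except Exception:  # non-DICOM files are skipped
            continue
    if not datasets:
        raise FileNotFoundError(f"no DICOM files in {directory}")
    uids = {ds.SeriesInstanceUID for ds in datasets}
    if len(uids) > 1:
        raise AmbiguousSeriesError(f"directory holds {len(uids)} series: {sorted(uids)}")

    have_tt = all(hasattr(ds, "TriggerTime") for ds in datasets)
    if have_tt:
        datasets.sort(key=lambda ds: float(ds.TriggerTime))
        times = np.array([float(ds.TriggerTime) for ds in datasets])
    else:
        warnings.warn("missing trigger times; falling back to instance-number order")
        datasets.sort(key=lambda ds: int(ds.InstanceNumber))
        times = np.arange(len(datasets), dtype=float)

    frames = np.stack([ds.pixel_array.astype(float) for ds in datasets])
    ps = datasets[0].PixelSpacing
    if abs(float(ps[0]) - float(ps[1])) > 1e-6:
        raise ValueError("anisotropic pixel spacing is not supported")
    slice_loc = float(getattr(datasets[0], "SliceLocation", 0.0))
    return TaggedCineSeries(
        frames=frames, pixel_spacing=float(ps[0]), trigger_times=times,
        tag_spacing=tag_spacing, plane_label=plane_label, slice_location=slice_loc,
    )


# ---------------------------------------------------------------------------
# contours and masks


def write_contours(path, contours: dict[str, np.ndarray]) -> None:
    rows = []
    for surface in ("endo", "epi"):
        for x, y in np.asarray(contours[surface], dtype=float):
            rows.append({"x_mm": x, "y_mm": y, "surface": surface})
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.6f")


def read_contours(path) -> dict[str, np.ndarray]:
    """Read an endo/epi contour pair from CSV (columns x_mm, y_mm, surface).

    Each surface must form a valid simple closed polygon and the endocardial
    contour must lie inside the epicardial one.
    """
    df = pd.read_csv(path)
    required = {"x_mm", "y_mm", "surface"}
    if not required.issubset(df.columns):
        raise ValueError(f"contour CSV must have columns {sorted(required)}")
    out = {}
    polys = {}
    for surface in ("endo", "epi"):
        pts = df.loc[df["surface"] == surface, ["x_mm", "y_mm"]].to_numpy(dtype=float)
        if pts.shape[0] < 3:
            raise GeometryError(f"{surface} contour needs >= 3 points")
        poly = Polygon(pts)
        if not poly.is_valid or poly.area <= 0:
            raise GeometryError(f"{surface} contour is not a simple closed polygon")
        out[surface] = pts
        polys[surface] = poly
    if not polys["epi"].contains(polys["endo"]):
        raise GeometryError("endocardial contour must lie inside the epicardial contour")
    return out


def contours_to_mask(contours: dict[str, np.ndarray], shape: tuple[int, int],
                     pixel_spacing: float) -> np.ndarray:
    """Myocardial mask: pixel centers inside the epicardial polygon and
    outside the endocardial polygon (even-odd containment)."""
    gx, gy = pixel_grid_mm(shape, pixel_spacing)
    epi = Polygon(np.asarray(contours["epi"], dtype=float))
    endo = Polygon(np.asarray(contours["endo"], dtype=float))
    inside_epi = contains_xy(epi, gx.ravel(), gy.ravel()).reshape(shape)
    inside_endo = contains_xy(endo, gx.ravel(), gy.ravel()).reshape(shape)
    return inside_epi & ~inside_endo


def mask_seed_points(mask: np.ndarray, pixel_spacing: float) -> np.ndarray:
    """(N, 2) mm coordinates of all pixel centers inside the mask."""
    gx, gy = pixel_grid_mm(mask.shape, pixel_spacing)
    return np.stack([gx[mask], gy[mask]], axis=1)


# ---------------------------------------------------------------------------
# tracks / curves / torsion files


def write_tracks_csv(path, tracks: MaterialPointTracks) -> None:
    n, T = tracks.n_points, tracks.n_frames
    df = pd.DataFrame(
        {
            "point_id": np.repeat(np.arange(n), T),
            "frame": np.tile(np.arange(T), n),
            "x_mm": tracks.positions[:, :, 0].ravel(),
            "y_mm": tracks.positions[:, :, 1].ravel(),
            "valid": tracks.valid.ravel().astype(int),
        }
    )
    df.to_csv(path, index=False, float_format="%.6f")


def read_tracks_csv(path, source: str = "unknown") -> MaterialPointTracks:
    df = pd.read_csv(path)
    n = df["point_id"].nunique()
    T = df["frame"].nunique()
    df = df.sort_values(["point_id", "frame"])
    pos = np.stack(
        [df["x_mm"].to_numpy().reshape(n, T), df["y_mm"].to_numpy().reshape(n, T)], axis=2
    )
    valid = df["valid"].to_numpy().reshape(n, T).astype(bool)
    return MaterialPointTracks(positions=pos, valid=valid, source=source)


def write_curve_csv(path, curve: _kin.RotationCurve) -> None:
    pd.DataFrame(
        {
            "percent_systole": curve.times_percent,
            "rotation_deg": curve.rotation_deg,
            "n_points": curve.n_points_used,
        }
    ).to_csv(path, index=False, float_format="%.9f")


def read_curve_csv(path, plane_label: str = "unknown", source: str = "unknown") -> _kin.RotationCurve:
    df = pd.read_csv(path)
    return _kin.RotationCurve(
        plane_label=plane_label,
        times_percent=df["percent_systole"].to_numpy(),
        rotation_deg=df["rotation_deg"].to_numpy(),
        n_points_used=df["n_points"].to_numpy(),
        source=source,
    )


def write_torsion_json(path, result: _kin.TorsionResult) -> None:
    write_json(
        path,
        {
            "times_percent": list(result.times_percent),
            "torsion_deg": list(result.torsion_deg),
            "end_systolic_apical_rotation": result.end_systolic_apical_rotation,
            "end_systolic_basal_rotation": result.end_systolic_basal_rotation,
            "end_systolic_torsion": result.end_systolic_torsion,
            "normalized_torsion": result.normalized_torsion,
            "slice_distance": result.slice_distance,
        },
    )


def read_torsion_json(path) -> _kin.TorsionResult:
    d = json.loads(Path(path).read_text())
    return _kin.TorsionResult(
        times_percent=np.asarray(d["times_percent"], dtype=float),
        torsion_deg=np.asarray(d["torsion_deg"], dtype=float),
        end_systolic_apical_rotation=d["end_systolic_apical_rotation"],
        end_systolic_basal_rotation=d["end_systolic_basal_rotation"],
        end_systolic_torsion=d["end_systolic_torsion"],
        normalized_torsion=d["normalized_torsion"],
        slice_distance=d["slice_distance"],
    )


# ---------------------------------------------------------------------------
# run configuration


_KNOWN_SECTIONS = {"engine", "harp", "ffd", "phantom", "kinematics", "seed", "output"}


@dataclass
class RunConfig:
    """Fully resolved run configuration; unknown keys are rejected."""

    engine: str = "both"           # harp | ffd | both
    harp: _harp.HarpConfig = field(default_factory=_harp.HarpConfig)
    ffd: _ffd.FfdConfig = field(default_factory=_ffd.FfdConfig)
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    resample_n: int = 51
    seed: int = 0
    orientation_flip: bool = False  # real-data handedness correction

    def __post_init__(self) -> None:
        if self.engine not in ("harp", "ffd", "both"):
            raise ValueError("engine must be harp | ffd | both")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        def build(dc_cls, section):
            known = {f.name for f in dataclasses.fields(dc_cls)}
            unknown = set(section) - known
            if unknown:
                raise ValueError(f"unknown config keys: {sorted(unknown)}")
            return dc_cls(**section)

        top_known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - top_known
        if unknown:
            raise ValueError(f"unknown config sections: {sorted(unknown)}")
        kwargs = dict(raw)
        if "harp" in kwargs and isinstance(kwargs["harp"], dict):
            sect = dict(kwargs["harp"])
            if "filter_spec" in sect and isinstance(sect["filter_spec"], dict):
                fs = dict(sect["filter_spec"])
                if "center_frequencies" in fs:
                    fs["center_frequencies"] = tuple(fs["center_frequencies"])
                sect["filter_spec"] = build(_harp.GaborFilterSpec, fs)
            kwargs["harp"] = build(_harp.HarpConfig, sect)
        if "ffd" in kwargs and isinstance(kwargs["ffd"], dict):
            kwargs["ffd"] = build(_ffd.FfdConfig, kwargs["ffd"])
        if "phantom" in kwargs and isinstance(kwargs["phantom"], dict):
            sect = dict(kwargs["phantom"])
            for key in ("apical_motion", "basal_motion"):
                if key in sect and isinstance(sect[key], dict):
                    sect[key] = build(MotionModel, sect[key])
            if "matrix" in sect:
                sect["matrix"] = tuple(sect["matrix"])
            kwargs["phantom"] = build(PhantomConfig, sect)
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def write_resolved(self, path) -> None:
        write_json(path, self.to_dict())


# ---------------------------------------------------------------------------
# end-to-end pipeline


def _track(engine: str, series: TaggedCineSeries, seeds: np.ndarray,
           cfg: RunConfig, mask: np.ndarray | None = None) -> MaterialPointTracks:
    if engine == "harp":
        return _harp.harp_track_series(series, seeds, cfg.harp)
    if engine == "ffd":
        return _ffd.ffd_track_series(series, seeds, cfg.ffd, domain=mask)
    raise ValueError(engine)


def analyze_study(
    bundle: StudyBundle, engine: str, cfg: RunConfig | None = None
) -> dict:
    """Track both planes with one engine and compute rotation + torsion."""
    cfg = cfg or RunConfig()
    out: dict = {"engine": engine, "curves": {}, "tracks": {}}
    for plane in ("apical", "basal"):
        series = bundle.series(plane)
        mask = contours_to_mask(bundle.contours[plane], series.shape, series.pixel_spacing)
        seeds = mask_seed_points(mask, series.pixel_spacing)
        log.info("tracking %s plane with %s engine (%d seeds)", plane, engine, len(seeds))
        tracks = _track(engine, series, seeds, cfg, mask=mask)
        curve, _ = _kin.plane_rotation_curve(
            tracks, series.trigger_times, plane, pixel_spacing=series.pixel_spacing,
            n_out=cfg.resample_n,
        )
        if cfg.orientation_flip:
            curve.rotation_deg = -curve.rotation_deg
        out["tracks"][plane] = tracks
        out["curves"][plane] = curve
    out["torsion"] = _kin.torsion(
        out["curves"]["apical"], out["curves"]["basal"], bundle.slice_distance
    )
    return out


def run_pipeline(cfg: RunConfig, bundle: StudyBundle, out_dir) -> dict:
    """Run the configured engines end-to-end on a study and write all outputs.

    Deterministic given the seed; every run archives its fully resolved
    configuration next to the outputs. Returns the in-memory results keyed by
    engine, plus the comparison report when both engines ran.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg.write_resolved(out / "resolved_config.json")
    engines = ["harp", "ffd"] if cfg.engine == "both" else [cfg.engine]
    results = {}
    for engine in engines:
        log.info("pipeline stage: %s engine", engine)
        res = analyze_study(bundle, engine, cfg)
        for plane in ("apical", "basal"):
            write_tracks_csv(out / f"tracks_{engine}_{plane}.csv", res["tracks"][plane])
            write_curve_csv(out / f"curve_{engine}_{plane}.csv", res["curves"][plane])
        write_torsion_json(out / f"torsion_{engine}.json", res["torsion"])
        results[engine] = res

    if len(engines) == 2:
        report = {}
        for measure, getter in (
            ("apical_rotation", lambda r: r["torsion"].end_systolic_apical_rotation),
            ("basal_rotation", lambda r: r["torsion"].end_systolic_basal_rotation),
            ("torsion", lambda r: r["torsion"].end_systolic_torsion),
        ):
            report[measure] = {
                "harp": getter(results["harp"]),
                "ffd": getter(results["ffd"]),
                "difference": getter(results["harp"]) - getter(results["ffd"]),
            }
        write_json(out / "comparison_report.json", report)
        results["comparison"] = report
    return results
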