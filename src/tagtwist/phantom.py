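"""Synthetic SPAMM-tagged short-axis phantom with exact ground-truth motion.

An annular myocardial cross-section rotates about its center (opposite signs
at the apical and basal levels, the systolic "wringing" motion) and contracts
radially. A grid tag pattern is imprinted in material coordinates so the tags
move with the tissue; tag contrast fades exponentially (T1-like) and additive
Gaussian noise emulates acquisition noise.

Coordinates are physical millimetres: x rightward (columns), y downward
(rows), origin at the image center. Rotation is counterclockwise-positive in
the (x, y) frame, the convention shared with the kinematics module
(counterclockwise viewed from the apex = positive; apical rotation positive,
basal negative in a healthy pattern).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MotionModel",
    "PhantomConfig",
    "GroundTruthMotion",
    "TaggedCineSeries",
    "PhantomStudy",
    "deform_point",
    "inverse_deform_point",
    "render_frame",
    "generate_study",
    "circle_contour",
    "pixel_grid_mm",
]


class PhantomConfigError(ValueError):
    """Raised for phantom configurations that cannot be rendered."""


@dataclass(frozen=True)
class MotionModel:
    """Rigid rotation plus radial contraction of an annulus about a center.

    The activation ramp s(t) = (k / (n_frames - 1)) ** timing_exponent is
    monotone with s = 0 at frame 0 (end-diastole) and s = 1 at the last frame
    (end-systole). At frame k a material point p maps to

        center + (1 - s * contraction_fraction) * R(s * peak_rotation) (p - center)

    which is an analytic bijection of the plane for contraction_fraction < 0.5.
    """

    center: tuple[float, float] = (0.0, 0.0)
    peak_rotation_deg: float = 8.0
    contraction_fraction: float = 0.1
    timing_exponent: float = 1.0
    n_frames: int = 22
    frame_interval_ms: float = 15.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.contraction_fraction < 0.5):
            raise PhantomConfigError(
                "contraction_fraction must be in [0, 0.5) for an invertible motion, "
                f"got {self.contraction_fraction}"
            )
        if self.timing_exponent <= 0:
            raise PhantomConfigError("timing_exponent must be > 0")
        if self.n_frames < 2:
            raise PhantomConfigError("n_frames must be >= 2")
        if self.frame_interval_ms <= 0:
            raise PhantomConfigError("frame_interval_ms must be > 0")

    def activation(self, frame: int | np.ndarray) -> float | np.ndarray:
        """Monotone activation s(frame) in [0, 1]."""
        self._check_frame(frame)
        return (np.asarray(frame, dtype=float) / (self.n_frames - 1)) ** self.timing_exponent

    def rotation_deg(self, frame: int | np.ndarray) -> float | np.ndarray:
        """Ground-truth rotation angle (degrees) at a frame."""
        return self.activation(frame) * self.peak_rotation_deg

    def _check_frame(self, frame) -> None:
        f = np.asarray(frame)
        if np.any(f < 0) or np.any(f >= self.n_frames):
            raise IndexError(f"frame {frame} outside [0, {self.n_frames})")


def _rotation_matrix(angle_deg: float) -> np.ndarray:
    a = np.deg2rad(angle_deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s], [s, c]])


def deform_point(model: MotionModel, p, frame: int) -> np.ndarray:
    """Forward motion: material point(s) ``p`` (mm) to their position at ``frame``.

    Accepts a single (2,) point or an (N, 2) array. Frame 0 is the identity.
    """
    model._check_frame(frame)
    s = float(model.activation(frame))
    p = np.asarray(p, dtype=float)
    if s == 0.0:
        return p.copy()   # frame 0 is the exact identity
    c = np.asarray(model.center, dtype=float)
    scale = 1.0 - s * model.contraction_fraction
    R = _rotation_matrix(s * model.peak_rotation_deg)
    return (p - c) @ (scale * R).T + c


def inverse_deform_point(model: MotionModel, q, frame: int) -> np.ndarray:
    """Analytic inverse of :func:`deform_point`: spatial point(s) at ``frame``
    back to material (frame-0) coordinates."""
    model._check_frame(frame)
    s = float(model.activation(frame))
    q = np.asarray(q, dtype=float)
    if s == 0.0:
        return q.copy()   # frame 0 is the exact identity
    c = np.asarray(model.center, dtype=float)
    scale = 1.0 - s * model.contraction_fraction
    R = _rotation_matrix(-s * model.peak_rotation_deg)
    return (q - c) @ (R / scale).T + c


def _default_apical() -> "MotionModel":
    return MotionModel(peak_rotation_deg=8.0)


def _default_basal() -> "MotionModel":
    return MotionModel(peak_rotation_deg=-4.0)


@dataclass(frozen=True)
class PhantomConfig:
    """Acquisition + geometry + motion parameters of a two-plane phantom study.

    Defaults emulate a clinical grid-SPAMM protocol: 8 mm tag spacing,
    1.25 mm isotropic pixels, 22 systolic phases. The rendered matrix defaults
    to 128 x 128 for desk-scale speed; ``matrix=(208, 256)`` reproduces the
    clinical matrix.
    """

    inner_radius: float = 15.0      # endocardial radius, mm
    outer_radius: float = 30.0      # epicardial radius, mm
    tag_spacing: float = 8.0        # mm between tag lines
    pixel_spacing: float = 1.25     # mm
    matrix: tuple[int, int] = (128, 128)  # rows, cols
    n_frames: int = 22
    frame_interval_ms: float = 15.0
    tag_fade_time_ms: float = 850.0  # T1-like exponential fade constant
    noise_sd: float = 0.05           # additive Gaussian sd; ~SNR 20 on unit signal
    seed: int = 0
    slice_gap: float = 40.0          # apical-basal distance, mm
    apical_motion: MotionModel = field(default_factory=_default_apical)
    basal_motion: MotionModel = field(default_factory=_default_basal)
    tag_contrast: float = 0.8        # raised-cosine tag depth alpha
    base_intensity: float = 0.2
    tag_amplitude: float = 0.8
    grid_angle_deg: float = 0.0      # tag grid orientation w.r.t. image axes

    def __post_init__(self) -> None:
        if self.inner_radius >= self.outer_radius:
            raise PhantomConfigError("inner_radius must be < outer_radius")
        if self.tag_spacing <= 2 * self.pixel_spacing:
            raise PhantomConfigError(
                "tag_spacing must exceed 2 x pixel_spacing for resolvable tags"
            )
        if self.pixel_spacing <= 0 or self.noise_sd < 0 or self.slice_gap <= 0:
            raise PhantomConfigError("pixel_spacing, slice_gap must be > 0; noise_sd >= 0")
        if not (0 < self.tag_contrast <= 1):
            raise PhantomConfigError("tag_contrast must be in (0, 1]")
        for label, m in (("apical", self.apical_motion), ("basal", self.basal_motion)):
            if m.n_frames != self.n_frames:
                raise PhantomConfigError(
                    f"{label} motion n_frames {m.n_frames} != config n_frames {self.n_frames}"
                )

    def with_(self, **kwargs) -> "PhantomConfig":
        """Return a copy with fields replaced (motions re-framed if n_frames changes)."""
        if "n_frames" in kwargs:
            nf = kwargs["n_frames"]
            for key in ("apical_motion", "basal_motion"):
                if key not in kwargs:
                    kwargs[key] = dataclasses.replace(getattr(self, key), n_frames=nf)
        return dataclasses.replace(self, **kwargs)

    @property
    def trigger_times_ms(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval_ms


@dataclass
class TaggedCineSeries:
    """One slice level's tagged cine images with geometry and timing metadata."""

    frames: np.ndarray          # (T, rows, cols) float
    pixel_spacing: float        # mm
    trigger_times: np.ndarray   # ms, strictly increasing
    tag_spacing: float          # mm
    plane_label: str            # "apical" | "basal"
    slice_location: float = 0.0  # mm

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.trigger_times = np.asarray(self.trigger_times, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[0] < 2:
            raise ValueError("frames must be (T, rows, cols) with T >= 2")
        if self.frames.shape[0] != self.trigger_times.shape[0]:
            raise ValueError("one trigger time per frame required")
        if np.any(np.diff(self.trigger_times) <= 0):
            raise ValueError("trigger_times must be strictly increasing")
        if self.pixel_spacing <= 0:
            raise ValueError("pixel_spacing must be > 0")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("frame intensities must be finite")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]


@dataclass
class GroundTruthMotion:
    """Exact per-frame rotation per plane and a dense displacement sampler."""

    models: dict[str, MotionModel]          # plane label -> motion
    end_systole_index: int

    def rotation_deg(self, plane: str) -> np.ndarray:
        m = self.models[plane]
        return np.asarray(m.rotation_deg(np.arange(m.n_frames)), dtype=float)

    def displace(self, plane: str, p, frame: int) -> np.ndarray:
        """Position at ``frame`` of material point(s) ``p`` (mm)."""
        return deform_point(self.models[plane], p, frame)

    def tracks(self, plane: str, seeds: np.ndarray) -> np.ndarray:
        """Exact trajectories (N, T, 2) of material seed points."""
        m = self.models[plane]
        return np.stack(
            [deform_point(m, seeds, k) for k in range(m.n_frames)], axis=1
        )


@dataclass
class PhantomStudy:
    """Everything :func:`generate_study` produces for one synthetic subject."""

    apical: TaggedCineSeries
    basal: TaggedCineSeries
    truth: GroundTruthMotion
    contours: dict[str, dict[str, np.ndarray]]  # plane -> {"endo": (N,2), "epi": (N,2)}
    config: PhantomConfig

    @property
    def slice_distance(self) -> float:
        return abs(self.basal.slice_location - self.apical.slice_location)


def pixel_grid_mm(shape: tuple[int, int], pixel_spacing: float) -> tuple[np.ndarray, np.ndarray]:
    """Physical (x, y) coordinates in mm of all pixel centers, origin at image center."""
    rows, cols = shape
    x = (np.arange(cols) - (cols - 1) / 2.0) * pixel_spacing
    y = (np.arange(rows) - (rows - 1) / 2.0) * pixel_spacing
    return np.meshgrid(x, y)


def _tag_pattern(x: np.ndarray, y: np.ndarray, cfg: PhantomConfig) -> np.ndarray:
    """Grid SPAMM pattern in material coordinates: product of two orthogonal
    raised cosines, minima (tag lines) at multiples of tag_spacing."""
    a = np.deg2rad(cfg.grid_angle_deg)
    u = np.cos(a) * x + np.sin(a) * y
    v = -np.sin(a) * x + np.cos(a) * y
    w = 2 * np.pi / cfg.tag_spacing
    return (1.0 - cfg.tag_contrast * np.cos(w * u)) * (1.0 - cfg.tag_contrast * np.cos(w * v))


def render_frame(
    cfg: PhantomConfig,
    model: MotionModel,
    frame: int,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Render one tagged frame of the deforming annulus.

    Each pixel center is pulled back to material coordinates through the
    analytic inverse motion; the annulus mask and the tag pattern are both
    evaluated there, so tags (and the tissue boundary) move with the tissue.
    Tag amplitude fades as exp(-trigger_time / tag_fade_time_ms). Noise is
    added only when an ``rng`` is supplied.
    """
    model._check_frame(frame)
    gx, gy = pixel_grid_mm(cfg.matrix, cfg.pixel_spacing)
    pts = np.stack([gx.ravel(), gy.ravel()], axis=1)
    ref = inverse_deform_point(model, pts, frame)
    xr = ref[:, 0].reshape(cfg.matrix)
    yr = ref[:, 1].reshape(cfg.matrix)

    cx, cy = model.center
    r = np.hypot(xr - cx, yr - cy)
    mask = (r >= cfg.inner_radius) & (r <= cfg.outer_radius)

    fade = np.exp(-frame * cfg.frame_interval_ms / cfg.tag_fade_time_ms)
    img = mask * (cfg.base_intensity + cfg.tag_amplitude * fade * _tag_pattern(xr - cx, yr - cy, cfg))
    if rng is not None and cfg.noise_sd > 0:
        img = img + rng.normal(0.0, cfg.noise_sd, size=img.shape)
    return img


def _render_series(cfg: PhantomConfig, model: MotionModel, label: str,
                   slice_location: float, rng: np.random.Generator | None) -> TaggedCineSeries:
    frames = np.stack([render_frame(cfg, model, k, rng) for k in range(cfg.n_frames)])
    return TaggedCineSeries(
        frames=frames,
        pixel_spacing=cfg.pixel_spacing,
        trigger_times=cfg.trigger_times_ms,
        tag_spacing=cfg.tag_spacing,
        plane_label=label,
        slice_location=slice_location,
    )


def circle_contour(center: tuple[float, float], radius: float, n: int = 256) -> np.ndarray:
    """Closed circular contour (first point not repeated), (n, 2) mm."""
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return np.stack([center[0] + radius * np.cos(t), center[1] + radius * np.sin(t)], axis=1)


def generate_study(cfg: PhantomConfig) -> PhantomStudy:
    """Generate the two-plane phantom study: tagged cine series for the apical
    and basal levels (opposite-signed rotation by default), exact ground
    truth, and the frame-0 endo/epi contours. Deterministic for a given seed.
    """
    rng = np.random.default_rng(cfg.seed) if cfg.noise_sd > 0 else None
    apical = _render_series(cfg, cfg.apical_motion, "apical", 0.0, rng)
    basal = _render_series(cfg, cfg.basal_motion, "basal", cfg.slice_gap, rng)
    truth = GroundTruthMotion(
        models={"apical": cfg.apical_motion, "basal": cfg.basal_motion},
        end_systole_index=cfg.n_frames - 1,
    )
    contours = {
        plane: {
            "endo": circle_contour(cfg.apical_motion.center if plane == "apical"
                                   else cfg.basal_motion.center, cfg.inner_radius),
            "epi": circle_contour(cfg.apical_motion.center if plane == "apical"
                                  else cfg.basal_motion.center, cfg.outer_radius),
        }
        for plane in ("apical", "basal")
    }
    return PhantomStudy(apical=apical, basal=basal, truth=truth, contours=contours, config=cfg)
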