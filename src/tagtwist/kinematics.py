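"""Rotation and torsion kinematics from tracked material points.

Per-plane rotation at frame t is the mean, over tracked myocardial points, of
the signed angle between the reference radius vector P0 - C0 and the current
radius vector Pt - Ct, where C is the per-frame center of mass of the tracked
point set. The magnitude comes from the normalized scalar product
arccos(<P0-C0, Pt-Ct> / (||P0-C0|| ||Pt-Ct||)); the sign from the z-component
of the cross product, counterclockwise-positive viewed from the apex (apical
rotation positive, basal negative in the healthy wringing pattern).

Torsion is the apical-minus-basal rotation difference; normalized torsion
divides the end-systolic value by the distance between the two slices. An
optional radius-scaled variant (mean myocardial radius over slice distance)
is provided behind a flag. Curves are resampled onto a common 0-100% systole
axis by linear interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tracks import MaterialPointTracks

__all__ = [
    "RotationCurve",
    "TorsionResult",
    "CenterTrack",
    "rotation_angle_unsigned",
    "rotation_angle_signed",
    "plane_rotation_curve",
    "time_normalize",
    "torsion",
]


class DegeneratePointError(ValueError):
    """Radius vector of zero length; the angle is undefined."""


class CurveError(RuntimeError):
    """Rotation curve could not be formed at some frame."""


@dataclass
class RotationCurve:
    """Signed rotation vs. percent of systole for one plane."""

    plane_label: str
    times_percent: np.ndarray   # strictly increasing, 0..100
    rotation_deg: np.ndarray
    n_points_used: np.ndarray
    source: str = "unknown"

    def __post_init__(self) -> None:
        self.times_percent = np.asarray(self.times_percent, dtype=float)
        self.rotation_deg = np.asarray(self.rotation_deg, dtype=float)
        self.n_points_used = np.asarray(self.n_points_used)
        if np.any(np.diff(self.times_percent) <= 0):
            raise ValueError("times_percent must be strictly increasing")
        if not (self.times_percent[0] == 0.0 and self.times_percent[-1] == 100.0):
            raise ValueError("times_percent must span 0 to 100")

    @property
    def end_systolic_rotation(self) -> float:
        return float(self.rotation_deg[-1])


@dataclass
class CenterTrack:
    """Per-frame center of mass of the tracked myocardial point set."""

    centers: np.ndarray   # (T, 2) mm


@dataclass
class TorsionResult:
    """Apical-basal torsion curve and its end-systolic scalars."""

    times_percent: np.ndarray
    torsion_deg: np.ndarray
    end_systolic_apical_rotation: float
    end_systolic_basal_rotation: float
    end_systolic_torsion: float
    normalized_torsion: float    # deg/mm
    slice_distance: float        # mm


def _radius_vectors(P, C):
    v = np.asarray(P, dtype=float) - np.asarray(C, dtype=float)
    n = np.linalg.norm(v, axis=-1)
    if np.any(n == 0):
        raise DegeneratePointError("point coincides with the center of mass")
    return v, n


def rotation_angle_unsigned(P0, C0, Pt, Ct) -> float | np.ndarray:
    """Unsigned rotation angle (degrees, in [0, 180]) of the radius vector.

    arccos of the normalized scalar product of P0-C0 and Pt-Ct, with the
    cosine clamped to [-1, 1] so colinear vectors never raise a domain fault.
    Pure radial scaling gives exactly 0.
    """
    v0, n0 = _radius_vectors(P0, C0)
    vt, nt = _radius_vectors(Pt, Ct)
    cosang = np.sum(v0 * vt, axis=-1) / (n0 * nt)
    cosang = np.clip(cosang, -1.0, 1.0)
    return np.degrees(np.arccos(cosang))


def rotation_angle_signed(P0, C0, Pt, Ct) -> float | np.ndarray:
    """Signed rotation angle: magnitude as above, sign from the z-component
    of (P0-C0) x (Pt-Ct), counterclockwise-positive viewed from the apex."""
    v0, _ = _radius_vectors(P0, C0)
    vt, _ = _radius_vectors(Pt, Ct)
    mag = rotation_angle_unsigned(P0, C0, Pt, Ct)
    cross = v0[..., 0] * vt[..., 1] - v0[..., 1] * vt[..., 0]
    sign = np.where(cross >= 0, 1.0, -1.0)
    return sign * mag


def time_normalize(times_ms, values, n_out: int = 51) -> tuple[np.ndarray, np.ndarray]:
    """Resample (time, value) samples onto n_out evenly spaced points over the
    sampled interval, relabeled 0-100% of systole. Linear interpolation;
    endpoint values are preserved exactly; idempotent at the same n_out."""
    t = np.asarray(times_ms, dtype=float)
    v = np.asarray(values, dtype=float)
    if t.size < 2:
        raise ValueError("need at least 2 samples")
    d = np.diff(t)
    if np.any(d == 0):
        raise ValueError("duplicate sample times")
    if np.any(d < 0):
        raise ValueError("times must be strictly increasing")
    pct = np.linspace(0.0, 100.0, n_out)
    tq = t[0] + pct / 100.0 * (t[-1] - t[0])
    out = np.interp(tq, t, v)
    out[0], out[-1] = v[0], v[-1]
    return pct, out


def plane_rotation_curve(
    tracks: MaterialPointTracks,
    trigger_times_ms,
    plane_label: str,
    pixel_spacing: float = 1.25,
    center_exclusion_factor: float = 2.0,
    n_out: int = 51,
) -> tuple[RotationCurve, CenterTrack]:
    """Whole-plane rotation curve from tracked points.

    Per frame, the center of mass C_t is the centroid of the points still
    valid at that frame; the curve value is the equal-weight mean of the
    signed per-point rotation. Points closer than
    ``center_exclusion_factor * pixel_spacing`` to either center (their angle
    is noise-dominated) are excluded from the mean at that frame. The raw
    per-frame curve is then resampled to the 0-100% systole axis.
    """
    t_ms = np.asarray(trigger_times_ms, dtype=float)
    T = tracks.n_frames
    if t_ms.shape[0] != T:
        raise ValueError("one trigger time per frame required")
    raw = np.zeros(T)
    counts = np.zeros(T, dtype=int)
    v0_all = tracks.positions[:, 0, :]

    valid0 = tracks.valid[:, 0]
    if not np.any(valid0):
        raise CurveError("no valid points at frame 0")
    C0 = v0_all[valid0].mean(axis=0)
    r_min = center_exclusion_factor * pixel_spacing

    counts[0] = int(np.sum(valid0))
    for t in range(1, T):
        sel = tracks.valid[:, t]
        if not np.any(sel):
            raise CurveError(f"no valid points at frame {t}")
        Pt = tracks.positions[sel, t, :]
        P0 = v0_all[sel]
        Ct = Pt.mean(axis=0)
        keep = (np.linalg.norm(P0 - C0, axis=1) > r_min) & (
            np.linalg.norm(Pt - Ct, axis=1) > r_min
        )
        if not np.any(keep):
            raise CurveError(f"all points within the center-exclusion radius at frame {t}")
        ang = rotation_angle_signed(P0[keep], C0, Pt[keep], Ct)
        raw[t] = float(np.mean(ang))
        counts[t] = int(np.sum(keep))

    pct, rot = time_normalize(t_ms, raw, n_out=n_out)
    _, npts = time_normalize(t_ms, counts.astype(float), n_out=n_out)
    rot[0] = 0.0  # reference frame: rotation is identically zero
    centers = np.stack(
        [tracks.positions[tracks.valid[:, t], t, :].mean(axis=0) for t in range(T)]
    )
    curve = RotationCurve(
        plane_label=plane_label, times_percent=pct, rotation_deg=rot,
        n_points_used=np.round(npts).astype(int), source=tracks.source,
    )
    return curve, CenterTrack(centers=centers)


def torsion(
    apical: RotationCurve,
    basal: RotationCurve,
    slice_distance: float,
    radius_scaled: bool = False,
    mean_radius: float | None = None,
) -> TorsionResult:
    """Pointwise apical-minus-basal torsion with end-systolic scalars.

    ``normalized_torsion`` divides the end-systolic torsion by the inter-slice
    distance (deg/mm). With ``radius_scaled=True`` the torsion is additionally
    multiplied by ``mean_radius / slice_distance`` (a shear-angle style
    normalization some packages use); off by default.
    """
    if slice_distance <= 0:
        raise ValueError("slice_distance must be > 0")
    if apical.times_percent.shape != basal.times_percent.shape or not np.allclose(
        apical.times_percent, basal.times_percent
    ):
        raise ValueError("apical and basal curves must share the same 0-100% grid")
    tor = apical.rotation_deg - basal.rotation_deg
    es_ap = apical.end_systolic_rotation
    es_ba = basal.end_systolic_rotation
    es_tor = es_ap - es_ba
    if radius_scaled:
        # shear-angle style: rotation difference scaled by mean myocardial
        # radius over inter-slice distance (degrees, size-normalized)
        if mean_radius is None or mean_radius <= 0:
            raise ValueError("radius_scaled torsion requires a positive mean_radius")
        norm = es_tor * mean_radius / slice_distance
    else:
        norm = es_tor / slice_distance
    return TorsionResult(
        times_percent=apical.times_percent.copy(),
        torsion_deg=tor,
        end_systolic_apical_rotation=es_ap,
        end_systolic_basal_rotation=es_ba,
        end_systolic_torsion=es_tor,
        normalized_torsion=norm,
        slice_distance=float(slice_distance),
    )
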