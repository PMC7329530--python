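"""Harmonic-phase (HARP) tag tracking with a Gabor filter bank.

A grid-SPAMM image carries two sinusoidal tag carriers. Bandpassing the
spectrum around one carrier's positive harmonic yields a complex "harmonic
image" whose phase is a material property of the tissue: a material point
keeps its pair of harmonic phases as it moves. Tracking therefore solves, per
point and per consecutive frame pair, the two-equation phase-constancy system
by Newton iteration on the wrapped phase residual.

A bank of Gabor filters at several center frequencies is applied and combined
per pixel by maximum magnitude, so the demodulation follows the local
frequency changes that radial contraction induces — the reason to prefer a
Gabor bank over single-band HARP.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates

from .phantom import TaggedCineSeries
from .tracks import MaterialPointTracks

__all__ = [
    "GaborFilterSpec",
    "HarmonicImage",
    "PhaseImagePair",
    "HarpConfig",
    "spectral_peak",
    "gabor_demodulate",
    "gabor_bank_demodulate",
    "harmonic_images",
    "harp_track",
    "harp_track_series",
]

log = logging.getLogger(__name__)


class PeakDetectionError(RuntimeError):
    """No usable spectral peak found in the search window."""


class FilterConfigError(ValueError):
    """Gabor filter incompatible with the image geometry."""


@dataclass(frozen=True)
class GaborFilterSpec:
    """Gaussian bandpass bank in the frequency domain.

    ``center_frequencies`` are scalar multiples applied to the per-direction
    carrier frequency; ``bandwidth_sigma`` is the Gaussian envelope width in
    cycles/mm. The filter is notched to exactly zero within ``dc_exclusion``
    times the carrier frequency of DC, excluding the untagged-image term.
    """

    center_frequencies: tuple[float, ...] = (0.85, 1.0, 1.15)
    bandwidth_sigma: float | None = None   # cycles/mm; default 0.3 / tag_spacing
    dc_exclusion: float = 0.25

    def sigma_for(self, tag_spacing: float) -> float:
        # 0.35/tag_spacing trades a little noise robustness for a smaller
        # spatial footprint, which limits phase corruption near the
        # myocardial boundary where the tissue-support step leaks into the
        # harmonic band
        return self.bandwidth_sigma if self.bandwidth_sigma is not None else 0.35 / tag_spacing

    def __post_init__(self) -> None:
        if any(f <= 0 for f in self.center_frequencies):
            raise FilterConfigError("center frequency multipliers must be > 0")
        if self.bandwidth_sigma is not None and self.bandwidth_sigma <= 0:
            raise FilterConfigError("bandwidth_sigma must be > 0")


@dataclass
class HarmonicImage:
    """Complex bandpassed image whose phase is the harmonic (material) phase."""

    data: np.ndarray            # complex (rows, cols)
    direction: np.ndarray       # unit 2-vector (x, y)
    center_frequency: float     # cycles/mm along direction
    pixel_spacing: float

    @property
    def phase(self) -> np.ndarray:
        return np.angle(self.data)

    @property
    def magnitude(self) -> np.ndarray:
        return np.abs(self.data)


@dataclass
class PhaseImagePair:
    """The two harmonic images (one per tag direction) of a single frame."""

    harmonics: tuple[HarmonicImage, HarmonicImage]
    pixel_spacing: float

    @property
    def phases(self) -> tuple[np.ndarray, np.ndarray]:
        return tuple(h.phase for h in self.harmonics)


@dataclass(frozen=True)
class HarpConfig:
    """Tracking parameters of the harmonic-phase engine."""

    filter_spec: GaborFilterSpec = field(default_factory=GaborFilterSpec)
    newton_tol: float = 1e-3       # rad, wrapped phase residual norm
    max_newton_iter: int = 20
    det_threshold: float = 1e-6    # rad^2/mm^2, Jacobian singularity guard
    grid_angle_deg: float = 0.0    # tag axes orientation


def _freq_grids(shape: tuple[int, int], pixel_spacing: float) -> tuple[np.ndarray, np.ndarray]:
    """fx, fy in cycles/mm on the unshifted FFT grid (fx varies along cols)."""
    rows, cols = shape
    fy = np.fft.fftfreq(rows, d=pixel_spacing)
    fx = np.fft.fftfreq(cols, d=pixel_spacing)
    return np.meshgrid(fx, fy)


def spectral_peak(
    image: np.ndarray,
    pixel_spacing: float,
    tag_spacing: float,
    direction,
    search_halfwidth: float = 0.35,
    min_peak_snr: float = 5.0,
) -> float:
    """Locate the tag harmonic frequency (cycles/mm) along ``direction``.

    Searches the FFT magnitude in a window centered on the nominal carrier
    1/tag_spacing along the (unit) direction, excluding DC, and refines the
    maximum by quadratic interpolation of log-magnitude on each frequency
    axis. Returns the projection of the refined peak onto ``direction``.
    Raises :class:`PeakDetectionError` when no peak rises above the noise
    floor (``min_peak_snr`` times the window median).
    """
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    f0 = 1.0 / tag_spacing
    fx, fy = _freq_grids(image.shape, pixel_spacing)
    spec = np.fft.fft2(image)
    mag = np.abs(spec)

    target = f0 * d
    dist = np.hypot(fx - target[0], fy - target[1])
    window = dist <= search_halfwidth * f0
    if not np.any(window):
        raise PeakDetectionError("search window contains no frequency bins")
    wmag = np.where(window, mag, 0.0)
    floor = np.median(mag[window])
    idx = np.unravel_index(np.argmax(wmag), mag.shape)
    if floor > 0 and mag[idx] < min_peak_snr * floor:
        raise PeakDetectionError(
            f"no spectral peak above noise floor near {f0:.4f} cycles/mm"
        )

    # quadratic refinement of log-magnitude along each axis
    def refine(axis: int) -> float:
        i, j = idx
        if axis == 0:
            vals = [mag[(i - 1) % mag.shape[0], j], mag[i, j], mag[(i + 1) % mag.shape[0], j]]
            step = fy[1, 0] - fy[0, 0] if mag.shape[0] > 1 else 0.0
            base = fy[i, j]
        else:
            vals = [mag[i, (j - 1) % mag.shape[1]], mag[i, j], mag[i, (j + 1) % mag.shape[1]]]
            step = fx[0, 1] - fx[0, 0] if mag.shape[1] > 1 else 0.0
            base = fx[i, j]
        lm, l0, lp = (np.log(max(v, 1e-300)) for v in vals)
        denom = lm - 2 * l0 + lp
        delta = 0.0 if denom == 0 else 0.5 * (lm - lp) / denom
        delta = float(np.clip(delta, -0.5, 0.5))
        return base + delta * step

    peak = np.array([refine(1), refine(0)])
    return float(peak @ d)


def _gabor_window(
    shape: tuple[int, int],
    pixel_spacing: float,
    center: np.ndarray,
    sigma: float,
    dc_exclusion_radius: float,
) -> np.ndarray:
    fx, fy = _freq_grids(shape, pixel_spacing)
    w = np.exp(-((fx - center[0]) ** 2 + (fy - center[1]) ** 2) / (2 * sigma ** 2))
    # hard notch around DC so the untagged image term never leaks through
    w[np.hypot(fx, fy) <= dc_exclusion_radius] = 0.0
    return w


def gabor_demodulate(
    image: np.ndarray,
    pixel_spacing: float,
    center_frequency: float,
    direction,
    sigma: float,
    dc_exclusion_radius: float | None = None,
) -> HarmonicImage:
    """Bandpass the image spectrum with a Gaussian centered at the positive
    harmonic ``center_frequency`` (cycles/mm) along ``direction`` and return
    the complex harmonic image. Linear in the input."""
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    nyquist = 0.5 / pixel_spacing
    if center_frequency >= nyquist:
        raise FilterConfigError(
            f"filter center {center_frequency:.4f} cycles/mm is at or beyond Nyquist {nyquist:.4f}"
        )
    if dc_exclusion_radius is None:
        dc_exclusion_radius = 0.25 * center_frequency
    w = _gabor_window(image.shape, pixel_spacing, center_frequency * d, sigma,
                      dc_exclusion_radius)
    data = np.fft.ifft2(np.fft.fft2(image) * w)
    return HarmonicImage(data=data, direction=d, center_frequency=center_frequency,
                         pixel_spacing=pixel_spacing)


def gabor_bank_demodulate(
    image: np.ndarray,
    pixel_spacing: float,
    carrier_frequency: float,
    direction,
    spec: GaborFilterSpec,
    tag_spacing: float,
) -> HarmonicImage:
    """Apply the filter bank (several center frequencies around the carrier)
    and combine per pixel by maximum magnitude response."""
    sigma = spec.sigma_for(tag_spacing)
    best: np.ndarray | None = None
    for mult in spec.center_frequencies:
        h = gabor_demodulate(
            image, pixel_spacing, mult * carrier_frequency, direction, sigma,
            dc_exclusion_radius=spec.dc_exclusion * carrier_frequency,
        )
        if best is None:
            best = h.data
        else:
            take = np.abs(h.data) > np.abs(best)
            best = np.where(take, h.data, best)
    d = np.asarray(direction, dtype=float)
    return HarmonicImage(data=best, direction=d / np.linalg.norm(d),
                         center_frequency=carrier_frequency, pixel_spacing=pixel_spacing)


def _tag_directions(grid_angle_deg: float) -> tuple[np.ndarray, np.ndarray]:
    a = np.deg2rad(grid_angle_deg)
    return (np.array([np.cos(a), np.sin(a)]), np.array([-np.sin(a), np.cos(a)]))


def harmonic_images(series: TaggedCineSeries, config: HarpConfig | None = None) -> list[PhaseImagePair]:
    """Demodulate every frame of a series along both tag directions.

    The carrier frequency per direction is detected once on frame 0 (tags are
    sharpest at end-diastole); the bank's frequency spread absorbs the
    contraction-induced shift in later frames.
    """
    config = config or HarpConfig()
    dirs = _tag_directions(config.grid_angle_deg)
    carriers = [
        spectral_peak(series.frames[0], series.pixel_spacing, series.tag_spacing, d)
        for d in dirs
    ]
    pairs = []
    for frame in series.frames:
        hs = tuple(
            gabor_bank_demodulate(frame, series.pixel_spacing, c, d,
                                  config.filter_spec, series.tag_spacing)
            for c, d in zip(carriers, dirs)
        )
        pairs.append(PhaseImagePair(harmonics=hs, pixel_spacing=series.pixel_spacing))
    return pairs


# ---------------------------------------------------------------------------
# tracking


def _mm_to_pixel(points: np.ndarray, shape: tuple[int, int], pixel_spacing: float) -> np.ndarray:
    """(N, 2) mm -> (2, N) array of (row, col) pixel coordinates."""
    cols = points[:, 0] / pixel_spacing + (shape[1] - 1) / 2.0
    rows = points[:, 1] / pixel_spacing + (shape[0] - 1) / 2.0
    return np.stack([rows, cols])


def _interp_complex(img: np.ndarray, coords: np.ndarray) -> np.ndarray:
    re = map_coordinates(img.real, coords, order=1, mode="nearest")
    im = map_coordinates(img.imag, coords, order=1, mode="nearest")
    return re + 1j * im


def _interp_real(img: np.ndarray, coords: np.ndarray) -> np.ndarray:
    return map_coordinates(img, coords, order=1, mode="nearest")


def _wrapped_gradient(phase_complex: np.ndarray, pixel_spacing: float) -> tuple[np.ndarray, np.ndarray]:
    """Spatial gradient (d/dx, d/dy) of the wrapped phase, rad/mm, computed
    through the complex representation so wrap boundaries do not corrupt it."""
    h = phase_complex
    gx = np.zeros(h.shape)
    gy = np.zeros(h.shape)
    # central differences via phase of products; one-sided at the borders
    gx[:, 1:-1] = np.angle(h[:, 2:] * np.conj(h[:, :-2])) / (2 * pixel_spacing)
    gx[:, 0] = np.angle(h[:, 1] * np.conj(h[:, 0])) / pixel_spacing
    gx[:, -1] = np.angle(h[:, -1] * np.conj(h[:, -2])) / pixel_spacing
    gy[1:-1, :] = np.angle(h[2:, :] * np.conj(h[:-2, :])) / (2 * pixel_spacing)
    gy[0, :] = np.angle(h[1, :] * np.conj(h[0, :])) / pixel_spacing
    gy[-1, :] = np.angle(h[-1, :] * np.conj(h[-2, :])) / pixel_spacing
    return gx, gy


def _wrap(a: np.ndarray) -> np.ndarray:
    return (a + np.pi) % (2 * np.pi) - np.pi


def harp_track(
    phase_pairs: list[PhaseImagePair],
    seeds: np.ndarray,
    config: HarpConfig | None = None,
    tag_spacing: float | None = None,
) -> MaterialPointTracks:
    """Track seed points (N, 2) mm through the sequence by phase constancy.

    For each consecutive frame pair the new position solves
    ``phi(x, t+1) = phi(x_t, t)`` for both tag directions by Newton iteration
    ``dx = -J^{-1} wrap(phi(x, t+1) - phi_target)`` with the 2x2 spatial
    phase-gradient Jacobian. Phase is always interpolated through its complex
    representation. Points with a singular Jacobian, a non-converged residual,
    a per-frame displacement at or beyond the half-tag-spacing wrap limit, or
    positions outside the image are flagged invalid from that frame on.
    """
    config = config or HarpConfig()
    if len(phase_pairs) < 2:
        raise ValueError("need at least 2 frames to track")
    seeds = np.atleast_2d(np.asarray(seeds, dtype=float))
    n, T = seeds.shape[0], len(phase_pairs)
    ps = phase_pairs[0].pixel_spacing
    shape = phase_pairs[0].harmonics[0].data.shape
    if tag_spacing is None:
        # wrap limit from the carrier: half the local tag period
        tag_spacing = 1.0 / phase_pairs[0].harmonics[0].center_frequency

    positions = np.zeros((n, T, 2))
    positions[:, 0] = seeds
    valid = np.ones((n, T), dtype=bool)

    # unit-magnitude complex phases and gradients per frame
    unit = []
    grads = []
    for pair in phase_pairs:
        hs = []
        gs = []
        for h in pair.harmonics:
            mag = np.abs(h.data)
            u = h.data / np.where(mag > 0, mag, 1.0)
            hs.append(u)
            gs.append(_wrapped_gradient(u, ps))
        unit.append(hs)
        grads.append(gs)

    half_extent_x = (shape[1] - 1) / 2.0 * ps
    half_extent_y = (shape[0] - 1) / 2.0 * ps

    for t in range(T - 1):
        prev = positions[:, t]
        coords_prev = _mm_to_pixel(prev, shape, ps)
        target = np.stack(
            [np.angle(_interp_complex(unit[t][d], coords_prev)) for d in range(2)], axis=1
        )  # (N, 2)
        x = prev.copy()
        ok = valid[:, t].copy()
        converged = np.zeros(n, dtype=bool)

        for _ in range(config.max_newton_iter):
            active = ok & ~converged
            if not np.any(active):
                break
            coords = _mm_to_pixel(x[active], shape, ps)
            phi = np.stack(
                [np.angle(_interp_complex(unit[t + 1][d], coords)) for d in range(2)], axis=1
            )
            r = _wrap(phi - target[active])
            res_ok = np.linalg.norm(r, axis=1) < config.newton_tol
            idx_active = np.flatnonzero(active)
            converged[idx_active[res_ok]] = True
            still = idx_active[~res_ok]
            if still.size == 0:
                continue
            coords_s = _mm_to_pixel(x[still], shape, ps)
            J = np.empty((still.size, 2, 2))
            for d in range(2):
                gx, gy = grads[t + 1][d]
                J[:, d, 0] = _interp_real(gx, coords_s)
                J[:, d, 1] = _interp_real(gy, coords_s)
            det = J[:, 0, 0] * J[:, 1, 1] - J[:, 0, 1] * J[:, 1, 0]
            sing = np.abs(det) < config.det_threshold
            ok[still[sing]] = False
            good = still[~sing]
            if good.size == 0:
                continue
            Jg = J[~sing]
            rg = _wrap(
                np.stack(
                    [np.angle(_interp_complex(unit[t + 1][d], _mm_to_pixel(x[good], shape, ps)))
                     for d in range(2)], axis=1
                ) - target[good]
            )
            dx = -np.linalg.solve(Jg, rg[..., None])[..., 0]
            # damp steps beyond a quarter tag period for stability
            nrm = np.linalg.norm(dx, axis=1)
            cap = tag_spacing / 4.0
            scale = np.where(nrm > cap, cap / np.maximum(nrm, 1e-12), 1.0)
            x[good] += dx * scale[:, None]

        ok &= converged
        # wrap-ambiguity limit: per-frame displacement must stay below half a tag period
        disp = np.linalg.norm(x - prev, axis=1)
        ok &= disp < tag_spacing / 2.0
        ok &= (np.abs(x[:, 0]) <= half_extent_x) & (np.abs(x[:, 1]) <= half_extent_y)

        n_lost = int(np.sum(valid[:, t] & ~ok))
        if n_lost:
            log.warning("harp_track: %d point(s) flagged invalid at frame %d", n_lost, t + 1)
        valid[:, t + 1] = valid[:, t] & ok
        positions[:, t + 1] = np.where(valid[:, t + 1, None], x, prev)

    return MaterialPointTracks(positions=positions, valid=valid, source="harp")


def harp_track_series(
    series: TaggedCineSeries,
    seeds: np.ndarray,
    config: HarpConfig | None = None,
) -> MaterialPointTracks:
    """Convenience: demodulate a series and track the seeds through it."""
    config = config or HarpConfig()
    pairs = harmonic_images(series, config)
    return harp_track(pairs, seeds, config, tag_spacing=series.tag_spacing)
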