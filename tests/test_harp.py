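"""HARP module: spectral peak detection, Gabor demodulation, phase tracking."""

import numpy as np
import pytest

from tagtwist.harp import (
    FilterConfigError,
    GaborFilterSpec,
    PeakDetectionError,
    gabor_demodulate,
    harmonic_images,
    harp_track,
    harp_track_series,
    spectral_peak,
)
from tagtwist.phantom import (
    MotionModel,
    PhantomConfig,
    TaggedCineSeries,
    generate_study,
    pixel_grid_mm,
)

X_DIR = np.array([1.0, 0.0])


def _cosine_image(shape=(96, 96), pixel_spacing=1.0, period_mm=10.0):
    gx, _ = pixel_grid_mm(shape, pixel_spacing)
    return np.cos(2 * np.pi * gx / period_mm)


# ---------------------------------------------------------------------------
# spectral_peak


def test_spectral_peak_pure_cosine():
    img = _cosine_image(period_mm=10.0)
    f = spectral_peak(img, 1.0, 10.0, X_DIR)
    assert abs(f - 0.1) < 0.005


def test_spectral_peak_phantom_frame0(study_clean):
    f = spectral_peak(study_clean.apical.frames[0], 1.25, 8.0, X_DIR)
    assert abs(f - 0.125) < 0.01


def test_spectral_peak_contraction_shifts_up(study_clean):
    # 10% end-systolic contraction compresses the material period -> higher f
    es = study_clean.config.n_frames - 1
    f0 = spectral_peak(study_clean.apical.frames[0], 1.25, 8.0, X_DIR)
    fes = spectral_peak(study_clean.apical.frames[es], 1.25, 8.0, X_DIR)
    assert fes > f0


def test_spectral_peak_no_peak_error():
    rng = np.random.default_rng(3)
    noise = rng.normal(size=(96, 96)) * 1e-6 + 1.0
    with pytest.raises(PeakDetectionError):
        spectral_peak(noise, 1.0, 10.0, X_DIR)


# ---------------------------------------------------------------------------
# gabor_demodulate


def test_demodulate_cosine_constant_magnitude_linear_phase():
    ps, period = 1.0, 10.0
    img = _cosine_image(pixel_spacing=ps, period_mm=period)
    h = gabor_demodulate(img, ps, 1 / period, X_DIR, sigma=0.03)
    interior = np.s_[20:-20, 20:-20]
    mag = h.magnitude[interior]
    assert mag.std() / mag.mean() < 0.01
    gx, _ = pixel_grid_mm(img.shape, ps)
    expected = np.angle(np.exp(1j * 2 * np.pi * gx / period))
    err = np.angle(np.exp(1j * (h.phase - expected)))[interior]
    assert np.max(np.abs(err)) < 0.02


def test_demodulate_dc_rejection():
    # constant image -> output magnitude ~0 relative to a tagged image's
    flat = np.ones((96, 96))
    tagged = 1.0 + 0.8 * _cosine_image()
    h_flat = gabor_demodulate(flat, 1.0, 0.1, X_DIR, sigma=0.03)
    h_tag = gabor_demodulate(tagged, 1.0, 0.1, X_DIR, sigma=0.03)
    assert h_flat.magnitude.max() < 1e-3 * h_tag.magnitude.max()


def test_demodulate_linearity():
    rng = np.random.default_rng(4)
    a = rng.normal(size=(64, 64))
    b = rng.normal(size=(64, 64))
    ha = gabor_demodulate(a, 1.0, 0.1, X_DIR, sigma=0.03).data
    hb = gabor_demodulate(b, 1.0, 0.1, X_DIR, sigma=0.03).data
    hab = gabor_demodulate(2.5 * a - 0.7 * b, 1.0, 0.1, X_DIR, sigma=0.03).data
    assert np.allclose(hab, 2.5 * ha - 0.7 * hb, atol=1e-12)


def test_demodulate_beyond_nyquist_rejected():
    img = _cosine_image()
    with pytest.raises(FilterConfigError):
        gabor_demodulate(img, 1.0, 0.6, X_DIR, sigma=0.03)


def test_filter_spec_validation():
    with pytest.raises(FilterConfigError):
        GaborFilterSpec(center_frequencies=(0.85, -1.0))
    with pytest.raises(FilterConfigError):
        GaborFilterSpec(bandwidth_sigma=0.0)


def test_phase_gradient_matches_carrier(study_clean):
    # phase difference between adjacent pixels along the tag normal
    series = study_clean.apical
    pairs = harmonic_images(series)
    h = pairs[0].harmonics[0]   # x direction
    phase = h.phase
    dphi = np.angle(np.exp(1j * (phase[:, 1:] - phase[:, :-1])))
    gx, gy = pixel_grid_mm(series.shape, series.pixel_spacing)
    r = np.hypot(gx, gy)
    interior = ((r >= study_clean.config.inner_radius + 3)
                & (r <= study_clean.config.outer_radius - 3))[:, :-1]
    expected = 2 * np.pi * series.pixel_spacing / series.tag_spacing
    assert abs(np.median(dphi[interior]) - expected) < 0.05 * expected


# ---------------------------------------------------------------------------
# harp_track


def _phase_pairs_for(frames, cfg=None, ps=1.25, tag=8.0):
    series = TaggedCineSeries(
        frames=np.asarray(frames), pixel_spacing=ps,
        trigger_times=np.arange(len(frames)) * 15.0,
        tag_spacing=tag, plane_label="apical",
    )
    return harmonic_images(series, cfg)


def test_track_zero_motion_stationary(study_clean):
    f0 = study_clean.apical.frames[0]
    pairs = _phase_pairs_for([f0, f0, f0])
    seeds = np.array([[20.0, 0.0], [0.0, 22.0], [-18.0, -12.0]])
    tracks = harp_track(pairs, seeds, tag_spacing=8.0)
    assert np.all(tracks.valid)
    drift = np.linalg.norm(tracks.positions - seeds[:, None, :], axis=2)
    assert drift.max() < 1e-6


def test_track_pure_rotation_recovery():
    cfg = PhantomConfig(
        noise_sd=0.0,
        apical_motion=MotionModel(peak_rotation_deg=10.0, contraction_fraction=0.0),
        basal_motion=MotionModel(peak_rotation_deg=-4.0),
    )
    study = generate_study(cfg)
    rng = np.random.default_rng(5)
    radii = rng.uniform(18, 27, 120)
    theta = rng.uniform(0, 2 * np.pi, 120)
    seeds = np.stack([radii * np.cos(theta), radii * np.sin(theta)], axis=1)
    tracks = harp_track_series(study.apical, seeds)
    es = cfg.n_frames - 1
    ok = tracks.valid[:, es]
    assert ok.mean() > 0.9
    p0, pe = seeds[ok], tracks.positions[ok, es]
    ang = np.degrees(np.arctan2(pe[:, 1], pe[:, 0]) - np.arctan2(p0[:, 1], p0[:, 0]))
    ang = (ang + 180) % 360 - 180
    assert abs(ang.mean() - 10.0) < 0.5


def test_track_wrap_limit_invalidates():
    # a per-frame step beyond half a tag period is ambiguous by construction:
    # the nearest phase-consistent solution lies >= tag_spacing/2 away and the
    # tracker must flag the point rather than report the aliased position
    ps, tag = 1.25, 8.0
    gx, gy = pixel_grid_mm((128, 128), ps)

    def pattern(dx, dy):
        w = 2 * np.pi / tag
        return (1 - 0.8 * np.cos(w * (gx - dx))) * (1 - 0.8 * np.cos(w * (gy - dy)))

    shift = tag / 2 + 0.5   # 4.5 mm along each axis: aliases to (-3.5, -3.5)
    frames = [pattern(0.0, 0.0), pattern(shift, shift)]
    pairs = _phase_pairs_for(frames, ps=ps, tag=tag)
    seeds = np.array([[0.0, 0.0], [10.0, -5.0], [-12.0, 8.0]])
    tracks = harp_track(pairs, seeds, tag_spacing=tag)
    assert not np.any(tracks.valid[:, 1])


def test_phase_material_constancy(study_clean):
    # along exact ground-truth trajectories the harmonic phase is constant
    series = study_clean.apical
    pairs = harmonic_images(series)
    rng = np.random.default_rng(6)
    radii = rng.uniform(19, 26, 60)
    theta = rng.uniform(0, 2 * np.pi, 60)
    seeds = np.stack([radii * np.cos(theta), radii * np.sin(theta)], axis=1)
    truth = study_clean.truth.tracks("apical", seeds)  # (N, T, 2)
    from tagtwist.harp import _interp_complex, _mm_to_pixel

    for d in range(2):
        phases = []
        for t in range(series.n_frames):
            coords = _mm_to_pixel(truth[:, t], series.shape, series.pixel_spacing)
            u = pairs[t].harmonics[d].data
            u = u / np.abs(u)
            phases.append(np.angle(_interp_complex(u, coords)))
        phases = np.stack(phases, axis=1)
        step = np.angle(np.exp(1j * np.diff(phases, axis=1)))
        assert np.percentile(np.abs(step), 95) < 0.05


def test_tracks_invariants(harp_clean, bundle_clean):
    from tagtwist.io import contours_to_mask, mask_seed_points

    series = bundle_clean.series("apical")
    mask = contours_to_mask(bundle_clean.contours["apical"], series.shape,
                            series.pixel_spacing)
    seeds = mask_seed_points(mask, series.pixel_spacing)
    tracks = harp_clean["tracks"]["apical"]
    assert np.array_equal(tracks.positions[:, 0], seeds)
    # monotone invalidation
    v = tracks.valid.astype(int)
    assert np.all(np.diff(v, axis=1) <= 0)


def test_noise_degrades_rotation_less_than_1deg(harp_clean, harp_noisy):
    for plane in ("apical", "basal"):
        clean = harp_clean["curves"][plane].end_systolic_rotation
        noisy = harp_noisy["curves"][plane].end_systolic_rotation
        assert abs(clean - noisy) < 1.0


def test_tracking_error_p95(study_clean, harp_clean):
    # 95th percentile end-systolic position error < 0.5 x pixel_spacing
    cfg = study_clean.config
    es = cfg.n_frames - 1
    for plane in ("apical", "basal"):
        tracks = harp_clean["tracks"][plane]
        ok = tracks.valid[:, es]
        truth_es = study_clean.truth.displace(plane, tracks.positions[ok, 0], es)
        err = np.linalg.norm(tracks.positions[ok, es] - truth_es, axis=1)
        assert np.percentile(err, 95) < 0.5 * cfg.pixel_spacing
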