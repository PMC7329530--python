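"""Phantom module: motion model, rendering, ground truth, determinism."""

import numpy as np
import pytest

from tagtwist.phantom import (
    MotionModel,
    PhantomConfig,
    PhantomConfigError,
    deform_point,
    generate_study,
    inverse_deform_point,
    pixel_grid_mm,
    render_frame,
)


# ---------------------------------------------------------------------------
# deform_point


def test_deform_point_pure_quarter_turn():
    m = MotionModel(peak_rotation_deg=90.0, contraction_fraction=0.0, n_frames=2)
    out = deform_point(m, (1.0, 0.0), 1)
    assert np.allclose(out, (0.0, 1.0), atol=1e-12)


def test_deform_point_identity_at_frame_zero():
    m = MotionModel(peak_rotation_deg=37.0, contraction_fraction=0.3,
                    center=(5.0, -3.0))
    rng = np.random.default_rng(1)
    pts = rng.normal(size=(50, 2)) * 30
    assert np.array_equal(deform_point(m, pts, 0), pts)


def test_deform_point_matrix_oracle():
    # independent hand-coded rotation + scaling matrix product
    m = MotionModel(peak_rotation_deg=10.0, contraction_fraction=0.1, n_frames=2)
    p = np.array([20.0, 0.0])
    a = np.deg2rad(10.0)
    R = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
    expected = 0.9 * (R @ p)
    assert np.allclose(deform_point(m, p, 1), expected, atol=1e-12)


def test_deform_point_frame_out_of_range():
    m = MotionModel(n_frames=5)
    with pytest.raises(IndexError):
        deform_point(m, (1.0, 0.0), 5)
    with pytest.raises(IndexError):
        deform_point(m, (1.0, 0.0), -1)


def test_round_trip_inverse():
    m = MotionModel(peak_rotation_deg=-12.0, contraction_fraction=0.2,
                    center=(3.0, 4.0), timing_exponent=1.7)
    rng = np.random.default_rng(2)
    pts = rng.normal(size=(200, 2)) * 25
    for frame in (0, 7, m.n_frames - 1):
        fwd = deform_point(m, pts, frame)
        back = inverse_deform_point(m, fwd, frame)
        assert np.max(np.abs(back - pts)) < 1e-9


def test_ground_truth_rotation_matches_deform_angle():
    # angle swept by any off-center point equals the rotation schedule exactly
    # (pure rotation case)
    m = MotionModel(peak_rotation_deg=8.0, contraction_fraction=0.0)
    p = np.array([17.0, 5.0])
    for frame in range(m.n_frames):
        q = deform_point(m, p, frame)
        ang = np.degrees(np.arctan2(q[1], q[0]) - np.arctan2(p[1], p[0]))
        ang = (ang + 180) % 360 - 180
        assert abs(ang - m.rotation_deg(frame)) < 1e-9


def test_activation_monotone_and_endpoints():
    for q in (0.5, 1.0, 2.3):
        m = MotionModel(timing_exponent=q, n_frames=22)
        s = np.array([m.activation(k) for k in range(m.n_frames)])
        assert s[0] == 0.0
        assert s[-1] == 1.0
        assert np.all(np.diff(s) >= 0)


def test_motion_model_validation():
    with pytest.raises(PhantomConfigError):
        MotionModel(contraction_fraction=0.5)
    with pytest.raises(PhantomConfigError):
        MotionModel(contraction_fraction=-0.01)
    with pytest.raises(PhantomConfigError):
        MotionModel(timing_exponent=0.0)
    with pytest.raises(PhantomConfigError):
        MotionModel(n_frames=1)


# ---------------------------------------------------------------------------
# render_frame


def test_frame0_independent_of_motion():
    cfg = PhantomConfig(noise_sd=0.0)
    a = render_frame(cfg, MotionModel(peak_rotation_deg=8.0), 0)
    b = render_frame(cfg, MotionModel(peak_rotation_deg=-15.0,
                                      contraction_fraction=0.3), 0)
    assert np.array_equal(a, b)


def test_frame0_tag_minima_on_grid_lines():
    cfg = PhantomConfig(noise_sd=0.0)
    img = render_frame(cfg, cfg.apical_motion, 0)
    gx, gy = pixel_grid_mm(cfg.matrix, cfg.pixel_spacing)
    # pixels on tag lines (material coordinate a multiple of tag_spacing in
    # either direction) are darker than pixels mid-way between lines
    inside = np.hypot(gx, gy)
    tissue = (inside >= cfg.inner_radius + 2) & (inside <= cfg.outer_radius - 2)
    tol = cfg.pixel_spacing / 2 + 1e-9  # nearest pixel centers to the lines
    on_line = tissue & (
        (np.abs((gx + cfg.tag_spacing / 2) % cfg.tag_spacing - cfg.tag_spacing / 2) < tol)
        | (np.abs((gy + cfg.tag_spacing / 2) % cfg.tag_spacing - cfg.tag_spacing / 2) < tol)
    )
    mid = tissue & (
        np.abs(gx % cfg.tag_spacing - cfg.tag_spacing / 2) < tol
    ) & (np.abs(gy % cfg.tag_spacing - cfg.tag_spacing / 2) < tol)
    assert np.any(on_line) and np.any(mid)
    assert img[on_line].mean() < 0.5 * img[mid].mean()


def test_pure_rotation_frame_matches_rotated_frame0():
    from scipy.ndimage import rotate

    cfg = PhantomConfig(noise_sd=0.0)
    model = MotionModel(peak_rotation_deg=8.0, contraction_fraction=0.0)
    k = cfg.n_frames - 1
    frame_k = render_frame(cfg, model, k)
    frame_0 = render_frame(cfg, model, 0)
    # undo fading so only geometry differs
    fade = np.exp(-k * cfg.frame_interval_ms / cfg.tag_fade_time_ms)
    mask = frame_0 > 0
    unfaded = np.where(mask, (frame_k - cfg.base_intensity * (frame_k > 0)) / fade
                       + cfg.base_intensity * (frame_k > 0), 0.0)
    # rotate frame 0 by +8 deg; array y axis is downward so a counterclockwise
    # rotation in (x, y) physical coordinates is scipy's angle=-8 about the
    # array center... verify via mean absolute difference under both signs and
    # require the correct one to be clearly smaller and small in absolute terms
    r_pos = rotate(frame_0, 8.0, reshape=False, order=3)
    r_neg = rotate(frame_0, -8.0, reshape=False, order=3)
    mad_pos = np.mean(np.abs(unfaded - r_pos)[mask])
    mad_neg = np.mean(np.abs(unfaded - r_neg)[mask])
    best = min(mad_pos, mad_neg)
    assert best < 0.05           # interpolation-level agreement
    assert best < 0.3 * max(mad_pos, mad_neg)  # unambiguous orientation


def test_tag_fade_ratio():
    cfg = PhantomConfig(noise_sd=0.0)
    model = MotionModel(peak_rotation_deg=0.0, contraction_fraction=0.0)
    f0 = render_frame(cfg, model, 0)
    f9 = render_frame(cfg, model, 9)
    mask = f0 > 0
    # least-squares amplitude of the (identical) tag pattern in both frames
    pattern = f0[mask] - np.mean(f0[mask])
    resp = f9[mask] - np.mean(f9[mask])
    amp = float(pattern @ resp / (pattern @ pattern))
    expected = np.exp(-9 * cfg.frame_interval_ms / cfg.tag_fade_time_ms)
    assert abs(amp - expected) < 1e-9


def test_render_noise_seeded():
    cfg = PhantomConfig(noise_sd=0.05)
    r1 = render_frame(cfg, cfg.apical_motion, 3, np.random.default_rng(7))
    r2 = render_frame(cfg, cfg.apical_motion, 3, np.random.default_rng(7))
    assert np.array_equal(r1, r2)


# ---------------------------------------------------------------------------
# generate_study


def test_generate_study_signs_and_determinism():
    cfg = PhantomConfig()
    s1 = generate_study(cfg)
    s2 = generate_study(cfg)
    rot_ap = s1.truth.rotation_deg("apical")
    rot_ba = s1.truth.rotation_deg("basal")
    assert rot_ap[-1] > 0 and rot_ba[-1] < 0
    assert rot_ap[0] == 0.0 and rot_ba[0] == 0.0
    assert np.array_equal(s1.apical.frames, s2.apical.frames)
    assert np.array_equal(s1.basal.frames, s2.basal.frames)


def test_generate_study_trigger_times():
    cfg = PhantomConfig().with_(n_frames=20)
    study = generate_study(cfg)
    tt = study.apical.trigger_times
    assert tt.shape == (20,)
    assert np.allclose(np.diff(tt), cfg.frame_interval_ms)


def test_ground_truth_center_is_fixed_point():
    study = generate_study(PhantomConfig())
    for plane in ("apical", "basal"):
        center = np.asarray(study.truth.models[plane].center, dtype=float)
        for frame in range(study.config.n_frames):
            moved = study.truth.displace(plane, center, frame)
            assert np.allclose(moved, center, atol=1e-12)


def test_phantom_config_validation():
    with pytest.raises(PhantomConfigError):
        PhantomConfig(inner_radius=30.0, outer_radius=15.0)
    with pytest.raises(PhantomConfigError):
        PhantomConfig(tag_spacing=2.0, pixel_spacing=1.25)
    with pytest.raises(PhantomConfigError):
        PhantomConfig(noise_sd=-0.1)
    with pytest.raises(PhantomConfigError):
        PhantomConfig(tag_contrast=0.0)
    with pytest.raises(PhantomConfigError):
        PhantomConfig(n_frames=10)  # motions still have 22 frames


def test_truth_tracks_shape_and_reference():
    study = generate_study(PhantomConfig(noise_sd=0.0))
    seeds = np.array([[20.0, 0.0], [0.0, -25.0], [17.0, 12.0]])
    tr = study.truth.tracks("apical", seeds)
    assert tr.shape == (3, study.config.n_frames, 2)
    assert np.array_equal(tr[:, 0], seeds)
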