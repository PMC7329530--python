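# Methods

This document records the models, algorithms and the reasoning behind the
parameter choices. Everything here describes the package's own design; the
numbers quoted are measured with the scripts in `analysis/` and the tests in
`tests/`.

## 1. Synthetic tagged phantom

### Geometry and motion

Each study holds two short-axis planes ("apical" and "basal") of an annular
myocardium: inner radius 15 mm, outer radius 30 mm, imaged at 128×128 pixels
of 1.25 mm, 22 frames 15 ms apart (systole ≈ 315 ms). The planes are 40 mm
apart. Motion is an analytic similarity map about a fixed center: rotation by
`activation(t) × peak_rotation` plus radial scaling by
`1 − activation(t) × contraction_fraction`, where `activation(t) =
(t/(T−1))^q` rises monotonically from 0 to 1 (q = 1 by default). Defaults:
apical +8°, basal −4° (counterclockwise-positive), 10 % radial contraction —
the healthy "wringing" pattern with realistic magnitudes. Because the motion
is closed-form and invertible, ground-truth trajectories, plane rotation
curves and torsion are exact, not themselves products of any tracker.

### Tag pattern and imaging

The image at frame *t* evaluates the tag pattern at the *material* coordinate
of each pixel (the inverse motion map applied to the pixel center), so tags
deform exactly with the tissue:

```
I(x, t) = base + A·fade(t) · (1 − c·cos(2π u/s)) · (1 − c·cos(2π v/s)) / norm
```

with tag spacing s = 8 mm, tag contrast c = 0.8, and tag fading
`fade(t) = exp(−t/850 ms)` modeling T1 relaxation of the tag magnetization.
Gaussian noise with σ = 0.05 (≈ SNR 20 against the mean myocardial signal) is
added from a seeded generator, so every study is bit-reproducible.

Realism and limits: the phantom reproduces the properties the engines
actually consume — a two-carrier SPAMM spectrum, carrier-frequency shifts
under contraction, tag fading, a sharp tissue/background boundary, additive
noise. It does not model through-plane motion, intra-myocardial strain
gradients, surface coil shading, or off-resonance; conclusions about the
engines are therefore about in-plane tracking fidelity, which is the quantity
rotation and torsion depend on.

## 2. HARP engine (harmonic phase, Gabor bank)

Each tag direction contributes a spectral harmonic at the carrier frequency
1/s. The harmonic is isolated by a bank of Gaussian bandpass (Gabor) filters
at {0.85, 1.0, 1.15}× the carrier, combined per pixel by maximum magnitude;
the bank follows the local frequency as contraction compresses the tag
period, which a single band does not. The filters are hard-notched to zero
within 0.25× the carrier of DC so the untagged-image term cannot leak in.

The bandwidth is σ = 0.35/s cycles/mm. A narrower band (e.g. 0.3/s) is
slightly more noise robust but has a larger spatial footprint, which corrupts
phase estimates near the myocardial boundary where the tissue-support step
leaks into the harmonic band; 0.35/s measurably reduced boundary-point loss
on the phantom at equal interior accuracy.

Tracking solves phase constancy: a material point keeps its pair of wrapped
harmonic phases. Per consecutive frame pair, a 2×2 Newton iteration on the
wrapped phase residual (gradients from wrapped finite differences of the
unit-normalized harmonic images) updates the position. Any per-frame step of
at least s/2 is inherently ambiguous (the phase pattern repeats every s), so
steps reaching that limit invalidate the point; invalidation is monotone — a
lost point stays lost. Note the converse is not detectable: a corruption that
lands exactly on another phase-consistent solution within the wrap radius is
indistinguishable from truth by construction.

Measured on the default phantom: both plane rotations recovered within 0.11°
noise-free and at SNR ≈ 20; 95th-percentile end-systolic position error below
half a pixel.

## 3. FFD engine (B-spline free-form deformation)

Consecutive frames are registered with a cubic B-spline displacement field
(control spacing 10 mm ≈ 1.25 tag periods — flexible enough for the
rotation/contraction field, stiff enough not to chase noise), minimizing mean
squared difference plus a small bending-energy penalty (weight 1e-3) with
L-BFGS-B (≤ 300 iterations, gradient tolerance 1e-8). Both images get a light
Gaussian pre-smoothing (0.5 px) to stabilize gradients. Transforms are
composed frame-to-frame to yield material trajectories; a point whose
composed position leaves the control-grid coverage is invalidated from that
frame on.

Two metric-sampling details matter far more than the optimizer settings, and
both were diagnosed as systematic biases before being fixed:

- **Staggered sampling (pixel locking).** Evaluating the metric at pixel
  centers interpolates only the warped moving image; at fractional
  displacements bilinear interpolation attenuates the tag carrier in the
  moving image while the fixed image keeps full amplitude. The optimizer then
  trades true alignment against amplitude mismatch and systematically
  under-recovers motion (≈ 12–18 % of mid-wall rotation on the phantom). The
  metric is therefore sampled on the half-pixel staggered grid, where *both*
  images are bilinearly interpolated and the attenuation cancels to first
  order.
- **Domain masking (boundary step).** Samples whose bilinear stencil touches
  the tissue/background step carry interpolation error that swamps the tag
  signal and drags the field at the boundary. Registration is restricted to
  the myocardial mask eroded by 1 px — exactly the erosion that removes every
  sample whose 2×2 stencil touches background. Deeper erosion starves thin
  annuli of samples at smaller image scales and was measurably worse.

Measured on the default phantom: plane-rotation errors −0.46°/+0.32°
noise-free and −0.55°/+0.40° at SNR ≈ 20; end-systolic positions agree with
the HARP engine within 0.95 mm RMS. A two-plane study registers in ≈ 20 s on
one CPU.

## 4. Rotation, torsion, normalization

Per frame, each valid material point contributes the signed angle between its
radius vector (point minus cavity center) at frame 0 and at frame t: the
magnitude from the arccos of the normalized dot product (clamped to [−1, 1]),
the sign from the z-component of the cross product. Scaling invariance of
this definition makes the rotation estimate exactly insensitive to radial
contraction. The cavity center is tracked as the centroid of the valid point
set per frame; points closer to the center than twice the median radius
divided by the exclusion factor are excluded as numerically degenerate. The
plane curve is the mean over points, resampled by linear interpolation onto
0–100 % of systole (51 samples) so different frame counts and heart rates are
comparable.

Torsion is the pointwise difference apical − basal on the common % grid; the
end-systolic value is the 100 % sample, and `normalized_torsion` divides by
the inter-slice distance (deg/mm; optionally scaled by mean radius when a
twist-per-length measure comparable across heart sizes is wanted).

## 5. Statistics

Cross-engine agreement uses Bland–Altman bias and 95 % limits of agreement
(bias ± 1.96 × sample SD of paired differences, literal 1.96), Spearman rank
correlation (mid-ranks on ties), Kruskal–Wallis for group comparisons, and
mean ± SD summaries. All are validated in the tests against independent
brute-force oracles to 1e-12 and by Monte Carlo calibration (limits-of-
agreement coverage in [94, 96] % at n = 10,000; Kruskal–Wallis type-I error
in [0.035, 0.065] over 2,000 null replicates).

## 6. Cohort experiment

Twelve synthetic subjects are drawn with apical peak rotation ~N(+8°, 2.5°),
basal ~N(−4°, 1.5°), contraction ~U(0.05, 0.15), at 96×96 / 14 frames (tags
remain 6.4 px apart) so the full two-engine cohort runs in ~2 minutes. Both
engines analyze every subject; agreement is summarized per measure with
Spearman ρ, Bland–Altman bias/limits, and the ground-truth between-subject SD
as the scale against which bias is judged. Measured at seed 0: apical ρ ≈
0.99, cross-engine bias ≈ 0.6° against a truth SD ≈ 2.0°.

## 7. Problem sizes and runtime budgets

Default sizes were chosen so the complete test suite runs on one CPU in a few
minutes: the 128×128 / 22-frame phantom exercises realistic sampling (6.4 px
per tag period) while a full two-engine analysis stays under a minute; the
cohort uses 96×96 / 14 frames for the same reason. The acceptance tests
assert these budgets explicitly (HARP < 2 min, FFD < 10 min per study, cohort
< 30 min, statistics and invariants < 1 min each).
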