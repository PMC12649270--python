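# Methods

## Scope and model

`bvrkin` implements a frozen-specimen validation of model-based biplane
videoradiography (BVR) tracking as a fully synthetic, reproducible
pipeline. The physical experiment it emulates: a cadaveric femur+tibia
pair, each carrying 6–8 implanted 1 mm beads, frozen rigid at a hop-landing
flexion angle and manipulated through the shared field of view of two
X-ray views while being tracked by (a) bead triangulation + rigid fitting
(gold standard) and (b) intensity-based 2D–3D model registration (method
under test). The rigid freeze makes the true tibiofemoral relative pose
constant, so the relative-kinematics difference between methods is pure
tracking error.

Assumptions inherited from that design:

* perfectly rigid bones and a perfectly constant relative pose (no thaw,
  no fixture compliance);
* ideal pinhole X-ray views with known calibration — no distortion,
  scatter, beam hardening, or motion blur;
* bead observations arrive as 2D coordinates (bead detection/centroiding
  belongs to the marker-tracking software being emulated, not to this
  package);
* frames are treated as independent observations in the agreement
  statistics (differences are in fact autocorrelated through the 10 Hz
  filter; no effective-n correction is applied, matching standard practice
  for this analysis).

## Scene geometry

`build_geometry` places two pinhole views symmetrically about the vertical
plane bisecting their central rays: source-to-image distance 1850 mm,
separation angle 55°, 250 Hz frame rate, 450 × 450 mm detectors at
0.45 mm/px, isocentre 1400 mm from each source (magnification ≈ 1.3).
Detector coordinates are pixels relative to the principal point. Hop
travel is +X (horizontal), drop travel is −Z (vertical); trajectories are
centred on the isocentre, so early/late frames of longer trials naturally
clip the field of view — reproducing the real phenomenon that partially
visible bones occur while entering/leaving the field.

## Synthetic specimen

Bead clouds are rejection-sampled in a distal-femur / proximal-tibia box
(minimum pairwise distance 5 mm, non-coplanarity 1 mm) and expressed in a
randomly offset "CT" frame, as a real scan's axes would be. Anatomical
frames follow a fixed landmark convention: origin midway between the
paired condylar/plateau landmarks, X = medial→lateral (flexion axis),
Z = long axis of the shaft (superior positive), Y = Z × X. The frozen
relative pose is constructed so that the joint's X-Y-Z decomposition gives
a flexion angle drawn uniformly in 20–55° with a few degrees of
abduction/rotation and an inferior offset of ~40 mm. Per-DOF agreement
values depend on this axis convention (it decides how an error splits
across FE/AA/IE and ML/AP/IS); the *magnitude* of a method difference
(total rotation angle, translation norm) does not, which is asserted by a
property test that spins the convention by 40°.

Three specimen presets carry the soft-tissue volumes 3038, 1203 and
3964 cm³. Soft tissue plays no mechanical role (it is frozen); the volume
is a stratification label, computed where needed by voxel-mask subtraction
(total specimen minus union of bone masks).

## Model-based tracking emulator

Real 2D–3D registration is out of scope (it lives in the tracking software
itself); the method under test is represented by a calibrated noise
process applied to the truth pose of each bone, in the bone's own frame,
pivoting on its anatomical origin (so rotational registration error does
not acquire a spurious lever arm from the arbitrary CT origin):

* rotation: axis wandering smoothly on the sphere, angle with half-normal
  marginal |N(0, σ_rot)|, default σ_rot = 0.5° per bone;
* translation: per-axis Gaussian, default σ_trans = 0.4 mm per bone;
* outliers: frames partially out of the field of view, plus frames drawn
  independently with probability 0.05, get noise scaled ×4 — reproducing
  the ~5% of frames beyond the limits of agreement seen at field edges.
  The ×4 multiplier is a free choice (no published quantification of how
  much extra error an edge frame carries);
* temporal correlation: each noise component is a stationary AR(1) process
  with corner frequency 4 Hz (marginal distributions exactly as above;
  `noise_correlation_hz=None` recovers white noise). Registration error
  tracks the slowly varying pose of the bone against the detectors, so
  frame-independent noise would be unrealistic — and would be almost
  entirely removed by the 10 Hz kinematics filter, leaving the pipeline
  insensitive to the very errors it is meant to measure. With a 4 Hz
  corner, most of the noise power lies in the filter passband.

Defaults were set inside the 0.4–0.6°/mm band so that the pooled pipeline
lands in the sub-degree / sub-millimetre accuracy regime typical of BVR
validations (translations at the band's lower end because the rotational
noise adds a lever-arm term across the ~40 mm femur–tibia origin offset).
They are tunable per trial and scaled per specimen via `noise_scale`; they
are a model of tracking error, not ground truth about any real tracker.

## Marker-based tracking

Bead projections with Gaussian pixel noise (default 0.5 px) are
triangulated by linear least squares on the two back-projected rays
(rejected below 1° ray separation); for two rays this equals the midpoint
of the common perpendicular, which serves as the closed-form oracle. Bone
pose is the Kabsch SVD fit (determinant-corrected) of the CT bead model
onto the triangulated points, cross-checked against Horn's quaternion
method to 1e-9. A frame needs ≥ 3 beads visible in *both* views per bone;
otherwise it is untrackable and shrinks downstream counts. Analysis uses
the longest contiguous run of frames where both bones are tracked by both
methods, so the filter always sees uniformly sampled data.

## Kinematics

Pose sequences are converted to scalar-first quaternions,
hemisphere-aligned (consecutive dot products ≥ 0), and each of the 4 + 3
components is filtered with a zero-phase forward–backward pass of a
2nd-order Butterworth at 10 Hz; quaternions are renormalized and poses
rebuilt. Numerical choices:

* the design cutoff is divided by (√2 − 1)^¼ ≈ 0.802 so the dual pass has
  its −3 dB point at the nominal 10 Hz; a causal single pass is available
  (`zero_phase=False`) since the original description does not specify;
* sequences are extended by iterated odd (antisymmetric) end-point
  reflection to 4·fs/fc samples per side before filtering: the built-in
  padding of the filtering routine is capped at n−1 samples, far shorter
  than the filter's settling time for 10-frame drop trials, and the
  resulting edge transients biased trial speed estimates by ~5% before
  this fix. Odd reflection extends a linear trend exactly, so
  constant-velocity segments filter to machine precision;
* minimum length 3·order + 1 = 7 frames, else an error advising the
  minimum;
* component-wise quaternion filtering + renormalization introduces a
  rotation error that vanishes as the sequence smooths; at the signal
  bandwidths used here it is far below the tracking noise floor.

The relative pose is `A_f ∘ T_f⁻¹ ∘ T_t ∘ A_t⁻¹` (tibia anatomical frame
expressed in the femoral anatomical frame); identical poses and frames
give the identity. Decomposition is X-Y-Z: R = Rx(FE)·Ry(AA)·Rz(IE),
translations taken directly on the femoral anatomical axes (ML = X,
AP = Y, IS = Z). |cos AA| < 1e-6 raises a gimbal-lock error rather than
silently dropping frames (the knee never approaches ±90° abduction).
Tibial speed is the central-difference velocity magnitude of the tibial
anatomical origin in the lab frame, computed from the filtered transforms
(one-sided at the ends); which tibial point defines "the" linear velocity
is a convention, and the anatomical origin is used. Time normalization is
linear interpolation onto 75 (hop) or 10 (drop) equally spaced points with
endpoints preserved exactly.

## Agreement statistics

Differences are signed model − marker (test minus reference — the sign
convention is ours). MAD ± SD describes accuracy; bias = mean difference;
precision is the limits-of-agreement half-width 1.96 × sample SD (ddof 1),
tabulated as a single non-negative number. The LoA confidence interval
uses the classical large-sample approximation SE(LoA) ≈ √(3/n)·SD, i.e. CI
half-width 1.96·√(3/n)·SD, emitted for the pooled analysis only. Outliers
are frames with |d − bias| > LoA, measured relative to the bias (not
zero); deviations below 1e-9 °/mm are never counted, so a numerically
zero difference set (the zero-noise null pipeline, where residuals are
solver precision ~1e-9) reports a zero outlier fraction instead of
reclassifying floating-point noise. The four stratifications are pooled,
per bone, per specimen, and per motion; per-stratum frame counts sum
exactly to the pooled count by construction.

## Problem sizes

The default demo runs 3 specimens × 33 trials (18 hop × 75 frames, 15
drop × 10 frames, ~1500 frames generated, ~1440 analyzed after
field-of-view attrition) in ~20 s. The acceptance script uses 100 trials
per motion for speed recovery and 10⁵ draws for the Bland–Altman
construction; Monte-Carlo oracle tests in the suite use 10⁴–10⁶ draws as
noted per test.

## What passing tests do and do not show

The generator reproduces the *structure* of a frozen-specimen BVR
validation (geometry, trial design, frame attrition at field edges,
noise magnitudes, outlier mechanism), so passing tests demonstrate that
the pipeline's algebra, filtering, and statistics are correct and that
calibrated noise propagates to agreement tables as theory predicts. It
does not render radiographs, so nothing here measures how a real
intensity-based registration behaves — specimen-to-specimen error
differences, bone-quality effects, and the true error spectrum of 2D–3D
registration are outside the model (the per-specimen `noise_scale` is a
dial, not a mechanism). Bead masking operates on synthetic disk renderings
only.
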