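# Methods

## The measurement problem

A cell attached to the inner surface of a parallel-plate flow chamber
is imaged from a single focal plane at a fixed cadence (5 min in the
motivating experimental design).  The only observable is the cell's
projected 2-D outline; the quantity of scientific interest is its
volume over time, from attachment to the onset of division, under a
controlled hydraulic-shear condition set by the volumetric flow rate.
`cellflow` implements the full inference chain and a synthetic imaging
model that makes every stage testable against exact ground truth.

## Pixel classifier

Segmentation is a per-pixel two-class decision from raw channel values
— deliberately minimal, matching the imaging situation of bright
pigmented cells on a darker, texture-free background.

* Input features: the three 8-bit RGB values scaled to [0, 1].  The
  option `features="luminance"` collapses them to one channel; RGB is
  the default because colour is the most discriminative cue for
  pigmented cells.
* Architecture: one tanh hidden layer (default 8 units, configurable)
  and a sigmoid output, so the raw output lies in [0, 1] and is
  thresholded at 0.5.
* Training: full-batch damped Levenberg–Marquardt on the mean squared
  error with an analytic Jacobian.  LM is the natural choice for a
  least-squares objective over a few dozen parameters; above a
  1000-parameter cap the trainer switches to L-BFGS-B, preserving the
  same stopping contract.  Training stops at the first of: training
  MSE ≤ 10⁻⁶; the epoch cap; validation MSE stale for 15 epochs.  The
  70/15/15 train/validation/test split is seeded and deterministic;
  test MSE and error rate are reported, never optimised.
* The classifier serialises to a single JSON file (weights, feature
  scaling, training report) and reloads to bit-identical predictions.

Labelled pixels come, in the synthetic setting, from the ground-truth
masks (`sample_training_pixels`), emulating manual annotation of raw
frames.

## Geometry and volumes

Connected components (8-connectivity, minimum area 5 px²) of the binary
mask yield centroid, pixel area, and moment-based fitted-ellipse axes
(scikit-image `regionprops`).  A single isotropic calibration ratio
(default 0.30 µm/pixel, sd 0.001) converts pixels to micrometres.

Two 2-D → 3-D rules are provided:

* `spheroid` (default): the cell is a prolate spheroid seen side-on,
  V = (4/3)·π·(L/2)·(W/2)².  Chosen because the target organisms are
  elongated; nothing in the imaging geometry identifies the out-of-plane
  axis, so the projected minor axis stands in for it.
* `equivalent_sphere`: V = (4/3)·π·r³ with r from the projected area.
  The two agree exactly for circular projections.

The synthetic renderer inverts whichever model is configured when
drawing cells, so measurement on a noise-free render returns the
generating volume *by construction*, up to rasterisation error.
Rasterisation (pixel-centre-inside test at sub-pixel centres) keeps
projected areas within ~1–2 % of π·a·b for semi-axes ≳ 5 px; because
volume scales with the cube of linear size, per-frame volume errors are
roughly 1.5× larger, and the 3 % round-trip contract is exercised on
cells of ≥ 50 µm³ at the default calibration.  Smaller cells carry
proportionally larger single-frame rasterisation noise, which the
smoothing step averages out at track level.

## Tracking

Cells are attached and essentially stationary, so frame-to-frame
association is greedy nearest-centroid matching gated at a maximum
displacement (default 20 px).  Event semantics:

* **division** — the tracked object is replaced by ≥ 2 fresh detections
  within the gate.  Plain greedy matching would silently continue the
  parent track onto the nearer daughter, so a match is re-classified as
  a split when the matched detection's volume is below 60 % of the
  track's last volume *and* a second fresh detection lies in the gate
  (daughters are rendered at 45 % of the parent volume, well below the
  60 % cut).  The division time is the frame at which the daughters
  appear.
* **lost** — no detection in the gate: the cell was flushed away; the
  end time is one frame interval after the last sighting.
* **censored** — the recording ended with the cell still present.

## Growth curves

* **Smoothing**: Sₜ = αYₜ + (1−α)Sₜ₋₁ with S₁ = Y₁.  The recursion
  leaves S₀ undefined; initialising at the first observation is the
  standard convention and makes a constant series an exact fixed point.
  α defaults to 0.1 — a strong smoother, appropriate because the
  fluctuation of single-cell volume series is dominated by imaging
  noise rather than biology.
* **Cubic model**: V(t) = at³ + bt² + ct + d by OLS on the cubic basis.
  The time axis is internally rescaled to [0, 1] before building the
  basis: on an 8000-min grid the raw Vandermonde matrix is
  ill-conditioned enough to corrupt coefficient recovery, while the
  rescaled fit recovers exact-cubic inputs to ~1e-13 relative error.
  Standard errors come from the usual OLS covariance.  R² = 1 −
  SS_res/SS_tot about the mean; for a zero-variance target (constant
  volume) R² is reported as 1 and flagged `constant_target`, a
  convention needed because every fitted track reports an R².
* **Fit input**: fits default to the smoothed series, mirroring how the
  curves are produced experimentally; `use_smoothed=False` fits raw
  volumes.  Coefficient-recovery validation uses noiseless raw series,
  since the smoother's lag on a steep ramp is a known, deliberate bias.
* **Division record**: a tracker split is authoritative — the volume at
  division is the last pre-split smoothed volume and the growth period
  is division time minus attachment (first-detection) time, reported in
  minutes and days (min/1440).  In single-object mode a fallback
  declares division at the first ≥ 30 % drop of the smoothed volume
  from its running maximum.  `detect_division(..., use_smoothed=False)`
  reads sizes off the raw series where the smoother's lag (≈ interval ×
  (1−α)/α near a linear ramp) would bias the size at division.
* **Lag phase**: the adaptation period is operationalised as the time
  until the smoothed volume first exceeds (1 + 10 %) of its initial
  value.

## Condition aggregation

Per flow rate: arithmetic mean and sample sd (ddof = 1, reported only
for n ≥ 2) of each coefficient and R²; the full lists of division
volumes and growth periods are retained for box plots.  Cell selection
mirrors experimental practice: the k = 3 longest-cultivated tracks per
experiment (ties → larger final volume, then id), or tracks matched on
initial volume (default 27 ± tol µm³) for cross-condition growth-rate
comparison.  The optimal flow is searched under two metrics: the
per-condition **maximum volume at division**, and the per-condition
**median growth period** (median because lost/censored tracks make the
per-condition samples small and skewed).

The flow → ε (turbulent energy-dissipation rate) map interpolates
linearly between anchors.  Only one interior anchor is physically
known (270 µL min⁻¹ → 5.62 × 10⁻⁵ m² s⁻³) together with the study-range
endpoints 6.2 × 10⁻⁶–7.5 × 10⁻⁵ m² s⁻³; assigning those endpoints to
the lowest (30) and highest (420) flows of the grid is an explicit
assumption, overridable with a user-supplied anchor map.  Outside the
anchored span the hydraulic relation is unknown and lookup raises
rather than extrapolates.

## Synthetic data: what it emulates and what it does not

The generator emulates: ellipsoidal bright cells (tens of µm³) on a
noisy darker background (additive per-channel Gaussian noise, default
sd 8 on 8-bit values, clipped); cubic volume trajectories; division —
the parent is replaced by two daughters at 45 % of its volume placed
along its major axis, guaranteeing the track-level volume-drop and
split signals the detectors key on; loss — disappearance from one frame
onward; optional multiplicative jitter on apparent area.  Frames are
bit-reproducible: one master seed, with per-frame child seeds, so any
frame can be regenerated independently.

It does **not** emulate optical blur/point-spread functions,
illumination gradients, focus drift, cell motility or multi-cell
colonies (coenobia), nor multi-generation growth (daughters keep their
birth volume).  Passing tests therefore demonstrate the correctness of
the algorithmic chain — classification, extraction, calibration,
tracking, smoothing, fitting, aggregation — under a controlled imaging
model, not robustness to real-microscopy artefacts.

The shear cohort used for end-to-end validation encodes a dose-response
as a Gaussian bump over flow rate (peak 270 µL min⁻¹, width 60, floor
0.4): growth rate scales with the squared response, division time with
its inverse, so the volume at division peaks — and the growth period
bottoms out — exactly at the response peak, while within a condition a
larger initial volume (d = 20, 27, 40 µm³) always divides larger.
For test-budget reasons the cohort is rendered at 192 × 192 px with a
30-min frame interval and division times of 900–2250 min — a
temporally thinned version of the motivating 5-min/7-day recordings;
nothing in the pipeline depends on the absolute cadence, and its scale
invariance is covered by the 5-min fixtures elsewhere in the suite.

## Numerical and degenerate-input choices

* Classifier output thresholding uses ≥, so threshold 0 gives an
  all-cell mask and any threshold > 1 an all-background mask.
* A single-class training set, an empty sample split with positive
  proportion, non-finite losses, degenerate (minor axis 0) ellipses,
  rank-deficient cubic designs, < 4 fit points, and α ∉ (0, 1) all
  raise immediately with specific messages.
* Mean/sd aggregation short-circuits identical values to (value, 0)
  exactly, so permutation invariance and the "n identical values" case
  hold without floating-point fuzz.
* A frame interval that does not divide the requested span truncates
  to the largest multiple with a warning.

## Known limitations

* The 2-D → 3-D volume rule is unidentifiable from a single focal
  plane; both provided models are conventions, and absolute volumes
  inherit that convention.
* The published coefficient-table scales (a ×10⁻¹⁰, b ×10⁻³, c ×10⁻²,
  t in min) are treated literally for round-trip validation; at those
  scales the quadratic term alone reaches ~10⁴ µm³ by t = 8000 min,
  which is inconsistent with single-cell curves of ≤ ~160 µm³.  The
  package validates coefficient *recovery*, not the table's internal
  dimensional consistency; noisy-recovery checks use realistic
  27→150 µm³ trajectories.
* Tracking assumes near-stationary cells; it is not a general-purpose
  cell tracker and will fragment tracks of motile cells.
* The LM trainer is full-batch and dense; it is intended for the tiny
  pixel networks it defaults to, not for large feature sets.
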