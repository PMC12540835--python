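# Methods

## Spindle frame and kinematics

All per-pair quantities are computed in a per-frame spindle reference frame
built from the two centrosome tracks: midpoint **m**, unit axis **û**, and
the equatorial plane through **m** perpendicular to **û**. The package
defaults to projected-2D mode (tracks from maximum-intensity projections;
the z column is ignored), and accepts 3D data with identical formulas —
in 2D the plane degenerates to the perpendicular line through **m**, and
`|(c−m)·û|` is unchanged.

Tracking gaps are expected (kinetochores are lost among neighbours, spindles
move in z). Gaps of at most `max_gap` frames (default 2) are bridged by
linear interpolation of each coordinate; longer gaps leave frames undefined
and every downstream rule operates on defined frames only. Frames whose pole
separation is at or below `eps_pole` (default 1 µm) are marked undefined
rather than fabricating a near-degenerate axis. Pole and kinetochore samples
are joined on integer frame index; fractional-time resampling is out of
scope.

Two distinct angles are exposed because two distinct definitions circulate
for "the angle of a kinetochore pair": `theta_pos`, between the pole–pole
line and the line joining the pair center to its nearest pole, and
`theta_orient`, between the sister–sister axis and the spindle axis. Both
are reported as acute values in [0°, 90°] since lines, not rays, are being
compared. An exact distance tie between the poles is assigned to pole A for
determinism.

## Event rules

- **Polar**: `d_pole < d_plane`, strict; a pair exactly equidistant is not
  polar.
- **Aligned-ever**: minimum `d_plane ≤ 3 µm`, inclusive boundary.
- **Plate crossing**: first frame with `d_plane < 2 µm`, strict, with no
  persistence requirement by default. An optional `min_dwell` (consecutive
  frames below the boundary) is available but defaults to 0; whether real
  crossings should be debounced is genuinely open, and the default is the
  simplest deterministic reading.
- **Congression velocity**: `(d_plane(t_c − w_eff) − d_plane(t_c)) / w_eff`
  with the nominal window `w` = 6 min (4 min in the U2OS preset). The
  velocity uses the distance-to-plane coordinate, not path length, which
  fixes the sign convention: positive toward the plate, negative away from
  it. When the track starts less than `w` before the crossing, the window
  shrinks to the covered span `w_eff`; spans below `w/2` raise an error
  instead of returning a poorly supported number.
- **Alignment success**: an initially polar pair (polar on its first defined
  frame at or after the reference time `t_ref`) succeeds when
  `d_plane ≤ 2 µm` on any defined frame within `(t_ref, t_ref + 30 min]`.
  Pairs lost before the window ends and never crossing count as failures.
  `t_ref` is configuration (recording start by default; washout or spindle
  elongation in other designs).
- **Counting schedule**: polar pairs are counted at 12 min and then every
  6 min; a pair contributes at a time point when it has a defined frame
  within half a counting step.
- **Misalignment categories**: the plate counts as formed when at least
  `plate_fraction` (default 0.75) of pairs lie within 3 µm of the plane —
  the operational cutoff is a package choice since "plate formed" has no
  standard numeric definition. With a formed plate, 0 pairs outside → tight,
  1–4 → low, ≥5 → high misalignment. Exactly 5 outside is scored high
  (the conservative reading of a ">5"/"<5" pair of rules that leaves 5
  unassigned).
- **Maximum chromosome spread**: the largest pairwise distance between pair
  centers at one frame.

Boundary conventions (≤ 3 µm inclusive, < 2 µm strict) are fixed once for
determinism at the boundaries and asserted by tests; threshold monotonicity
(raising the success distance or lengthening the window never lowers the
success fraction) holds by construction and is checked on simulated cells.

## Intensity quantification

Per kinetochore: integrate the sum projection over a spot region, subtract
the mean cytoplasmic background per pixel times the region area, divide by
the number of z-planes `n_z`. Negative corrected values are retained and
flagged, not clipped, so group means stay unbiased. The manual oval of
interactive workflows is replaced by a deterministic region: the connected
component around the seed of pixels at or above half of (local peak − local
floor), capped at radius `r_max` = 6 px, falling back to a 2-px disk when
thresholding yields fewer than 3 px (flat neighbourhood). One region, fixed
on the reference (CENP-A) channel, is reused across channels. For synthetic
data the background region is an 8–12 px annulus around the seed minus any
spot mask; for user data it is an explicit cytoplasm mask.

Channel ratios (target / CENP-A) remove per-kinetochore gain; the
within-cell normalization divides each ratio (and each pole distance) by the
mean over that cell's aligned group, making distributions comparable across
cells with different staining efficiency. Both normalizations are exactly
gain-invariant, which the tests assert to 1e-6.

"Mad2 signal loss" over a window is the fractional loss
`(I(t₀) − I(t₁)) / I(t₀)` by default (an absolute-difference variant sits
behind a flag); fractional loss is the natural choice when intensities are
in arbitrary units that differ between cells.

## Statistics

One-way ANOVA (F) with two-sided Tukey HSD post-hoc comparisons using the
studentized-range distribution and the Tukey–Kramer allowance for unequal
group sizes; pooled two-proportion z-tests and Pearson's chi-square test of
independence, both without continuity correction; closed-form OLS with a
two-tailed t-test on the slope (n − 2 df) and R²; and mean ± s.d. with the
t-based CI for the mean and the χ²-based CI for the s.d. Zero-variance
inputs yield collapsed, flagged intervals. Star tiers
(0.05/0.01/0.001/0.0001) are display-only; raw p-values are always emitted.
Null-simulation tests check that the familywise error of ANOVA+Tukey and the
type-I error of the z- and slope tests sit at the nominal 5%.

## Synthetic data: what it emulates and what it does not

Each polar pair starts 1–3 µm from a pole (uniform, with a lateral offset up
to ±60°), waits an exponential initiation time `T ~ Exp(λ_init)`, drifts at
`v_slow` with Gaussian positional jitter before `T`, then approaches the
plane at a per-pair fast velocity until within 1 µm of it, where it holds
with jitter. The interkinetochore distance rises logistically from
`δ_lat` = 0.6 µm to `δ_bio` = 1.0 µm centred at `T` (rise time 4 min),
matching the typical rest vs stretched sister separation in human cells; the
sister axis relaxes exponentially toward the spindle axis after `T`
(τ = 3 min). Mad2-like intensity stays at `I0` until `τ_pre` = 2 min before
fast movement, then decays at a per-pair `k_fast` (geometric mean 0.3/min);
pairs that never initiate within the recording decay at `k_slow` = 0.03/min
from t = 0 — so intensity decline precedes movement by construction, and
non-initiating pairs lose signal more slowly. A latent bivariate normal with
correlation ρ = 0.8 couples each pair's fast velocity (lognormal spread
σ = 0.2 around 0.8 µm/min) to its Mad2 decay rate (σ = 0.4).

Defaults are simulator choices, not measurements: pole separation 12 µm and
frame interval 1 min match a typical RPE-1 metaphase spindle and
confocal-assay cadence; λ_init = 0.1/min ("reactivated") vs 0.01/min
("inhibited") encodes a 10-fold initiation-rate difference with identical
movement parameters — the qualitative claim that motor activity gates
initiation, not translocation. The fast-phase speed has no published numeric
value to match, so validation is parameter *recovery* (the analysis must
return what was programmed), not value-matching.

Not emulated: microtubule/force mechanics, anaphase onset (an input, not an
inference), z-motion and drift, photobleaching, spot overlap and
mis-tracking, and cell-to-cell parameter heterogeneity beyond the per-pair
lognormals. Passing tests therefore demonstrate that the decision rules and
estimators are correct and calibrated on data with the assumed structure —
not that real microscopy meets those assumptions.

Randomness is counter-based: every stream derives from
`(master_seed, crc32(condition), cell, pair, purpose)`, so any single pair
is reproducible in isolation and conditions/cells are independent.

Image stacks render each kinetochore as a pixel-integrated 3D Gaussian
(erf-based, so the discrete sum equals the programmed integrated amplitude
up to field truncation) over a constant background, with optional Poisson
noise.

## Numerical choices and problem sizes

Unit vectors are normalised with a guard on separation; angle cosines are
clipped to [0, 1] before arccos; ties broken toward pole A; boundary rules
as above. The test suite and acceptance script use deliberately small
problem sizes — tens of cells, 60–300 pairs, 10⁴-replicate vectorised null
simulations — chosen so the full validation runs in well under a minute per
suite while keeping Monte-Carlo error far below the asserted tolerances
(binomial/3-s.e. bands are stated alongside each check).

## Known limitations

- The 6-min velocity window can include part of the slow phase when a pair
  initiates close to the plate-crossing threshold, diluting the windowed
  velocity relative to the pair's true fast-phase speed; the dedicated
  recovery preset (16 µm spindle, immediate initiation) isolates the
  estimator itself, which is unbiased to ~0.1%.
- Gap interpolation is linear; fast direction reversals inside a bridged gap
  are invisible.
- The misalignment categorisation depends on the `plate_fraction` cutoff for
  "plate formed", which has no canonical value.
- In projected-2D mode all distances are projections; out-of-plane geometry
  shortens them.
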