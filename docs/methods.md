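# Methods

## The simulation model

The package studies one question: holding everything else ideal, how do
in-plane voxel size, slice thickness and object orientation limit the volume
and shape accuracy of labeling a small structure?  "Everything else ideal"
means: the object is a perfect triaxial ellipsoid of known geometry; the MR
signal is noise-free, contrast is binary (object vs. nothing), and the only
acquisition physics retained is Fourier sampling at the acquisition
resolution.  What survives is exactly the partial volume effect and Gibbs
ringing that voxel geometry imposes, which is the effect under study.

### Analytic k-space and reconstruction

The indicator function of an ellipsoid has a closed-form continuous Fourier
transform (the building block of the classical 3D analytical head phantom):
for semi-axes (a, b, c), volume V, rotation R, world centre t and frequency
vector k,

    F(k) = V * 3(sin u - u cos u)/u^3 * exp(-2*pi*i k.t),
    u = 2*pi * |(a k'_x, b k'_y, c k'_z)|,   k' = R^T k.

`analytic_kspace` evaluates this exactly at the discrete frequencies of the
acquisition grid (integer multiples of 1/FoV per axis, fftfreq ordering, DC
at index (0,0,0)); `reconstruct` applies the inverse DFT.  Numerical
choices:

* **Small-u series.**  The u → 0 limit of the radial profile is handled by
  the series 1 − u²/10 + u⁴/280 below u = 10⁻³, avoiding catastrophic
  cancellation; the DC sample is then exactly intensity × volume, and the
  test suite holds this volume-conservation identity to 10⁻⁹ relative
  tolerance under arbitrary rigid poses.
* **Cell-centred coordinates.**  Voxel m along an axis with n voxels of
  size d sits at −FoV/2 + (m + 0.5)d.  This convention is symmetric for odd
  and even n, which is what lets the two odd-slice-count cells of the design
  (15 and 9 slices at 2.0 mm in-plane with factors 1.2 and 2.0) align with
  the even 360-voxel reference grid with no padding, shifting or
  interpolation anywhere in the pipeline.
* **Real part, then [0, 1] rescale.**  The phantom is real-valued, so the
  imaginary residual of the inverse DFT (discrete sampling asymmetry) is
  discarded.  Intensities are then min–max rescaled per volume to [0.0, 1.0],
  the range a windowed image presents to a rater; this folds the negative
  Gibbs undershoot into the displayed range (background lands near 0.08
  rather than 0.0 at typical geometries).  The raw, unscaled reconstruction
  — whose values approximate the partial-volume occupancy fraction directly
  — remains available (`scale=False`) and is what the rasterization-oracle
  agreement and Parseval checks use, since display scaling is a monotone
  transform irrelevant to thresholding but ruinous to a literal
  intensity-difference comparison.
* **Rotation composition.**  The orientation rotation (parallel/diagonal/
  orthogonal = 0°/45°/90° about x) is applied first, then the random
  rigid-body rotation, both about the FoV centre; translation last.  The
  composed transform acts on k-space as a rotation of the frequency vector
  plus a phase ramp.

An independent brute-force pathway, `rasterize_oracle`, estimates each
voxel's occupancy fraction by regular sub-voxel sampling of the analytic
membership test.  The Fourier and rasterization pathways share no code
beyond the geometry types; their mean absolute intensity difference at
0.1 mm isotropic voxels is below 0.02 (measured ≈ 0.001), degrading
monotonically as voxels coarsen.

### Simulated raters

The labeling decision is modelled as a logistic psychometric curve in
scaled voxel intensity, P(label | i) = expit(β₀ + β₁ i), fitted from
(intensity, binary label) tables by maximum likelihood (statsmodels Logit).
Perfect separation — a threshold that classifies the table exactly — has no
finite ML optimum; such fits are flagged and returned with the slope capped
at 500 (preserving the separating midpoint) rather than left to diverge.
Coefficients fitted per resolution are averaged arithmetically into a
single curve per rater.

The curve is applied to **all** voxels, not an explicit edge set: its tails
make interior voxels near-certain inclusions and background near-certain
exclusions, so the edge region emerges from the partial-volume intensity
ramp itself.  Two application modes exist: *stochastic* (independent
Bernoulli per voxel, the default, seeded and reproducible) and *expected*
(include iff p ≥ 0.5), which gives a deterministic surface useful for
regression tests.

**Default curves.**  The shipped defaults are liberal β = (−9, 29)
(midpoint ≈ 0.31) and joint β = (−13, 28) (midpoint ≈ 0.46).  These are
package placeholders, not fitted values: they encode a liberal rater whose
inclusion threshold sits below the conservative joint rater's, both steep.
The background floor matters when Bernoulli labeling is applied to every
voxel of a 36 mm FoV: expected false-positive volume is P(0) × 46656 mm³,
so P(0) must stay below ~10⁻⁴ for the false-positive volume to stay below a
few percent of the 164.9 mm³ object.  The defaults satisfy this; any
quantitative claim about specific human raters requires re-fitting from
their label tables, and every rater-dependent output is parameterized
accordingly.

The **optimal rater** knows the truth volume: it computes the proportion of
the FoV cube the object occupies (164.9/36³ ≈ 0.00354 for the default
design), builds the empirical survival function of voxel intensities over
*unique* intensity levels, and linearly interpolates the threshold whose
suprathreshold proportion matches the target.  Interpolating over unique
levels (rather than raw order statistics) is what makes the threshold land
strictly between discrete intensity plateaus when the target falls between
their survival values.  Two volumes are recorded: the *continuous*
proportion-matched volume (equal to the truth by construction — this is the
bookkeeping under which the optimal rater's volume deviation is ~0 in every
cell, independent of voxel size) and the *discrete* mask volume (count ×
voxel volume), which at coarse grids can only approximate the target to
within about one voxel and is the mask actually used for Dice.

### Metrics and the reference

Shape agreement is Dice, 2|A∩B|/(|A|+|B|) (defined as 1.0 for two empty
masks), computed on a common grid: the coarse mask is up-sampled to the
reference grid by nearest-neighbor assignment (each reference voxel takes
the value of the source voxel with the nearest centre; boundary ties, which
cannot occur for the design's rational size ratios, would round half-down
in index space).  For integer per-axis size ratios this is exact block
replication and preserves physical volume to the last bit — asserted in
tests, including the odd-matrix cells.

The reference mask is the **optimal rater's labeling of the same variant
reconstructed at 0.1 mm isotropic**, not the analytic membership mask: the
comparison isolates what coarse geometry destroys relative to the best
achievable labeling at the finest resolution, rather than mixing in the
(tiny) residual error of the finest resolution itself.  The analytic
membership mask remains available through the oracle for testing; at 0.1 mm
the two agree with Dice > 0.99.

### The factorial experiment

Defaults reproduce the study conditions: 100 rigid-body variants (uniform
per-axis translation within ±4 mm and rotation within ±8°), three
orientations, in-plane sizes {0.1, 0.2, 0.5, 1.0, 2.0} mm, thickness
factors {1.0, 1.2, 1.5, 1.8, 2.0, 3.0} — 9000 reconstructions per rater in
a 36 mm cubic FoV chosen so every combination yields an integer matrix.
Seeding is hierarchical: a single master seed derives per-variant pose
seeds and per-trial labeling seeds through `numpy.random.SeedSequence`, so
any subset of the design is bit-reproducible and independent of iteration
order.  Reference masks are cached per (seed, variant, orientation) and
reused across all resolutions and raters.

Aggregations: per-cell mean/SD and normal-approximation 95% CIs
(mean ± 1.96·SD/√n) of deviation and Dice; the equal-voxel-volume
comparison (0.1 mm ×8 vs 0.2 mm isotropic, 0.5 mm ×8 vs 1.0 mm isotropic)
separating voxel-shape from voxel-size effects; and a guideline table
keyed by the voxel volume as a percentage of the structure volume
(isotropic tiers ≈ 0.0006, 0.005, 0.08, 0.6, 4.85%), flagging cells above
the acceptable (0.75) and ideal (0.90) Dice levels.

The Dice-vs-deviation relationship is summarised by an anchored
exponential, DCS(d) = (1 − c)·exp(−k·d) + c, with d the absolute percentage
deviation, fitted by least squares; the inverse mapping
d = −ln((q − c)/(1 − c))/k reports the deviation corresponding to a Dice
level.  The functional form is a package choice (monotone, anchored at
(0, 1), with a floor reflecting the non-zero overlap of same-centre masks);
thresholds derived from it are labeled as coming from this fit.

## Problem sizes used in the shipped checks

The test suite and the acceptance script run desk-scale versions of the
design, chosen as the smallest cohorts in which the claims are stable:

* Reduced cohort for the headline Dice claims: 3 variants per cell at
  0.2 mm in-plane (all six factors, all orientations) and 5 variants per
  orientation at 2.0 mm with factor 3, fixed master seed, references at the
  full 0.1 mm / 36 mm geometry (360³ voxels).
* Unit and property tests use a half-scale ellipsoid (1.35, 1.35, 2.7 mm)
  in a 12 mm FoV, preserving every geometric ratio while keeping the finest
  grids at 120³.

## What the generator does and does not emulate

The phantom reproduces resolution-dependent partial volume and ringing
exactly, for a perfectly ellipsoidal, homogeneous, noise-free object.  It
does **not** model MR noise, coil sensitivity, relaxation contrast,
susceptibility, motion artifacts, irregular anatomical shape, or
neighbouring structures — so passing tests bound what voxel geometry
*alone* does to labeling accuracy; real acquisitions can only do worse.
Guideline numbers (e.g. "isotropic voxels below ~5% of the structure volume
keep Dice above 0.75 for the optimal rater") are therefore best-case floors,
and psychometric-rater results depend entirely on the supplied β
coefficients.

## Known limitations

* The optimal rater's continuous-volume bookkeeping makes its *volume* row
  trivially perfect; its Dice row is the informative one.
* The logistic rater model has no spatial component: inclusion decisions
  are voxel-wise independent, which understates the spatial coherence of
  human raters at very coarse grids.
* Upsampling is exact only for integer voxel-size ratios (always true in
  the shipped design); non-integer ratios fall back to nearest-neighbor
  assignment, which preserves volume only approximately.
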