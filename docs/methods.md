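# Methods

`luquant` is a desk-scale simulation testbed for absolute activity
quantification in ¹⁷⁷Lu SPECT at the 208 keV photopeak, built around the
MIRD-style workflow: acquire three energy windows, reconstruct with OSEM
including attenuation correction (AC), resolution recovery (RR) and
scatter handling, convert counts to MBq with a camera normalization
factor (CNF), and segment each object to read off its activity.  Every
stage is implemented so that the end-to-end quantification error of known
digital phantoms can be measured under controlled, repeatable conditions.

## Forward model

The projector is the classic rotation-based factorization of a
parallel-beam SPECT system matrix.  For each view the volume is rotated
so rays run along a grid axis; each constant-depth plane is weighted by
the cumulative attenuation to the detector (half-voxel self-attenuation
convention, `exp(-Δl (Σ_{k>j} μ_k + μ_j/2))`) and blurred with an
isotropic Gaussian whose width grows linearly with the distance to the
collimator face,

    σ(d) = σ₀ + s·d,     defaults σ₀ = 3.0 mm, s = 0.02,

then the planes are summed.  Numerical choices that matter:

* **Rotations are sparse matrices in splat (mass-preserving) form** — the
  transpose of the inverse-angle bilinear gather.  Every in-bounds voxel
  distributes exactly unit weight, so total counts are conserved through
  the rotation (gather-form interpolation loses up to ~3% at oblique
  angles, which would bias quantification per view).  The adjoint used in
  reconstruction is the literal matrix transpose, so the dot-product test
  holds to machine precision.
* **Per-plane blur widths are quantized to 0.1 pixel** and planes sharing
  a width are blurred in one pass (blur commutes with summation within a
  group).  The Gaussian kernel is symmetric, truncated at 4σ with zero
  padding, hence exactly self-adjoint.
* The same operator serves simulation and reconstruction, but the
  simulation runs on a grid with half the detector pitch (default 2.4 mm
  / 128³ versus 4.8 mm / 64³ with a 64×64 detector) and its projections
  are 2×2-rebinned; together with the independent scatter generator this
  avoids the pure inverse crime.

The reconstruction-side forward model carries a 1/n_views factor, i.e.
image voxels are in **total-scan counts**.  This is the convention under
which the tomographic CNF, total image counts / (A · t_p · n_p), lands on
the same counts/(MBq·s) scale as a planar sensitivity measurement.

## Scatter and the energy windows

Scatter is modelled in projection space, not by photon transport — enough
to exercise, and controllably bias, the triple-energy-window (TEW)
correction:

* self-scatter `S = f_s · G(primary, FWHM)` and high-energy downscatter
  `H = f_he · G(primary, 2·FWHM)` with Gaussian broadening kernels
  (periodic padding keeps count totals exact).  Defaults: `f_he = 0.03`
  (the downscatter-to-primary count ratio in the photopeak window),
  `f_s = 0.25` for water-filled phantoms, `0.05` in air, kernel FWHM
  40 mm.  The self-scatter fractions and kernel width are declared
  assumptions of the generator, not measured values.
* Each bin carries a scatter spectral density across the windows
  (LSW 153.0–187.0, PW 187.2–228.8, USW 229.5–280.2 keV).  The density is
  linear in energy across the photopeak, normalized so its photopeak
  integral equals S+H, and the flanking windows sample it **extrapolated
  to the photopeak edges** (the idealization underlying TEW; with these
  asymmetric windows a density sampled at the flanking-window centers
  would leave the trapezoidal estimate biased even for a perfectly linear
  spectrum).  A quadratic `spectral_curvature` term (default 2×10⁻⁵
  keV⁻²) bends the density inside the flanking windows, giving TEW a
  tunable bias — with the default, TEW overestimates scatter by ~3.7%,
  i.e. activity is mildly underestimated.  At zero curvature TEW is
  exactly unbiased in expectation, which the property tests pin down.

Counting noise is independent Poisson per bin and window, seeded.

## Reconstruction

OSEM with 10 angle-interleaved subsets (90 views → 9 per subset) and 6
iterations.  The scatter estimate — per-bin TEW, the simulator's
ground-truth S+H ("ideal" mode), or nothing — enters the denominator of
the multiplicative update, never subtracted from the data, preserving the
Poisson structure.  No smoothing is applied to any window before TEW.
Initialization is uniform inside the inscribed field-of-view cylinder;
the denominator is floored at 10⁻¹⁰ of its maximum.  Zero-sensitivity
voxels are masked from the update and exact zeros stay zero.

## Camera normalization

Planar method 1: all photopeak counts of a point-source scan divided by
activity × duration (biased up by the ~8% scatter present in the window).
Planar method 2: the same after TEW subtraction on the window totals —
the study's reference, used for all counts-to-MBq conversions.
Tomographic: total counts of a TEW-corrected reconstruction divided by
activity × total scan time.  The simulated point source sits 30 cm from
the collimator; planar counts are integrated over the whole detector
field of view.  Decay correction of the stated activity is the caller's
responsibility.

## Segmentation

All methods operate inside an enclosing VOI per insert, the programmatic
replacement for manually drawn regions: voxels within 35 mm of the insert
surface that are closer (in surface distance) to that insert than to any
other, so neighbouring VOIs never share voxels.  The hot-voxel reference
is the mean of the 9 highest-valued VOI voxels.

* **Fixed threshold**: keep voxels ≥ fraction × reference.  0.1% for
  scans in air and 1% in cold water (sweeping spilled counts back in),
  40% as the clinical reference in warm background.
* **CT-based**: the phantom's true geometry block-resampled to the
  reconstruction grid; spill-out makes it underestimate.
* **IADT** (iterative adaptive dual thresholding): two threshold curves,
  one recovering volume and one activity, as functions of the
  signal-to-background ratio (SBR).  Calibration finds, per insert and
  calibration scan, the largest threshold fraction reproducing the true
  volume/activity (bisection; inserts whose profile cannot reach the
  truth are excluded with a warning), and re-measures each scan's SBR
  from its own image with the same estimator segmentation later uses
  (reference over the mean of VOI background voxels one voxel clear of
  the mask).  Indexing the knots by the measured rather than nominal SBR
  cancels the noise bias of the hot-voxel reference between calibration
  and application.  The fitted fractions are, to within ±0.003, linear in
  1/SBR — the classical adaptive-threshold form f ≈ a + b/SBR — so
  queries interpolate linearly in 1/SBR and extrapolate the end segments
  (fractions bounded in [0.02, 0.95]); this matters because the
  bottles-in-warm-water condition sits at SBR ≈ 49, well above the
  highest calibration level of 14, where clamping would leave a ≈ −13%
  bias.  Segmentation starts from the 40% mask and iterates
  measure-SBR → look up fractions → re-segment until both fractions move
  < 10⁻³ (max 20 passes).  The thresholds are learned from the
  calibration scans at run time, never hand-set.

IADT assumes a uniform uptake in the VOI; it degrades for objects a few
voxels across (spill-in floods the mask once the threshold approaches the
background level), which is why accuracy claims are restricted to ≥34 ml.

## Study conditions and the synthetic generator

The eight phantom presets mirror the bench configurations: Jaszczak
spheres (0.5–113 ml, 3.19 MBq/ml) in air / cold water / warm water
(background 0.49 MBq/ml, SBR ≈ 6.5), Jaszczak bottles (8.5–34 ml,
5.11 MBq/ml) in air and warm water (background 0.104 MBq/ml, SBR 49.1),
a thorax body with lung/spine/bone inserts holding four 34 ml bottles in
cold water, and large bottles (34–199.5 ml) on the camera bed with and
without water bags.  Insert positions inside the containers are not
dictated by the bench hardware and are preset on rings with clearance;
exact coordinates live in `phantoms.py`.  The "true" activity used for
error computation is the rasterized phantom content (fractional-fill
voxelization by supersampling, volume accurate to well under 1%), so the
error measures the imaging chain, not the voxelization residue.
Attenuation coefficients at 208 keV are frozen from standard tables
(water 0.136 cm⁻¹; air treated as vacuum; lung 0.041; bone-like 0.25;
bed 0.03).

Detector sensitivity is 10 counts/(MBq·s) — the simulation's ground-truth
CNF — with per-projection durations of 10–40 s; photopeak totals run
10⁶–10⁸ events per scan.  The full study uses 5 Poisson realizations per
configuration and reports per-insert errors averaged over realizations.
The 0.5 ml sphere is never analyzed, the first bed bottle is excluded
(its nominal activity is knowingly wrong), and the 1 ml sphere is dropped
in warm background where it is invisible; these exclusions follow the
bench study's analysis rules.

What the generator does *not* emulate: object-dependent spatial scatter
asymmetries (the scatter kernel is shift-invariant), septal penetration
and collimator scatter, detector energy resolution beyond the
window-fraction model, dead time, and Bremsstrahlung.  Passing tests
therefore demonstrate the correctness and internal consistency of the
correction and segmentation chain under these idealizations, not the
absolute accuracy achievable on any particular camera.

## Statistics

Errors are signed percent differences from truth.  The Mann-Whitney
rank test (two-sided, tie-corrected) compares scatter-correction
variants; Mood's median test (ties counted below the grand median)
compares the three segmentation methods at once.  p < 0.05 is flagged as
a significant difference.  No multiple-testing correction is applied.

## Known limitations

* The projector is parallel-beam with a circular orbit by default;
  non-circular orbits are supported as per-view radii but no preset uses
  them.
* The scatter spectral model is a bookkeeping device: its flanking-window
  counts are consistent with a documented piecewise density, but it is
  not a physical downscatter spectrum.
* IADT curves are averaged over calibration inserts of 17–199.5 ml;
  volume dependence of the optimal threshold below ~17 ml is not
  captured, consistent with the method's stated range.
* Reconstruction-grid voxels (4.8 mm) limit the smallest quantifiable
  insert; sub-2 ml objects are at or below two voxels across.
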