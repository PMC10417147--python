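# Methods

This note documents the models implemented in `cbctsct`, the defaults and why
they were chosen, what the synthetic phantoms do and do not emulate, and the
numerical decisions a maintainer would want to know about. Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Image model and geometry

Volumes are axis-aligned scalar grids (`voxels[ix, iy, iz]`, X right–left,
Y anterior–posterior with +Y posterior, Z inferior–superior); physical
position = origin + index · spacing, all in mm. Every image carries an
intensity kind (`HU`, `CBCT_GRAY`, `DOSE`, `DENSITY`) that is checked before
cross-image arithmetic: CBCT gray values are never implicitly treated as CT
numbers. Grid presets mirror the clinical scanners this workflow targets —
CT 512×512×387 at 1.17×1.17×1.00 mm, CBCT 512×512×110 at 0.54×0.54×2.50 mm
with a 26 cm field of view — while tests and the acceptance script run on a
downscaled 96×96×60 grid at 3 mm (preset `"test"`; a 48³-class preset
`"test_small"` exists for smoke tests). These sizes keep a full case
evaluation under ~20 s on one CPU without changing any algorithmic behavior.

FOV retraction (the focus region for deformable registration, default margin
20 mm) is a Euclidean-distance-transform erosion in physical units, so an
anisotropic 2.5 mm slice spacing erodes correctly; iterated structuring
elements would not.

## Synthetic phantoms

`phantoms` generates the study conditions: a head-and-neck-like planning CT
with three separable tissue classes (air −1000 HU; soft tissue 40 ± 12 HU
with smoothly correlated texture, correlation length ≈ 1.5 voxels; bone
700 ± 40 HU), a body whose cross-section widens from neck to shoulders, a
spine, mandible ring, posterolateral shoulder-bone surrogates that reach up
toward the low neck, an airway and a sinus cavity, a spherical high-risk CTV
in the mid neck and an elongated standard-risk CTV extending inferiorly
toward the shoulders (nodal volumes run into the lower neck, which is why
shoulder setup matters clinically).

The treatment-day anatomy is produced by an *analytic* pull-back deformation
whose exact field is returned as registration ground truth: a radial
contraction around the high-risk target (default volume reduction 16.4 %, the
reported mean early-course target shrinkage; the linear scale factor is
(1−s)^(1/3), exact inside the target and smoothly tapered outside), a rigid
translation of each shoulder surrogate with a smooth 22 mm taper, and
optional air-cavity filling (intensity-only). Binary masks are warped by
anti-aliasing the indicator (Gaussian, 0.6 voxel), interpolating, and
thresholding at 0.5: interpolating the raw binary lattice parks the
half-level surface between voxel centers and swallows sub-voxel boundary
motion, which would break volume bookkeeping for the shrinkage.

The CBCT simulator degrades the treatment-day image *in image space*:
`CBCT = gray_map(HU) + shading + streaks + noise`, cropped to a cylindrical
26 cm FOV with a truncated z-range. The gray map is monotone (default gain
0.8, offset 40, optional quadratic term; monotonicity over [−1000, 3000] HU
is validated) and its exact piecewise-linear inverse is returned for
recovery tests. Shading is a smooth low-frequency field (radial cupping +
long-wavelength axial cosine, wavelength ≥ 5 cm by construction, default
amplitude 80 gray units); the optional shoulder streak is a localized
negative bias between the shoulder surrogates emulating photon starvation.
Projection/reconstruction physics is deliberately not simulated: the
correction algorithms only ever see image-domain data, and reconstruction
parameters are reported not to influence evaluation doses. Consequences:
passing tests demonstrate recovery of monotone intensity distortion plus
smooth shading plus noise, not of structured streak/scatter artifacts, beam
hardening tied to anatomy, or motion.

Cohorts are sampled per case: scenario parameters (shrinkage N(0.164, 0.08)
clipped to [0, 0.45], shoulder shifts N(0, 4 mm) per axis, cavity fill with
probability 0.3) plus planted ground-truth D99 losses. The loss marginals
are lognormal, fitted once to the published interquartile ranges (high-risk
0.7–2.4 pp → μ=0.259, σ=0.913; standard-risk 0.5–3.2 pp → μ=0.235, σ=1.376),
coupled by a Gaussian copula with ρ = 0.7 because the two per-structure
trigger lists overlap in practice. Surrogate-image errors are zero-mean
normal with SDs set so E|error| matches the published per-image accuracies.
Every stochastic operation is a pure function of its seed.

## Registration

Rigid alignment is SimpleITK's centered Euler transform with a mean-squares
metric, full (deterministic) sampling and a three-level pyramid.

The deformable step must satisfy a specific contract — displacement
identically zero outside the retracted-FOV focus, smooth and plausible
inside — rather than replicate any commercial hybrid algorithm. It is built
from symmetric-forces demons with three choices that implementation
experience forced:

* **Translation pre-alignment.** The dominant global shift (daily setup
  error) is estimated by windowed phase correlation with parabolic sub-voxel
  refinement, the moving image is pre-shifted, and the constant is added
  back afterwards. Seeding demons with a constant initial field instead
  lets its zero-boundary field smoothing erode the constant toward zero.
* **Single full-resolution level** (60 iterations, field smoothing σ = 2.0
  voxels). Coarse pyramid levels smooth away the soft-tissue texture that
  anchors flat regions, after which residual smooth intensity offsets drive
  multi-millimeter drift. Multi-level schedules remain configurable for
  larger motions.
* **Intensity-difference threshold 20 HU.** Differences below ≈2× the
  texture SD are indistinguishable from residual shading/noise and would
  otherwise push flat regions around; real tissue interfaces differ by
  hundreds of HU. The cost is that pure-texture regions under-recover
  sub-threshold deformation; recovery is therefore assessed at structures
  with real contrast.

When the fixed image is a CBCT-derived target, the part outside the FOV is
composited from the (pre-aligned) moving image with an 8 mm feather so the
truncation boundary exerts no forces. The final field is multiplied by a
feathered focus indicator — exactly zero outside the focus, full inside an
8 mm transition. Divergence is declared when the smoothed-image MSE inside
the focus worsens by more than 5 % *and* by more than 1 % of the scene
variance; well-aligned images wobble below that from interpolation alone. A
fixed-point numerical inverse supplies the reported inverse-consistency
error. Contours are mapped with the same anti-aliased indicator rule as
phantom masks; an empty post-warp CTV logs a warning instead of failing
silently.

## corrCBCT

Inside the focus region the loop alternates, per iteration:

1. joint histogram of (deformed pCT HU × artifact-corrected gray), 128×128
   bins; tissue classes from the log-domain modes of the gray marginal
   (log because the air mode dwarfs the others), merged when no genuine
   valley separates them and discarded below 1 % of the voxel mass; class
   gray = windowed weighted mean, class HU = conditional mode with parabolic
   sub-bin refinement (a median is skewed by partial-volume tails, a raw bin
   center quantizes by half a bin width);
2. monotone piecewise-linear conversion through the class junctions
   (isotonic adjustment with a logged warning if mode noise breaks
   monotonicity; linear extrapolation with terminal slopes, clamped to
   [−1024, 3071] HU);
3. artifact map = normalized-convolution Gaussian low-pass (σ = 25 mm, the
   operational meaning of "low-frequency") of the difference between the
   converted CBCT and the deformed pCT over the full FOV, with voxels
   differing by more than 150 HU excluded (those are anatomy or registration
   misses, not shading) and the result feathered to zero at the mask edge;
4. the artifact estimate is folded back into a running *gray-space* shading
   field via the conversion's local slope, and the next iteration refits the
   conversion on deshaded gray values. This joint relaxation matters twice:
   a shading-contaminated histogram skews the junctions, and the low-pass
   recovers only part of the shading per pass near the region edge, so the
   iteration converges geometrically where a single pass stays biased.

DIR runs once, at the first iteration, against the artifact-pre-corrected
converted CBCT (re-registration each iteration is a config switch); the
conversion/artifact loop is what iterates. Convergence: mean |ΔHU| between
corrected images < 2 HU, at most 5 iterations. The composite output is the
corrected CBCT inside the FOV and the deformed pCT outside, blended over a
10 mm feather; beyond the band the extension equals the deformed pCT
exactly. The returned artifact map is the total accumulated correction, not
the last pass's residual.

The artifact-recovery figure of merit is measured where it is meaningful:
amplitude (regression slope of map against planted shading) over the FOV
interior retracted by two filter sigmas (50 mm), because the map is
*deliberately* feathered to zero at the mask edge; the mean-residual bound
applies over the whole 20 mm-retracted focus. The comparison baseline for
the corrected image is a nominal two-point rescale (image air mode →
−1000 HU, soft-tissue mode → 0 HU), i.e. what a clinic gets without
patient-specific histogram fitting.

## virtCT and gtCT

virtCT: base = pCT warped by the corrCBCT's deformation; inside the FOV a
voxel is overridden with the corrCBCT CT number when |Δρ| > 0.3 g/cm³ and
min(ρ) < 0.6 g/cm³, both densities computed from HU through the same
piecewise-linear calibration (air −1000 → 0.001, water 0 → 1.0, bone 1500 →
1.85 g/cm³, terminal slopes beyond, floored at zero) so Δρ is commensurate.
Ties are excluded: comparisons are strict, as printed. The override mask is
returned for audit, and with a high shoulder-streak amplitude it reproduces
the known failure mode — spurious low-density overrides between the
shoulders whose count decreases monotonically as the streak amplitude goes
to zero.

gtCT: the vfCT deformed to the same-day CBCT (conversion fitted against the
vfCT with the same histogram machinery; the setup shift is estimated first
so the artifact pre-correction is taken against aligned anatomy, otherwise
shift-correlated edge differences leak into the correction and bias the
registration equilibrium toward the unshifted position).

## Dose proxy and D99

The dose engine is an explicit simplification, not a transport code. HU →
relative stopping power by a piecewise-linear table (−1000 → 0.001, 0 → 1.0,
1500 → 1.55). Beams are parallel, axial (anterior + two posterior obliques
by default, weights equal), with the beam's-eye-view aperture = target
projection + 5 mm margin. The per-ray water-equivalent path length is the
cumulative SPR integral (midpoint rule; the volume form uses a cumulative
sum along the rotated beam axis). Each ray deposits a flat plateau up to its
planned distal range — the WEPL of the target's distal surface along *that
ray* plus a 5 mm water-equivalent margin, sized like clinical robustness
margins so voxelization-level range noise does not eat into coverage — and
a linear distal falloff over 5 mm WEPL. Per-ray distal conformance is what
makes the proxy mechanistically faithful for monitoring: upstream density
error shifts a ray's effective depth and pushes distal target voxels into
the falloff, which is the coverage-loss mechanism of interest; a single
global range per beam leaves shallow voxels with unbounded slack and hides
it. No lateral scatter, no nuclear halo, no robust evaluation.

Plans are normalized so D99 of the high-risk CTV on the planning anatomy is
100 %; evaluation doses on other image sets reuse the beams, per-ray ranges
and normalization, so ΔD99 isolates anatomy/setup change. D99 uses the
lower-quantile convention: the largest dose d with at least 99 % of the
structure's voxels receiving ≥ d — exactly the ⌈0.99·n⌉-th largest voxel
dose (100 voxels with one cold voxel → 100 %; with two → 0 %).

Because the proxy casts sharp geometric shadows (no scatter in-fill), a
structure corner that falls behind newly introduced bone loses dose
abruptly; D99, being a near-minimum metric, then drops by tens of points
where a clinical calculation would show a smaller, smeared loss. The
*ordering* (standard-risk loss exceeding high-risk loss under shoulder
shifts) is the physically meaningful output at desk scale, not the
magnitudes.

## Trigger rules and statistics

ΔD99 = plan − evaluation, in percentage points of plan-normalized relative
dose (positive = loss; the published thresholds do not distinguish percent
from percentage points, this implementation fixes the latter). Review is
triggered by ΔD99 > 3 pp on a high-risk CTV or > 5 pp on a standard-risk
CTV, strict inequalities per the printed ">"; boundary hits are logged. The
per-case review flag is the OR over structures. When a vfCT is present the
decision uses the gtCT evaluation; in CBCT-only operation it uses the
virtCT.

Cohort summaries report |ΔD99| of each surrogate against the gtCT (mean ±
SD per image kind and risk level, SD undefined at n = 1), the IQR and mean
of gtCT-based coverage loss, trigger counts, and paired two-sided Wilcoxon
signed-rank comparisons between surrogates. The Wilcoxon implementation
discards zeros (Wilcoxon's convention), midranks ties, enumerates the exact
null distribution of W⁺ by subset-sum for n ≤ 15 (p = 2·min(P≤, P≥), capped
at 1) and uses the tie-corrected normal approximation without continuity
correction above; significance is read at p < 0.05.

## Known limitations

* The dose proxy's shadows are sharp (see above); absolute ΔD99 magnitudes
  on phantoms are not calibrated against clinical dose engines.
* Demons under-recovers deformation in texture-only regions below the 20 HU
  force threshold; contours without intensity contrast (CTVs) move with the
  interpolated field of nearby interfaces.
* The shading estimator is unbiased only where the low-pass has support;
  within ~1 filter sigma of the FOV boundary residual shading of a few HU
  persists by construction (the map feathers to zero there).
* Grids are axis-aligned; oblique orientation matrices, 4D data and DICOM-RT
  structure I/O are out of scope (masks travel as a bit-packed label volume
  plus JSON sidecar).
* Cohort-level coverage losses are planted from published summary
  statistics, not generated through 200 full image pipelines; the image
  pipeline is exercised end to end on individual materialized cases.
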