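# Methods

## Slice acquisition model

A 2D multi-slice acquisition is modelled per slice: slice `i` of stack
`s` observes the non-negative HR volume `x` through a linear operator
`A_{s,i}` plus noise.  Each slice pixel value is a normalized weighted
sum of the HR voxels inside a truncation ellipsoid around the pixel's
(motion-corrected) world position; the weights are an oriented 3D
Gaussian approximating the single-shot slice profile, with covariance

    diag( (1.2 s1)² / (8 ln 2),  (1.2 s2)² / (8 ln 2),  s3² / (8 ln 2) )   [mm²]

in slice coordinates — i.e. the through-plane FWHM equals the slice
thickness `s3` and the in-plane FWHM is 1.2× the pixel spacing — rotated
into the reconstruction frame by the slice's effective orientation.
Numerical choices, made here because the slice-profile model alone does
not fix them:

* the Gaussian is evaluated at voxel centres (no integration over voxel
  volumes), the standard choice in the SRR literature;
* support is truncated at 3 standard deviations per principal axis;
* weights are renormalized to unit sum per pixel, so constant volumes
  are reproduced exactly and the operator stays well-scaled near the
  grid boundary.  Pixels whose support lies entirely outside the grid
  are zero and flagged.

The operator is assembled sparsely per slice (its exact transpose is
the adjoint); tests verify equality with a dense row-by-row matrix and
the inner-product adjoint identity to near machine precision.

## Reconstruction

The volume is the minimizer of
`Σ ½‖y − A x‖² + α/2 ‖∇x‖²  s.t.  x ≥ 0`, with forward finite
differences in voxel units (spacing-free) and a Neumann far boundary.
The solver is conjugate gradients on the normal equations with
projection onto the non-negative orthant between restarts (default 10
restarts × 20 inner iterations, tolerance 1e-6 on the relative normal
residual; the simulation studies use smaller budgets noted below).  In
the interior case the solution matches a dense normal-equations solve
to machine precision; with the constraint active the objective is
monotone under restarts because each restart starts from the projected
iterate.  Convexity makes the result initialization-independent to
solver tolerance.

Default regularization weights follow the studied protocols: α = 0.01
on 0.78 mm grids and 0.02 on 0.98 mm grids; an L-curve sweep utility
(`l_curve`) reports the data/regularity trade-off and its log-log
curvature but performs no automatic selection.

The reconstruction grid is isotropic at the in-plane spacing of the
first stack.  Its field of view is the union of the *pairwise
intersections* of the stacks' masked bounding boxes (one stack: its own
box), dilated by one voxel.  Super-resolution is determined only where
several orientations overlap, and this rule keeps a slice with grossly
wrong recorded geometry from inflating the grid with a region that only
it would populate — in such a region the solver would reproduce the bad
slice exactly and outlier scoring would become blind to it.

Initialization is a discrete Nadaraya-Watson kernel regression: every
voxel is the PSF-weighted mean of all slice pixels whose oriented
Gaussian weight reaches it (un-normalized weights, threshold 0).  The
iterative pipeline then deconvolves this estimate once on all slices
before the first registration round, since the framework alternates
volumetric reconstruction with slice registration and a
kernel-smoothed average is a systematically too-forgiving target for
similarity scoring.

## Rigid slice-to-volume registration

Registration maximizes masked NCC between the slice pixels and the
slice the forward model would acquire from the target volume at the
candidate pose.  The PSF projection is evaluated by convolving the
target once per stack orientation with the oriented slice-profile
Gaussian and sampling the result at the transformed pixel centres
(cubic B-spline interpolation, spline-prefiltered once) — the same
Gaussian weighting as the explicit operator, amortized over all
candidate poses.  Optimization is derivative-free (Powell) over 6
parameters — 3 Euler angles about the slice centre, 3 translations —
at full pixel resolution.  Earlier coarse-to-fine subsampling levels
are supported but off by default: at desk-scale fields of view the
coarse level degraded rotation estimates more than it saved time.

The search range (default ±4.5 mm, ±3.5°) is a motion prior: candidate
poses are penalized quadratically once their *total* deviation from the
anchor pose — the pose after volumetric stack alignment — exceeds the
range.  Anchoring the range (rather than re-centring it on each warm
start) prevents a slice with grossly wrong recorded geometry from being
dragged, over repeated warm-started registrations, to a spuriously
consistent pose; breath-hold slice motion beyond ~1.5× the simulated
amplitude is not plausible under the study conditions.  A registered
pose never scores worse than its initialization; a flat or empty
overlap returns the initialization flagged as failed.

Stack-level initialization (`align_stacks`) registers each stack as a
rigid body to a target volume, estimating the bulk *translation* only:
against a kernel-smoothed target the stack rotation is weakly
determined, and residual rotations are the job of the per-slice
correction.  Called directly without a target it uses the first stack
as the reference; the robust pipeline instead aligns every stack to
the all-stack scattered-data consensus, which stays usable even when
one stack contains a grossly corrupted slice.

## Outlier-robust pipeline

Per iteration `k`: re-register every slice to the current volume;
normalize the gauge (see below); score every slice as
`NCC(y_{s,i}, A_{s,i} x^{k−1})` inside its mask; keep the inlier set
`{i : score ≥ σ_k}` (ties kept); re-solve on the inliers.  Defaults
follow the studied protocol: 3 iterations with σ = 0.6 / 0.65 / 0.7
(the schedule's last value repeats if more iterations are requested).
Two additional policies:

* **Degrees-of-freedom schedule** (default 3, 6, 6): the first round
  optimizes translations only.  Against the still-blurry first volume
  the rotational landscape is shallow and full 6-DoF fits degraded the
  pose estimates; translations are well-conditioned from the start.
* **Minimum demonstrated support**: a slice whose recorded pose leaves
  fewer than 25 % of its masked pixels (or < 32 pixels) inside the
  reconstruction grid cannot demonstrate agreement with it and is
  treated as an outlier.  Retention requires evidence, not absence of
  counter-evidence.

Registrations are warm-started from the previous iteration's estimates.
All slices (inliers and outliers) are re-registered and re-scored every
iteration, so a slice can re-enter the inlier set.

**Gauge normalization.**  The reconstruction is defined only up to one
global rigid transform of its frame.  After each registration round the
mean slice correction (chordal-mean rotation, centroid-matching
translation) is factored out of all corrections, pinning the frame to
the average scanner frame.  Without this the frame drifts with the mean
of the motion draws, which degrades ground-truth comparisons and
inflates apparent per-slice motion errors.  `motion_errors` removes the
same common residual transform before reporting per-slice errors, and
`ground_truth_similarity(align=True)` removes it for volume scoring.

## Reference-guided pipeline

Three steps, non-iterative: (1) rigid S2V registration of every slice
to the HR reference (same machinery, reference as target); (2)
optionally, an in-plane free-form deformation of each slice towards its
reference cross-section — a 2D displacement field on a control lattice
(default spacing 5 pixels, cubic interpolation) maximizing LNCC with a
bending-energy penalty (weight 0.01), displacements confined to the
slice plane because the thick slice profile makes the through-plane
component unobservable; (3) one regularized solve on all slices (no
outlier rejection), with the rigid estimates carried by the operators
and the deformation applied to the pixel data.

## Similarity measures

NCC (Pearson), LNCC (mask-weighted windowed NCC, half-width 2), SSIM
(window 7, intensities rescaled to [0, 1] over the mask,
outside-mask voxels pinned to a constant so windows cannot leak
unmasked intensities), PSNR (peak = masked reference maximum), MI and
NMI (Studholme, 32-bin joint histogram).  All metrics evaluate strictly
inside the mask; all are symmetric except PSNR (reference is the second
argument).

## Phantom simulator

The generator emulates the studied acquisition protocol: 0.78 mm
in-plane pixels, 5 mm slice thickness (through-plane/in-plane ratio
≈ 6.4), stacks axial/coronal/sagittal, optional half-slice-shifted
duplicates, and four oblique orientations with slice-select unit
vectors toward the lower corners of [-1, 1]³ (fixed label order
(+,+,−), (−,+,−), (+,−,−), (−,−,−); in-plane axes by projecting the
world x-axis onto the slice plane).  The six studied source-data
configurations (2, 3, 6, 6, 7 and 10 series) are available by name.

The phantom itself (default 64³ voxels ≈ 50 mm cube) is a torso-like
superellipsoid containing nested ellipsoids, ~40 organ-scale blobs
(3–8 mm, ±0.15–0.3 intensity), fine smoothed texture (amplitude 0.18),
and thin bright tubes (1–2 voxel diameter) emulating ducts whose
clarity thick slices destroy; intensities lie in [0, 1] with background
exactly 0.  The organ-scale blobs matter: with only smooth nested
shapes, 5 mm-thick slabs of the volume are mutually similar enough that
a grossly misposed slice can still correlate ≥ 0.6 with the wrong slab,
and slice rotations are nearly unobservable.  Real abdominal anatomy is
strongly structured at the organ scale, and so is the phantom.

Per-slice motions are i.i.d. uniform draws within the given amplitudes
(rotation about the slice centre); no breathing-cycle correlation is
modelled, consistent with treating each breath-hold slice as
independently and approximately rigidly displaced.  Noise is additive
Gaussian.  Slice masks are the nominal-pose projections of the phantom
support (threshold 0.3), mimicking ROI masks drawn on the acquired
series and propagated between them; end-cap slices whose mask is below
25 % of the stack's median cross-section are dropped, as a protocol
planned on the anatomy would not process slivers of partial-volume
boundary.  Corruption for rejection studies is either a gross pose
error (15 mm translation plus 10–20° rotation — calibrated so the
corrupted slices' NCC to their recorded-pose projections stays below
0.6) or replacement of the masked pixels by a random permutation of
themselves; corruption targets content-bearing slices, since the pose
of a near-empty sliver is ill-determined even in principle.  Everything
is deterministic given seeds.

What passing simulated tests does *not* show: the phantom has no bias
fields, no Rician noise floor (Gaussian noise only; a Rician option
exists but is off), no through-plane deformation, no breathing
correlation, and far less fine-scale texture than real tissue.
Conclusions about absolute similarity values on patient data do not
transfer; ordering and mechanism-level conclusions are the point.

## Desk-scale study conditions

The simulation studies use the protocol's resolution geometry on small
fields of view so they run in minutes on one core; sizes are stated in
`srrkit.evaluation` (`MOTION_EXPERIMENT`, `REJECTION_EXPERIMENT`):

* **Motion recovery**: 64³ phantom (50 mm), six stacks (a+c+s+3obl),
  ±3 mm / ±3° per-slice motion, 1 % noise, five seeds.  The robust
  pipeline runs 4 iterations here (σ = 0.6, 0.65, 0.7, 0.7; DoF
  3, 6, 6, 6): a 50 mm field of view conditions slice rotations much
  more weakly than clinical-size anatomy (a rotation moves edge pixels
  by ~r·θ, and r is 4–8× smaller), so registration benefits from one
  extra round.  Solver budget 2 restarts × 15 CG iterations per solve.
* **Outlier rejection**: 48³ phantom, three stacks (a+c+s), two
  corrupted slices per repetition (alternating mispose / noise
  replacement), 20 repetitions; registration with 200 evaluations.
* **Configuration ordering**: 36³ phantom, robust pipeline at protocol
  defaults (3 iterations), configurations a+c, a+c+s, a+c+s+3obl,
  five seeds.

## Known limitations

* Rotations about in-plane axes remain the weakest-determined motion
  parameters; at desk scale their recovered errors (~0.5–1°) exceed
  translation errors (~0.3–0.5 mm ≈ half a voxel) by design of the
  physics, not of the implementation.
* The self-referential pipeline can absorb a *consistent* set of pose
  errors into a smoothly deformed reconstruction (a deformation gauge
  beyond the rigid one); more input orientations shrink this mode.
* The in-plane FFD step is a minimal implementation (L-BFGS on a
  control lattice); it recovers smooth few-pixel warps but is not a
  production deformable registration.
* Robust (Huber/M-estimator) and total-variation data terms are
  deliberately not implemented; `solve_srr` is the single Tikhonov
  solver and a `solver` flag is reserved for future variants.
* Stack-level initialization estimates translation only; datasets with
  large whole-stack rotations would need the per-slice search range
  widened or a full 6-DoF volumetric pre-registration.
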