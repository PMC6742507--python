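# srrkit

Super-resolution reconstruction (SRR) of isotropic 3D MR volumes from
multiple anisotropic 2D multi-slice acquisitions, with rigid
slice-to-volume (S2V) motion correction, outlier-robust slice rejection,
and a reference-guided (optionally in-plane deformable) variant.

Clinical 2D single-shot T2-weighted protocols acquire sharp in-plane
detail (≈0.78 mm pixels) but thick slices (≈5 mm), so small structures
such as bile ducts vanish between slices and reformats are unreadable.
When the same anatomy is imaged in several orientations — axial,
coronal, sagittal, half-slice-shifted duplicates, and oblique planes
tilted toward the lower corners of the unit cube — the stacks jointly
oversample the volume and an isotropic image can be estimated, provided
the per-slice motion between breath-holds is corrected and corrupted
slices are discarded.  `srrkit` implements that estimation problem
end-to-end, together with a digital-phantom simulator of the
acquisition protocol so every component can be validated against known
ground truth.

## Model

Each acquired slice `y_{s,i}` (stack `s`, slice `i`) is modelled as a
linear observation of the unknown HR volume `x ≥ 0`:

    y_{s,i} = A_{s,i} x + n_{s,i}

where `A_{s,i}` averages HR voxels under an oriented 3D Gaussian
point-spread function with covariance
`diag((1.2 s1)²/(8 ln 2), (1.2 s2)²/(8 ln 2), s3²/(8 ln 2))`
in slice coordinates (`s1, s2` in-plane spacings, `s3` slice
thickness), rotated by the slice's motion-corrected world orientation.
The volume is recovered by first-order-Tikhonov-regularized
non-negative least squares,

    x* = argmin_{x≥0}  Σ_s Σ_{i∈I_s} ½‖y_{s,i} − A_{s,i} x‖² + α/2 ‖∇x‖²,

solved matrix-free by projected conjugate gradients.  The
outlier-robust pipeline alternates volumetric reconstruction with rigid
S2V re-registration of every slice, keeping at iteration `k` only the
inlier set `I_{s,σ}^k = {i : NCC(y_{s,i}, A_{s,i} x^{k−1}) ≥ σ_k}`
(default schedule σ = 0.6, 0.65, 0.7).  The reference-guided variant
instead registers every slice rigidly (optionally plus an in-plane
B-spline deformation) to a separately acquired HR reference volume and
solves the same inverse problem once.

## Worked example

```python
import numpy as np
from srrkit import (make_phantom, build_plan, simulate_dataset,
                    reconstruct_outlier_robust, reconstruct_static,
                    ground_truth_similarity)
from srrkit.motion_correction import RegistrationSettings

phantom = make_phantom(dims=(64, 64, 64))          # 50 mm cube, 0.78 mm voxels
plan = build_plan("a+c+s+3obl")                    # six stacks, 5 mm slices
stacks, truth = simulate_dataset(phantom, plan, amplitude_t=3.0,
                                 amplitude_r=3.0, noise_sd=0.01, seed=1)

robust = reconstruct_outlier_robust(
    stacks, iterations=4, sigma_schedule=(0.6, 0.65, 0.7, 0.7),
    dof_schedule=(3, 6, 6, 6), alpha=0.01,
    settings=RegistrationSettings(seed=1, max_eval=150),
    solver_kwargs=dict(max_outer=2, inner_iter=15))
static = reconstruct_static(stacks, alpha=0.01,
                            solver_kwargs=dict(max_outer=2, inner_iter=15))

for name, res in [("robust", robust), ("static", static)]:
    ncc = ground_truth_similarity(res, phantom, align=True)["NCC"].value
    print(f"{name:7s} ground-truth NCC = {ncc:.3f}")
print("slices rejected per iteration:", robust.rejected_count)
```

prints

```
robust  ground-truth NCC = 0.979
static  ground-truth NCC = 0.370
slices rejected per iteration: [0, 0, 0, 0]
```

i.e. with ±3 mm / ±3° per-slice motion the uncorrected baseline
reconstruction barely correlates with the true anatomy, while the
motion-corrected, outlier-robust reconstruction is nearly exact; on
this motion-only dataset no slices are discarded.

A thin CLI mirrors the library: `srr simulate`, `srr reconstruct`,
`srr evaluate`, `srr grid` (see `srr --help`); volumes are NIfTI-1,
motion estimates and scores are CSV.

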