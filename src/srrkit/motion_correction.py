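"""Slice-to-volume motion correction and the reconstruction pipelines.

Three reconstruction strategies are provided:

* ``reconstruct_static`` — no motion correction; slices are used at
  their scanner-reported poses (baseline).
* ``reconstruct_reference_guided`` — non-iterative three-step scheme
  against a separately acquired HR reference volume: (1) rigid
  slice-to-volume registration of every slice to the reference,
  (2) optionally an in-plane B-spline free-form deformation of each
  slice against its reference cross-section (thick slices make the
  through-plane deformation component unobservable, so it is neglected),
  (3) a single regularized SRR solve using all slices.
* ``reconstruct_outlier_robust`` — iterative two-step scheme using only
  the acquired stacks: starting from a Nadaraya-Watson scattered-data
  initialization of the volumetrically aligned stacks, each iteration
  rigidly re-registers every slice to the current reconstruction,
  rejects slices whose similarity to their simulated counterpart falls
  below a per-iteration threshold sigma (default schedule 0.6 / 0.65 /
  0.7 over 3 iterations, NCC), and re-solves the SRR problem on the
  surviving inlier set.

Rigid slice-to-volume registration maximizes the (masked) similarity
between the slice pixels and the slice the forward model would acquire
from the target volume at the candidate pose.  The PSF projection is
evaluated by pre-blurring the target volume with the slice-profile
Gaussian of the stack orientation and sampling the blurred volume at
the transformed pixel centres — the same Gaussian weighting as the
explicit operator, amortized over all candidate poses.  Optimization is
derivative-free (Powell) over 6 parameters (3 Euler angles about the
slice centre, 3 translations) at two resolution levels, bounded by a
configurable search range chosen to bracket plausible breath-hold
motion.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage, optimize, signal

from .image_core import Image3D, RigidTransform, Slice, Stack, world_to_voxel
from .forward_model import (make_slice_operator, orient_covariance,
                            oriented_gaussian_kernel, psf_covariance)
from .reconstruction import (ReconGrid, SRRProblem, build_problem,
                             default_grid, scattered_init, solve_srr)
from . import similarity as sim

__all__ = ["RegistrationSettings", "RegistrationResult", "SRRResult",
           "register_slice_rigid", "align_stacks", "select_inliers",
           "reconstruct_static", "reconstruct_outlier_robust",
           "reconstruct_reference_guided", "deform_slice_inplane",
           "prepare_registration_target",
           "DeformationResult"]


@dataclass
class RegistrationSettings:
    metric: str = "NCC"
    max_eval: int = 200           # metric evaluations per optimizer level
    levels: int = 1               # pixel subsampling levels (1 = full res;
                                  # coarse levels trade precision for speed)
    search_range_mm: float = 4.5  # brackets the breath-hold motion prior
    search_range_deg: float = 3.5  # plus residual stack-alignment error
    restrict_to_mask: bool = True
    psf_aware: bool = True        # evaluate through the slice-profile blur
    n_starts: int = 1             # extra seeded multi-starts beyond init
    jitter_mm: float = 2.0
    jitter_deg: float = 2.0
    interp_order: int = 3         # target sampling (cubic localizes best)
    seed: int = 0
    min_valid_pixels: int = 16


@dataclass
class RegistrationResult:
    transform: RigidTransform
    metric_value: float
    success: bool


@dataclass
class SRRResult:
    """Reconstruction output: volume, motion estimates and bookkeeping."""

    volume: Image3D
    corrections: dict               # (stack_id, slice_index) -> RigidTransform
    inlier_history: list            # per iteration: {stack_id: set(indices)}
    params: dict
    rejected_count: list = field(default_factory=list)
    slice_scores: dict = field(default_factory=dict)
    failed_registrations: list = field(default_factory=list)


def _blur_volume_for_orientation(volume: Image3D, slc: Slice) -> np.ndarray:
    """Volume convolved with the slice-profile Gaussian of this slice's
    current orientation (the registration fast path)."""
    cov_w = orient_covariance(psf_covariance(*slc.spacing3),
                              slc.effective_pose().rotation)
    kernel = oriented_gaussian_kernel(cov_w, volume)
    return signal.fftconvolve(volume.data, kernel, mode="same")


def prepare_registration_target(volume: Image3D, slc: Slice,
                                settings: "RegistrationSettings") -> np.ndarray:
    """Sampling-ready registration target for one stack orientation:
    the (optionally PSF-blurred) volume, spline-prefiltered once so that
    every metric evaluation can interpolate without refiltering."""
    data = (_blur_volume_for_orientation(volume, slc)
            if settings.psf_aware else volume.data)
    if settings.interp_order > 1:
        data = ndimage.spline_filter(data, order=settings.interp_order)
    return data


def _sample_metric(slc: Slice, volume: Image3D, blurred: np.ndarray,
                   correction: RigidTransform, settings: RegistrationSettings,
                   step: int = 1):
    """Masked similarity between slice pixels and the blurred volume
    sampled at the candidate pose.  Returns (value, n_valid)."""
    n1, n2 = slc.pixels.shape
    if settings.restrict_to_mask and slc.mask is not None:
        sub = slc.mask[::step, ::step]
    else:
        sub = np.ones(slc.pixels[::step, ::step].shape, dtype=bool)
    ii, jj = np.nonzero(sub)
    idx = np.stack([ii * step, jj * step, np.zeros(ii.size)], axis=1).astype(float)
    eff = correction.compose(slc.pose)
    world = eff.apply(idx * slc.spacing3)
    vox = world_to_voxel(volume, world)
    vals = ndimage.map_coordinates(blurred, vox.T, order=settings.interp_order,
                                   mode="constant", cval=0.0, prefilter=False)
    pix = slc.pixels[::step, ::step][sub]
    valid = np.all((vox >= 0) & (vox <= np.array(volume.shape) - 1), axis=1)
    n_valid = int(valid.sum())
    if n_valid < settings.min_valid_pixels:
        return -np.inf, n_valid
    a, b = pix[valid], vals[valid]
    if np.ptp(a) < 1e-12 or np.ptp(b) < 1e-12:
        return 0.0, n_valid
    if settings.metric.upper() == "NCC":
        return sim.ncc(a, b, on_zero_variance="zero"), n_valid
    return sim.evaluate_similarity(a, b, metric=settings.metric).value, n_valid


def register_slice_rigid(slc: Slice, volume: Image3D,
                         init: RigidTransform | None = None,
                         settings: RegistrationSettings | None = None,
                         blurred: np.ndarray | None = None,
                         dof: int = 6,
                         anchor: RigidTransform | None = None
                         ) -> RegistrationResult:
    """Rigid slice-to-volume registration.

    Maximizes the configured metric between the slice and its simulated
    counterpart from ``volume``; the returned pose never scores worse
    than ``init``.  ``dof=3`` optimizes translation only (rotations are
    weakly conditioned against blurry targets, so the robust pipeline
    estimates the dominant translational motion first).

    The search range acts as a motion prior: candidate poses are
    penalized once they deviate from ``anchor`` (by default the initial
    pose) by more than the configured range, so a slice whose recorded
    geometry is grossly wrong cannot be dragged to a spuriously
    consistent pose across repeated warm-started registrations.  An
    empty or flat overlap returns ``init`` flagged as failed.
    """
    settings = settings or RegistrationSettings()
    init = init or slc.correction
    if blurred is None:
        blurred = prepare_registration_target(volume, slc, settings)
    center = replace(slc, correction=RigidTransform.identity()).center_world()
    p_init = init.params(center=center)
    p_anchor = (anchor.params(center=center) if anchor is not None
                else p_init.copy())

    free = slice(3, 6) if dof == 3 else slice(0, 6)
    ranges = np.array([settings.search_range_deg] * 3
                      + [settings.search_range_mm] * 3)

    def objective(sub, step):
        params = p_init.copy()
        params[free] = sub
        # soft search-range constraint: smooth quadratic penalty keeps
        # Powell's line searches well-posed everywhere
        excess = np.maximum(np.abs(params - p_anchor) - ranges, 0.0)
        c = RigidTransform.from_params(params, center=center)
        v, _ = _sample_metric(slc, volume, blurred, c, settings, step=step)
        return -v + float(excess @ excess)

    init_val, n_valid = _sample_metric(slc, volume, blurred, init, settings)
    if not np.isfinite(init_val) and n_valid < settings.min_valid_pixels:
        return RegistrationResult(init, -np.inf, False)

    rng = np.random.default_rng(settings.seed + 13 * slc.slice_index
                                + 1009 * slc.stack_id)
    starts = [p_init]
    for _ in range(max(settings.n_starts - 1, 0)):
        jit = np.concatenate([
            rng.uniform(-settings.jitter_deg, settings.jitter_deg, 3),
            rng.uniform(-settings.jitter_mm, settings.jitter_mm, 3)])
        starts.append(p_init + jit)

    lo, hi = p_anchor - ranges, p_anchor + ranges

    best_p, best_v = p_init, init_val
    steps = [2 ** (settings.levels - 1 - l) for l in range(settings.levels)]
    for p0 in starts:
        p = np.clip(p0, lo, hi)[free]
        for step in steps:
            res = optimize.minimize(
                objective, p, args=(step,), method="Powell",
                options={"maxfev": settings.max_eval,
                         "xtol": 1e-3, "ftol": 1e-6})
            p = res.x
        full = p_init.copy()
        full[free] = p
        v, _ = _sample_metric(
            slc, volume, blurred,
            RigidTransform.from_params(full, center=center), settings)
        if v > best_v:
            best_p, best_v = full, v
    transform = RigidTransform.from_params(best_p, center=center)
    # flat metric landscape (e.g. featureless overlap) counts as failure
    success = np.isfinite(best_v) and best_v > 0.0
    if best_v < init_val:
        transform, best_v = init, init_val
    return RegistrationResult(transform, float(best_v), bool(success))


def align_stacks(stacks: list, target: Image3D | None = None,
                 settings: RegistrationSettings | None = None,
                 grid_spacing: float | None = None,
                 dof: int = 3) -> list:
    """Volumetric (stack-level) initialization.

    Each stack is registered as a rigid body to ``target`` (or, when no
    target is given, to a scattered-data volume built from the first
    stack, which then keeps the identity).  By default only the bulk
    translation is estimated (``dof=3``): against a kernel-smoothed
    single-stack target the stack-level rotation is weakly determined,
    and residual rotations are the job of the per-slice correction.
    The resulting transform is installed as the initial correction of
    every slice in the stack.
    """
    settings = settings or RegistrationSettings()
    transforms = []
    first_is_reference = target is None
    if target is None:
        g = default_grid([stacks[0]], spacing=grid_spacing)
        target = scattered_init([stacks[0]], g)
    for si, st in enumerate(stacks):
        if first_is_reference and si == 0:
            transforms.append(RigidTransform.identity())
            continue
        blurred = prepare_registration_target(target, st.slices[0], settings)
        mid = st.slices[len(st.slices) // 2]
        center = mid.center_world()
        ranges = np.array([settings.search_range_deg] * 3
                          + [settings.search_range_mm] * 3)

        free = slice(3, 6) if dof == 3 else slice(0, 6)

        def objective(sub):
            params = np.zeros(6)
            params[free] = sub
            c = RigidTransform.from_params(params, center=center)
            excess = np.maximum(np.abs(params) - ranges, 0.0)
            vals = []
            for s in st.slices:
                v, _ = _sample_metric(s, target, blurred, c, settings)
                if np.isfinite(v):
                    vals.append(v)
            if not vals:
                return np.inf
            return -float(np.mean(vals)) + float(excess @ excess)

        p0 = np.zeros(6)[free]
        res = optimize.minimize(objective, p0, method="Powell",
                                options={"maxfev": max(settings.max_eval, 300),
                                         "xtol": 1e-3, "ftol": 1e-8})
        if not np.isfinite(res.fun) or res.fun >= objective(p0):
            warnings.warn(f"align_stacks: registration failed for stack {si}, "
                          "keeping identity")
            transforms.append(RigidTransform.identity())
            continue
        full = np.zeros(6)
        full[free] = res.x
        transforms.append(RigidTransform.from_params(full, center=center))
    for st, T in zip(stacks, transforms):
        for s in st.slices:
            s.correction = T
    return transforms


def select_inliers(stacks: list, current_recon: Image3D, sigma: float,
                   metric: str = "NCC", truncation: float = 3.0,
                   operators: dict | None = None):
    """Slice-index sets of slices whose similarity to their simulated
    counterpart from the current reconstruction is >= sigma (ties kept).

    Scores are computed inside the slice mask, excluding pixels with no
    PSF support in the grid.  ``operators`` may carry pre-assembled
    slice operators keyed by (stack_id, slice_index).  Returns
    ``(sets, scores)`` keyed by stack.
    """
    sets, scores = {}, {}
    for st in stacks:
        keep = set()
        for s in st.slices:
            op = None
            if operators is not None:
                op = operators.get((st.stack_id, s.slice_index))
            if op is None:
                op = make_slice_operator(s, current_recon, truncation)
            proj = op.apply(current_recon.data)
            m = s.mask if s.mask is not None else np.ones_like(s.pixels, bool)
            n_mask = max(int(m.sum()), 1)
            m = m & ~op.out_of_support
            # retention requires demonstrated agreement: a slice whose
            # recorded pose leaves most of its ROI outside the grid
            # cannot demonstrate it and is treated as an outlier
            if m.sum() < max(32, 0.25 * n_mask):
                score = -1.0
            else:
                try:
                    score = sim.evaluate_similarity(s.pixels, proj, m,
                                                    metric=metric).value
                except ValueError:
                    score = -1.0
            scores[(st.stack_id, s.slice_index)] = score
            if score >= sigma:
                keep.add(s.slice_index)
        sets[st.stack_id] = keep
    return sets, scores


def _remove_mean_correction(stacks: list) -> RigidTransform:
    """Normalize the gauge: the reconstruction is only defined up to a
    global rigid transform, so after each registration round the mean
    slice correction (chordal-mean rotation, mean displacement of the
    slice centres) is factored out, pinning the reconstruction frame to
    the average scanner frame."""
    slices = [s for st in stacks for s in st.slices]
    centers = np.array([replace(s, correction=RigidTransform.identity())
                        .center_world() for s in slices])
    c = centers.mean(axis=0)
    M = np.mean([s.correction.rotation for s in slices], axis=0)
    U, _, Vt = np.linalg.svd(M)
    G_R = U @ np.diag([1.0, 1.0, np.linalg.det(U @ Vt)]) @ Vt
    moved = np.mean([s.correction.apply(c) for s in slices], axis=0)
    G = RigidTransform(G_R.T, c - G_R.T @ moved)
    for s in slices:
        s.correction = G.compose(s.correction)
    return G


def _result_corrections(stacks: list) -> dict:
    return {(st.stack_id, s.slice_index): s.correction
            for st in stacks for s in st.slices}


def _all_indices(stacks: list) -> dict:
    return {st.stack_id: {s.slice_index for s in st.slices} for st in stacks}


def _problem_inliers(problem: SRRProblem, sets: dict) -> list:
    return [i for i, s in enumerate(problem.slices)
            if s.slice_index in sets.get(s.stack_id, set())]


def reconstruct_static(stacks: list, alpha: float = 0.01,
                       grid: ReconGrid | None = None,
                       grid_spacing: float | None = None,
                       solver_kwargs: dict | None = None) -> SRRResult:
    """Baseline SRR at the scanner-reported poses, no motion correction."""
    stacks = copy.deepcopy(stacks)
    for st in stacks:
        for s in st.slices:
            s.correction = RigidTransform.identity()
    grid = grid or default_grid(stacks, spacing=grid_spacing)
    problem = build_problem(stacks, grid, alpha)
    x = solve_srr(problem, **(solver_kwargs or {}))
    return SRRResult(volume=x, corrections=_result_corrections(stacks),
                     inlier_history=[_all_indices(stacks)],
                     params={"method": "static", "alpha": alpha},
                     rejected_count=[0])


def reconstruct_outlier_robust(stacks: list, iterations: int = 3,
                               sigma_schedule=(0.6, 0.65, 0.7),
                               alpha: float = 0.01,
                               grid: ReconGrid | None = None,
                               grid_spacing: float | None = None,
                               settings: RegistrationSettings | None = None,
                               metric: str = "NCC",
                               solver_kwargs: dict | None = None,
                               stack_align: bool = True,
                               dof_schedule=(3, 6, 6)) -> SRRResult:
    """Iterative two-step rigid motion correction with outlier rejection.

    Pipeline: volumetric stack alignment -> scattered-data initial
    volume -> ``iterations`` rounds of {rigid S2V re-registration of
    every slice to the current volume (warm-started from the previous
    estimates); inlier selection at sigma_k; regularized SRR solve on
    the inliers}.
    """
    if len(stacks) < 3:
        warnings.warn("outlier-robust SRR is designed for stacks in at "
                      "least three orientations; results may be unstable")
    settings = settings or RegistrationSettings()
    dofs = list(dof_schedule)
    stacks = copy.deepcopy(stacks)
    if stack_align:
        # align every stack to the all-stack scattered-data consensus:
        # robust to a corrupted slice in any single stack, unlike using
        # the first stack alone as the reference
        g0 = default_grid(stacks, spacing=grid_spacing)
        align_stacks(stacks, target=scattered_init(stacks, g0),
                     settings=settings, grid_spacing=grid_spacing)
    anchors = {(st.stack_id, s.slice_index): s.correction
               for st in stacks for s in st.slices}
    grid = grid or default_grid(stacks, spacing=grid_spacing)
    x = scattered_init(stacks, grid)
    if iterations > 0:
        # the framework alternates volumetric reconstruction and S2V
        # registration: deconvolve the scattered-data estimate once on
        # all slices so the first registration and inlier-selection
        # round sees a sharp volume, not the kernel-smoothed initializer
        problem0 = build_problem(stacks, grid, alpha)
        x = solve_srr(problem0, x0=x, **(solver_kwargs or {}))
    sched = list(sigma_schedule)
    inlier_history, rejected, failed = [], [], []
    total = sum(len(st) for st in stacks)
    scores = {}
    # iterations == 0 degenerates to a single selection + cold solve,
    # which with sigma = -1 is exactly the static baseline
    for k in range(max(iterations, 1)):
        sigma = sched[min(k, len(sched) - 1)]
        if iterations > 0:
            for st in stacks:
                blurred = prepare_registration_target(x, st.slices[0], settings)
                for s in st.slices:
                    r = register_slice_rigid(
                        s, x, init=s.correction, settings=settings,
                        blurred=blurred, dof=dofs[min(k, len(dofs) - 1)],
                        anchor=anchors[(st.stack_id, s.slice_index)])
                    s.correction = r.transform
                    if not r.success:
                        failed.append((k, st.stack_id, s.slice_index))
            G = _remove_mean_correction(stacks)
            anchors = {key: G.compose(a) for key, a in anchors.items()}
        problem = build_problem(stacks, grid, alpha)
        op_map = {(s.stack_id, s.slice_index): op
                  for s, op in zip(problem.slices, problem.operators)}
        sets, scores = select_inliers(stacks, x, sigma, metric=metric,
                                      operators=op_map)
        n_in = sum(len(v) for v in sets.values())
        if n_in == 0:
            detail = "; ".join(f"({sid},{idx}): {v:.3f}"
                               for (sid, idx), v in sorted(scores.items()))
            raise RuntimeError("all slices rejected at iteration "
                               f"{k + 1} (sigma={sigma}); scores: {detail}")
        inlier_history.append(sets)
        rejected.append(total - n_in)
        problem.inliers = _problem_inliers(problem, sets)
        x = solve_srr(problem, x0=x if iterations > 0 else None,
                      **(solver_kwargs or {}))
    return SRRResult(volume=x, corrections=_result_corrections(stacks),
                     inlier_history=inlier_history,
                     params={"method": "outlier_robust", "alpha": alpha,
                             "sigma_schedule": sched, "iterations": iterations,
                             "metric": metric},
                     rejected_count=rejected, slice_scores=scores,
                     failed_registrations=failed)


@dataclass
class DeformationResult:
    slice: Slice
    displacement: np.ndarray    # (2, n1, n2) in pixels
    success: bool


def _bspline_field(control: np.ndarray, shape: tuple, spacing: float):
    """Dense displacement from a control lattice by cubic interpolation."""
    n1, n2 = shape
    ii, jj = np.meshgrid(np.arange(n1) / spacing, np.arange(n2) / spacing,
                         indexing="ij")
    return np.stack([
        ndimage.map_coordinates(control[a], [ii, jj], order=3, mode="nearest")
        for a in range(2)])


def deform_slice_inplane(slc: Slice, reference_section: np.ndarray,
                         grid_spacing_px: int = 5, metric: str = "LNCC",
                         bending_weight: float = 0.01, lncc_radius: int = 2,
                         max_iter: int = 30) -> DeformationResult:
    """In-plane free-form deformation of a slice towards its reference
    cross-section.

    A 2D displacement field parameterized on a control lattice (spacing
    ``grid_spacing_px`` pixels, cubic interpolation) is optimized to
    maximize LNCC between the warped slice and the reference section,
    with a bending-energy penalty.  Displacements are confined to the
    slice plane.  On failure the undeformed slice is returned flagged.
    """
    n1, n2 = slc.pixels.shape
    nc1 = int(np.ceil((n1 - 1) / grid_spacing_px)) + 1
    nc2 = int(np.ceil((n2 - 1) / grid_spacing_px)) + 1
    shape_c = (2, nc1, nc2)
    m = slc.mask if slc.mask is not None else np.ones((n1, n2), bool)
    ii, jj = np.meshgrid(np.arange(n1, dtype=float),
                         np.arange(n2, dtype=float), indexing="ij")

    ref = np.asarray(reference_section, dtype=float)
    if ref.shape != (n1, n2):
        raise ValueError("reference section shape mismatch")

    def warp(u):
        return ndimage.map_coordinates(slc.pixels, [ii + u[0], jj + u[1]],
                                       order=1, mode="nearest")

    def bending(c):
        e = 0.0
        for a in range(2):
            for ax in (0, 1):
                d2 = np.diff(c[a], n=2, axis=ax)
                e += float(np.mean(d2 ** 2)) if d2.size else 0.0
        return e

    def objective(theta):
        c = theta.reshape(shape_c)
        u = _bspline_field(c, (n1, n2), grid_spacing_px)
        try:
            s = sim.lncc(warp(u), ref, m, radius=lncc_radius)
        except ValueError:
            return 1e3
        return -s + bending_weight * bending(c)

    theta0 = np.zeros(int(np.prod(shape_c)))
    try:
        f0 = objective(theta0)
        if f0 >= 1e3:
            return DeformationResult(replace(slc), np.zeros((2, n1, n2)), False)
        res = optimize.minimize(objective, theta0, method="L-BFGS-B",
                                options={"maxiter": max_iter, "eps": 0.05})
        theta = res.x if res.fun < f0 else theta0
    except Exception:
        return DeformationResult(replace(slc), np.zeros((2, n1, n2)), False)
    u = _bspline_field(theta.reshape(shape_c), (n1, n2), grid_spacing_px)
    return DeformationResult(replace(slc, pixels=warp(u)), u, True)


def reconstruct_reference_guided(stacks: list, reference: Image3D,
                                 deformable: bool = False, alpha: float = 0.01,
                                 grid: ReconGrid | None = None,
                                 grid_spacing: float | None = None,
                                 settings: RegistrationSettings | None = None,
                                 solver_kwargs: dict | None = None,
                                 deform_kwargs: dict | None = None) -> SRRResult:
    """Reference-guided three-step reconstruction (rigid, optionally with
    in-plane deformation), using all slices without outlier rejection."""
    settings = settings or RegistrationSettings()
    stacks = copy.deepcopy(stacks)
    failed, scores = [], {}
    for st in stacks:
        blurred = prepare_registration_target(reference, st.slices[0], settings)
        for s in st.slices:
            r = register_slice_rigid(s, reference, init=s.correction,
                                     settings=settings, blurred=blurred)
            s.correction = r.transform
            scores[(st.stack_id, s.slice_index)] = r.metric_value
            if not r.success:
                failed.append((0, st.stack_id, s.slice_index))
    if deformable:
        for st in stacks:
            for j, s in enumerate(st.slices):
                vox = world_to_voxel(reference, s.pixel_centers_world())
                section = ndimage.map_coordinates(
                    reference.data, vox.T, order=1, mode="constant",
                    cval=0.0).reshape(s.pixels.shape)
                d = deform_slice_inplane(s, section, **(deform_kwargs or {}))
                if d.success:
                    st.slices[j] = d.slice
                else:
                    failed.append((1, st.stack_id, s.slice_index))
    grid = grid or default_grid(stacks, spacing=grid_spacing)
    problem = build_problem(stacks, grid, alpha)
    x = solve_srr(problem, **(solver_kwargs or {}))
    return SRRResult(volume=x, corrections=_result_corrections(stacks),
                     inlier_history=[_all_indices(stacks)],
                     params={"method": "reference_guided", "alpha": alpha,
                             "deformable": deformable},
                     rejected_count=[0], slice_scores=scores,
                     failed_registrations=failed)
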