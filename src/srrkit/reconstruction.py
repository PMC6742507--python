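"""Tikhonov-regularized, non-negative super-resolution reconstruction.

The HR volume x on an isotropic grid is estimated from the posed LR
slices {(y_si, A_si)} by minimizing

    sum_s sum_{i in I_s}  1/2 ||y_si - A_si x||^2  +  alpha/2 ||grad x||^2
    subject to x >= 0,

a convex least-squares problem.  The gradient penalty uses forward
finite differences in voxel units (first-order Tikhonov).  The solver is
conjugate gradients on the normal equations of the stacked operator
[A; sqrt(alpha) * grad], with the non-negativity constraint enforced by
projection between CG restarts (default 10 outer restarts x 20 inner
iterations).  In the interior (strictly positive solution) case this
reduces to plain CG and agrees with a dense normal-equations solve.

Restricting the slice set to the inliers of an outlier-rejection
iteration gives the robust variant; with every slice marked inlier the
two problems coincide.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .image_core import Image3D
from .forward_model import make_slice_operator

__all__ = ["ReconGrid", "SRRProblem", "spatial_gradient", "gradient_adjoint",
           "scattered_init", "solve_srr", "build_problem", "default_grid",
           "objective", "l_curve"]


@dataclass
class ReconGrid:
    """Isotropic reconstruction lattice (geometry only, no data)."""

    spacing: float
    origin: np.ndarray
    direction: np.ndarray
    dims: tuple

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.direction = np.asarray(self.direction, dtype=float).reshape(3, 3)
        self.dims = tuple(int(d) for d in self.dims)
        if self.spacing <= 0:
            raise ValueError("grid spacing must be positive")

    def to_image(self, data=None) -> Image3D:
        arr = np.zeros(self.dims) if data is None else np.asarray(data, float)
        return Image3D(arr.reshape(self.dims), np.full(3, self.spacing),
                       self.origin, self.direction)

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.dims))


def _stack_bbox(st) -> tuple:
    """World-space axis-aligned bounding box of a stack's masked data."""
    pts = []
    for s in st.slices:
        n1, n2 = s.pixels.shape
        if s.mask is not None and s.mask.any():
            ii, jj = np.nonzero(s.mask)
            lo2 = [ii.min(), jj.min()]
            hi2 = [ii.max(), jj.max()]
        else:
            lo2, hi2 = [0, 0], [n1 - 1, n2 - 1]
        corners = np.array([[lo2[0], lo2[1], 0], [hi2[0], lo2[1], 0],
                            [lo2[0], hi2[1], 0], [hi2[0], hi2[1], 0]], float)
        corners = corners * s.spacing3
        half = np.array([0.0, 0.0, s.thickness / 2.0])
        pts.append(s.effective_pose().apply(corners - half))
        pts.append(s.effective_pose().apply(corners + half))
    P = np.concatenate(pts, axis=0)
    return P.min(axis=0), P.max(axis=0)


def default_grid(stacks: list, spacing: float | None = None,
                 margin: int = 1) -> ReconGrid:
    """Axis-aligned isotropic reconstruction grid.

    Spacing defaults to the in-plane resolution of the first stack, the
    resolution at which in-plane detail is actually sampled.  The field
    of view is the union of the pairwise intersections of the stacks'
    masked footprints (dilated by ``margin`` voxels): super-resolution
    is only determined where several orientations overlap, and this
    rule keeps a single slice with grossly wrong recorded geometry from
    inflating the grid with a region only it would populate.  With a
    single stack its own footprint is used.
    """
    if spacing is None:
        spacing = float(stacks[0].in_plane_spacing[0])
    boxes = [_stack_bbox(st) for st in stacks]
    if len(boxes) == 1:
        lo, hi = boxes[0]
    else:
        los, his = [], []
        for i in range(len(boxes)):
            for j in range(i + 1, len(boxes)):
                l = np.maximum(boxes[i][0], boxes[j][0])
                h = np.minimum(boxes[i][1], boxes[j][1])
                if np.all(h > l):
                    los.append(l)
                    his.append(h)
        if los:
            lo = np.min(los, axis=0)
            hi = np.max(his, axis=0)
        else:  # disjoint stacks: fall back to the union
            lo = np.min([b[0] for b in boxes], axis=0)
            hi = np.max([b[1] for b in boxes], axis=0)
    lo = lo - margin * spacing
    hi = hi + margin * spacing
    dims = np.maximum(np.ceil((hi - lo) / spacing).astype(int) + 1, 1)
    return ReconGrid(spacing, lo, np.eye(3), tuple(dims))


def spatial_gradient(x: np.ndarray) -> list:
    """Forward finite differences per axis, zero at the far boundary."""
    x = np.asarray(x, dtype=float)
    out = []
    for ax in range(x.ndim):
        g = np.zeros_like(x)
        sl_hi = [slice(None)] * x.ndim
        sl_lo = [slice(None)] * x.ndim
        sl_hi[ax] = slice(1, None)
        sl_lo[ax] = slice(0, -1)
        g[tuple(sl_lo)] = x[tuple(sl_hi)] - x[tuple(sl_lo)]
        out.append(g)
    return out


def gradient_adjoint(gs: list) -> np.ndarray:
    """Adjoint of :func:`spatial_gradient` (negative divergence with the
    matching boundary treatment): <grad x, g> = <x, adjoint(g)>."""
    out = np.zeros_like(np.asarray(gs[0], dtype=float))
    for ax, g in enumerate(gs):
        g = np.asarray(g, dtype=float)
        d = np.zeros_like(g)
        sl_hi = [slice(None)] * g.ndim
        sl_lo = [slice(None)] * g.ndim
        sl_hi[ax] = slice(1, None)
        sl_lo[ax] = slice(0, -1)
        d[tuple(sl_lo)] -= g[tuple(sl_lo)]
        d[tuple(sl_hi)] += g[tuple(sl_lo)]
        out += d
    return out


@dataclass
class SRRProblem:
    """Slices, their operators, the inlier sets and the grid."""

    slices: list            # list of Slice
    operators: list         # matching list of SliceOperator
    grid: ReconGrid
    alpha: float = 0.01
    inliers: list | None = None   # indices into `slices`; None = all

    def __post_init__(self):
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if len(self.slices) != len(self.operators):
            raise ValueError("slices and operators must align")
        if self.inliers is not None:
            bad = [i for i in self.inliers if not 0 <= i < len(self.slices)]
            if bad:
                raise ValueError(f"inlier indices out of range: {bad}")

    def active(self):
        idx = range(len(self.slices)) if self.inliers is None else self.inliers
        return [(self.slices[i], self.operators[i]) for i in idx]

    def stacked(self):
        """All active operators vertically stacked into one sparse matrix
        (and its transpose), with the matching stacked data vector.
        Cached until the inlier set changes."""
        key = tuple(sorted(self.inliers)) if self.inliers is not None else None
        cached = getattr(self, "_stacked_cache", None)
        if cached is not None and cached[0] == key:
            return cached[1]
        from scipy import sparse as _sp
        pairs = self.active()
        A = _sp.vstack([op.weights for _, op in pairs]).tocsr()
        AT = A.T.tocsr()
        y = np.concatenate([s.pixels.ravel() for s, _ in pairs])
        self._stacked_cache = (key, (A, AT, y))
        return A, AT, y


def build_problem(stacks: list, grid: ReconGrid, alpha: float = 0.01,
                  truncation: float = 3.0) -> SRRProblem:
    """Assemble operators for every slice at its current correction."""
    gimg = grid.to_image()
    slices, ops = [], []
    for st in stacks:
        for s in st.slices:
            slices.append(s)
            ops.append(make_slice_operator(s, gimg, truncation))
    return SRRProblem(slices, ops, grid, alpha)


def scattered_init(stacks: list, grid: ReconGrid, truncation: float = 3.0,
                   weight_threshold: float = 0.0) -> Image3D:
    """Nadaraya-Watson kernel regression of all slice pixels onto the HR
    lattice: each voxel is the PSF-weight-weighted mean of every slice
    pixel whose oriented Gaussian weight at that voxel exceeds the
    threshold.  Voxels receiving no weight are set to 0."""
    gimg = grid.to_image()
    num = np.zeros(grid.n_voxels)
    den = np.zeros(grid.n_voxels)
    for st in stacks:
        for s in st.slices:
            op = make_slice_operator(s, gimg, truncation)
            raw = op.raw_weights.tocoo()
            keep = raw.data > weight_threshold
            vals = s.pixels.ravel()[raw.row[keep]]
            np.add.at(num, raw.col[keep], raw.data[keep] * vals)
            np.add.at(den, raw.col[keep], raw.data[keep])
    with np.errstate(invalid="ignore", divide="ignore"):
        x = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    out = gimg.like(x.reshape(grid.dims))
    out.mask = (den > 0).reshape(grid.dims)
    return out


def _normal_apply(problem: SRRProblem, x: np.ndarray) -> np.ndarray:
    """(A^T A + alpha grad^T grad) x, x given and returned as 3D."""
    A, AT, _ = problem.stacked()
    out = (AT @ (A @ x.ravel())).reshape(problem.grid.dims)
    if problem.alpha > 0:
        out += problem.alpha * gradient_adjoint(spatial_gradient(x))
    return out


def _rhs(problem: SRRProblem) -> np.ndarray:
    A, AT, y = problem.stacked()
    return (AT @ y).reshape(problem.grid.dims)


def objective(problem: SRRProblem, x: np.ndarray) -> float:
    """sum 1/2 ||y - A x||^2 + alpha/2 ||grad x||^2 over active slices."""
    x = np.asarray(x, dtype=float).reshape(problem.grid.dims)
    A, _, y = problem.stacked()
    r = y - A @ x.ravel()
    val = 0.5 * float(r @ r)
    if problem.alpha > 0:
        gs = spatial_gradient(x)
        val += 0.5 * problem.alpha * float(sum(np.sum(g * g) for g in gs))
    return val


def _cg(problem, x, b, n_iter, tol):
    r = b - _normal_apply(problem, x)
    p = r.copy()
    rs = float(np.sum(r * r))
    b_norm = float(np.sqrt(np.sum(b * b))) + 1e-30
    for _ in range(n_iter):
        if np.sqrt(rs) / b_norm < tol:
            break
        Ap = _normal_apply(problem, p)
        denom = float(np.sum(p * Ap))
        if denom <= 0:
            break
        alpha = rs / denom
        x = x + alpha * p
        r = r - alpha * Ap
        rs_new = float(np.sum(r * r))
        p = r + (rs_new / rs) * p
        rs = rs_new
    return x, np.sqrt(rs) / b_norm


def solve_srr(problem: SRRProblem, max_outer: int = 10, inner_iter: int = 20,
              tol: float = 1e-6, x0: Image3D | np.ndarray | None = None,
              history: list | None = None) -> Image3D:
    """Minimize the SRR objective subject to x >= 0.

    Projected CG: ``max_outer`` restarts of ``inner_iter`` CG iterations
    on the normal equations, projecting onto the non-negative orthant at
    each restart.  Stops early once the relative normal-equation residual
    of the projected iterate falls below ``tol``.  Returns the best
    iterate (with a warning if the tolerance was not reached).
    """
    if not list(problem.active()):
        raise ValueError("no inlier slices to reconstruct from")
    if x0 is None:
        x = np.zeros(problem.grid.dims)
    elif isinstance(x0, Image3D):
        x = np.maximum(x0.data.copy(), 0.0)
    else:
        x = np.maximum(np.asarray(x0, dtype=float).reshape(problem.grid.dims), 0.0)
    b = _rhs(problem)
    res = np.inf
    for _ in range(max_outer):
        x, res = _cg(problem, x, b, inner_iter, tol)
        x = np.maximum(x, 0.0)
        if history is not None:
            history.append(objective(problem, x))
        if res < tol:
            break
    if res >= tol and res > 1e-2:
        warnings.warn(f"solve_srr: not converged (relative residual {res:.2e})")
    return problem.grid.to_image(x)


def l_curve(stacks: list, grid: ReconGrid, alphas,
            solver_kwargs: dict | None = None):
    """Sweep the regularization weight and report the L-curve.

    Returns a list of records (alpha, data_norm, reg_norm, curvature)
    where curvature is the discrete log-log curvature of the
    (data_norm, reg_norm) curve; the corner (maximum curvature) is the
    usual heuristic choice of alpha.  No automatic selection is made.
    """
    kw = solver_kwargs or {}
    pb = build_problem(stacks, grid, alpha=0.0)
    rho, eta = [], []
    for a in alphas:
        pb.alpha = float(a)
        x = solve_srr(pb, **kw)
        pb.alpha = 0.0
        rho.append(np.sqrt(2.0 * objective(pb, x.data)))
        gs = spatial_gradient(x.data)
        eta.append(np.sqrt(sum(float(np.sum(g * g)) for g in gs)))
    lr, le = np.log10(np.maximum(rho, 1e-30)), np.log10(np.maximum(eta, 1e-30))
    curv = np.zeros(len(alphas))
    for i in range(1, len(alphas) - 1):
        d1 = np.array([lr[i + 1] - lr[i - 1], le[i + 1] - le[i - 1]]) / 2
        d2 = np.array([lr[i + 1] - 2 * lr[i] + lr[i - 1],
                       le[i + 1] - 2 * le[i] + le[i - 1]])
        denom = (d1 @ d1) ** 1.5
        curv[i] = (d1[0] * d2[1] - d1[1] * d2[0]) / denom if denom > 0 else 0.0
    return [{"alpha": float(a), "data_norm": float(r), "reg_norm": float(e),
             "curvature": float(c)}
            for a, r, e, c in zip(alphas, rho, eta, curv)]
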