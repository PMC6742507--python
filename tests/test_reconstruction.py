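import numpy as np
import pytest

from srrkit.forward_model import orient_covariance, psf_covariance
from srrkit.image_core import world_to_voxel
from srrkit.phantom_sim import build_plan, make_phantom, simulate_dataset
from srrkit.reconstruction import (ReconGrid, build_problem, default_grid,
                                   gradient_adjoint, l_curve, objective,
                                   scattered_init, solve_srr, spatial_gradient)


class TestSpatialGradient:
    def test_constant_volume_zero_gradient(self):
        gs = spatial_gradient(np.full((5, 6, 7), 2.5))
        assert all(np.all(g == 0.0) for g in gs)

    def test_ramp_gradient_is_slope(self):
        x = np.arange(6.0)[:, None, None] * np.ones((6, 5, 4)) * 3.0
        g0 = spatial_gradient(x)[0]
        assert np.allclose(g0[:-1], 3.0)
        assert np.all(g0[-1] == 0.0)

    def test_adjoint_inner_product(self):
        rng = np.random.default_rng(0)
        x = rng.random((6, 7, 5))
        gs = [rng.random((6, 7, 5)) for _ in range(3)]
        lhs = sum(np.sum(a * b) for a, b in zip(spatial_gradient(x), gs))
        rhs = np.sum(x * gradient_adjoint(gs))
        assert lhs == pytest.approx(rhs, abs=1e-10)


def _nw_oracle(stacks, grid, truncation=3.0):
    """Brute-force Nadaraya-Watson: loop every (voxel, pixel) pair and
    accumulate oriented-Gaussian weights computed from first principles."""
    gimg = grid.to_image()
    num = np.zeros(grid.dims)
    den = np.zeros(grid.dims)
    vox_idx = np.indices(grid.dims).reshape(3, -1).T.astype(float)
    M = gimg.direction @ np.diag(gimg.spacing)
    vox_world = vox_idx @ M.T + gimg.origin
    for st in stacks:
        for s in st.slices:
            eff = s.effective_pose()
            cov = orient_covariance(psf_covariance(*s.spacing3), eff.rotation)
            prec = np.linalg.inv(cov)
            centers = s.pixel_centers_world()
            for pix_val, c in zip(s.pixels.ravel(), centers):
                d = vox_world - c
                q = np.einsum("ni,ij,nj->n", d, prec, d)
                w = np.where(q <= truncation ** 2, np.exp(-0.5 * q), 0.0)
                num += (w * pix_val).reshape(grid.dims)
                den += w.reshape(grid.dims)
    out = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    return out


class TestScatteredInit:
    def test_constant_stacks_give_constant_volume(self, small_phantom):
        plan = build_plan("a+c", in_plane_spacing=1.0, thickness=3.0)
        stacks, _ = simulate_dataset(small_phantom, plan, seed=3)
        for st in stacks:
            for s in st.slices:
                s.pixels = np.full_like(s.pixels, 4.2)
        grid = default_grid(stacks)
        vol = scattered_init(stacks, grid)
        covered = vol.mask
        assert np.allclose(vol.data[covered], 4.2, atol=1e-9)

    def test_matches_bruteforce_oracle(self):
        ph = make_phantom(dims=(12, 12, 12), spacing=1.0, seed=2)
        plan = build_plan("a+c", in_plane_spacing=1.0, thickness=2.0)
        stacks, _ = simulate_dataset(ph, plan, seed=4)
        grid = ReconGrid(1.0, ph.origin, ph.direction, ph.shape)
        vol = scattered_init(stacks, grid)
        oracle = _nw_oracle(stacks, grid)
        assert np.allclose(vol.data, oracle, atol=1e-8)


def _interior_problem(alpha=0.01):
    """Tiny strictly-positive phantom so the unconstrained optimum is
    interior and the non-negativity constraint is inactive."""
    ph = make_phantom(dims=(6, 6, 6), spacing=1.0, seed=5)
    ph = ph.like(ph.data + 0.5)
    plan = build_plan("a+c+s", in_plane_spacing=1.0, thickness=2.0)
    stacks, _ = simulate_dataset(ph, plan, seed=6)
    grid = ReconGrid(1.0, ph.origin, ph.direction, ph.shape)
    return build_problem(stacks, grid, alpha=alpha), ph


def _dense_solution(problem):
    n = problem.grid.n_voxels
    A = np.vstack([op.dense() for op in problem.operators])
    y = np.concatenate([s.pixels.ravel() for s in problem.slices])
    I = np.eye(n)
    G = np.array([np.concatenate([g.ravel() for g in
                                  spatial_gradient(I[:, c].reshape(problem.grid.dims))])
                  for c in range(n)]).T
    N = A.T @ A + problem.alpha * (G.T @ G)
    return np.linalg.solve(N, A.T @ y), A, G


class TestSolveSRR:
    def test_matches_dense_normal_equations(self):
        problem, _ = _interior_problem()
        xd, _, _ = _dense_solution(problem)
        assert xd.min() > 0  # interior: constraint inactive
        x = solve_srr(problem, max_outer=20, inner_iter=50, tol=1e-12)
        f_dense = objective(problem, xd.reshape(problem.grid.dims))
        f_solver = objective(problem, x.data)
        assert f_solver <= f_dense + 1e-6

    def test_exact_data_recovery_full_rank(self):
        problem, ph = _interior_problem(alpha=0.0)
        _, A, _ = _dense_solution(_interior_problem(alpha=1.0)[0])
        assert np.linalg.matrix_rank(A) == problem.grid.n_voxels
        # regenerate data exactly from a known non-negative volume
        x_true = ph.data
        for s, op in zip(problem.slices, problem.operators):
            s.pixels = op.apply(x_true)
        problem._stacked_cache = None
        x = solve_srr(problem, max_outer=20, inner_iter=60, tol=1e-12)
        rel = np.linalg.norm(x.data - x_true) / np.linalg.norm(x_true)
        assert rel < 0.05

    def test_huge_alpha_flattens_volume(self):
        problem, _ = _interior_problem(alpha=1e6)
        x = solve_srr(problem, max_outer=10, inner_iter=30)
        spread = x.data.max() - x.data.min()
        assert spread < 0.01 * max(x.data.mean(), 1e-12)

    def test_convexity_independent_of_initialization(self):
        problem, ph = _interior_problem()
        x1 = solve_srr(problem, max_outer=20, inner_iter=50, tol=1e-12)
        x2 = solve_srr(problem, max_outer=20, inner_iter=50, tol=1e-12,
                       x0=np.full(problem.grid.dims, 2.0))
        f1, f2 = objective(problem, x1.data), objective(problem, x2.data)
        assert abs(f1 - f2) <= 1e-6 * max(abs(f1), 1.0)

    def test_output_nonnegative(self):
        problem, _ = _interior_problem()
        for s in problem.slices:
            s.pixels = s.pixels - 0.6  # push the optimum against the bound
        problem._stacked_cache = None
        x = solve_srr(problem, max_outer=10, inner_iter=20)
        assert x.data.min() >= 0.0

    def test_full_inlier_subset_reproduces_full_problem(self):
        problem, _ = _interior_problem()
        x_all = solve_srr(problem, max_outer=5, inner_iter=20)
        problem.inliers = list(range(len(problem.slices)))
        x_subset = solve_srr(problem, max_outer=5, inner_iter=20)
        assert np.array_equal(x_all.data, x_subset.data)

    def test_no_inliers_raises(self):
        problem, _ = _interior_problem()
        problem.inliers = []
        with pytest.raises(ValueError, match="no inlier"):
            solve_srr(problem)


def test_l_curve_reports_monotone_tradeoff(small_phantom):
    plan = build_plan("a+c", in_plane_spacing=1.0, thickness=3.0)
    stacks, _ = simulate_dataset(small_phantom, plan, noise_sd=0.02, seed=9)
    grid = default_grid(stacks)
    rows = l_curve(stacks, grid, alphas=[1e-3, 1e-2, 1e-1],
                   solver_kwargs=dict(max_outer=3, inner_iter=15))
    assert len(rows) == 3
    regs = [r["reg_norm"] for r in rows]
    assert regs[0] >= regs[1] >= regs[2]  # stronger alpha, smoother volume
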