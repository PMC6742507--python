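import numpy as np
import pytest
from dataclasses import replace

from srrkit.image_core import RigidTransform
from srrkit.motion_correction import (RegistrationSettings, align_stacks,
                                      deform_slice_inplane,
                                      reconstruct_outlier_robust,
                                      reconstruct_reference_guided,
                                      reconstruct_static, register_slice_rigid,
                                      select_inliers)
from srrkit.phantom_sim import build_plan, make_phantom, simulate_dataset
from srrkit.reconstruction import default_grid
from srrkit.similarity import lncc


@pytest.fixture(scope="module")
def reg_phantom():
    return make_phantom(dims=(40, 40, 40), seed=0)


@pytest.fixture(scope="module")
def reg_stack(reg_phantom):
    geom = build_plan("a+c+s").stacks[0]
    from srrkit.phantom_sim import simulate_stack
    stack, motions = simulate_stack(reg_phantom, geom, amplitude_t=0.0,
                                    amplitude_r=0.0, noise_sd=0.005, seed=2)
    return stack, motions


class TestRegisterSliceRigid:
    def test_self_registration_fixed_point(self, reg_phantom, reg_stack):
        stack, _ = reg_stack
        s = stack.slices[len(stack) // 2]
        r = register_slice_rigid(s, reg_phantom,
                                 settings=RegistrationSettings(seed=1))
        c = s.center_world()
        assert np.linalg.norm(r.transform.apply(c) - c) < 0.1
        assert r.transform.rotation_angle_deg() < 0.1
        assert r.success

    def test_recovers_known_inplane_translation(self, reg_phantom, reg_stack):
        stack, _ = reg_stack
        s = stack.slices[len(stack) // 2]
        true = RigidTransform.from_params([0, 0, 0, 2.0, 0.0, 0.0],
                                          center=s.center_world())
        moved = replace(s, correction=true)
        from srrkit.forward_model import make_slice_operator
        op = make_slice_operator(moved, reg_phantom)
        displaced = replace(s, pixels=op.apply(reg_phantom.data))
        r = register_slice_rigid(displaced, reg_phantom,
                                 settings=RegistrationSettings(seed=1))
        c = s.center_world()
        err = np.linalg.norm(r.transform.apply(c) - true.apply(c))
        assert err < 0.5

    def test_recovers_known_rotation(self, reg_phantom, reg_stack):
        stack, _ = reg_stack
        s = stack.slices[len(stack) // 2]
        true = RigidTransform.from_params([0, 0, 3.0, 0, 0, 0],
                                          center=s.center_world())
        from srrkit.forward_model import make_slice_operator
        op = make_slice_operator(replace(s, correction=true), reg_phantom)
        rotated = replace(s, pixels=op.apply(reg_phantom.data))
        r = register_slice_rigid(rotated, reg_phantom,
                                 settings=RegistrationSettings(seed=1))
        resid = RigidTransform(r.transform.rotation @ true.rotation.T,
                               np.zeros(3))
        assert resid.rotation_angle_deg() < 1.0

    def test_empty_overlap_returns_init_flagged(self, reg_phantom, reg_stack):
        stack, _ = reg_stack
        s = stack.slices[0]
        far = replace(s, pose=RigidTransform(s.pose.rotation,
                                             s.pose.translation + 500.0))
        r = register_slice_rigid(far, reg_phantom,
                                 settings=RegistrationSettings(seed=1))
        assert not r.success
        assert np.allclose(r.transform.translation, far.correction.translation)


class TestAlignStacks:
    def test_aligned_stacks_get_near_identity(self, reg_phantom):
        plan = build_plan("a+c+s")
        stacks, _ = simulate_dataset(reg_phantom, plan, noise_sd=0.005, seed=4)
        transforms = align_stacks(stacks,
                                  settings=RegistrationSettings(seed=4))
        assert len(transforms) == len(stacks)
        for T in transforms:
            assert np.linalg.norm(T.translation) < 1.0
            assert T.rotation_angle_deg() < 1.0

    def test_recovers_known_stack_offset(self, reg_phantom):
        plan = build_plan("a+c+s")
        stacks, _ = simulate_dataset(reg_phantom, plan, noise_sd=0.005, seed=5)
        offset = np.array([3.0, 0.0, 0.0])
        for s in stacks[1].slices:
            s.pose = RigidTransform(s.pose.rotation,
                                    s.pose.translation + offset)
        transforms = align_stacks(stacks,
                                  settings=RegistrationSettings(seed=5))
        # the estimated correction must undo the +3 mm pose error
        assert np.linalg.norm(transforms[1].translation + offset) < 0.5


class TestSelectInliers:
    @pytest.fixture(scope="class")
    def recon_and_stacks(self, reg_phantom):
        plan = build_plan("a+c", in_plane_spacing=0.78, thickness=5.0)
        stacks, _ = simulate_dataset(reg_phantom, plan, seed=6)
        return reg_phantom, stacks

    def test_sigma_minus_one_retains_all(self, recon_and_stacks):
        recon, stacks = recon_and_stacks
        sets, _ = select_inliers(stacks, recon, sigma=-1.0)
        for st in stacks:
            assert sets[st.stack_id] == {s.slice_index for s in st.slices}

    def test_noiseless_self_consistent_slices_retained(self, recon_and_stacks):
        recon, stacks = recon_and_stacks
        sets, scores = select_inliers(stacks, recon, sigma=0.7)
        total = sum(len(st.slices) for st in stacks)
        assert sum(len(v) for v in sets.values()) == total
        assert min(scores.values()) > 0.95

    def test_shuffled_slice_rejected(self, recon_and_stacks):
        recon, stacks = recon_and_stacks
        from srrkit.phantom_sim import corrupt_slices
        bad_stack, bad = corrupt_slices(stacks[0], 1, mode="noise", seed=7)
        sets, _ = select_inliers([bad_stack, stacks[1]], recon, sigma=0.6)
        assert bad[0] not in sets[0]
        assert sets[1] == {s.slice_index for s in stacks[1].slices}

    def test_threshold_nesting(self, recon_and_stacks):
        recon, stacks = recon_and_stacks
        lo, _ = select_inliers(stacks, recon, sigma=0.6)
        hi, _ = select_inliers(stacks, recon, sigma=0.7)
        for sid in lo:
            assert hi[sid] <= lo[sid]


class TestPipelines:
    @pytest.fixture(scope="class")
    def motion_free(self, reg_phantom):
        plan = build_plan("a+c+s")
        return simulate_dataset(reg_phantom, plan, noise_sd=0.005, seed=8)

    def test_robust_reduces_to_static(self, motion_free):
        stacks, _ = motion_free
        sw = dict(max_outer=2, inner_iter=10)
        stat = reconstruct_static(stacks, alpha=0.01, solver_kwargs=sw)
        rob = reconstruct_outlier_robust(
            stacks, iterations=0, sigma_schedule=(-1.0,), alpha=0.01,
            stack_align=False, solver_kwargs=sw)
        assert np.array_equal(stat.volume.data, rob.volume.data)
        assert rob.rejected_count == [0]

    def test_static_bookkeeping(self, motion_free):
        stacks, _ = motion_free
        res = reconstruct_static(stacks, alpha=0.01,
                                 solver_kwargs=dict(max_outer=1, inner_iter=5))
        assert len(res.inlier_history) == 1
        for st in stacks:
            assert res.inlier_history[0][st.stack_id] == \
                {s.slice_index for s in st.slices}
        assert res.volume.data.min() >= 0.0

    def test_reference_guided_matches_static_without_motion(self, reg_phantom,
                                                            motion_free):
        stacks, _ = motion_free
        sw = dict(max_outer=3, inner_iter=15)
        grid = default_grid(stacks)
        stat = reconstruct_static(stacks, alpha=0.01, grid=grid,
                                  solver_kwargs=sw)
        rg = reconstruct_reference_guided(
            stacks, reg_phantom, deformable=False, alpha=0.01, grid=grid,
            settings=RegistrationSettings(seed=9), solver_kwargs=sw)
        # motion-free: registrations stay near identity and the volumes agree
        for T in rg.corrections.values():
            assert T.rotation_angle_deg() < 0.3
        rel = (np.linalg.norm(rg.volume.data - stat.volume.data)
               / np.linalg.norm(stat.volume.data))
        assert rel < 0.05


class TestDeformSliceInplane:
    @pytest.fixture(scope="class")
    def textured_slice(self, reg_phantom, reg_stack):
        stack, _ = reg_stack
        return stack.slices[len(stack) // 2]

    def test_identity_fixed_point(self, textured_slice):
        res = deform_slice_inplane(textured_slice, textured_slice.pixels,
                                   max_iter=10)
        assert res.success
        assert np.abs(res.displacement).max() < 0.3

    def test_recovers_smooth_bump(self, textured_slice):
        from scipy import ndimage
        s = textured_slice
        n1, n2 = s.pixels.shape
        ii, jj = np.meshgrid(np.arange(n1, dtype=float),
                             np.arange(n2, dtype=float), indexing="ij")
        bump = 2.0 * np.exp(-(((ii - n1 / 2) / 6.0) ** 2
                              + ((jj - n2 / 2) / 6.0) ** 2))
        warped = ndimage.map_coordinates(s.pixels, [ii + bump, jj],
                                         order=1, mode="nearest")
        slc = replace(s, pixels=warped)
        before = lncc(slc.pixels, s.pixels, s.mask, radius=2)
        res = deform_slice_inplane(slc, s.pixels, max_iter=30)
        after = lncc(res.slice.pixels, s.pixels, s.mask, radius=2)
        assert after > before
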