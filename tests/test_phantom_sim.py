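import numpy as np
import pytest

from srrkit.forward_model import make_slice_operator
from srrkit.phantom_sim import (CONFIG_NAMES, OBLIQUE_CORNERS, build_plan,
                                corrupt_slices, make_phantom, simulate_stack,
                                simulate_dataset)
from srrkit.similarity import ncc


class TestMakePhantom:
    def test_deterministic_for_seed(self):
        a = make_phantom(dims=(20, 20, 20), seed=42)
        b = make_phantom(dims=(20, 20, 20), seed=42)
        assert np.array_equal(a.data, b.data)

    def test_intensity_range_and_background(self):
        ph = make_phantom(dims=(24, 24, 24), seed=1)
        assert ph.data.min() >= 0.0 and ph.data.max() <= 1.0
        assert np.all(ph.data[~ph.mask] == 0.0)

    def test_tubes_brighter_than_bulk(self):
        ph = make_phantom(dims=(32, 32, 32), seed=3)
        fg = ph.data[ph.mask]
        tube_level = 0.9  # tubes are drawn at 0.95 before clipping
        non_tube = fg[fg < tube_level]
        assert (fg >= tube_level).sum() > 0
        assert tube_level > np.percentile(non_tube, 90)


class TestBuildPlan:
    @pytest.mark.parametrize("name,count", [
        ("a+c", 2), ("a+c+s", 3), ("2a+2c+2s", 6), ("a+c+s+3obl", 6),
        ("a+c+s+4obl", 7), ("2a+2c+2s+4obl", 10)])
    def test_series_counts(self, name, count):
        assert len(build_plan(name)) == count

    def test_unknown_configuration_raises(self):
        with pytest.raises(ValueError, match="unknown configuration"):
            build_plan("axial-only")

    def test_oblique_normals_toward_lower_corners(self):
        plan = build_plan("a+c+s+4obl")
        normals = [g.normal for g in plan.stacks if "oblique" in g.plane_label]
        assert len(normals) == 4
        for n in normals:
            assert np.linalg.norm(n) == pytest.approx(1.0, abs=1e-9)
            assert n[2] < 0  # toward the lower corners
        for i in range(4):
            for j in range(i + 1, 4):
                cosang = normals[i] @ normals[j]
                assert min(abs(cosang - 1 / 3), abs(cosang + 1 / 3)) < 1e-12

    def test_every_normal_unit_length(self):
        for name in CONFIG_NAMES:
            for g in build_plan(name).stacks:
                assert np.linalg.norm(g.normal) == pytest.approx(1.0, abs=1e-9)


class TestSimulateStack:
    def test_no_motion_no_noise_equals_forward_projection(self, small_phantom):
        geom = build_plan("a+c+s", in_plane_spacing=1.0, thickness=3.0).stacks[0]
        stack, motions = simulate_stack(small_phantom, geom, seed=5)
        for s in stack.slices:
            assert motions[(0, s.slice_index)].rotation_angle_deg() == 0.0
            op = make_slice_operator(s, small_phantom)
            assert np.allclose(s.pixels, op.apply(small_phantom.data))

    def test_noise_calibration(self, small_phantom):
        resid = []
        for geom in build_plan("a+c", in_plane_spacing=1.0,
                               thickness=3.0).stacks:
            clean, _ = simulate_stack(small_phantom, geom, noise_sd=0.0, seed=8)
            noisy, _ = simulate_stack(small_phantom, geom, noise_sd=0.01, seed=8)
            resid += [(a.pixels - b.pixels).ravel()
                      for a, b in zip(noisy.slices, clean.slices)]
        resid = np.concatenate(resid)
        assert resid.size >= 1e4
        assert abs(resid.std() - 0.01) < 0.001

    def test_half_shift_interleaves_slice_centres(self, small_phantom):
        plan = build_plan("2a+2c+2s", in_plane_spacing=1.0, thickness=3.0)
        ax = [g for g in plan.stacks if g.plane_label == "axial"][0]
        axs = [g for g in plan.stacks if g.plane_label == "axial_shifted"][0]
        st, _ = simulate_stack(small_phantom, ax, seed=1)
        sts, _ = simulate_stack(small_phantom, axs, seed=1, stack_id=1)
        n = ax.normal
        z = np.array(sorted(s.center_world() @ n for s in st.slices))
        zs = np.array(sorted(s.center_world() @ n for s in sts.slices))
        # shifted centres sit exactly half a thickness off the base comb
        offs = (zs[:, None] - z[None, :]) % ax.thickness
        assert np.allclose(offs, ax.thickness / 2.0, atol=1e-9)

    def test_through_plane_sampling_ratio(self):
        geom = build_plan("a+c").stacks[0]
        ratio = geom.thickness / geom.in_plane_spacing
        assert round(ratio) == 6  # ~six-fold through-plane upsampling


class TestCorruptSlices:
    def test_zero_corruptions_is_identity(self, tiny_dataset):
        stacks, _ = tiny_dataset
        out, bad = corrupt_slices(stacks[0], 0, seed=1)
        assert bad == []
        for a, b in zip(out.slices, stacks[0].slices):
            assert np.array_equal(a.pixels, b.pixels)
            assert np.allclose(a.pose.translation, b.pose.translation)

    def test_mispose_changes_pose_not_pixels(self, tiny_dataset):
        stacks, _ = tiny_dataset
        out, bad = corrupt_slices(stacks[0], 2, mode="mispose", seed=2)
        assert len(bad) == 2
        for a, b in zip(out.slices, stacks[0].slices):
            assert np.array_equal(a.pixels, b.pixels)
            moved = not np.allclose(a.pose.translation, b.pose.translation)
            assert moved == (a.slice_index in bad)

    def test_noise_mode_replaces_pixels_keeps_pose(self, tiny_dataset):
        stacks, _ = tiny_dataset
        out, bad = corrupt_slices(stacks[1], 1, mode="noise", seed=3)
        for a, b in zip(out.slices, stacks[1].slices):
            assert np.allclose(a.pose.translation, b.pose.translation)
            if a.slice_index in bad:
                assert not np.array_equal(a.pixels, b.pixels)
                # histogram preserved inside the mask
                assert np.allclose(sorted(a.pixels[a.mask]),
                                   sorted(b.pixels[b.mask]))

    def test_cannot_corrupt_all_slices(self, tiny_dataset):
        stacks, _ = tiny_dataset
        with pytest.raises(ValueError):
            corrupt_slices(stacks[0], len(stacks[0].slices), seed=1)

    def test_mispose_severity_calibration(self):
        """Corrupted slices must not resemble the projection at their
        recorded (wrong) pose, the property outlier rejection relies on."""
        ph = make_phantom(dims=(40, 40, 40), seed=0)
        plan = build_plan("a+c+s")
        stacks, _ = simulate_dataset(ph, plan, amplitude_t=3.0, amplitude_r=3.0,
                                     noise_sd=0.01, seed=20)
        vals = []
        for seed in range(6):
            cor, bad = corrupt_slices(stacks[seed % 3], 2, mode="mispose",
                                      seed=seed)
            for s in cor.slices:
                if s.slice_index in bad:
                    op = make_slice_operator(s, ph)
                    m = s.mask & ~op.out_of_support
                    if m.sum() > 2:
                        vals.append(ncc(s.pixels[m], op.apply(ph.data)[m],
                                        on_zero_variance="zero"))
        assert max(vals) < 0.6


def test_dataset_determinism(small_phantom):
    plan = build_plan("a+c", in_plane_spacing=1.0, thickness=3.0)
    s1, t1 = simulate_dataset(small_phantom, plan, amplitude_t=2.0,
                              amplitude_r=2.0, noise_sd=0.01, seed=33)
    s2, t2 = simulate_dataset(small_phantom, plan, amplitude_t=2.0,
                              amplitude_r=2.0, noise_sd=0.01, seed=33)
    for a, b in zip(s1, s2):
        for x, y in zip(a.slices, b.slices):
            assert np.array_equal(x.pixels, y.pixels)
    for k in t1.motions:
        assert np.allclose(t1.motions[k].translation,
                           t2.motions[k].translation, atol=1e-12)
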