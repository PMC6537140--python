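"""Intensity integration, dead-cell masking, NTH detection, TVB subtraction."""

import numpy as np
import pytest

from flimhca import default_template
from flimhca.plate_io import GatedStack
from flimhca.segmentation import (
    build_intensity_image,
    detect_foci_nth,
    mask_dead_cells,
    segment_stack,
    subtract_tvb,
)
from flimhca.simulate import (
    DeadCell,
    Focus,
    SceneSpec,
    random_scene,
    render_gated_stack,
)
from conftest import MASTER_SEED


def _stack_from_frames(frames, fixed_bg=0.0, shape=None):
    frames = np.asarray(frames, dtype=float)
    tpl = default_template(frame_shape=frames.shape[1:])
    return GatedStack(frames=frames, template=tpl, fixed_background_dn=fixed_bg)


class TestIntensityImage:
    def test_constant_frames_minus_background_is_zero(self):
        stack = _stack_from_frames(np.full((12, 8, 8), 10.0), fixed_bg=10.0)
        np.testing.assert_array_equal(build_intensity_image(stack), 0.0)

    def test_single_bright_pixel_sums_across_frames(self):
        frames = np.full((12, 8, 8), 10.0)
        frames[:, 3, 4] += 100.0
        stack = _stack_from_frames(frames, fixed_bg=10.0)
        img = build_intensity_image(stack)
        assert img[3, 4] == pytest.approx(1200.0)
        assert img.sum() == pytest.approx(1200.0)

    def test_negative_residuals_clamped(self):
        stack = _stack_from_frames(np.full((12, 8, 8), 5.0), fixed_bg=10.0)
        assert build_intensity_image(stack).min() == 0.0

    def test_matches_simulator_forward_model(self):
        """For a noiseless rendered scene the intensity image equals the
        PSF-spread emitter map times the summed gate fractions."""
        tpl = default_template(frame_shape=(32, 32))
        scene = SceneSpec(
            foci=[Focus(16.0, 16.0, 2e4, 4.0)],
            camera_offset_dn=30.0,
            poisson_noise=False,
            bleach_rate=0.0,
        )
        stack, _ = render_gated_stack(scene, tpl)
        img = build_intensity_image(stack)
        total = stack.frames.sum(axis=0) - 12 * 30.0
        np.testing.assert_allclose(img, np.maximum(total, 0), rtol=1e-9, atol=1e-9)
        from flimhca.decay_model import gate_signal
        from flimhca.simulate import DEFAULT_IRF

        g = gate_signal(4.0, 2e4, tpl.delays_ns, 4.0, 12.5, DEFAULT_IRF)
        assert img.sum() == pytest.approx(g.sum(), rel=1e-6)


class TestDeadCellMask:
    def test_uniform_image_is_empty(self):
        assert not mask_dead_cells(np.full((64, 64), 7.0)).any()

    def test_small_blob_not_masked(self):
        img = np.full((64, 64), 10.0)
        img[10:13, 10:13] = 1e5  # 9 px < min_area_px
        assert not mask_dead_cells(img, min_area_px=40).any()

    def test_synthetic_dead_cell_masked_without_touching_foci(self):
        """Injected bright blobs are fully excluded while no focus center
        is swallowed (3 seeds here; 20-seed sweep in acceptance)."""
        tpl = default_template(frame_shape=(128, 128))
        for s in range(3):
            rng = np.random.default_rng(MASTER_SEED + s)
            scene = random_scene(tpl, 4.0, rng, n_cells=4, dead_cell_prob=0.0)
            scene.dead_cells = [DeadCell(64.0, 64.0, 10.0)]
            stack, truth = render_gated_stack(scene, tpl)
            img = build_intensity_image(stack)
            mask = mask_dead_cells(img)
            assert mask[64, 64]
            rr, cc = np.mgrid[0:128, 0:128]
            blob = (rr - 64) ** 2 + (cc - 64) ** 2 <= 100
            assert mask[blob].all()
            for r, c, _, _ in truth["foci"]:
                if (r - 64) ** 2 + (c - 64) ** 2 > 16**2:
                    assert not mask[int(round(r)), int(round(c))]


class TestNTHDetection:
    def test_single_bright_pixel_on_flat_background(self):
        img = np.full((32, 32), 10.0)
        img[12, 17] = 100.0
        assert detect_foci_nth(img) == [(12, 17)]

    def test_plateau_tie_broken_row_major(self):
        img = np.full((32, 32), 10.0)
        img[12, 17] = img[12, 18] = 100.0
        assert detect_foci_nth(img) == [(12, 17)]

    def test_near_edge_centers_discarded(self):
        img = np.full((32, 32), 10.0)
        img[1, 17] = 100.0
        assert detect_foci_nth(img) == []

    def test_scale_equivariance(self, small_template):
        """Multiplying the stack by c > 0 leaves detections unchanged."""
        rng = np.random.default_rng(MASTER_SEED)
        scene = random_scene(small_template, 4.0, rng, n_cells=4)
        stack, _ = render_gated_stack(scene, small_template)
        img = build_intensity_image(stack)
        a = detect_foci_nth(img)
        b = detect_foci_nth(173.0 * img)
        assert a == b and len(a) > 0

    def test_centers_avoid_exclusion_mask(self, small_template):
        rng = np.random.default_rng(MASTER_SEED + 1)
        scene = random_scene(small_template, 4.0, rng, n_cells=5, dead_cell_prob=1.0)
        stack, _ = render_gated_stack(scene, small_template)
        img = build_intensity_image(stack)
        excl = mask_dead_cells(img)
        for r, c in detect_foci_nth(img, excl):
            assert not excl[r - 1 : r + 2, c - 1 : c + 2].any()


class TestTVB:
    def test_member_minus_ring_median(self):
        """Ring at 5 DN, members at 12 DN -> 7 DN per pixel, 63 per focus."""
        frames = np.full((12, 16, 16), 5.0)
        frames[:, 7:10, 7:10] = 12.0
        stack = _stack_from_frames(frames)
        regions = subtract_tvb(stack, [(8, 8)])
        assert len(regions) == 1
        np.testing.assert_allclose(regions[0].decay_dn, 63.0)
        np.testing.assert_allclose(regions[0].per_frame_tvb_dn, 5.0)
        assert regions[0].total_signal_dn == pytest.approx(63.0 * 7)

    def test_ring_median_robust_to_outlier(self):
        frames = np.full((12, 16, 16), 5.0)
        frames[:, 5, 5] = 100.0  # one hot ring pixel
        frames[:, 7:10, 7:10] = 12.0
        stack = _stack_from_frames(frames)
        regions = subtract_tvb(stack, [(8, 8)])
        np.testing.assert_allclose(regions[0].per_frame_tvb_dn, 5.0)

    def test_uniform_frame_varying_offset_cancels_exactly(self, small_template):
        """The pipeline's background-immunity claim: any spatially uniform
        per-frame offset leaves every focus decay unchanged to < 1e-9."""
        rng = np.random.default_rng(MASTER_SEED + 2)
        scene = random_scene(small_template, 4.0, rng, n_cells=4, dead_cell_prob=0.0)
        stack, _ = render_gated_stack(scene, small_template)
        img = build_intensity_image(stack)
        centers = detect_foci_nth(img)
        base = subtract_tvb(stack, centers)
        offsets = rng.uniform(0, 500, size=stack.frames.shape[0])
        shifted = GatedStack(
            frames=stack.frames + offsets[:, None, None],
            template=stack.template,
            fixed_background_dn=stack.fixed_background_dn,
        )
        mod = subtract_tvb(shifted, centers)
        for r0, r1 in zip(base, mod):
            scale = np.abs(r0.decay_dn).max()
            assert np.abs(r1.decay_dn - r0.decay_dn).max() < 1e-9 * max(scale, 1.0)

    def test_neighbor_member_pixels_excluded_from_ring(self):
        frames = np.full((12, 20, 20), 5.0)
        stack = _stack_from_frames(frames)
        regions = subtract_tvb(stack, [(8, 8), (8, 12)])
        reg = regions[0]
        members_other = {(r + dr, c + dc) for (r, c) in [(8, 12)]
                         for dr in (-1, 0, 1) for dc in (-1, 0, 1)}
        assert not (set(reg.ring_px) & members_other)
        assert len(reg.ring_px) >= 8

    def test_focus_with_starved_ring_dropped(self):
        frames = np.full((12, 20, 20), 5.0)
        stack = _stack_from_frames(frames)
        exclusion = np.zeros((20, 20), dtype=bool)
        exclusion[5:12, 5:12] = True  # eats the whole ring
        regions = subtract_tvb(stack, [(8, 8)], exclusion)
        assert regions == []


def test_segment_stack_end_to_end(small_template):
    rng = np.random.default_rng(MASTER_SEED + 3)
    scene = random_scene(small_template, 4.0, rng, n_cells=4, dead_cell_prob=0.0)
    stack, truth = render_gated_stack(scene, small_template)
    regions, info = segment_stack(stack)
    assert info["n_regions"] == len(regions) > 0
    assert all(len(r.member_px) == 9 for r in regions)
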