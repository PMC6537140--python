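"""Synthetic-instrument forward model: exactness, linearity, determinism."""

import numpy as np
import pytest
from helpers import gaussian_irf_samples

from flimhca import default_template, generate_reference_decay
from flimhca.decay_model import DeltaIRF, GaussianIRF, model_gated_decay
from flimhca.plate_io import PlateLayout, WellInfo
from flimhca.simulate import (
    Cell,
    Focus,
    SceneSpec,
    generate_plate,
    random_scene,
    render_gated_stack,
    simulate_plate,
)
from flimhca.stats import rank_sum_test
from conftest import MASTER_SEED


def _tiny_template(shape=(32, 32)):
    return default_template(frame_shape=shape)


class TestRenderForwardModel:
    def test_noiseless_focus_matches_analytic_gates(self):
        """With noise, offset, autofluorescence and bleaching off, the
        frame-summed focus signal equals the analytic gated decay."""
        tpl = _tiny_template()
        scene = SceneSpec(
            foci=[Focus(16.0, 16.0, 5e4, 4.0)],
            autofluor_rate_dn=0.0,
            camera_offset_dn=0.0,
            poisson_noise=False,
            bleach_rate=0.0,
        )
        stack, _ = render_gated_stack(scene, tpl, DeltaIRF())
        per_frame = stack.flim_frames.sum(axis=(1, 2))
        expect = model_gated_decay(4.0, 5e4, tpl, DeltaIRF())
        np.testing.assert_allclose(per_frame, expect, rtol=1e-6)
        # every pixel shares the temporal shape: ratio across frames constant
        center = stack.flim_frames[:, 16, 16]
        np.testing.assert_allclose(
            center / center[0], expect / expect[0], rtol=1e-9
        )

    def test_linearity_in_amplitude(self):
        """Doubling every focus amplitude doubles the signal above offset."""
        tpl = _tiny_template()
        foci1 = [Focus(16.2, 15.7, 1e4, 3.0), Focus(8.4, 20.1, 5e3, 3.0)]
        foci2 = [Focus(f.row, f.col, 2 * f.amplitude_dn, f.tau_ns) for f in foci1]
        kw = dict(camera_offset_dn=50.0, poisson_noise=False)
        a, _ = render_gated_stack(SceneSpec(foci=foci1, **kw), tpl)
        b, _ = render_gated_stack(SceneSpec(foci=foci2, **kw), tpl)
        np.testing.assert_allclose(
            b.frames - 50.0, 2 * (a.frames - 50.0), rtol=1e-9, atol=1e-9
        )

    def test_same_seed_bit_identical(self):
        tpl = _tiny_template()
        scene = SceneSpec(
            cells=[Cell(16, 16)], foci=[Focus(16, 16, 1e4, 4.0)], seed=77
        )
        a, _ = render_gated_stack(scene, tpl)
        b, _ = render_gated_stack(scene, tpl)
        np.testing.assert_array_equal(a.frames, b.frames)

    def test_focus_outside_frame_rejected(self):
        tpl = _tiny_template()
        scene = SceneSpec(foci=[Focus(40.0, 10.0, 1e4, 4.0)])
        with pytest.raises(ValueError, match="outside"):
            render_gated_stack(scene, tpl)

    def test_bleaching_scales_frames_in_acquisition_order(self):
        tpl = _tiny_template()
        kw = dict(foci=[Focus(16, 16, 1e4, 4.0)], poisson_noise=False,
                  camera_offset_dn=0.0)
        clean, _ = render_gated_stack(SceneSpec(bleach_rate=0.0, **kw), tpl)
        bleached, _ = render_gated_stack(SceneSpec(bleach_rate=0.01, **kw), tpl)
        factors = bleached.frames.sum(axis=(1, 2)) / clean.frames.sum(axis=(1, 2))
        np.testing.assert_allclose(factors, 0.99 ** np.arange(12), rtol=1e-9)


class TestReferenceDecayGeneration:
    def test_delta_irf_is_wrapped_exponential(self):
        ref = generate_reference_decay(2.5, DeltaIRF(), amplitude_dn=1.0)
        t = ref.times_ns
        expect = np.exp(-t / 2.5) / (2.5 * (1 - np.exp(-12.5 / 2.5)))
        np.testing.assert_allclose(ref.values, expect, rtol=1e-12)

    @pytest.mark.parametrize("tau_ref", [0.1, 2.5])
    def test_gaussian_irf_matches_fine_grid_convolution(self, tau_ref):
        """Simulated reference matches a 1 ps circular-convolution oracle."""
        ref = generate_reference_decay(
            tau_ref, GaussianIRF(0.5, 0.1), amplitude_dn=1.0
        )
        n = 12500
        irf = gaussian_irf_samples(0.5, 0.1, n)
        from helpers import wrapped_exp_samples

        f = wrapped_exp_samples(tau_ref, n)
        conv = np.fft.irfft(np.fft.rfft(irf) * np.fft.rfft(f)) * (12.5 / n)
        oracle = conv[:: n // 500]
        assert np.max(np.abs(ref.values - oracle)) / oracle.max() < 1e-4

    def test_noise_deterministic_under_seed(self):
        a = generate_reference_decay(2.5, GaussianIRF(), noise_scale=2.0, seed=5)
        b = generate_reference_decay(2.5, GaussianIRF(), noise_scale=2.0, seed=5)
        np.testing.assert_array_equal(a.values, b.values)

    def test_tau_out_of_period_rejected(self):
        with pytest.raises(ValueError):
            generate_reference_decay(13.0, DeltaIRF())


def _two_strain_layout(wells_per_strain=3, fovs_per_well=15):
    wells = {}
    for i in range(wells_per_strain):
        wells[f"A{i + 1}"] = WellInfo("ctrl", "g1", "negative_control")
        wells[f"B{i + 1}"] = WellInfo("query", "g1", "query")
    return PlateLayout(
        wells=wells,
        fovs_per_well=fovs_per_well,
        replicate_wells_per_strain=wells_per_strain,
    )


class TestPlateGeneration:
    def test_plate_counts(self):
        """2 strains x 3 wells x 15 FOVs -> 90 stacks and 90 truth rows."""
        layout = _two_strain_layout()
        truth = {"ctrl": (4.0, 1.0), "query": (3.75, 1.0)}
        tpl = _tiny_template()
        n = 0
        for stack, rec in simulate_plate(layout, truth, tpl, seed=1, n_cells=1):
            assert stack.frames.shape == (12, 32, 32)
            assert rec["tau_ns"] in (4.0, 3.75)
            n += 1
        assert n == 90

    def test_missing_truth_entry_names_strain(self):
        layout = _two_strain_layout(1, 1)
        with pytest.raises(KeyError, match="query"):
            next(iter(simulate_plate(layout, {"ctrl": (4.0, 1.0)}, _tiny_template())))

    def test_generate_plate_writes_stacks_and_truth(self, tmp_path):
        layout = _two_strain_layout(1, 2)
        truth = {"ctrl": (4.0, 1.0), "query": (3.75, 1.0)}
        table = generate_plate(
            layout, truth, _tiny_template(), seed=3, out_dir=tmp_path, n_cells=1
        )
        assert len(table) == 4
        assert (tmp_path / "ground_truth.csv").exists()
        assert len(list(tmp_path.glob("*.ome.tif"))) == 4

    def test_seeded_plate_reproducible(self):
        layout = _two_strain_layout(1, 2)
        truth = {"ctrl": (4.0, 1.0), "query": (3.75, 1.0)}
        tpl = _tiny_template()
        a = [s.frames for s, _ in simulate_plate(layout, truth, tpl, seed=9, n_cells=1)]
        b = [s.frames for s, _ in simulate_plate(layout, truth, tpl, seed=9, n_cells=1)]
        for fa, fb in zip(a, b):
            np.testing.assert_array_equal(fa, fb)

    def test_fret_contrast_not_visible_in_intensity(self, small_template):
        """Strains differing only in lifetime (delta-tau = 250 ps) are
        indistinguishable by total intensity: the FRET readout lives in the
        decay, not the brightness (equal amplitude scales)."""
        layout = _two_strain_layout(3, 15)
        truth = {"ctrl": (4.0, 1.0), "query": (3.75, 1.0)}
        pvals = []
        for s in range(6):
            totals = {"ctrl": [], "query": []}
            for stack, rec in simulate_plate(
                layout, truth, small_template, seed=MASTER_SEED + s, n_cells=3
            ):
                totals[stack.strain_id].append(float(stack.frames.sum()))
            pvals.append(rank_sum_test(totals["ctrl"], totals["query"]))
        assert np.median(pvals) > 0.01


class TestSceneStatistics:
    def test_random_scene_respects_cell_count_and_bounds(self, small_template):
        rng = np.random.default_rng(MASTER_SEED)
        scene = random_scene(small_template, 4.0, rng, n_cells=6)
        assert len(scene.cells) == 6
        assert 6 <= len(scene.foci) <= 12
        h, w = small_template.frame_shape
        for f in scene.foci:
            assert 0 <= f.row < h and 0 <= f.col < w

    def test_fit_precision_improves_with_photon_budget(self, small_template):
        """Fitted-lifetime spread shrinks monotonically as the focus photon
        budget grows (three amplitude levels, 40 replicates each)."""
        from flimhca.fitting import process_fov

        ref = generate_reference_decay(2.5, GaussianIRF())
        sds = []
        for k, amp in enumerate([6e3, 3e4, 1.5e5]):
            taus = []
            ss = np.random.SeedSequence(MASTER_SEED + 100 + k)
            for child in ss.spawn(40):
                rng = np.random.default_rng(child)
                scene = random_scene(
                    small_template, 2.5, rng, n_cells=3,
                    focus_amplitude_dn=amp, bleach_rate=0.0, dead_cell_prob=0.0,
                )
                stack, _ = render_gated_stack(scene, small_template, GaussianIRF())
                res = process_fov(stack, ref, threshold_dn=0.0)
                if np.isfinite(res.tau_fit_ns):
                    taus.append(res.tau_fit_ns)
            sds.append(np.std(taus))
        assert sds[0] > sds[1] > sds[2]
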