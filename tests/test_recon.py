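"""WF averaging, OS-SIM demodulation, MAP estimation, and spectral merging."""

import numpy as np
import pytest
from scipy import ndimage

import panosim as ps
from conftest import all_on_pattern


def _stack_from_values(values, tile=8):
    """Stack whose every pixel follows the given per-phase sequence."""
    n = len(values)
    data = np.tile(np.asarray(values, dtype=float)[:, None, None], (1, tile, tile))
    pat = ps.PatternSet(period_px=n, n_phases=n, orientation_deg=0.0,
                        duty=1.0, masks=np.ones((n, tile, tile)))
    return ps.TileStack(data=data, pattern=pat, position=(0, 0))


class TestWidefield:
    def test_is_exact_arithmetic_mean(self):
        a = np.array([[0.0, 2.0], [2.0, 0.0]])
        b = np.array([[2.0, 0.0], [0.0, 2.0]])
        pat = all_on_pattern(2)
        stack = ps.TileStack(data=np.stack([a, b]), pattern=pat, position=(0, 0))
        np.testing.assert_array_equal(ps.reconstruct_widefield(stack), np.ones((2, 2)))

    def test_idempotent_on_identical_phases(self):
        img = ps.make_scene("texture", 64, seed=2)[:8, :8]
        stack = ps.TileStack(data=np.stack([img] * 5),
                             pattern=all_on_pattern(8, 5), position=(0, 0))
        np.testing.assert_allclose(ps.reconstruct_widefield(stack), img,
                                   rtol=1e-15, atol=0)

    def test_matches_forward_model_oracle(self):
        layout = ps.MosaicLayout(rows=1, cols=1, tile_px=64)
        pat = ps.make_line_patterns(64, 8, 4)
        scene = ps.make_scene("texture", 80, seed=6)
        vig = ps.make_vignette(64, 0.3)
        truth = ps.SceneGroundTruth(scene=scene, psf_sigma_px=1.0,
                                    vignette_truth=vig, seed=6)
        stack = ps.simulate_mosaic(truth, layout, pat)[0]
        oracle = ndimage.gaussian_filter(scene[:64, :64], 1.0) * vig * pat.duty
        np.testing.assert_allclose(ps.reconstruct_widefield(stack), oracle,
                                   rtol=1e-10, atol=1e-10)


class TestOssim:
    def test_unmodulated_stack_gives_zero(self):
        img = ps.make_scene("texture", 64, seed=2)[:8, :8]
        stack = ps.TileStack(data=np.stack([img] * 4),
                             pattern=all_on_pattern(8, 4), position=(0, 0))
        np.testing.assert_allclose(ps.reconstruct_ossim(stack), 0.0, atol=1e-10)

    def test_cosine_modulation_amplitude_recovered(self):
        # I_n = c + a*cos(2 pi n / N): demodulation returns a exactly
        n = np.arange(5)
        stack = _stack_from_values(10.0 + 4.0 * np.cos(2 * np.pi * n / 5))
        np.testing.assert_allclose(ps.reconstruct_ossim(stack), 4.0, atol=1e-10)

    def test_alternating_sequence_has_no_fundamental(self):
        # [1,0,1,0] puts all its energy at the N/2 harmonic, none at n=1
        stack = _stack_from_values([1.0, 0.0, 1.0, 0.0])
        np.testing.assert_allclose(ps.reconstruct_ossim(stack), 0.0, atol=1e-10)

    def test_requires_three_phases(self):
        stack = _stack_from_values([1.0, 2.0])
        with pytest.raises(ValueError, match="3 phases"):
            ps.reconstruct_ossim(stack)


class TestMapEstimate:
    def test_all_on_pattern_recovers_mean(self):
        # duty-1 pattern, no PSF, lambda 0: data term alone is minimized by
        # the per-pixel mean of the phase images
        img = np.round(ps.make_scene("texture", 64, seed=4))[:32, :32]
        pat = all_on_pattern(32)
        stack = ps.TileStack(data=np.stack([img, img]), pattern=pat, position=(0, 0))
        params = ps.ReconParams(map_iterations=10, map_lambda=0.0,
                                psf_sigma_px=0.0, upsample_factor=1)
        est = ps.map_estimate(stack, pat, params)
        np.testing.assert_allclose(est, img, atol=1e-8)

    def test_objective_lower_at_truth_than_at_wf_init(self):
        tile = 64
        layout = ps.MosaicLayout(rows=1, cols=1, tile_px=tile)
        pat = ps.make_line_patterns(tile, 8, 4)
        scene = ps.make_scene("texture", tile + 8, seed=2)
        truth = ps.SceneGroundTruth(scene=scene, psf_sigma_px=1.0, seed=2)
        stack = ps.simulate_mosaic(truth, layout, pat)[0]

        def objective(x):  # independent evaluation of the data term
            return sum(
                float(np.sum((ndimage.gaussian_filter(pat.masks[n] * x, 1.0)
                              - stack.data[n]) ** 2))
                for n in range(stack.n_phases)
            )

        obj_truth = objective(scene[:tile, :tile])
        obj_wf = objective(ps.reconstruct_widefield(stack))
        assert obj_truth <= obj_wf
        params = ps.ReconParams(map_iterations=15, map_lambda=0.0,
                                psf_sigma_px=1.0, upsample_factor=1)
        est = ps.map_estimate(stack, pat, params)
        # the solver must beat its own initialization
        assert objective(est) < obj_wf

    def test_estimate_nonnegative_and_deterministic(self):
        tile = 48
        layout = ps.MosaicLayout(rows=1, cols=1, tile_px=tile)
        pat = ps.make_line_patterns(tile, 8, 4)
        truth = ps.SceneGroundTruth(
            scene=ps.make_scene("texture", tile + 8, seed=8),
            psf_sigma_px=1.0, poisson_scale=50.0, seed=8)
        stack = ps.simulate_mosaic(truth, layout, pat)[0]
        params = ps.ReconParams(map_iterations=8, upsample_factor=1)
        a = ps.map_estimate(stack, pat, params)
        b = ps.map_estimate(stack, pat, params)
        assert a.min() >= 0
        np.testing.assert_array_equal(a, b)


class TestSpectralMerge:
    def test_identity_when_inputs_equal(self):
        img = ps.make_scene("texture", 64, seed=1)
        for cutoff in (0.2, 0.4, 0.8):
            np.testing.assert_allclose(ps.spectral_merge(img, img, cutoff), img,
                                       atol=1e-9)

    def test_dc_comes_from_low_image(self):
        rng = np.random.default_rng(0)
        low = rng.uniform(1, 2, (64, 64))
        high = rng.uniform(5, 6, (64, 64))
        out = ps.spectral_merge(low, high, 0.4)
        # w(0)=1: output DC = s * DC(low); recover s from the spectra
        fr = np.hypot(np.fft.fftfreq(64)[:, None], np.fft.fftfreq(64)[None, :])
        ann = (fr >= 0.4 * 0.5 - 0.025) & (fr <= 0.4 * 0.5 + 0.025)
        s = np.mean(np.abs(np.fft.fft2(high)[ann])) / np.mean(np.abs(np.fft.fft2(low)[ann]))
        assert np.fft.fft2(out)[0, 0].real == pytest.approx(
            s * np.fft.fft2(low)[0, 0].real, rel=1e-6)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            ps.spectral_merge(np.ones((8, 8)), np.ones((16, 16)), 0.4)

    def test_output_nonnegative(self):
        rng = np.random.default_rng(3)
        out = ps.spectral_merge(rng.uniform(0, 1, (64, 64)),
                                rng.uniform(0, 1, (64, 64)), 0.4)
        assert out.min() >= 0


@pytest.fixture(scope="module")
def star_recons():
    tile = 128
    layout = ps.MosaicLayout(rows=1, cols=1, tile_px=tile, pixel_size_nm=100.0)
    pat = ps.make_line_patterns(tile, 10, 5)
    truth = ps.SceneGroundTruth(
        scene=ps.make_scene("star", tile + 8, seed=3), psf_sigma_px=1.5,
        poisson_scale=100.0, read_sigma=0.5, seed=3)
    stack = ps.simulate_mosaic(truth, layout, pat)[0]
    params = ps.ReconParams(map_iterations=20, psf_sigma_px=1.5, upsample_factor=2)
    return ps.reconstruct_mapsim(stack, pat, params), stack, pat, params


class TestMapsimPipeline:

    def test_shapes_and_nonnegativity(self, star_recons):
        res, stack, _, params = star_recons
        tile = stack.data.shape[1]
        assert res.wf.shape == res.os.shape == (tile, tile)
        assert res.mapsim.shape == (tile * 2, tile * 2)
        for img in (res.wf, res.os, res.mapsim):
            assert img.min() >= 0

    def test_resolution_improves_over_widefield(self, star_recons):
        res, stack, _, params = star_recons
        r_wf = ps.resolution_from_psd(ps.psd_ca(res.wf), 100.0)
        r_ms = ps.resolution_from_psd(ps.psd_ca(res.mapsim), 100.0 / 2)
        assert r_ms < r_wf

    def test_energy_matches_os_scale(self, star_recons):
        res, *_ = star_recons
        assert res.mapsim.mean() == pytest.approx(res.os.mean(), rel=0.2)

    def test_deterministic(self, star_recons):
        res, stack, pat, params = star_recons
        res2 = ps.reconstruct_mapsim(stack, pat, params)
        np.testing.assert_array_equal(res.mapsim, res2.mapsim)

    def test_uniform_scene_stays_uniform(self):
        tile = 64
        layout = ps.MosaicLayout(rows=1, cols=1, tile_px=tile)
        pat = ps.make_line_patterns(tile, 8, 4)
        truth = ps.SceneGroundTruth(scene=np.full((tile + 8, tile + 8), 50.0),
                                    psf_sigma_px=1.0, seed=0)
        stack = ps.simulate_mosaic(truth, layout, pat)[0]
        params = ps.ReconParams(map_iterations=10, psf_sigma_px=1.0, upsample_factor=1)
        res = ps.reconstruct_mapsim(stack, pat, params)
        interior = res.mapsim[8:-8, 8:-8]
        assert np.ptp(interior) / interior.mean() < 0.05
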