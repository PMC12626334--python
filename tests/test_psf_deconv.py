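import numpy as np
import pytest

from azquant.psf import (
    PSFModel,
    average_psfs,
    convolve_psf,
    delta_psf,
    detect_beads,
    extract_psf,
    i_divergence,
    richardson_lucy,
    synthetic_gaussian_psf,
)
from azquant.synthetic import NoiseModel, generate_bead_field

VS = (0.37, 0.079, 0.079)


class TestPSFModel:
    def test_normalizes_and_validates(self):
        k = np.zeros((5, 5, 5))
        k[2, 2, 2] = 4.0
        m = PSFModel(k, VS)
        assert m.kernel.sum() == pytest.approx(1.0, abs=1e-12)
        with pytest.raises(ValueError):
            PSFModel(-k, VS)

    def test_off_center_peak_rejected(self):
        k = np.zeros((9, 9, 9))
        k[0, 0, 0] = 1.0
        with pytest.raises(ValueError, match="central"):
            PSFModel(k, VS)

    @pytest.mark.parametrize("sigma", [(0.2, 0.1, 0.1), (0.6, 0.2, 0.2), (1e-9, 1e-9, 1e-9)])
    def test_gaussian_unit_sum(self, sigma):
        m = synthetic_gaussian_psf(sigma, window=(9, 11, 11), voxel_size=VS)
        assert m.kernel.sum() == pytest.approx(1.0, abs=1e-9)

    def test_gaussian_symmetry(self):
        k = synthetic_gaussian_psf((0.4, 0.15, 0.15), window=(9, 11, 11), voxel_size=VS).kernel
        np.testing.assert_allclose(k, k[::-1, ::-1, ::-1], atol=1e-15)

    def test_sigma_zero_limit_is_delta(self):
        k = synthetic_gaussian_psf((0.0, 0.0, 0.0), window=(5, 5, 5), voxel_size=VS).kernel
        expect = np.zeros((5, 5, 5))
        expect[2, 2, 2] = 1.0
        np.testing.assert_array_equal(k, expect)


class TestDetectBeads:
    def test_single_bead_centroid(self, small_psf):
        stack, pos = generate_bead_field(1, 400.0, small_psf, shape=(24, 48, 48), seed=2)
        found = detect_beads(stack, min_separation_um=1.0)
        assert found.shape == (1, 3)
        err_vox = np.abs(found[0] - pos[0]) / np.array(VS)
        assert np.all(err_vox < 0.5)

    def test_close_pair_both_discarded(self):
        vol = np.zeros((20, 40, 40))
        vol[10, 10, 10] = 100.0
        vol[10, 10, 14] = 100.0  # 0.316 µm apart laterally
        vol[10, 30, 30] = 100.0
        found = detect_beads(vol, min_separation_um=1.0, threshold=50.0, voxel_size=VS)
        assert found.shape == (1, 3)  # only the isolated bead survives

    def test_five_beads_rms_quarter_voxel(self, small_psf):
        stack, pos = generate_bead_field(
            5, 400.0, small_psf, min_separation_um=2.5, shape=(32, 96, 96), seed=6
        )
        found = detect_beads(stack, min_separation_um=1.0)
        assert len(found) == 5
        # match by nearest neighbour then compare in voxel units
        errs = []
        for p in pos:
            d = np.linalg.norm(found - p, axis=1)
            errs.append((found[np.argmin(d)] - p) / np.array(VS))
        rms = np.sqrt(np.mean(np.square(errs)))
        assert rms < 0.25

    def test_no_beads_raises(self):
        with pytest.raises(ValueError, match="no beads"):
            detect_beads(np.zeros((5, 5, 5)), threshold=1.0, voxel_size=VS)


class TestExtractAverage:
    def test_extracted_matches_generating_kernel(self, small_psf):
        stack, pos = generate_bead_field(1, 800.0, small_psf, shape=(24, 48, 48), seed=3)
        cand = extract_psf(stack, pos[0], window=small_psf.kernel.shape)
        k = small_psf.kernel
        cos = (cand * k).sum() / np.sqrt((cand**2).sum() * (k**2).sum())
        assert cos >= 0.999

    def test_border_centroid_rejected(self, small_psf):
        vol = np.zeros((24, 48, 48))
        vol[2, 2, 2] = 100.0
        with pytest.raises(ValueError, match="bounds"):
            extract_psf(vol, np.array([2, 2, 2]) * np.array(VS), window=(9, 15, 15), voxel_size=VS)

    def test_uniform_image_no_signal(self):
        vol = np.full((24, 48, 48), 7.0)
        with pytest.raises(ValueError, match="no signal"):
            extract_psf(vol, np.array([12, 24, 24]) * np.array(VS), window=(9, 15, 15), voxel_size=VS)

    def test_average_identity_and_idempotence(self):
        k = synthetic_gaussian_psf((0.3, 0.1, 0.1), window=(7, 9, 9), voxel_size=VS).kernel
        one = average_psfs([k * 13.0], VS)
        np.testing.assert_allclose(one.kernel, k, atol=1e-12)
        many = average_psfs([k * 2, k * 2, k * 2], VS)
        np.testing.assert_allclose(many.kernel, k, atol=1e-12)

    def test_shifted_candidates_make_double_lobe(self):
        # documents why detection must centre beads before averaging
        k = np.zeros((1, 1, 7))
        k[0, 0, 3] = 1.0
        shifted = np.roll(k, 1, axis=2)
        avg = average_psfs([k, shifted], VS).kernel
        assert avg[0, 0, 3] == pytest.approx(0.5)
        assert avg[0, 0, 4] == pytest.approx(0.5)


def _rl_1d(observed, kernel, n_iter):
    """Run the package RL on a 1D profile embedded as a (1,1,n) volume."""
    obs = np.asarray(observed, dtype=float)[None, None, :]
    psf = PSFModel(np.asarray(kernel, dtype=float)[None, None, :], VS)
    return richardson_lucy(obs, psf, n_iter=n_iter)[0, 0]


class TestRichardsonLucy:
    def test_delta_psf_fixed_point_one_iteration(self, rng):
        obs = rng.random((6, 10, 12)) * 50 + 1
        e1 = richardson_lucy(obs, delta_psf(voxel_size=VS), n_iter=1)
        np.testing.assert_allclose(e1, obs, rtol=1e-10)
        e5 = richardson_lucy(obs, delta_psf(voxel_size=VS), n_iter=5)
        np.testing.assert_allclose(e5, obs, rtol=1e-9)

    def test_uniform_observed_stays_uniform(self):
        obs = np.full((8, 12, 12), 5.0)
        psf = synthetic_gaussian_psf((0.3, 0.1, 0.1), window=(5, 7, 7), voxel_size=VS)
        out = richardson_lucy(obs, psf, n_iter=10)
        np.testing.assert_allclose(out, 5.0, rtol=1e-6)

    def test_1d_toy_improves_and_divergence_monotone(self):
        truth = np.array([0.0, 0.0, 10.0, 0.0, 0.0])
        kernel = np.array([0.25, 0.5, 0.25])
        observed = np.convolve(truth, kernel, mode="same")
        divs = []
        prev_est = None
        for k in range(1, 51):
            est = _rl_1d(observed, kernel, k)
            reblurred = convolve_psf(est[None, None, :], kernel[None, None, :])[0, 0]
            divs.append(i_divergence(observed, reblurred))
            prev_est = est
        rmse_obs = np.sqrt(np.mean((observed - truth) ** 2))
        rmse_est = np.sqrt(np.mean((prev_est - truth) ** 2))
        assert rmse_est < rmse_obs
        assert all(b <= a + 1e-9 for a, b in zip(divs, divs[1:]))

    def test_nonnegativity_every_iteration(self, rng):
        obs = rng.poisson(5.0, size=(6, 10, 10)).astype(float)
        psf = synthetic_gaussian_psf((0.3, 0.1, 0.1), window=(5, 7, 7), voxel_size=VS)
        for k in (1, 3, 7):
            assert richardson_lucy(obs, psf, n_iter=k).min() >= 0

    def test_flux_conserved_interior_signal(self, small_psf):
        vol = np.zeros((24, 48, 48))
        vol[12, 24, 24] = 1000.0
        blurred = convolve_psf(vol, small_psf.kernel)
        out = richardson_lucy(blurred, small_psf, n_iter=20)
        assert out.sum() == pytest.approx(blurred.sum(), rel=0.01)

    def test_contrast_improvement_on_render(self, tiny_scene, small_psf):
        from azquant.synthetic import render_stack

        rng = np.random.default_rng(3)
        noisy = render_stack(tiny_scene, small_psf, NoiseModel(poisson=True, gaussian_sd=1.0), rng=rng)
        vol = noisy.channel("puncta").astype(float)
        dec = richardson_lucy(vol, small_psf, n_iter=15)

        def contrast(v):
            # peak-to-mean: total flux is conserved, so concentration at the
            # true centres measures restoration sharpness
            peaks = [v[p.voxel] for p in tiny_scene.puncta]
            return np.median(peaks) / v.mean()

        assert contrast(dec) > contrast(vol)

    def test_agrees_with_reference_implementation(self):
        # independent oracle: scikit-image RL (uniform init, direct conv)
        # converges to the same restoration on an interior-supported signal
        from skimage.restoration import richardson_lucy as sk_rl

        rng = np.random.default_rng(8)
        truth = np.zeros((16, 16, 16))
        for _ in range(4):
            z, y, x = rng.integers(5, 11, 3)
            truth[z, y, x] = rng.uniform(50, 150)
        kernel = synthetic_gaussian_psf(
            (0.2, 0.1, 0.1), window=(5, 5, 5), voxel_size=VS
        ).kernel
        observed = convolve_psf(truth, kernel)
        ours = richardson_lucy(observed, PSFModel(kernel, VS), n_iter=40)
        theirs = sk_rl(observed, kernel, num_iter=40, clip=False)
        inner = (slice(4, 12),) * 3
        denom = np.abs(theirs[inner]).max()
        assert np.abs(ours[inner] - theirs[inner]).max() / denom < 0.05

    def test_input_validation(self):
        psf = delta_psf(voxel_size=VS)
        with pytest.raises(ValueError):
            richardson_lucy(np.zeros((4, 4, 4)), psf, n_iter=5)
        with pytest.raises(ValueError):
            richardson_lucy(np.ones((4, 4, 4)), psf, n_iter=0)
        with pytest.raises(ValueError):
            richardson_lucy(np.ones((4, 4, 4)), psf, epsilon=0.0)


def test_convolution_matches_direct_small_grid(rng):
    # frequency-domain path vs direct triple-loop convolution on a tiny grid
    from scipy.ndimage import convolve as nd_convolve

    img = rng.random((8, 8, 8))
    kernel = rng.random((3, 5, 5))
    kernel /= kernel.sum()
    ours = convolve_psf(img, kernel)
    direct = nd_convolve(img, kernel, mode="mirror")
    np.testing.assert_allclose(ours, direct, atol=1e-8)
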