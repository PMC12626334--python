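"""Simulation benchmarks: detection scoring, profile/H recovery, power and
type-I error of the full pipeline, colocalization null behaviour.

These are the package's validation experiments. Each benchmark builds its
scenes from :mod:`azquant.synthetic`, runs the real pipeline stages, and
scores the result against the generator's ground truth. Problem sizes are
chosen to be desk-scale; seeds are explicit everywhere.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Any

import numpy as np

from . import segmentation as seg
from .pipeline import DeconvolutionParams, SegmentationParams, analyze_sample
from .psf import PSFModel, synthetic_gaussian_psf
from .stats import mann_whitney_u
from .synthetic import (
    NoiseModel,
    SceneConfig,
    generate_group_study,
    generate_paired_channels,
    generate_scene,
    render_stack,
)

__all__ = [
    "default_psf",
    "scale_scene_to_peak_snr",
    "detection_benchmark",
    "recovery_benchmark",
    "power_benchmark",
    "coloc_null_benchmark",
]


def default_psf(voxel_size=(0.370, 0.079, 0.079), window=None) -> PSFModel:
    """The package's default confocal-like PSF: anisotropic Gaussian with
    lateral σ 0.15 µm and axial σ 0.5 µm (FWHM ≈ 0.35 / 1.18 µm)."""
    from .psf import DEFAULT_PSF_WINDOW

    return synthetic_gaussian_psf(
        (0.5, 0.15, 0.15), window=window or DEFAULT_PSF_WINDOW, voxel_size=voxel_size
    )


def scale_scene_to_peak_snr(
    config: SceneConfig, psf: PSFModel, peak_snr: float, noise: NoiseModel
) -> SceneConfig:
    """Rescale amplitudes so the scene's geometric-mean median punctum has
    the requested peak SNR.

    Peak SNR is defined as s / sqrt(s + b + σ_g²) with s the expected peak
    signal above background (amplitude × PSF maximum), b the background and
    σ_g the Gaussian read-noise SD — i.e. signal over the noise SD at the
    peak under the Poisson + Gaussian model. Solving for s gives the
    amplitude scale; compartment ratios are preserved.
    """
    var_floor = config.background + noise.gaussian_sd**2
    s = 0.5 * (peak_snr**2 + np.sqrt(peak_snr**4 + 4 * peak_snr**2 * var_floor))
    p0 = float(psf.kernel.max())
    target_amp = s / p0
    current = float(np.exp(np.mean(config.log_amp_mean)))
    shift = np.log(target_amp / current)
    return replace(
        config, log_amp_mean=tuple(np.array(config.log_amp_mean) + shift)
    )


def _detect_centroids(stack, scene, params, psf, deconv) -> np.ndarray:
    res = analyze_sample(
        stack,
        scene.compartment_labels,
        scene.compartment_names,
        params,
        psf=psf,
        deconv=deconv,
        sample_id="bench",
    )
    return np.array([r.centroid_um for r in res.records]).reshape(-1, 3), res


def detection_benchmark(
    seed: int = 0,
    peak_snr: float = 5.0,
    match_dist_um: float = 0.3,
) -> dict[str, Any]:
    """Detection scores on (a) a noiseless well-separated scene and (b) a
    noisy scene at the given peak SNR.

    The noiseless scene spaces puncta at least 3× the largest PSF FWHM
    apart, where detection should be perfect at a 0.3 µm match radius; the
    noisy scene uses the default study-density conditions.
    """
    psf = default_psf()
    fwhm_max = 2.3548 * 0.5  # largest (axial) PSF FWHM, µm
    params = SegmentationParams()
    out: dict[str, Any] = {}

    cfg_clean = SceneConfig(
        shape=(32, 128, 320),
        counts=(5,) * 5,
        min_separation_um=3.0 * fwhm_max,
        margin_um=(1.5, 0.8, 0.8),
        background=0.0,
        seed=seed,
    )
    scene = generate_scene(cfg_clean)
    stack = render_stack(scene, psf, NoiseModel.off())
    det, _ = _detect_centroids(
        stack, scene, replace(params, threshold_mode="mean_plus_k_sd", threshold_value=2.0),
        psf, DeconvolutionParams(enabled=False),
    )
    m = seg.match_to_ground_truth(det, scene.positions_um(), match_dist_um)
    out["noiseless"] = {
        "precision": m.precision,
        "recall": m.recall,
        "f1": m.f1,
        "n_true": m.n_true,
    }

    noise = NoiseModel(poisson=True, gaussian_sd=1.0, gain=1.0)
    cfg_noisy = scale_scene_to_peak_snr(
        SceneConfig(seed=seed + 1), psf, peak_snr, noise
    )
    scene_n = generate_scene(cfg_noisy)
    stack_n = render_stack(scene_n, psf, noise)
    det_n, _ = _detect_centroids(
        stack_n, scene_n, params, psf, DeconvolutionParams(enabled=True, n_iter=15)
    )
    m_n = seg.match_to_ground_truth(det_n, scene_n.positions_um(), match_dist_um)
    out["snr5"] = {
        "precision": m_n.precision,
        "recall": m_n.recall,
        "f1": m_n.f1,
        "n_true": m_n.n_true,
        "peak_snr": peak_snr,
    }
    return out


def recovery_benchmark(
    n_samples: int = 20,
    seed: int = 0,
    peak_snr: float = 5.0,
    scene: SceneConfig | None = None,
    deconv_iters: int = 15,
) -> dict[str, Any]:
    """Profile and H recovery on seeded synthetic brains.

    Each brain uses the default study conditions (a three-fold increase of
    the true median from γ1 to γ5) at the requested peak SNR; the pipeline
    estimate of the normalized median profile and of H is scored against
    the generator truth per sample.
    """
    from .psf import fitted_window

    noise = NoiseModel(poisson=True, gaussian_sd=1.0, gain=1.0)
    base = scene or SceneConfig()
    psf = default_psf(window=fitted_window(base.shape))
    base = scale_scene_to_peak_snr(base, psf, peak_snr, noise)
    params = SegmentationParams()
    deconv = DeconvolutionParams(enabled=deconv_iters > 0, n_iter=max(deconv_iters, 1))
    rng = np.random.default_rng(seed)
    profile_errors = []
    h_errors = []
    h_true_all, h_est_all = [], []
    for i in range(n_samples):
        cfg = replace(base, seed=int(rng.integers(2**31 - 1)))
        sc = generate_scene(cfg)
        stack = render_stack(sc, psf, noise, rng=rng)
        res = analyze_sample(
            stack,
            sc.compartment_labels,
            sc.compartment_names,
            params,
            psf=psf,
            deconv=deconv,
            sample_id=f"brain-{i:02d}",
        )
        true_norm = sc.true_medians / sc.true_medians.mean()
        est_norm = res.profile.normalized
        profile_errors.append(np.abs(est_norm - true_norm) / true_norm)
        h_true_all.append(sc.true_H)
        h_est_all.append(res.H)
        h_errors.append(abs(res.H - sc.true_H) / sc.true_H)
    profile_errors = np.array(profile_errors)
    return {
        "n_samples": n_samples,
        "profile_rel_error_max": float(profile_errors.max()),
        "profile_rel_error_mean": float(profile_errors.mean()),
        "per_compartment_rel_error": profile_errors.mean(axis=0).tolist(),
        "h_rel_error_max": float(np.max(h_errors)),
        "h_rel_error_mean": float(np.mean(h_errors)),
        "h_true_mean": float(np.mean(h_true_all)),
        "h_est_mean": float(np.mean(h_est_all)),
    }


def power_benchmark(
    n_runs: int = 100,
    n_per_group: int = 15,
    h_a: float = 0.5,
    h_b: float = 0.25,
    alpha: float = 0.05,
    seed: int = 0,
    peak_snr: float = 5.0,
    scene: SceneConfig | None = None,
    deconv_iters: int = 0,
) -> dict[str, Any]:
    """Rejection rates of pipeline + Mann–Whitney over seeded cohort runs.

    Each run simulates two groups of brains (group A at heterogeneity
    ``h_a``, group B at ``h_b``), runs the full measurement pipeline per
    brain, and tests the per-sample H values. Also runs the matched null
    (both groups at ``h_a``) for the type-I error rate. Uses a reduced grid
    per run so many runs are affordable.
    """
    noise = NoiseModel(poisson=True, gaussian_sd=1.0, gain=1.0)
    base = scene or SceneConfig(
        shape=(12, 48, 128), counts=(15,) * 5, min_separation_um=0.5,
        margin_um=(0.8, 0.4, 0.4),
    )
    from .psf import fitted_window

    # compact PSF window (±4σ) keeps the per-run render FFT small
    psf = default_psf(window=fitted_window(base.shape, (9, 17, 17)))
    base = scale_scene_to_peak_snr(base, psf, peak_snr, noise)
    params = SegmentationParams()
    deconv = DeconvolutionParams(enabled=deconv_iters > 0, n_iter=max(deconv_iters, 1))
    rng = np.random.default_rng(seed)

    def one_run(h_true_b: float, run_seed: int) -> float:
        samples = generate_group_study(
            {"A": n_per_group, "B": n_per_group},
            {"A": h_a, "B": h_true_b},
            base,
            psf,
            noise,
            seed=run_seed,
        )
        hs: dict[str, list[float]] = {"A": [], "B": []}
        for j, s in enumerate(samples):
            res = analyze_sample(
                s.stack,
                s.scene.compartment_labels,
                s.scene.compartment_names,
                params,
                psf=psf,
                deconv=deconv,
                sample_id=f"{s.group}{j}",
                group=s.group,
            )
            if res.heterogeneity is not None:
                hs[s.group].append(res.H)
        return mann_whitney_u(hs["A"], hs["B"]).pvalue

    reject_effect = 0
    reject_null = 0
    for _ in range(n_runs):
        if one_run(h_b, int(rng.integers(2**31 - 1))) < alpha:
            reject_effect += 1
        if one_run(h_a, int(rng.integers(2**31 - 1))) < alpha:
            reject_null += 1
    return {
        "n_runs": n_runs,
        "n_per_group": n_per_group,
        "h_a": h_a,
        "h_b": h_b,
        "power": reject_effect / n_runs,
        "type_i_rate": reject_null / n_runs,
        "alpha": alpha,
    }


def coloc_null_benchmark(
    seed: int = 0, n_rois: int = 4000, rho: float = 0.0
) -> dict[str, Any]:
    """Pipeline colocalization R on paired channels with known correlation.

    Renders ``n_rois`` puncta, segments loose ROIs on channel A (as in the
    rotated-control design), and computes the per-ROI density Pearson R and
    its 180°-rotation control.
    """
    from .coloc import pearson_roi_correlation

    psf = default_psf()
    # oversample puncta so the brightest-first cap at n_rois is met even
    # after merges near the separation limit
    cfg = SceneConfig(
        shape=(44, 288, 352),
        counts=(n_rois // 3,) * 5,
        min_separation_um=0.65,
        margin_um=(0.8, 0.4, 0.4),
        background=1.0,
        log_amp_mean=tuple(np.log(2000.0) for _ in range(5)),
        log_amp_sd=(0.5,) * 5,
        seed=seed,
    )
    scene = generate_scene(cfg)
    noise = NoiseModel(poisson=True, gaussian_sd=1.0)
    stack, a1, a2 = generate_paired_channels(scene, rho, psf, noise, seed=seed + 1)
    cha = stack.channel("chA")
    chb = stack.channel("chB")
    mask, _ = seg.apply_intensity_threshold(cha, "mean_plus_k_sd", 3.0)
    seeds = seg.find_maxima_3d(cha, cfg.voxel_size, mask=mask, min_distance_um=0.4)
    seeds = sorted(seeds, key=lambda s: -s.intensity)[:n_rois]
    loose = seg.SEGMENTATION_PRESETS["loose"]
    rois, _ = seg.segment_spots(
        cha, seeds, cfg.voxel_size, fraction=loose["fraction"],
        max_radius_um=loose["max_radius_um"], dilate=loose["dilate"],
        stats=False,
    )
    res = pearson_roi_correlation(cha, chb, rois)
    true_r = float(np.corrcoef(np.log(a1), np.log(a2))[0, 1]) if len(a1) > 2 else np.nan
    return {
        "n_rois": res.n_rois,
        "r": res.r,
        "r_control": res.r_control,
        "rho": rho,
        "true_log_amplitude_r": true_r,
    }
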