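"""Simulate a small brain volume and run the measurement pipeline on it.

A synthetic scene places puncta with per-compartment lognormal amplitudes,
renders them through a confocal-like PSF with Poisson + read noise, and the
pipeline recovers the per-compartment median profile and H. Ground truth is
known, so the recovery error is printed alongside.
"""

import numpy as np

from azquant.benchmarks import default_psf, scale_scene_to_peak_snr
from azquant.pipeline import DeconvolutionParams, SegmentationParams, analyze_sample
from azquant.psf import fitted_window
from azquant.synthetic import NoiseModel, SceneConfig, generate_scene, render_stack

cfg = SceneConfig(shape=(20, 64, 200), counts=(40,) * 5, seed=42)
noise = NoiseModel(poisson=True, gaussian_sd=1.0)
psf = default_psf(window=fitted_window(cfg.shape))
cfg = scale_scene_to_peak_snr(cfg, psf, peak_snr=5.0, noise=noise)

scene = generate_scene(cfg)
stack = render_stack(scene, psf, noise)
res = analyze_sample(
    stack,
    compartment_labels=scene.compartment_labels,
    compartment_names=scene.compartment_names,
    params=SegmentationParams(),
    psf=psf,
    deconv=DeconvolutionParams(enabled=True, n_iter=10),
    sample_id="demo",
)

true_norm = scene.true_medians / scene.true_medians.mean()
print("clusters per compartment:", res.profile.counts.tolist())
print("true normalized profile:", np.round(true_norm, 3))
print("est. normalized profile:", np.round(res.profile.normalized, 3))
print(f"true H* = {scene.true_H:.4f}   estimated H = {res.H:.4f}")
# The estimated profile tracks the generator's 3-fold gamma1->gamma5 ramp;
# the residual differences reflect detection and median sampling noise.
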