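"""Estimate an experimental PSF from a bead field and deconvolve a render.

Sub-resolution beads are simulated, detected, windowed and averaged into a
single unit-sum PSF; Richardson-Lucy deconvolution with that PSF then
sharpens a noisy punctum render, which shows as an increased peak-to-mean
contrast at the true punctum centres.
"""

import numpy as np

from azquant.psf import average_psfs, detect_beads, extract_psf, richardson_lucy, synthetic_gaussian_psf
from azquant.synthetic import NoiseModel, SceneConfig, generate_bead_field, generate_scene, render_stack

true_psf = synthetic_gaussian_psf((0.5, 0.15, 0.15), window=(11, 21, 21))
beads, positions = generate_bead_field(
    6, 3000.0, true_psf, min_separation_um=3.0, shape=(40, 128, 128), seed=1
)
centroids = detect_beads(beads, min_separation_um=2.0)
candidates = [extract_psf(beads, c, window=true_psf.kernel.shape) for c in centroids]
est_psf = average_psfs(candidates, beads.voxel_size)
cos = (est_psf.kernel * true_psf.kernel).sum() / np.sqrt(
    (est_psf.kernel**2).sum() * (true_psf.kernel**2).sum()
)
print(f"beads detected: {len(centroids)}; PSF cosine similarity to truth: {cos:.4f}")

cfg = SceneConfig(shape=(20, 64, 160), counts=(15,) * 5, seed=2)
scene = generate_scene(cfg)
stack = render_stack(scene, true_psf, NoiseModel(poisson=True, gaussian_sd=1.0))
raw = stack.channel("puncta").astype(float)
dec = richardson_lucy(raw, est_psf, n_iter=15)

peaks = lambda v: np.median([v[p.voxel] for p in scene.puncta])
print(f"peak/mean contrast raw:         {peaks(raw) / raw.mean():6.1f}")
print(f"peak/mean contrast deconvolved: {peaks(dec) / dec.mean():6.1f}")
# Deconvolution concentrates each punctum's flux, raising the contrast at
# true punctum centres; total intensity is conserved.
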