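"""ROI-density colocalization with the 180°-rotation chance baseline.

Two channels are rendered at the same puncta with a log-space amplitude
correlation of 0.8. ROIs are segmented on channel A with the wide-ROI
preset and reused for channel B; Pearson R of the per-ROI signal densities
is compared against the same computation with channel B rotated 180°
in-plane, which estimates the correlation expected by chance.
"""

import numpy as np

from azquant import segmentation as seg
from azquant.benchmarks import default_psf
from azquant.coloc import pearson_roi_correlation
from azquant.synthetic import NoiseModel, SceneConfig, generate_paired_channels, generate_scene

cfg = SceneConfig(
    shape=(24, 96, 200),
    counts=(80,) * 5,
    min_separation_um=0.7,
    log_amp_mean=(np.log(2000.0),) * 5,
    log_amp_sd=(0.5,) * 5,
    background=1.0,
    seed=5,
)
scene = generate_scene(cfg)
psf = default_psf(window=(15, 25, 25))
stack, a1, a2 = generate_paired_channels(
    scene, rho=0.8, psf=psf, noise=NoiseModel(poisson=True, gaussian_sd=1.0)
)
cha, chb = stack.channel("chA"), stack.channel("chB")

mask, _ = seg.apply_intensity_threshold(cha, "mean_plus_k_sd", 3.0)
seeds = seg.find_maxima_3d(cha, cfg.voxel_size, mask=mask, min_distance_um=0.4)
loose = seg.SEGMENTATION_PRESETS["loose"]
rois, _ = seg.segment_spots(
    cha, seeds, cfg.voxel_size, fraction=loose["fraction"],
    max_radius_um=loose["max_radius_um"], dilate=loose["dilate"], stats=False,
)
res = pearson_roi_correlation(cha, chb, rois)

print(f"ROIs analyzed:        {res.n_rois}")
print(f"signal R:             {res.r:.3f}")
print(f"rotated control R:    {res.r_control:.3f}")
print(f"true amplitude R:     {np.corrcoef(np.log(a1), np.log(a2))[0, 1]:.3f}")
# A signal R far above the near-zero control indicates genuine per-punctum
# co-enrichment rather than shared background structure.
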