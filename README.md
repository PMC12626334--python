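# azquant

Quantification of presynaptic active-zone (AZ) punctum heterogeneity in 3D
fluorescence stacks.

## The problem

Presynaptic AZs appear as diffraction-limited puncta when a scaffold protein
such as Bruchpilot (Brp) is fluorescently labelled. In the fly mushroom-body
γ lobe, a single Kenyon-cell axon traverses five anatomical compartments
(γ1–γ5), and the brightness of its AZ puncta differs systematically between
compartments. `azquant` implements the image-analysis chain needed to
quantify that compartmental structure from conventional confocal stacks:

1. **PSF estimation and deconvolution** — an experimental point-spread
   function is averaged from sub-resolution bead images (default window
   21 × 32 × 32 voxels at 0.370 × 0.079 × 0.079 µm) and used for
   Richardson–Lucy restoration,
       e_{k+1} = e_k · ( PSF* ⊛ ( I / (PSF ⊛ e_k) ) ).
2. **3D spot segmentation** — intensity threshold, 26-neighbourhood 3D
   maxima, seeded region growing (voxels ≥ f·seed intensity within a
   physical radius), per-cluster intensity statistics. All distances are in
   µm, respecting the ~4.7× axial anisotropy.
3. **The heterogeneity statistic** — per sample, the median punctum
   intensity M_c of each compartment c ∈ {γ1..γ5}; the normalized profile
   M̃_c = M_c / mean(M_c); and the heterogeneity level
       H = SD( log₂ M_c ,  c = 1..5 )   (n−1 denominator),
   which is invariant to global brightness and to per-compartment punctum
   counts.
4. **Colocalization control** — per-ROI signal density (total grey value /
   ROI volume) of two channels over one ROI set segmented from the first
   channel; Pearson R, with the second channel rotated 180° in-plane as the
   chance baseline.
5. **Ratiometric calcium normalization** — frame-wise division of a sensor
   channel by a stable reference with a floor guard, then per-compartment
   basal means.
6. **Group statistics** — exact/normal Mann–Whitney U, Kruskal–Wallis,
   repeated-measures and log-transformed one-way ANOVA, Pearson R, and
   Benjamini–Hochberg FDR for post-hoc families (q = 0.05).

Because raw stacks of this kind are rarely shareable, the package ships a
first-class synthetic-scene generator (`azquant.synthetic`) that renders
ground-truth puncta through the same optics/noise model the analysis
assumes, so every stage is validated end-to-end against known truth.

## Worked example

```python
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
    stack, scene.compartment_labels, scene.compartment_names,
    SegmentationParams(), psf=psf,
    deconv=DeconvolutionParams(enabled=True, n_iter=10), sample_id="demo",
)
print(np.round(res.profile.normalized, 3), round(res.H, 4))
```

Running the full version of this script, `examples/02_simulate_and_measure.py`,
prints:

```
true normalized profile: [0.532 0.643 0.907 1.248 1.671]
est. normalized profile: [0.564 0.664 0.833 1.24  1.7  ]
true H* = 0.6756   estimated H = 0.6543
```

The estimated profile tracks the generator's three-fold γ1→γ5 intensity
ramp, and the estimated heterogeneity H is within a few percent of the
scene's true H*. The `examples/` directory contains one short script per
capability (statistic, simulation+measurement, PSF/deconvolution,
colocalization, calcium ratio, group comparison).

A thin CLI mirrors the library for shell use:

```bash
azquant simulate --out sim/            # render a synthetic brain + truth
azquant segment sim/stack.tif --mask sim/compartments.tif --out seg/
azquant stats --groups cohort.csv      # tidy (sample, group, value) CSV
azquant benchmark --seed 0             # reduced-scale validation report
```

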