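"""A two-group synthetic cohort compared on heterogeneity level.

Emulates a fed-vs-starved style design: group "fed" brains carry a true
heterogeneity of 0.5, group "starved" 0.25, plus per-brain global
brightness jitter. The pipeline measures H per brain and compares groups
with a two-sided Mann-Whitney U test.
"""

import numpy as np

from azquant.pipeline import DeconvolutionParams, PipelineConfig, run_pipeline
from azquant.synthetic import NoiseModel, SceneConfig

config = PipelineConfig(
    scene=SceneConfig(
        shape=(14, 48, 140),
        counts=(20,) * 5,
        min_separation_um=0.6,
        margin_um=(0.8, 0.4, 0.4),
        seed=0,
    ),
    noise=NoiseModel(poisson=True, gaussian_sd=1.0),
    deconvolution=DeconvolutionParams(enabled=False),
    groups={"fed": 8, "starved": 8},
    h_true={"fed": 0.5, "starved": 0.25},
    seed=123,
)
bundle = run_pipeline(config)

for group in config.groups:
    hs = [s.H for s in bundle["samples"] if s.group == group and np.isfinite(s.H)]
    print(f"{group:8s} H: mean {np.mean(hs):.3f}  (n = {len(hs)})")
test = bundle["tests"][0]
print(f"Mann-Whitney U = {test.statistic:.1f}, two-sided p = {test.pvalue:.4g}")
# A small p indicates the measured per-brain H separates the groups; the
# statistic is computed on pipeline-estimated H, not on the generator truth.
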