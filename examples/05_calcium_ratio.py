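"""Ratiometric normalization of a calcium-sensor time series.

A two-channel series emulates a GCaMP-type sensor fused to a stable red
fluorophore: dividing signal by reference frame-by-frame cancels
expression-level differences, and averaging stimulus-free frames per
compartment yields basal calcium-level estimates.
"""

import numpy as np

from azquant.coloc import compartment_basal_mean, ratiometric_normalize
from azquant.synthetic import NoiseModel, generate_ratiometric_series

true_ratios = (1.0, 1.0, 2.0, 2.0, 3.0)
stack, labels = generate_ratiometric_series(
    n_frames=100,
    ratios=true_ratios,
    reference_level=100.0,
    noise=NoiseModel(poisson=False, gaussian_sd=8.0),
    seed=11,
)
ratio = ratiometric_normalize(stack)

print("compartment   true   estimated")
for ci, r_true in enumerate(true_ratios, start=1):
    est = compartment_basal_mean(ratio, labels == ci)
    print(f"   gamma{ci}     {r_true:4.1f}    {est:7.4f}")
# With a clean reference channel the ratio estimator is unbiased; the
# estimates sit within sampling error of the programmed ratios.
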