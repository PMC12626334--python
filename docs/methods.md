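# Methods

This note documents the models, defaults and numerical choices behind
`azquant`, and what the simulation-based validation does and does not show.

## Measurement model

A punctum (one active zone) is treated as a sub-resolution point source of
amplitude *a* (photons). The observed single channel is

    I(x) = Poisson( gain · [ b + Σ_i a_i · PSF(x − x_i) ] ) + N(0, σ_g²),

clipped at zero: *b* is a uniform background, PSF is the unit-sum system
kernel, and σ_g is Gaussian read noise. Peak SNR of a punctum is defined as
s / √(s + b + σ_g²) with s = a · max(PSF), i.e. peak signal over the noise
SD at the peak under this model.

### PSF

The experimental-PSF path detects isolated beads (connected components
above mean + 4 SD, intensity-weighted centroids, pairs closer than a
minimum separation are both discarded — aggregation corrupts the average),
extracts a window around each (default 21 z × 32 y × 32 x voxels at
0.370/0.079/0.079 µm), subtracts the window-border median, clips negatives,
and averages candidates into a unit-sum kernel. The synthetic fallback is a
separable anisotropic Gaussian, default σ = (0.5, 0.15, 0.15) µm zyx
(FWHM ≈ 1.18 µm axial / 0.35 µm lateral — a typical high-NA confocal).

### Richardson–Lucy

The iteration e_{k+1} = e_k · (PSF* ⊛ (I / max(PSF ⊛ e_k, ε))) starts from
a *flat image at the observed mean* — an intentionally uninformative start
that also makes the delta-PSF case return the observation exactly after one
iteration. Boundaries use reflective padding (no FFT wrap-around); ε
defaults to 1e-12; the default iteration count is 30 (config). Kernels
with even axes are zero-padded by one trailing plane so the kernel peak
coincides with the convolution centre; otherwise the forward/adjoint pair
would be misaligned by one voxel and the iteration would drift. Convolution
runs in the frequency domain; equality with direct convolution is asserted
on small grids in the tests.

## Detection and measurement

Stage order: (optional) deconvolve → threshold → find 3D maxima → grow
ROIs → extract per-cluster statistics → per-compartment medians → H.

* **Threshold** modes: absolute, mean + k·SD (default k = 3), percentile.
  The realized value is always recorded.
* **Maxima**: a voxel ≥ all 26 neighbours inside the mask; optional noise
  tolerance (peak minus dimmest neighbour ≥ tolerance); equal-valued
  plateaus contribute one seed at the lexicographically smallest (z,y,x);
  of any pair closer than `min_distance_um` (default 0.4 µm, *physical*
  distance) only the brighter survives.
* **Region growing**: 26-connected voxels with intensity ≥
  max(f · seed, floor), f = 0.5 by default, capped at 0.6 µm from the seed.
  Contested voxels go to the first (brighter-seeded) region by default —
  a watershed-free behaviour; nearest-seed splitting is available for dense
  scenes. The `loose` preset (f = 0.1, radius cap 0.35 µm, no dilation)
  produces wide ROIs of nearly constant volume for colocalization — see
  below for why constant volume matters.
* **Measure on raw**: when deconvolution is enabled it defines *geometry
  only* (seeds and ROI shapes); intensity statistics are extracted from the
  raw volume. Partially converged RL redistributes flux at a rate that
  depends on local contrast, which biases *ratios* of per-cluster
  intensities between dim and bright compartments; the raw image has no
  such bias, while the sharpened image still gives cleaner detection and
  compact ROIs. With this split the recovered normalized profile is
  accurate to a few percent where either image alone shows 15–20% bias at
  peak SNR 5.
* **Background correction**: the median of sub-threshold voxels inside the
  lobe is subtracted from per-cluster statistics (mean/median/max per
  voxel; sum per voxel count), so medians estimate signal above background.
  Without it the additive background compresses the normalized profile.
* **Per-cluster statistic**: the compartment median is taken over
  per-cluster *mean* voxel intensity by default (volume-robust); sum, max
  and median are selectable and recorded.

## The heterogeneity statistic

H = sample SD (n−1) of log₂ M_c over the five compartment medians.
Properties relied on downstream: H ≥ 0 with equality iff all medians are
equal; exact invariance to global rescaling (between-sample brightness);
insensitivity to per-compartment punctum counts (medians). Log base 2 is
the package convention (shared with the pseudo-colour maps,
log₂(I / lobe mean)); the base and denominator choice are recorded in every
result. The n−1 denominator was chosen over n; with five fixed compartments
the choice is a constant factor and does not affect comparisons.

Samples with any empty compartment have no defined H; they are flagged and
excluded rather than imputed. The pseudo-colour lobe mean is computed over
the full lobe mask (not only signal-positive voxels); zero voxels map to
the lower clip.

## Synthetic scenes — what they emulate

The generator is the package's ground truth. Geometry: five equal slabs
along x mimic the γ lobe's linear compartment order (arbitrary label
volumes accepted). Placement: rejection sampling with a minimum pairwise
physical separation (default 0.8 µm), positions snapped to voxel centres.
Amplitudes: i.i.d. lognormal per compartment — intensities are positive
and right-skewed, and the analysis' log-transform presumes multiplicative
structure. Default true profile: median amplitude rising three-fold from
γ1 to γ5. Background: b = 2 photons, read noise σ_g = 1, gain 1 — a dim-
background GaAsP-detector-like regime; SNR-critical experiments rescale
amplitudes to a stated peak SNR (5 unless noted) for the scene's
geometric-mean median punctum. The membrane-reference channel is a
smoothed lobe-mask indicator. Scene truth records realized per-compartment
amplitude medians and H* computed by the *same* `heterogeneity_sd` code the
pipeline uses.

Group studies spread the five log₂ medians mean-preservingly with the unit-
SD pattern (−2,−1,0,1,2)/√2.5 scaled by the target H, and multiply each
sample's amplitudes by a lognormal brightness jitter (log-SD 0.2) that the
statistic must cancel.

Not emulated: realistic axon geometry, spatially varying background,
punctum substructure (STED-scale rings), depth-dependent PSF, motion or
bleaching. Passing these simulations therefore demonstrates correctness of
the *computational chain* under the stated noise model, not robustness to
every property of real tissue.

## Colocalization

Per-ROI signal density (sum / volume) is computed for both channels over
the ROI set segmented from channel A; Pearson R is reported with a control
in which channel B is rotated 180° per z-slice (full 3D point reflection
optional; the choice is recorded). Rotation preserves the marginal
intensity distribution exactly, so a non-zero control R flags structured
background.

ROI volume must be nearly constant across ROIs: if ROI size varies with the
channel-A amplitude (as it does for threshold-defined loose ROIs over a
noise floor), both channels' densities are diluted by the shared volume and
acquire a spurious positive correlation even for independent amplitudes.
The `loose` preset therefore caps ROIs at a fixed physical radius with a
low inclusion fraction (volume CV < 10%), which brings the independent-
channel R down to the sampling-noise level (|R| ≈ 1/√n). When more ROIs
exist than requested, the brightest seeds are kept first (recorded).

Ratiometric series: noise is applied to the sensor channel only — the
reference models a stable structural fluorophore — so the expected
frame-wise ratio equals the programmed value exactly and the basal-mean
estimator is unbiased; reference voxels below 5% of the channel's 99th
percentile are masked rather than divided.

## Statistics

All tests are two-sided. Mann–Whitney U: exact permutation null (counting
recurrence, equivalent to full enumeration) when n+m ≤ 12 without ties;
otherwise mid-rank normal approximation with tie-corrected variance and
continuity correction; zero null variance gives p = 1. Kruskal–Wallis:
tie-corrected H with χ²(k−1) p (scipy). RM one-way ANOVA:
F = MS_condition / MS_condition×subject, df (k−1, (k−1)(n−1)), no
sphericity correction (flagged when k > 2). One-way ANOVA on logs errors
on nonpositive data and is invariant to common rescaling. BH-FDR: the
original step-up procedure at q = 0.05 (statsmodels), with adjusted
p-values monotone-enforced. Which p-value (exact vs approximate) was
computed is recorded in every result.

## Validation problem sizes

Chosen as desk-scale defaults; all seeds explicit.

* Profile/H recovery: 20 brains of 40 × 128 × 256 voxels, 150
  puncta/compartment, peak SNR 5, RL 15 iterations.
* Detection: noiseless scene with ≥ 3× the largest PSF FWHM separation
  (perfect-score regime) and a default-density scene at peak SNR 5,
  matching radius 0.3 µm, optimal bipartite assignment (greedy available
  and labelled).
* Colocalization: 4000 brightest ROIs from ~6600 puncta in a
  44 × 288 × 352 grid, ρ ∈ {0, 0.9}.
* Power: 100 cohort runs × 2 (effect and null), 15 samples/group on a
  reduced 12 × 48 × 128 grid with 15 puncta/compartment, deconvolution off
  for this screen (detection is unambiguous at this density and the H
  contrast, not restoration, is under test).

## Known limitations

* Region growing assigns contested voxels greedily by seed brightness in
  the default (watershed-free) mode; for very dense scenes use
  `split="nearest-seed"`.
* H estimated from moderate cluster counts is slightly inflated by median
  sampling noise (a variance, not a bias of the statistic itself); group
  comparisons are unaffected because both groups share the inflation.
* The exact Mann–Whitney path requires tie-free data; measured intensities
  in practice are effectively continuous.
* TIFF support covers plain multi-page and ImageJ-style files with voxel
  size in metadata; proprietary microscope formats are out of scope (pass
  an explicit voxel-size override after conversion).
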