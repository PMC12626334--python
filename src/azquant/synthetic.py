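"""Ground-truth scene generation and stack rendering.

Because the study's raw confocal stacks are not deposited, every stage of
the pipeline is validated on simulated data with the statistical structure
the analysis assumes: diffraction-limited puncta with per-compartment
lognormal amplitude distributions, PSF blurring, Poisson shot noise plus
Gaussian read noise, a smooth membrane-reference channel, paired channels
with controllable amplitude correlation, and ratiometric two-channel time
series. The generator records the true per-compartment amplitude medians
and the true heterogeneity H* (computed with the same statistic as the
pipeline), providing an automated stand-in for manually annotated ground
truth.

Geometry defaults emulate the γ-lobe's linear compartment order: five equal
slabs along x. Amplitudes are lognormal — fluorescence intensities are
positive and right-skewed, and the pipeline's log-transform presumes
multiplicative structure. All randomness flows from one NumPy PCG64
generator seeded in the config.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import ndimage

from .heterogeneity import GAMMA_COMPARTMENTS, heterogeneity_sd
from .psf import PSFModel, convolve_psf
from .stack_io import DEFAULT_VOXEL_SIZE_UM, ImageStack, VoxelSize

__all__ = [
    "SceneConfig",
    "NoiseModel",
    "Punctum",
    "SyntheticScene",
    "slab_compartments",
    "generate_scene",
    "render_stack",
    "generate_bead_field",
    "generate_paired_channels",
    "generate_ratiometric_series",
    "generate_group_study",
    "GroupSample",
]

# Mean-preserving spread pattern over the five compartments, unit sample SD
# in log space: H of a scene built from it scales linearly with the factor.
_SPREAD = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
_SPREAD = _SPREAD / np.std(_SPREAD, ddof=1)


@dataclass
class NoiseModel:
    """Standard fluorescence camera model: Poisson shot noise on
    gain-scaled photon counts plus additive Gaussian read noise."""

    poisson: bool = True
    gaussian_sd: float = 1.0
    gain: float = 1.0

    def __post_init__(self) -> None:
        if self.gaussian_sd < 0:
            raise ValueError("gaussian_sd must be >= 0")
        if self.gain <= 0:
            raise ValueError("gain must be > 0")

    @classmethod
    def off(cls) -> "NoiseModel":
        return cls(poisson=False, gaussian_sd=0.0, gain=1.0)

    def apply(self, expected: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        out = expected * self.gain
        if self.poisson:
            out = rng.poisson(np.maximum(out, 0)).astype(float)
        if self.gaussian_sd > 0:
            out = out + rng.normal(0.0, self.gaussian_sd, size=out.shape)
        return np.clip(out, 0, None)


@dataclass
class SceneConfig:
    """Study conditions for one synthetic brain volume.

    ``log_amp_mean``/``log_amp_sd`` are the natural-log parameters of the
    per-compartment lognormal amplitude distributions (amplitudes in
    photons); the distribution median of compartment c is exp(µ_c). The
    defaults put the median punctum three-fold brighter in γ5 than in γ1
    with moderate within-compartment spread, on a dim uniform background —
    the regime the compartmental-heterogeneity analysis addresses.
    """

    shape: tuple[int, int, int] = (40, 128, 256)
    voxel_size: VoxelSize | tuple[float, float, float] = DEFAULT_VOXEL_SIZE_UM
    counts: tuple[int, ...] = (150, 150, 150, 150, 150)
    # median amplitudes 2500 -> 7500 photons: with the default confocal-like
    # PSF (max ~0.013) this gives punctum peaks comfortably above the dim
    # background, i.e. a bright structural-marker regime
    log_amp_mean: tuple[float, ...] = tuple(
        np.log(2500.0) + np.log(3.0) * np.linspace(0, 1, 5)
    )
    log_amp_sd: tuple[float, ...] = (0.35,) * 5
    min_separation_um: float = 0.8
    margin_um: tuple[float, float, float] = (1.0, 0.5, 0.5)
    background: float = 2.0
    membrane_level: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.voxel_size = VoxelSize.coerce(self.voxel_size)
        k = len(self.counts)
        if not (len(self.log_amp_mean) == len(self.log_amp_sd) == k):
            raise ValueError("counts, log_amp_mean, log_amp_sd must have equal length")
        if any(c < 0 for c in self.counts):
            raise ValueError("counts must be >= 0")
        if any(s < 0 for s in self.log_amp_sd):
            raise ValueError("log_amp_sd must be >= 0")
        if self.min_separation_um < 0:
            raise ValueError("min_separation_um must be >= 0")

    @property
    def n_compartments(self) -> int:
        return len(self.counts)


@dataclass(frozen=True)
class Punctum:
    position_um: tuple[float, float, float]
    voxel: tuple[int, int, int]
    amplitude: float
    compartment: int  # 1-based label


@dataclass
class SyntheticScene:
    """Ground truth: puncta, compartment labels, true medians and H*."""

    puncta: list[Punctum]
    config: SceneConfig
    compartment_labels: np.ndarray
    true_medians: np.ndarray
    true_H: float
    rng_algorithm: str = "numpy.random.PCG64"

    def positions_um(self, compartment: int | None = None) -> np.ndarray:
        pts = [
            p.position_um
            for p in self.puncta
            if compartment is None or p.compartment == compartment
        ]
        return np.array(pts, dtype=float).reshape(-1, 3)

    def amplitudes(self, compartment: int | None = None) -> np.ndarray:
        return np.array(
            [
                p.amplitude
                for p in self.puncta
                if compartment is None or p.compartment == compartment
            ]
        )

    @property
    def compartment_names(self) -> dict[int, str]:
        n = self.config.n_compartments
        if n == 5:
            return {i + 1: GAMMA_COMPARTMENTS[i] for i in range(5)}
        return {i + 1: f"c{i + 1}" for i in range(n)}


def slab_compartments(shape: tuple[int, int, int], n: int = 5) -> np.ndarray:
    """Label volume of ``n`` equal slabs along x (1..n), the default layout."""
    z, y, x = shape
    edges = np.linspace(0, x, n + 1).astype(int)
    labels = np.zeros(shape, dtype=np.int32)
    for i in range(n):
        labels[:, :, edges[i] : edges[i + 1]] = i + 1
    return labels


def generate_scene(
    config: SceneConfig, compartment_labels: np.ndarray | None = None
) -> SyntheticScene:
    """Place puncta with minimum separation and draw lognormal amplitudes.

    Placement is rejection sampling (Poisson-disk-like): candidate voxels
    are drawn uniformly inside the compartment (respecting ``margin_um``
    from the stack border) and rejected when closer than
    ``min_separation_um`` (physical distance) to an accepted punctum.
    Positions are voxel centres, reported in µm. Raises when the requested
    packing cannot be met within bounded retries.
    """
    rng = np.random.default_rng(config.seed)
    labels = (
        slab_compartments(config.shape, config.n_compartments)
        if compartment_labels is None
        else np.asarray(compartment_labels)
    )
    vs = VoxelSize.coerce(config.voxel_size)
    scale = np.array(vs.zyx)
    margin_vox = np.ceil(np.asarray(config.margin_um) / scale).astype(int)

    accepted_pos: list[np.ndarray] = []
    puncta: list[Punctum] = []
    for ci, count in enumerate(config.counts, start=1):
        comp_vox = np.argwhere(labels == ci)
        inside = (
            (comp_vox >= margin_vox).all(axis=1)
            & (comp_vox < np.array(config.shape) - margin_vox).all(axis=1)
        )
        comp_vox = comp_vox[inside]
        if count > 0 and len(comp_vox) == 0:
            raise ValueError(f"compartment {ci} has no voxels inside the margins")
        placed = 0
        attempts = 0
        max_attempts = max(200 * count, 1000)
        amps = rng.lognormal(config.log_amp_mean[ci - 1], config.log_amp_sd[ci - 1], count)
        while placed < count:
            if attempts >= max_attempts:
                raise RuntimeError(
                    f"infeasible packing: placed {placed}/{count} puncta in "
                    f"compartment {ci} after {attempts} attempts"
                )
            attempts += 1
            voxel = comp_vox[rng.integers(len(comp_vox))]
            pos = voxel * scale
            if config.min_separation_um > 0 and accepted_pos:
                d2 = ((np.asarray(accepted_pos) - pos) ** 2).sum(axis=1)
                if d2.min() < config.min_separation_um**2:
                    continue
            accepted_pos.append(pos)
            puncta.append(
                Punctum(
                    position_um=tuple(float(v) for v in pos),
                    voxel=tuple(int(v) for v in voxel),
                    amplitude=float(amps[placed]),
                    compartment=ci,
                )
            )
            placed += 1

    medians = np.array(
        [
            np.median([p.amplitude for p in puncta if p.compartment == ci])
            if config.counts[ci - 1] > 0
            else np.nan
            for ci in range(1, config.n_compartments + 1)
        ]
    )
    finite = medians[np.isfinite(medians)]
    true_H = heterogeneity_sd(finite) if len(finite) >= 2 else np.nan
    return SyntheticScene(puncta, config, labels, medians, float(true_H))


def _delta_volume(scene: SyntheticScene, amplitudes: np.ndarray | None = None) -> np.ndarray:
    vol = np.zeros(scene.config.shape, dtype=float)
    amps = scene.amplitudes() if amplitudes is None else np.asarray(amplitudes)
    for p, a in zip(scene.puncta, amps):
        vol[p.voxel] += a
    return vol


def render_stack(
    scene: SyntheticScene,
    psf: PSFModel,
    noise: NoiseModel | None = None,
    rng: np.random.Generator | None = None,
    amplitudes: np.ndarray | None = None,
) -> ImageStack:
    """Render the observable two-channel stack for a scene.

    Channel ``puncta`` is background + Σ amplitude·PSF(x − x_punctum)
    passed through the noise model; channel ``membrane`` is a smoothed
    indicator of the lobe mask at ``membrane_level`` (the CD4::tdTomato-like
    reference used for compartment identification, density area and
    ratiometric division).
    """
    cfg = scene.config
    if noise is None:
        noise = NoiseModel.off()
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    if any(k > s for k, s in zip(psf.kernel.shape, cfg.shape)):
        raise ValueError("PSF kernel larger than the scene grid")
    expected = convolve_psf(_delta_volume(scene, amplitudes), psf.kernel) + cfg.background
    ch1 = noise.apply(expected, rng)
    membrane = ndimage.gaussian_filter(
        (scene.compartment_labels > 0).astype(float), sigma=2.0
    ) * cfg.membrane_level
    ch2 = noise.apply(membrane, rng)
    return ImageStack(
        np.stack([ch1, ch2]), cfg.voxel_size, ["puncta", "membrane"]
    )


def generate_bead_field(
    n_beads: int,
    amplitude: float,
    psf: PSFModel,
    noise: NoiseModel | None = None,
    min_separation_um: float = 3.0,
    shape: tuple[int, int, int] = (60, 192, 192),
    seed: int = 0,
) -> tuple[ImageStack, np.ndarray]:
    """Render a calibration field of sub-resolution beads.

    Beads are delta objects blurred by ``psf``; their true positions (µm,
    zyx rows) are returned so PSF extraction can be checked against the
    generating kernel. The margin keeps every bead a full PSF window from
    the border.
    """
    vs = psf.voxel_size
    scale = np.array(vs.zyx)
    margin = (np.array(psf.kernel.shape) // 2 + 1) * scale
    cfg = SceneConfig(
        shape=shape,
        voxel_size=vs,
        counts=(n_beads,),
        log_amp_mean=(float(np.log(amplitude)),),
        log_amp_sd=(0.0,),
        min_separation_um=min_separation_um,
        margin_um=tuple(margin),
        background=0.0,
        seed=seed,
    )
    scene = generate_scene(cfg, compartment_labels=np.ones(shape, dtype=np.int32))
    stack = render_stack(scene, psf, noise or NoiseModel.off())
    beads = ImageStack(stack.data[:1], vs, ["beads"])
    return beads, scene.positions_um()


def paired_amplitudes(
    a1: np.ndarray,
    rho: float,
    rng: np.random.Generator,
    log_mean: float,
    log_sd: float,
) -> np.ndarray:
    """Second-channel amplitudes sharing a Gaussian copula (correlation
    ``rho`` in log space) with ``a1``, back-transformed to lognormal with
    the given log-mean and log-SD."""
    loga = np.log(np.asarray(a1, dtype=float))
    sd = loga.std()
    z1 = (loga - loga.mean()) / sd if sd > 0 else np.zeros_like(loga)
    z2 = rho * z1 + np.sqrt(max(0.0, 1.0 - rho**2)) * rng.standard_normal(len(loga))
    return np.exp(log_mean + log_sd * z2)


def generate_paired_channels(
    scene: SyntheticScene,
    rho: float,
    psf: PSFModel,
    noise: NoiseModel | None = None,
    seed: int | None = None,
    amp2_log_mean: float | None = None,
    amp2_log_sd: float | None = None,
) -> tuple[ImageStack, np.ndarray, np.ndarray]:
    """Two signal channels whose per-punctum amplitudes share a Gaussian
    copula with correlation ``rho`` in log space.

    Emulates the co-enrichment of an active-zone scaffold channel with a
    calcium-channel channel at the same puncta. Returns
    ``(stack, amplitudes_A, amplitudes_B)``; the stack has channels
    ``chA``/``chB`` rendered from the same punctum positions.
    """
    if not -1.0 <= rho <= 1.0:
        raise ValueError("rho must be in [-1, 1]")
    cfg = scene.config
    rng = np.random.default_rng(cfg.seed + 2 if seed is None else seed)
    a1 = scene.amplitudes()
    mu2 = float(np.mean(cfg.log_amp_mean)) if amp2_log_mean is None else amp2_log_mean
    sd2 = float(np.mean(cfg.log_amp_sd)) if amp2_log_sd is None else amp2_log_sd
    a2 = paired_amplitudes(a1, rho, rng, mu2, sd2)
    noise = noise or NoiseModel.off()
    chA = noise.apply(
        convolve_psf(_delta_volume(scene, a1), psf.kernel) + cfg.background, rng
    )
    chB = noise.apply(
        convolve_psf(_delta_volume(scene, a2), psf.kernel) + cfg.background, rng
    )
    stack = ImageStack(np.stack([chA, chB]), cfg.voxel_size, ["chA", "chB"])
    return stack, a1, a2


def generate_ratiometric_series(
    n_frames: int,
    ratios: Sequence[float],
    reference_level: float = 100.0,
    noise: NoiseModel | None = None,
    shape: tuple[int, int, int] = (8, 32, 80),
    voxel_size: VoxelSize | Sequence[float] = DEFAULT_VOXEL_SIZE_UM,
    compartment_labels: np.ndarray | None = None,
    seed: int = 0,
) -> tuple[ImageStack, np.ndarray]:
    """Two-channel time series emulating a ratiometric sensor.

    Inside compartment c the signal channel has expectation
    ``ratios[c-1] · reference_level`` in every frame; the reference channel
    is the constant ``reference_level``. Noise is applied to the signal
    channel only (the reference models a stable structural fluorophore), so
    the frame-wise expected ratio equals ``ratios[c-1]`` exactly. Returns
    ``(stack, labels)`` with stack axes (t, c, z, y, x) and channels
    ``signal``/``reference``.
    """
    if n_frames < 1:
        raise ValueError("need at least one frame")
    labels = (
        slab_compartments(shape, len(ratios))
        if compartment_labels is None
        else np.asarray(compartment_labels)
    )
    rng = np.random.default_rng(seed)
    noise = noise or NoiseModel.off()
    r_map = np.zeros(shape, dtype=float)
    for ci, r in enumerate(ratios, start=1):
        r_map[labels == ci] = r
    frames = []
    ref = np.full(shape, float(reference_level))
    for _ in range(n_frames):
        sig = noise.apply(r_map * reference_level, rng)
        frames.append(np.stack([sig, ref]))
    stack = ImageStack(
        np.stack(frames), VoxelSize.coerce(voxel_size), ["signal", "reference"]
    )
    return stack, labels


@dataclass
class GroupSample:
    group: str
    scene: SyntheticScene
    stack: ImageStack
    brightness: float  # multiplicative global jitter applied to amplitudes


def scene_config_for_h(
    base: SceneConfig, h_true: float, median_scale: float = 1.0
) -> SceneConfig:
    """Config whose per-compartment amplitude medians have log₂ sample SD
    ``h_true`` (mean-preserving spread around the base's mean log-median)."""
    n = base.n_compartments
    pattern = _SPREAD if n == 5 else (
        (np.arange(n) - (n - 1) / 2) / np.std(np.arange(n), ddof=1)
    )
    mean_log = float(np.mean(base.log_amp_mean))
    log_medians = mean_log + h_true * np.log(2.0) * pattern + np.log(median_scale)
    return replace(base, log_amp_mean=tuple(log_medians))


def generate_group_study(
    n_per_group: dict[str, int],
    h_true: dict[str, float],
    base_config: SceneConfig,
    psf: PSFModel,
    noise: NoiseModel | None = None,
    seed: int = 0,
    brightness_jitter_sd: float = 0.2,
) -> list[GroupSample]:
    """Render a cohort of samples per group with prescribed heterogeneity.

    Each group's scenes have per-compartment median amplitudes spread
    (mean-preserving, in log₂) to the group's ``h_true``. Every sample also
    receives a lognormal global brightness factor
    (``sd = brightness_jitter_sd`` in log) emulating staining/acquisition
    variability between brains — the heterogeneity statistic must be
    invariant to it.
    """
    rng = np.random.default_rng(seed)
    samples: list[GroupSample] = []
    for group in n_per_group:
        cfg_g = scene_config_for_h(base_config, h_true[group])
        for i in range(n_per_group[group]):
            brightness = float(np.exp(rng.normal(0.0, brightness_jitter_sd)))
            cfg = replace(
                cfg_g,
                seed=int(rng.integers(2**31 - 1)),
                log_amp_mean=tuple(np.array(cfg_g.log_amp_mean) + np.log(brightness)),
            )
            scene = generate_scene(cfg)
            stack = render_stack(scene, psf, noise, rng=rng)
            samples.append(GroupSample(group, scene, stack, brightness))
    return samples
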