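"""Experimental PSF estimation from bead fields and Richardson–Lucy deconvolution.

The point-spread function is estimated the way the study's bead protocol
implies: sub-resolution fluorescent beads are detected in a calibration
stack, a window is extracted around each isolated bead, background is
subtracted, and the candidates are averaged into a single unit-sum kernel
(default window 21 z × 32 y × 32 x voxels).

Deconvolution is the Richardson–Lucy iteration

    e_{k+1} = e_k · ( psf* ⊛ ( observed / max(psf ⊛ e_k, ε) ) )

with ``psf*`` the flipped kernel, started from a flat image at the observed
mean and run with reflective boundary padding. RL is the maximum-likelihood
restoration under Poisson noise; it preserves non-negativity and, for exact
``observed = psf ⊛ truth`` data, monotonically decreases the Csiszár
I-divergence between the observation and the reblurred estimate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage
from scipy.signal import fftconvolve
from scipy.spatial import cKDTree

from .stack_io import ImageStack, VoxelSize

__all__ = [
    "PSFModel",
    "DEFAULT_PSF_WINDOW",
    "detect_beads",
    "extract_psf",
    "average_psfs",
    "synthetic_gaussian_psf",
    "delta_psf",
    "convolve_psf",
    "richardson_lucy",
    "i_divergence",
]

# (z, y, x) — matches the study's averaged-PSF image size of
# 32 × 32 pixels × 21 slices.
DEFAULT_PSF_WINDOW = (21, 32, 32)


@dataclass
class PSFModel:
    """A nonnegative 3D kernel summing to one, with physical voxel size."""

    kernel: np.ndarray
    voxel_size: VoxelSize

    def __post_init__(self) -> None:
        k = np.asarray(self.kernel, dtype=float)
        if k.ndim != 3:
            raise ValueError("PSF kernel must be 3D")
        if k.min() < 0:
            raise ValueError("PSF kernel must be nonnegative")
        s = k.sum()
        if s <= 0:
            raise ValueError("PSF kernel sums to zero")
        if abs(s - 1.0) > 1e-9:
            k = k / s
        # single dominant central lobe: peak inside the central third
        peak = np.unravel_index(np.argmax(k), k.shape)
        for p, n in zip(peak, k.shape):
            if not (n / 3.0 - 1 <= p <= 2 * n / 3.0):
                raise ValueError(
                    f"PSF peak {peak} outside the central third of window {k.shape}"
                )
        self.kernel = k
        self.voxel_size = VoxelSize.coerce(self.voxel_size)

    @property
    def window(self) -> tuple[int, int, int]:
        return self.kernel.shape


def detect_beads(
    stack: ImageStack | np.ndarray,
    min_separation_um: float = 2.0,
    threshold: float | None = None,
    voxel_size: VoxelSize | None = None,
    border_um: float | Sequence[float] | None = None,
) -> np.ndarray:
    """Detect isolated beads; return subvoxel centroids in µm, (n, 3) zyx.

    Candidate objects are connected components above ``threshold`` (default:
    mean + 4 SD). Centroids are intensity-weighted centres of mass. Beads
    closer than ``min_separation_um`` to another bead (both are discarded —
    aggregates corrupt the PSF) or closer than ``border_um`` to the stack
    border are dropped.
    """
    if isinstance(stack, ImageStack):
        if stack.n_channels != 1:
            raise ValueError("bead detection expects a single-channel stack")
        vol = stack.channel(0)
        vs = stack.voxel_size
    else:
        vol = np.asarray(stack, dtype=float)
        if voxel_size is None:
            raise ValueError("voxel_size required for a bare array")
        vs = VoxelSize.coerce(voxel_size)
    if threshold is None:
        threshold = float(vol.mean() + 4.0 * vol.std())
    mask = vol > threshold
    labels, n = ndimage.label(mask, structure=np.ones((3, 3, 3), dtype=int))
    if n == 0:
        raise ValueError("no beads found above threshold")
    centroids_vox = np.array(
        ndimage.center_of_mass(vol, labels, index=range(1, n + 1)), dtype=float
    ).reshape(n, 3)
    scale = np.array(vs.zyx)
    centroids_um = centroids_vox * scale

    keep = np.ones(n, dtype=bool)
    if n > 1:
        tree = cKDTree(centroids_um)
        pairs = tree.query_pairs(min_separation_um)
        for i, j in pairs:
            keep[i] = keep[j] = False
    if border_um is not None:
        b = np.broadcast_to(np.asarray(border_um, dtype=float), (3,))
        extent = np.array(vol.shape) * scale
        for i, c in enumerate(centroids_um):
            if (c < b).any() or (c > extent - b).any():
                keep[i] = False
    out = centroids_um[keep]
    if out.size == 0:
        raise ValueError("all detected beads discarded (too close or near border)")
    return out


def extract_psf(
    stack: ImageStack | np.ndarray,
    centroid_um: Sequence[float],
    window: tuple[int, int, int] = DEFAULT_PSF_WINDOW,
    voxel_size: VoxelSize | None = None,
) -> np.ndarray:
    """Extract one background-subtracted PSF candidate around a bead.

    The window is centred on the voxel nearest to the centroid; the median of
    the window border is subtracted as local background and negatives are
    clipped to zero.
    """
    if isinstance(stack, ImageStack):
        vol = stack.channel(0)
        vs = stack.voxel_size
    else:
        vol = np.asarray(stack, dtype=float)
        if voxel_size is None:
            raise ValueError("voxel_size required for a bare array")
        vs = VoxelSize.coerce(voxel_size)
    center = np.round(np.asarray(centroid_um, dtype=float) / np.array(vs.zyx)).astype(int)
    half = [w // 2 for w in window]
    lo = center - half
    hi = lo + np.array(window)
    if (lo < 0).any() or (hi > np.array(vol.shape)).any():
        raise ValueError(
            f"PSF window {window} around voxel {tuple(center)} exceeds stack bounds"
        )
    cand = vol[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]].astype(float).copy()
    border = np.ones(cand.shape, dtype=bool)
    border[1:-1, 1:-1, 1:-1] = False
    cand -= np.median(cand[border])
    np.clip(cand, 0, None, out=cand)
    if cand.sum() <= 0:
        raise ValueError("no signal in PSF window after background subtraction")
    return cand


def average_psfs(
    candidates: Sequence[np.ndarray], voxel_size: VoxelSize | Sequence[float]
) -> PSFModel:
    """Voxel-wise mean of candidate PSFs, normalized to unit sum."""
    if len(candidates) == 0:
        raise ValueError("need at least one PSF candidate")
    shape = candidates[0].shape
    for c in candidates:
        if c.shape != shape:
            raise ValueError("PSF candidates must share one window shape")
    mean = np.mean(candidates, axis=0)
    return PSFModel(mean / mean.sum(), VoxelSize.coerce(voxel_size))


def synthetic_gaussian_psf(
    sigma_um: Sequence[float] = (0.5, 0.15, 0.15),
    window: tuple[int, int, int] = DEFAULT_PSF_WINDOW,
    voxel_size: VoxelSize | Sequence[float] = (0.370, 0.079, 0.079),
) -> PSFModel:
    """Separable anisotropic Gaussian kernel (σ in µm, zyx), unit sum.

    A σ→0 axis degenerates to a delta along that axis.
    """
    vs = VoxelSize.coerce(voxel_size)
    grids = []
    for w, sig, step in zip(window, sigma_um, vs.zyx):
        pos = (np.arange(w) - w // 2) * step
        if sig <= 0:
            g = (pos == 0).astype(float)
        else:
            g = np.exp(-0.5 * (pos / sig) ** 2)
        grids.append(g)
    kernel = grids[0][:, None, None] * grids[1][None, :, None] * grids[2][None, None, :]
    return PSFModel(kernel / kernel.sum(), vs)


def fitted_window(
    shape_zyx: tuple[int, int, int],
    window: tuple[int, int, int] = DEFAULT_PSF_WINDOW,
) -> tuple[int, int, int]:
    """Shrink a PSF window (to odd sizes) so it fits inside a given grid."""
    out = []
    for w, s in zip(window, shape_zyx):
        w2 = min(w, s)
        if w2 % 2 == 0:
            w2 -= 1
        out.append(max(w2, 1))
    return tuple(out)


def delta_psf(
    window: tuple[int, int, int] = (1, 1, 1),
    voxel_size: VoxelSize | Sequence[float] = (0.370, 0.079, 0.079),
) -> PSFModel:
    """Identity kernel — useful as a fixture and a fixed-point check."""
    k = np.zeros(window)
    k[window[0] // 2, window[1] // 2, window[2] // 2] = 1.0
    return PSFModel(k, VoxelSize.coerce(voxel_size))


def _oddify(kernel: np.ndarray) -> np.ndarray:
    """Pad even axes with one trailing zero so the kernel centre index
    ``s // 2`` coincides with fftconvolve's 'same' centre ``(s - 1) // 2``
    (keeps convolution unshifted and the RL adjoint exact for even windows
    such as the default 32 × 32 lateral size)."""
    pads = [(0, 1 - s % 2) for s in kernel.shape]
    return np.pad(kernel, pads) if any(p[1] for p in pads) else kernel


def convolve_psf(
    image: np.ndarray, kernel: np.ndarray, boundary: str = "reflect"
) -> np.ndarray:
    """'same'-size, centre-aligned convolution of a volume with a PSF kernel.

    ``boundary='reflect'`` pads before convolving (no wrap-around);
    ``boundary='zero'`` is plain zero-padded convolution.
    """
    kernel = _oddify(np.asarray(kernel, dtype=float))
    if boundary == "zero":
        return fftconvolve(image, kernel, mode="same")
    pad = [(s // 2, s // 2) for s in kernel.shape]
    padded = np.pad(image, pad, mode=boundary) if any(p[0] for p in pad) else image
    out = fftconvolve(padded, kernel, mode="same")
    if any(p[0] for p in pad):
        sl = tuple(slice(p0, n - p1) for (p0, p1), n in zip(pad, padded.shape))
        out = out[sl]
    return out


def richardson_lucy(
    observed: ImageStack | np.ndarray,
    psf: PSFModel,
    n_iter: int = 30,
    epsilon: float = 1e-12,
) -> ImageStack | np.ndarray:
    """Richardson–Lucy deconvolution of a single-channel volume.

    Starts from a flat image at the observed mean; a delta PSF therefore
    returns the observation exactly after one iteration. The ratio image is
    guarded by ``epsilon`` against division by zero. Returns the same type as
    the input (stack in, stack out).
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    if isinstance(observed, ImageStack):
        if observed.n_channels != 1:
            raise ValueError("deconvolve one channel at a time")
        vol = observed.channel(0).astype(float)
    else:
        vol = np.asarray(observed, dtype=float)
    if vol.max() <= 0:
        raise ValueError("observed image is all zero")
    if vol.min() < 0:
        # tolerate FFT round-off from an upstream convolution, nothing more
        if vol.min() < -1e-9 * vol.max():
            raise ValueError("observed image must be nonnegative")
        vol = np.clip(vol, 0, None)
    kernel = _oddify(psf.kernel)
    if any(k > s for k, s in zip(kernel.shape, vol.shape)):
        raise ValueError("PSF kernel larger than the image")
    flipped = kernel[::-1, ::-1, ::-1]
    estimate = np.full_like(vol, vol.mean())
    for _ in range(n_iter):
        blurred = convolve_psf(estimate, kernel)
        ratio = vol / np.maximum(blurred, epsilon)
        estimate = estimate * convolve_psf(ratio, flipped)
        np.clip(estimate, 0, None, out=estimate)
    if isinstance(observed, ImageStack):
        return ImageStack(
            estimate[None], observed.voxel_size, list(observed.channel_names)
        )
    return estimate


def i_divergence(observed: np.ndarray, reblurred: np.ndarray, epsilon: float = 1e-12) -> float:
    """Csiszár I-divergence D(obs ‖ reblurred), the RL objective."""
    o = np.asarray(observed, dtype=float)
    r = np.maximum(np.asarray(reblurred, dtype=float), epsilon)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(o > 0, o * np.log(o / r), 0.0)
    return float(np.sum(term - o + r))
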