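"""ROI-based colocalization with a 180°-rotation control, and ratiometric
calcium-signal normalization.

Colocalization follows the ROI-density design: 3D ROIs are segmented on the
reference channel (with a loose, wide-ROI setting), the signal density
(total grey value / ROI volume) is computed for both channels over the SAME
ROI set, and Pearson's R of the paired densities is reported. The chance
baseline is estimated by correlating against the 180°-rotated second
channel — rotation preserves the marginal intensity distribution exactly,
so any residual correlation measures structured background rather than
true co-enrichment.

Ratiometric normalization divides a calcium-sensor channel by a stable
reference fluorophore frame by frame, cancelling expression-level
variation; voxels where the reference falls below a floor are masked rather
than producing unstable ratios.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .stack_io import ImageStack

__all__ = [
    "ColocResult",
    "roi_signal_density",
    "rotate_180",
    "pearson_roi_correlation",
    "ratiometric_normalize",
    "compartment_basal_mean",
]


@dataclass
class ColocResult:
    """Per-ROI density pairs, their Pearson R, and the rotated control R."""

    n_rois: int
    density_a: np.ndarray
    density_b: np.ndarray
    density_b_rotated: np.ndarray
    r: float
    r_control: float
    rotation: str = "per-slice 180° in (y, x)"


def roi_signal_density(volume: np.ndarray, rois: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Signal density (total grey value / ROI volume in voxels) per ROI.

    Returns ``(roi_ids, densities)`` for labels > 0, in ascending label
    order.
    """
    labels = np.asarray(rois)
    ids = np.unique(labels)
    ids = ids[ids > 0]
    if ids.size == 0:
        raise ValueError("ROI label volume is empty")
    vol = np.asarray(volume, dtype=float)
    sums = np.bincount(labels.ravel(), weights=vol.ravel(), minlength=ids.max() + 1)
    counts = np.bincount(labels.ravel(), minlength=ids.max() + 1)
    return ids, sums[ids] / counts[ids]


def rotate_180(volume: np.ndarray) -> np.ndarray:
    """Rotate every z-slice by 180° in-plane; an exact involution.

    A voxel at (z, y, x) maps to (z, Y−1−y, X−1−x). Total intensity and the
    marginal intensity distribution are preserved exactly.
    """
    return np.asarray(volume)[:, ::-1, ::-1].copy()


def point_reflect_3d(volume: np.ndarray) -> np.ndarray:
    """Full 3D point reflection (optional alternative control)."""
    return np.asarray(volume)[::-1, ::-1, ::-1].copy()


def pearson_roi_correlation(
    channel_a: np.ndarray,
    channel_b: np.ndarray,
    rois: np.ndarray,
    rotation: str = "slice",
) -> ColocResult:
    """Pearson R of per-ROI signal densities, with a rotated-channel control.

    ``rois`` must be segmented from channel A (typically with the loose
    preset) and is reused unchanged for channel B and for the control, in
    which channel B is rotated 180° (per-slice by default,
    ``rotation='point'`` for full 3D point reflection).
    """
    ids, da = roi_signal_density(channel_a, rois)
    _, db = roi_signal_density(channel_b, rois)
    if len(ids) < 3:
        raise ValueError("need at least 3 ROIs for a defined correlation")
    if np.std(da) == 0 or np.std(db) == 0:
        raise ValueError("zero-variance ROI densities; correlation undefined")
    rot = rotate_180(channel_b) if rotation == "slice" else point_reflect_3d(channel_b)
    _, db_rot = roi_signal_density(rot, rois)
    r = float(sps.pearsonr(da, db).statistic)
    r_ctrl = (
        float(sps.pearsonr(da, db_rot).statistic) if np.std(db_rot) > 0 else 0.0
    )
    return ColocResult(
        n_rois=len(ids),
        density_a=da,
        density_b=db,
        density_b_rotated=db_rot,
        r=r,
        r_control=r_ctrl,
        rotation="per-slice 180° in (y, x)" if rotation == "slice" else "3D point reflection",
    )


def pearson_voxel_correlation(
    channel_a: np.ndarray, channel_b: np.ndarray, mask: np.ndarray | None = None
) -> float:
    """Per-voxel Pearson R (diagnostic only; the ROI-density R is primary).

    Voxel-wise correlation is dominated by background co-structure and
    resolution, so it is reported for sanity checks, not inference.
    """
    a = np.asarray(channel_a, dtype=float).ravel()
    b = np.asarray(channel_b, dtype=float).ravel()
    if mask is not None:
        sel = np.asarray(mask, dtype=bool).ravel()
        a, b = a[sel], b[sel]
    if a.size < 3 or np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("voxel correlation undefined")
    return float(sps.pearsonr(a, b).statistic)


def ratiometric_normalize(
    series: ImageStack,
    signal_channel: str | int = "signal",
    reference_channel: str | int = "reference",
    reference_floor: float | None = None,
) -> np.ndarray:
    """Frame-wise ratio signal/reference with a division guard.

    Voxels whose reference intensity falls below ``reference_floor``
    (default: 5% of the reference channel's 99th percentile) are NaN-masked.
    Returns an array of shape (t, z, y, x).
    """
    if not series.has_time:
        data = series.data[None]
    else:
        data = series.data
    si = (
        series.channel_names.index(signal_channel)
        if isinstance(signal_channel, str)
        else signal_channel
    )
    ri = (
        series.channel_names.index(reference_channel)
        if isinstance(reference_channel, str)
        else reference_channel
    )
    sig = data[:, si].astype(float)
    ref = data[:, ri].astype(float)
    if reference_floor is None:
        reference_floor = 0.05 * float(np.percentile(ref, 99))
    ratio = np.full(sig.shape, np.nan)
    ok = ref >= max(reference_floor, np.finfo(float).tiny)
    ratio[ok] = sig[ok] / ref[ok]
    return ratio


def compartment_basal_mean(
    ratio: np.ndarray,
    compartment_mask: np.ndarray,
    frames: Sequence[int] | None = None,
) -> float:
    """Mean ratio in a compartment ROI, averaged over selected frames.

    Per frame, the mean is over unmasked (non-NaN) ROI voxels; the per-frame
    means are then averaged over ``frames`` (default: all). Emulates basal
    (stimulus-free) calcium-level estimation.
    """
    mask = np.asarray(compartment_mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty compartment ROI")
    t_idx = range(ratio.shape[0]) if frames is None else frames
    per_frame = []
    for t in t_idx:
        vals = ratio[t][mask]
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            continue
        per_frame.append(vals.mean())
    if not per_frame:
        raise ValueError("no unmasked voxels in any selected frame")
    return float(np.mean(per_frame))
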