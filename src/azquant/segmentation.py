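"""3D punctum detection: threshold, maxima finding, seeded region growing,
per-cluster statistics and scoring against ground truth.

The detection scheme mirrors the classic 3D-suite workflow for diffraction-
limited spots: an intensity threshold suppresses background, local 3D maxima
(26-neighbourhood) seed the clusters, and each cluster is grown from its
seed by accepting 26-connected voxels above a fraction of the seed
intensity, out to a maximum physical radius. All distances are in µm so the
strong axial anisotropy of confocal stacks (≈4.7× for 0.370 vs 0.079 µm
voxels) is handled correctly.
"""

from __future__ import annotations

import heapq
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage
from scipy.optimize import linear_sum_assignment
from scipy.spatial import cKDTree

from .stack_io import VoxelSize

__all__ = [
    "SeedPoint",
    "ClusterRecord",
    "DetectionMatchResult",
    "apply_intensity_threshold",
    "find_maxima_3d",
    "segment_spots",
    "compute_cluster_stats",
    "compute_density",
    "match_to_ground_truth",
    "SEGMENTATION_PRESETS",
]

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)

# The "loose" preset reproduces the wide-ROI colocalization setting: a low
# inclusion fraction with a hard radius cap yields wide ROIs of nearly
# constant volume, so per-ROI densities are not coupled through ROI-size
# dilution. "default" is the punctum-intensity measurement setting.
SEGMENTATION_PRESETS = {
    "default": {"fraction": 0.5, "dilate": 0, "max_radius_um": 0.6},
    "loose": {"fraction": 0.1, "dilate": 0, "max_radius_um": 0.35},
}


@dataclass(frozen=True)
class SeedPoint:
    """A local 3D maximum used as a region-growing start point."""

    voxel: tuple[int, int, int]
    intensity: float


@dataclass
class ClusterRecord:
    """One segmented punctum: voxel statistics in physical units."""

    id: int
    seed: SeedPoint
    volume_voxels: int
    volume_um3: float
    centroid_um: tuple[float, float, float]
    sum_intensity: float
    mean_intensity: float
    median_intensity: float
    max_intensity: float
    compartment: str | int = ""
    sample_id: str = ""


@dataclass
class DetectionMatchResult:
    """One-to-one matching of detections against ground-truth positions."""

    n_true: int
    n_detected: int
    true_positives: list[tuple[int, int]]  # (detected idx, truth idx)
    false_positive_idx: list[int]
    false_negative_idx: list[int]
    max_dist_um: float
    mode: str = "optimal"

    @property
    def precision(self) -> float:
        return len(self.true_positives) / self.n_detected if self.n_detected else 0.0

    @property
    def recall(self) -> float:
        return len(self.true_positives) / self.n_true if self.n_true else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if (p + r) > 0 else 0.0


def apply_intensity_threshold(
    volume: np.ndarray,
    mode: str = "mean_plus_k_sd",
    value: float = 3.0,
) -> tuple[np.ndarray, float]:
    """Binary foreground mask for background suppression.

    Modes: ``absolute`` (threshold = ``value``), ``mean_plus_k_sd``
    (mean + value·SD) and ``percentile`` (``value``-th percentile, linear
    interpolation). Returns ``(mask, threshold)``; the realized threshold is
    reported for provenance. Voxels ≥ threshold are foreground.
    """
    vol = np.asarray(volume, dtype=float)
    if mode == "absolute":
        thr = float(value)
    elif mode == "mean_plus_k_sd":
        thr = float(vol.mean() + value * vol.std())
    elif mode == "percentile":
        if not 0 <= value <= 100:
            raise ValueError("percentile must be in [0, 100]")
        thr = float(np.percentile(vol, value))
    else:
        raise ValueError(f"unknown threshold mode {mode!r}")
    return vol >= thr, thr


def find_maxima_3d(
    volume: np.ndarray,
    voxel_size: VoxelSize | Sequence[float],
    mask: np.ndarray | None = None,
    min_distance_um: float = 0.0,
    noise_tolerance: float = 0.0,
) -> list[SeedPoint]:
    """Find 3D local maxima (26-neighbourhood) to seed spot segmentation.

    A voxel qualifies when it is ≥ all 26 neighbours, lies in ``mask``, and
    stands out from the dimmest neighbouring shoulder by at least
    ``noise_tolerance``. Equal-valued plateaus yield one seed at the
    lexicographically smallest (z, y, x). Of any pair of seeds closer than
    ``min_distance_um`` (physical distance), only the brighter survives
    (ties broken lexicographically).
    """
    vol = np.asarray(volume, dtype=float)
    vs = VoxelSize.coerce(voxel_size)
    if mask is None:
        mask = np.ones(vol.shape, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask: nothing to search for maxima")
    footprint = np.ones((3, 3, 3), dtype=bool)
    local_max = vol >= ndimage.maximum_filter(vol, footprint=footprint, mode="reflect")
    if noise_tolerance > 0:
        shoulder = ndimage.minimum_filter(vol, footprint=footprint, mode="reflect")
        local_max &= (vol - shoulder) >= noise_tolerance
    cand = local_max & mask
    if not cand.any():
        return []
    # collapse equal-valued plateaus to their lexicographically first voxel
    labels, n = ndimage.label(cand, structure=_STRUCT26)
    seeds: list[tuple[float, tuple[int, int, int]]] = []
    idx = np.argwhere(labels > 0)
    order = np.lexsort((idx[:, 2], idx[:, 1], idx[:, 0]))
    seen: set[int] = set()
    for k in order:
        z, y, x = idx[k]
        lab = labels[z, y, x]
        if lab in seen:
            continue
        seen.add(lab)
        seeds.append((vol[z, y, x], (int(z), int(y), int(x))))
    # brighter-first min-distance suppression
    seeds.sort(key=lambda s: (-s[0], s[1]))
    if min_distance_um > 0 and len(seeds) > 1:
        scale = np.array(vs.zyx)
        kept_pos: list[np.ndarray] = []
        kept: list[tuple[float, tuple[int, int, int]]] = []
        tree: cKDTree | None = None
        for inten, voxel in seeds:
            p = np.array(voxel) * scale
            if kept_pos:
                tree = cKDTree(kept_pos)
                if tree.query_ball_point(p, min_distance_um):
                    continue
            kept_pos.append(p)
            kept.append((inten, voxel))
        seeds = kept
    return [SeedPoint(voxel, float(inten)) for inten, voxel in seeds]


def _grow_region(
    vol: np.ndarray,
    seed: tuple[int, int, int],
    threshold: float,
    max_radius_um: float,
    scale: np.ndarray,
) -> np.ndarray:
    """26-connected region from ``seed``: voxels ≥ threshold within the
    physical radius, connected to the seed through that set. Returns an
    (n, 3) voxel-index array. Implemented as a connected-component search on
    a local window (equivalent to a flood fill, vectorised)."""
    radius_vox = np.maximum(np.floor(max_radius_um / scale).astype(int), 0)
    lo = np.maximum(np.array(seed) - radius_vox, 0)
    hi = np.minimum(np.array(seed) + radius_vox + 1, np.array(vol.shape))
    win = vol[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
    local_seed = tuple(np.array(seed) - lo)
    zz, yy, xx = np.ogrid[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
    d2 = (
        ((zz - seed[0]) * scale[0]) ** 2
        + ((yy - seed[1]) * scale[1]) ** 2
        + ((xx - seed[2]) * scale[2]) ** 2
    )
    mask = (win >= threshold) & (d2 <= max_radius_um**2)
    if not mask[local_seed]:
        return np.array(seed, dtype=int).reshape(1, 3)
    labels, _ = ndimage.label(mask, structure=_STRUCT26)
    vox = np.argwhere(labels == labels[local_seed])
    return vox + lo


def segment_spots(
    volume: np.ndarray,
    seeds: Sequence[SeedPoint],
    voxel_size: VoxelSize | Sequence[float],
    fraction: float = 0.5,
    floor: float = 0.0,
    max_radius_um: float = 0.6,
    split: str = "none",
    dilate: int = 0,
    stats: bool = True,
) -> tuple[np.ndarray, list[ClusterRecord]]:
    """Grow one 3D ROI per seed and return (label volume, cluster records).

    Each region accepts 26-connected voxels with intensity
    ≥ max(fraction·seed, floor), out to ``max_radius_um`` from the seed.
    Voxels reachable from several seeds are resolved per ``split``:
    ``nearest-seed`` assigns by physical distance (ties to the brighter
    seed); ``none`` lets the brighter seed claim first (no re-splitting, as
    in a watershed-free workflow). ``dilate`` adds that many 1-voxel
    26-connected shells afterwards (the loose-ROI preset), without
    overwriting other clusters. Labels are 1-based; 0 is background.
    ``stats=False`` skips the per-cluster statistics pass (callers that
    re-measure on a different volume) and returns an empty record list.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    if split not in ("none", "nearest-seed"):
        raise ValueError(f"unknown split mode {split!r}")
    vol = np.asarray(volume, dtype=float)
    vs = VoxelSize.coerce(voxel_size)
    scale = np.array(vs.zyx)
    labels = np.zeros(vol.shape, dtype=np.int32)

    active: list[tuple[int, SeedPoint]] = []
    for i, s in enumerate(sorted(seeds, key=lambda s: (-s.intensity, s.voxel))):
        if s.intensity < floor:
            warnings.warn(f"seed {s.voxel} below floor {floor}; dropped")
            continue
        active.append((i, s))

    claims: dict[tuple[int, int, int], list[int]] = {}
    kept_seeds: list[SeedPoint] = []
    for lab, (_, s) in enumerate(active, start=1):
        thr = max(fraction * s.intensity, floor)
        region = _grow_region(vol, s.voxel, thr, max_radius_um, scale)
        kept_seeds.append(s)
        for v in map(tuple, region):
            claims.setdefault(v, []).append(lab)

    for v, labs in claims.items():
        if len(labs) == 1:
            labels[v] = labs[0]
            continue
        if split == "none":
            labels[v] = labs[0]  # brighter seed grew first (seeds sorted above)
        else:
            best = None
            for lab in labs:
                s = kept_seeds[lab - 1]
                d = float(np.linalg.norm((np.array(v) - np.array(s.voxel)) * scale))
                key = (d, -s.intensity, lab)
                if best is None or key < best[0]:
                    best = (key, lab)
            labels[v] = best[1]

    if dilate > 0:
        for _ in range(dilate):
            grown = ndimage.grey_dilation(labels, footprint=_STRUCT26)
            labels = np.where(labels == 0, grown, labels)

    if not stats:
        return labels, []
    records = compute_cluster_stats(labels, vol, vs, seeds=kept_seeds)
    return labels, records


def compute_cluster_stats(
    labels: np.ndarray,
    volume: np.ndarray,
    voxel_size: VoxelSize | Sequence[float],
    seeds: Sequence[SeedPoint] | None = None,
    compartments: np.ndarray | None = None,
    compartment_names: dict[int, str] | None = None,
) -> list[ClusterRecord]:
    """Per-cluster sum/mean/median/max intensity, volume and µm centroid.

    Centroids are intensity-weighted. If a compartment label volume is
    given, each cluster is tagged with the compartment containing its seed
    (or, lacking seeds, its centroid voxel).
    """
    vs = VoxelSize.coerce(voxel_size)
    vol = np.asarray(volume, dtype=float)
    records: list[ClusterRecord] = []
    scale = np.array(vs.zyx)
    objects = ndimage.find_objects(labels)
    for lab, sl in enumerate(objects, start=1):
        if sl is None:
            continue
        offset = np.array([s.start for s in sl])
        vox = np.argwhere(labels[sl] == lab) + offset
        vals = vol[tuple(vox.T)]
        wsum = vals.sum()
        if wsum > 0:
            centroid = (vox * scale).T @ vals / wsum
        else:
            centroid = (vox * scale).mean(axis=0)
        seed = seeds[lab - 1] if seeds is not None and lab - 1 < len(seeds) else SeedPoint(
            tuple(vox[np.argmax(vals)]), float(vals.max())
        )
        comp: str | int = ""
        if compartments is not None:
            cid = int(compartments[seed.voxel])
            comp = (
                compartment_names.get(cid, cid) if compartment_names is not None else cid
            )
        records.append(
            ClusterRecord(
                id=int(lab),
                seed=seed,
                volume_voxels=int(len(vox)),
                volume_um3=float(len(vox) * vs.volume_um3),
                centroid_um=tuple(float(c) for c in centroid),
                sum_intensity=float(wsum),
                mean_intensity=float(vals.mean()),
                median_intensity=float(np.median(vals)),
                max_intensity=float(vals.max()),
                compartment=comp,
            )
        )
    return records


def compute_density(
    records: Sequence[ClusterRecord],
    compartment_mask: np.ndarray,
    voxel_size: VoxelSize | Sequence[float],
    reference_mask: np.ndarray | None = None,
    denominator: str = "projected_area",
) -> tuple[float, bool]:
    """Punctum density of one compartment: count / membrane-reference area.

    ``denominator='projected_area'`` divides the centroid count by the area
    (µm²) of the z max-projection of the reference-positive compartment mask
    (the cluster-per-membrane-area convention); ``'volume'`` divides by the
    mask volume in µm³. Returns ``(density, ok)`` where ``ok`` is False for
    an empty compartment (density 0).
    """
    vs = VoxelSize.coerce(voxel_size)
    mask = np.asarray(compartment_mask, dtype=bool)
    if reference_mask is not None:
        mask = mask & np.asarray(reference_mask, dtype=bool)
    if not mask.any():
        return 0.0, False
    count = 0
    scale = np.array(vs.zyx)
    for r in records:
        voxel = np.round(np.array(r.centroid_um) / scale).astype(int)
        voxel = np.clip(voxel, 0, np.array(mask.shape) - 1)
        if mask[tuple(voxel)]:
            count += 1
    if denominator == "projected_area":
        denom = float(mask.any(axis=0).sum() * vs.y * vs.x)
    elif denominator == "volume":
        denom = float(mask.sum() * vs.volume_um3)
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    return count / denom, True


def match_to_ground_truth(
    detected_um: np.ndarray,
    true_um: np.ndarray,
    max_dist_um: float = 0.3,
    mode: str = "optimal",
) -> DetectionMatchResult:
    """Score detections against ground-truth positions (µm, zyx rows).

    ``optimal`` solves the bipartite assignment minimising total distance
    among pairs within ``max_dist_um`` (deterministic, order-independent);
    ``greedy`` pairs closest-first and is provided for comparison only.
    """
    det = np.asarray(detected_um, dtype=float).reshape(-1, 3)
    tru = np.asarray(true_um, dtype=float).reshape(-1, 3)
    nd, nt = len(det), len(tru)
    pairs: list[tuple[int, int]] = []
    if nd and nt:
        d = np.linalg.norm(det[:, None, :] - tru[None, :, :], axis=2)
        if mode == "optimal":
            big = max_dist_um * 1e6 + 1.0
            cost = np.where(d <= max_dist_um, d, big)
            ri, ci = linear_sum_assignment(cost)
            pairs = [(int(i), int(j)) for i, j in zip(ri, ci) if d[i, j] <= max_dist_um]
        elif mode == "greedy":
            order = [
                (d[i, j], i, j)
                for i in range(nd)
                for j in range(nt)
                if d[i, j] <= max_dist_um
            ]
            heapq.heapify(order)
            used_d: set[int] = set()
            used_t: set[int] = set()
            while order:
                _, i, j = heapq.heappop(order)
                if i in used_d or j in used_t:
                    continue
                used_d.add(i)
                used_t.add(j)
                pairs.append((i, j))
        else:
            raise ValueError(f"unknown matching mode {mode!r}")
    matched_d = {i for i, _ in pairs}
    matched_t = {j for _, j in pairs}
    return DetectionMatchResult(
        n_true=nt,
        n_detected=nd,
        true_positives=pairs,
        false_positive_idx=[i for i in range(nd) if i not in matched_d],
        false_negative_idx=[j for j in range(nt) if j not in matched_t],
        max_dist_um=max_dist_um,
        mode=mode,
    )
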