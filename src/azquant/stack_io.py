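"""Image-stack and table I/O with fixed coordinate and unit conventions.

Conventions used throughout the package:

* array axis order is ``(z, y, x)`` for volumes, with optional leading
  ``channel`` and ``time`` axes, i.e. ``(c, z, y, x)`` or ``(t, c, z, y, x)``;
* indices are 0-based, ranges are half-open;
* physical distances, centroids and volumes are in micrometres, carried by a
  :class:`VoxelSize` attached to every stack. Voxel anisotropy (e.g. the
  0.370/0.079 µm axial/lateral sampling of the study's confocal stacks) is
  respected by every downstream physical-distance computation.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "VoxelSize",
    "ImageStack",
    "CompartmentMaskSet",
    "read_stack",
    "write_stack",
    "crop_subvolume",
    "write_cluster_table",
    "read_cluster_table",
    "CLUSTER_TABLE_COLUMNS",
]

DEFAULT_VOXEL_SIZE_UM = (0.370, 0.079, 0.079)


@dataclass(frozen=True)
class VoxelSize:
    """Physical voxel size in µm per voxel, ordered (z, y, x)."""

    z: float
    y: float
    x: float

    def __post_init__(self) -> None:
        if not all(s > 0 for s in (self.z, self.y, self.x)):
            raise ValueError(f"voxel size must be strictly positive, got {self}")

    @property
    def zyx(self) -> tuple[float, float, float]:
        return (self.z, self.y, self.x)

    @property
    def volume_um3(self) -> float:
        """Volume of one voxel in µm³."""
        return self.z * self.y * self.x

    @classmethod
    def coerce(cls, value: "VoxelSize | Sequence[float]") -> "VoxelSize":
        if isinstance(value, VoxelSize):
            return value
        z, y, x = value
        return cls(float(z), float(y), float(x))


@dataclass
class ImageStack:
    """An n-channel 3D (optionally +time) voxel grid with physical metadata.

    ``data`` is indexed ``(c, z, y, x)`` or ``(t, c, z, y, x)``; intensities
    are nonnegative.
    """

    data: np.ndarray
    voxel_size: VoxelSize
    channel_names: list[str] = dataclasses.field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim not in (4, 5):
            raise ValueError(
                f"stack data must be (c,z,y,x) or (t,c,z,y,x), got shape {self.data.shape}"
            )
        if self.data.size == 0:
            raise ValueError("stack has zero voxels")
        if np.issubdtype(self.data.dtype, np.floating) and not np.isfinite(self.data).all():
            raise ValueError("stack contains non-finite values")
        if self.data.min() < 0:
            raise ValueError("stack contains negative intensities")
        self.voxel_size = VoxelSize.coerce(self.voxel_size)
        if not self.channel_names:
            self.channel_names = [f"ch{i}" for i in range(self.n_channels)]
        if len(self.channel_names) != self.n_channels:
            raise ValueError(
                f"{len(self.channel_names)} channel names for {self.n_channels} channels"
            )

    @property
    def has_time(self) -> bool:
        return self.data.ndim == 5

    @property
    def n_frames(self) -> int:
        return self.data.shape[0] if self.has_time else 1

    @property
    def n_channels(self) -> int:
        return self.data.shape[1] if self.has_time else self.data.shape[0]

    @property
    def shape_zyx(self) -> tuple[int, int, int]:
        return tuple(self.data.shape[-3:])

    def channel(self, key: int | str, frame: int | None = None) -> np.ndarray:
        """Return one channel volume ``(z, y, x)``."""
        idx = self.channel_names.index(key) if isinstance(key, str) else int(key)
        if self.has_time:
            if frame is None:
                raise ValueError("time stack: a frame index is required")
            return self.data[frame, idx]
        if frame not in (None, 0):
            raise ValueError("not a time stack")
        return self.data[idx]


@dataclass
class CompartmentMaskSet:
    """Integer label volume assigning voxels to named compartments.

    Label 0 is background; labels 1..k map to compartment names (by default
    the five mushroom-body γ-lobe compartments γ1..γ5).
    """

    labels: np.ndarray
    names: dict[int, str]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("label volume must be 3D (z,y,x)")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("label volume must be integer")
        present = set(np.unique(self.labels)) - {0}
        declared = set(self.names)
        if not present <= declared:
            raise ValueError(f"labels {sorted(present - declared)} have no declared name")
        missing = [lab for lab in declared if lab not in present]
        if missing:
            raise ValueError(f"declared compartments with no voxels: {sorted(missing)}")

    @property
    def label_ids(self) -> list[int]:
        return sorted(self.names)

    @classmethod
    def gamma_lobe(cls, labels: np.ndarray) -> "CompartmentMaskSet":
        """Name labels 1..5 as γ1..γ5."""
        return cls(labels, {i: f"gamma{i}" for i in range(1, 6)})


def _axes_to_tczyx(data: np.ndarray, axes: str) -> tuple[np.ndarray, bool]:
    """Reorder a tifffile series to (t,c,z,y,x) collapsed to present axes."""
    axes = axes.upper().replace("S", "C").replace("Q", "Z").replace("I", "Z")
    order = [ax for ax in "TCZYX" if ax in axes]
    if sorted(axes) != sorted(order) or data.ndim != len(axes):
        raise ValueError(f"unsupported TIFF axis layout {axes!r}")
    data = np.moveaxis(data, [axes.index(ax) for ax in order], range(len(order)))
    has_time = "T" in axes
    # insert missing axes: C, Z
    if "C" not in axes:
        data = np.expand_dims(data, 1 if has_time else 0)
    if "Z" not in axes:
        data = np.expand_dims(data, -3)
    return data, has_time


def read_stack(
    path: str | Path,
    voxel_size_override: VoxelSize | Sequence[float] | None = None,
    channel_names: Sequence[str] | None = None,
) -> ImageStack:
    """Read a multi-page TIFF into an :class:`ImageStack`.

    Voxel size is taken from ImageJ/OME-style metadata written by
    :func:`write_stack`; pass ``voxel_size_override`` for plain TIFFs without
    readable calibration.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"file not found: {path}")
    with tifffile.TiffFile(path) as tif:
        series = tif.series[0]
        data = series.asarray()
        axes = series.axes
        vs = _voxel_size_from_metadata(tif)
    if data.ndim == 3 and len(axes) != 3:  # defensive; tifffile reports axes
        axes = "ZYX"
    data, _ = _axes_to_tczyx(data, axes)
    if data.ndim == 5 and data.shape[0] == 1:
        data = data[0]
    if voxel_size_override is not None:
        vs = VoxelSize.coerce(voxel_size_override)
    if vs is None:
        raise ValueError(
            f"{path}: no voxel-size metadata; pass voxel_size_override explicitly"
        )
    names = list(channel_names) if channel_names else None
    if names is None:
        names_n = data.shape[1] if data.ndim == 5 else data.shape[0]
        names = [f"ch{i}" for i in range(names_n)]
    return ImageStack(data, vs, names)


def _voxel_size_from_metadata(tif: tifffile.TiffFile) -> VoxelSize | None:
    try:
        meta = tif.imagej_metadata or {}
        spacing = meta.get("spacing")
        page = tif.pages[0]
        xres = page.tags.get("XResolution")
        yres = page.tags.get("YResolution")
        if spacing is None or xres is None or yres is None:
            return None
        xr = xres.value[0] / xres.value[1]
        yr = yres.value[0] / yres.value[1]
        if xr <= 0 or yr <= 0 or spacing <= 0:
            return None
        return VoxelSize(float(spacing), 1.0 / yr, 1.0 / xr)
    except Exception:
        return None


def write_stack(stack: ImageStack, path: str | Path) -> Path:
    """Write a stack as ImageJ-flavoured TIFF with voxel size in metadata.

    Lossless for integer data; float data is stored as float32.
    """
    path = Path(path)
    if not path.parent.exists():
        raise FileNotFoundError(f"parent directory does not exist: {path.parent}")
    data = stack.data
    # ImageJ TIFF supports uint8/uint16/float32; keep integers lossless in
    # uint16 where they fit, fall back to float32 (exact below 2**24)
    if np.issubdtype(data.dtype, np.floating):
        data = data.astype(np.float32)
    elif data.dtype == np.uint8:
        pass
    elif np.issubdtype(data.dtype, np.integer):
        if data.min() >= 0 and data.max() <= np.iinfo(np.uint16).max:
            data = data.astype(np.uint16)
        else:
            data = data.astype(np.float32)
    vs = stack.voxel_size
    # ImageJ hyperstacks require TZCYXS axis order
    if stack.has_time:
        data = np.moveaxis(data, 1, 2)
        axes = "TZCYX"
    else:
        data = np.moveaxis(data, 0, 1)
        axes = "ZCYX"
    tifffile.imwrite(
        path,
        data,
        imagej=True,
        resolution=(1.0 / vs.x, 1.0 / vs.y),
        metadata={
            "spacing": vs.z,
            "unit": "um",
            "axes": axes,
            "Labels": stack.channel_names,
        },
    )
    return path


def crop_subvolume(
    stack: ImageStack,
    z: tuple[int, int],
    y: tuple[int, int],
    x: tuple[int, int],
) -> ImageStack:
    """Crop a (z,y,x) sub-volume given half-open, 0-based bounds.

    Mirrors the study's per-compartment sub-stack cropping; all channels (and
    frames) are cropped together and the voxel size is inherited.
    """
    shape = stack.shape_zyx
    for (lo, hi), n, name in zip((z, y, x), shape, "zyx"):
        if not (0 <= lo < hi <= n):
            raise ValueError(
                f"invalid {name} bounds [{lo}, {hi}) for axis of length {n}"
            )
    sl = (..., slice(*z), slice(*y), slice(*x))
    return ImageStack(stack.data[sl].copy(), stack.voxel_size, list(stack.channel_names))


CLUSTER_TABLE_COLUMNS = [
    "sample_id",
    "cluster_id",
    "compartment",
    "centroid_z_um",
    "centroid_y_um",
    "centroid_x_um",
    "volume_voxels",
    "volume_um3",
    "sum_intensity",
    "mean_intensity",
    "median_intensity",
    "max_intensity",
]


def write_cluster_table(records: Iterable, path: str | Path) -> Path:
    """Write segmented-cluster records as CSV with a fixed header.

    ``records`` is any iterable of objects exposing the cluster-record
    attributes (see ``azquant.segmentation.ClusterRecord``).
    """
    path = Path(path)
    rows = []
    for r in records:
        rows.append(
            {
                "sample_id": getattr(r, "sample_id", ""),
                "cluster_id": r.id,
                "compartment": r.compartment,
                "centroid_z_um": r.centroid_um[0],
                "centroid_y_um": r.centroid_um[1],
                "centroid_x_um": r.centroid_um[2],
                "volume_voxels": r.volume_voxels,
                "volume_um3": r.volume_um3,
                "sum_intensity": r.sum_intensity,
                "mean_intensity": r.mean_intensity,
                "median_intensity": r.median_intensity,
                "max_intensity": r.max_intensity,
            }
        )
    df = pd.DataFrame(rows, columns=CLUSTER_TABLE_COLUMNS)
    df.to_csv(path, index=False)
    return path


def read_cluster_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(CLUSTER_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"cluster table missing columns: {sorted(missing)}")
    return df


def write_json_summary(summary: dict, path: str | Path) -> Path:
    path = Path(path)

    def _default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return dataclasses.asdict(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    path.write_text(json.dumps(summary, indent=2, default=_default))
    return path
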