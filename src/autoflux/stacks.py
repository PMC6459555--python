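"""In-memory containers for 3D fluorescence data and label volumes.

Axis order is fixed throughout the package as ``(plane, row, column)`` —
``(z, y, x)`` — matching the plane-major layout of multi-page TIFF stacks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import tifffile

from .errors import InvalidInputError

CHANNELS = ("green", "red", "blue")


@dataclass
class ImageStack:
    """One channel's 3D voxel grid.

    Parameters
    ----------
    voxels : ndarray, shape (nz, ny, nx)
        Nonnegative, finite intensities.
    channel : str
        One of ``green`` (488 nm), ``red`` (561 nm), ``blue`` (DAPI), or an
        arbitrary label for derived stacks.
    voxel_size : tuple of float, optional
        Physical voxel extent ``(z, y, x)``; purely metadata.
    """

    voxels: np.ndarray
    channel: str = "green"
    voxel_size: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3 or self.voxels.shape[0] < 1:
            raise InvalidInputError(
                f"stack must be 3D (plane,row,column); got shape {self.voxels.shape}"
            )
        if not np.all(np.isfinite(self.voxels)):
            raise InvalidInputError("stack contains non-finite intensities")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    def copy_with(self, voxels: np.ndarray) -> "ImageStack":
        return ImageStack(voxels, channel=self.channel, voxel_size=self.voxel_size)


@dataclass
class CellMask:
    """Binary foreground mask congruent with its source stack."""

    mask: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask)
        if self.mask.dtype != bool:
            vals = np.unique(self.mask)
            if not np.all(np.isin(vals, (0, 1))):
                raise InvalidInputError("cell mask must be strictly binary")
            self.mask = self.mask.astype(bool)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.mask.shape  # type: ignore[return-value]

    def volume(self) -> int:
        return int(self.mask.sum())


@dataclass
class LabelVolume:
    """Integer-labeled 3D segmentation; 0 is background.

    ``kind`` distinguishes nuclei / cells / punctae volumes. The object
    table (label, volume, centroid, bbox, border flag) is computed lazily.
    """

    labels: np.ndarray
    kind: str = "cells"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise InvalidInputError("label volume must be 3D")
        if self.labels.min() < 0:
            raise InvalidInputError("labels must be nonnegative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    def label_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]

    @property
    def n_objects(self) -> int:
        return int(self.label_ids().size)

    def object_table(self) -> pd.DataFrame:
        """Per-object table: volume, centroid, bounding box, border flag."""
        from scipy import ndimage as ndi

        ids = self.label_ids()
        if ids.size == 0:
            return pd.DataFrame(
                columns=[
                    "label", "volume_vox", "centroid_z", "centroid_y", "centroid_x",
                    "bbox_zmin", "bbox_ymin", "bbox_xmin",
                    "bbox_zmax", "bbox_ymax", "bbox_xmax", "border_flag",
                ]
            )
        counts = ndi.sum_labels(np.ones_like(self.labels, dtype=np.int64), self.labels, ids)
        centroids = ndi.center_of_mass(np.ones(self.shape), self.labels, ids)
        objects = ndi.find_objects(self.labels)
        ny, nx = self.shape[1], self.shape[2]
        rows = []
        for i, lab in enumerate(ids):
            sl = objects[int(lab) - 1]
            cz, cy, cx = centroids[i]
            border = sl[1].start == 0 or sl[2].start == 0 or sl[1].stop == ny or sl[2].stop == nx
            rows.append(
                dict(
                    label=int(lab), volume_vox=int(counts[i]),
                    centroid_z=cz, centroid_y=cy, centroid_x=cx,
                    bbox_zmin=sl[0].start, bbox_ymin=sl[1].start, bbox_xmin=sl[2].start,
                    bbox_zmax=sl[0].stop, bbox_ymax=sl[1].stop, bbox_xmax=sl[2].stop,
                    border_flag=bool(border),
                )
            )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# TIFF I/O — plane-major multi-page, one file per channel.

def write_stack(path, stack: ImageStack, dtype=np.float32) -> None:
    tifffile.imwrite(path, stack.voxels.astype(dtype))


def read_stack(path, channel: str = "green") -> ImageStack:
    return ImageStack(tifffile.imread(path), channel=channel)


def write_mask(path, mask: CellMask) -> None:
    """Persist a binary mask as 8-bit multi-page TIFF (0/255)."""
    tifffile.imwrite(path, (mask.mask.astype(np.uint8) * 255))


def read_mask(path) -> CellMask:
    arr = tifffile.imread(path)
    return CellMask(arr > 0)


def write_labels(path, vol: LabelVolume) -> None:
    """Persist labels as 16-bit multi-page TIFF."""
    if vol.labels.max() > np.iinfo(np.uint16).max:
        raise InvalidInputError("more than 65535 labels; cannot persist as 16-bit TIFF")
    tifffile.imwrite(path, vol.labels.astype(np.uint16))


def read_labels(path, kind: str = "cells") -> LabelVolume:
    return LabelVolume(tifffile.imread(path).astype(np.int32), kind=kind)
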