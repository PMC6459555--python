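"""Nucleus and cell segmentation.

Nuclei come from the DAPI channel by slice-by-slice relative thresholding
followed by watershed splitting of touching objects on the inverted
distance transform. Cells are then carved out of the cell mask by seeded
watershed from the nucleus labels (multi-source flooding at constant
altitude, i.e. a geodesic-distance partition of the mask), edges are
eroded to drop the blurred excess admitted by the p-value mask, and cells
touching the lateral field boundary are discarded.

The per-slice relative threshold is: slice mode + t * (slice max - slice
mode), with the mode estimated from a 256-bin histogram (default t = 0.5).
This is a scale-free rule robust to axial intensity falloff.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.segmentation import watershed

from .errors import InvalidParameterError, NoSeedsError
from .stacks import CellMask, ImageStack, LabelVolume

logger = logging.getLogger(__name__)

DEFAULT_RELATIVE_THRESHOLD = 0.5
DEFAULT_MIN_NUCLEUS_VOLUME = 500
DEFAULT_EROSION_RADIUS_XY = 2
DEFAULT_EROSION_RADIUS_Z = 0


def _slice_mode(plane: np.ndarray, bins: int = 256) -> float:
    hist, edges = np.histogram(plane.ravel(), bins=bins)
    i = int(np.argmax(hist))
    return 0.5 * (edges[i] + edges[i + 1])


def relative_threshold_planes(
    voxels: np.ndarray, relative_threshold: float
) -> np.ndarray:
    """Per-plane foreground: plane > mode + t * (max - mode).

    A blank plane (max ~= mode) contributes no foreground.
    """
    out = np.zeros(voxels.shape, dtype=bool)
    for z in range(voxels.shape[0]):
        plane = voxels[z]
        mode = _slice_mode(plane)
        mx = float(plane.max())
        if mx <= mode:
            continue
        thr = mode + relative_threshold * (mx - mode)
        out[z] = plane > thr
    return out


def segment_nuclei(
    blue: ImageStack,
    relative_threshold: float = DEFAULT_RELATIVE_THRESHOLD,
    min_volume: int = DEFAULT_MIN_NUCLEUS_VOLUME,
    smoothing_sigma=(0.0, 1.0, 1.0),
    min_peak_distance: int = 6,
) -> LabelVolume:
    """Segment nuclei from the DAPI channel.

    Slice-wise relative thresholding -> stacked binary volume -> watershed
    on the inverted Euclidean distance transform (peaks at least
    ``min_peak_distance`` apart seed the split of touching nuclei) ->
    objects under ``min_volume`` voxels discarded. Labels are relabeled
    consecutively from 1.
    """
    if not (0.0 < relative_threshold < 1.0):
        raise InvalidParameterError("relative_threshold must be in (0, 1)")
    vox = blue.voxels.astype(np.float32)
    if np.any(np.asarray(smoothing_sigma) > 0):
        vox = ndi.gaussian_filter(vox, sigma=smoothing_sigma, mode="nearest")
    fg = relative_threshold_planes(vox, relative_threshold)
    if not fg.any():
        return LabelVolume(np.zeros(blue.shape, dtype=np.int32), kind="nuclei")
    edt = ndi.distance_transform_edt(fg)
    edt_smooth = ndi.gaussian_filter(edt, sigma=1.0)
    peaks = peak_local_max(
        edt_smooth, min_distance=min_peak_distance, labels=fg, exclude_border=False
    )
    markers = np.zeros(fg.shape, dtype=np.int32)
    for i, (z, y, x) in enumerate(peaks, start=1):
        markers[z, y, x] = i
    labels = watershed(-edt, markers=markers, mask=fg, connectivity=3)
    # drop undersized objects, relabel consecutively (deterministic order)
    ids, counts = np.unique(labels[labels > 0], return_counts=True)
    keep = ids[counts >= min_volume]
    out = np.zeros_like(labels, dtype=np.int32)
    for new, old in enumerate(keep, start=1):
        out[labels == old] = new
    return LabelVolume(out, kind="nuclei")


def segment_cells(mask: CellMask, nuclei: LabelVolume) -> tuple[LabelVolume, int]:
    """Seeded watershed of the cell mask from nucleus labels.

    Multi-source flooding at constant altitude assigns every masked voxel
    reachable from a seed to the geodesically nearest nucleus; cell label
    ids equal their seed nucleus ids. Returns ``(cells, n_unassigned)``
    where ``n_unassigned`` counts masked voxels unreachable from any seed
    (left at 0 in the label volume).
    """
    if nuclei.n_objects == 0:
        raise NoSeedsError("cell segmentation requires at least one nucleus seed")
    markers = np.where(mask.mask, nuclei.labels, 0)
    labels = watershed(
        np.zeros(mask.shape, dtype=np.uint8), markers=markers, mask=mask.mask, connectivity=3
    )
    n_unassigned = int((mask.mask & (labels == 0)).sum())
    return LabelVolume(labels.astype(np.int32), kind="cells"), n_unassigned


def _cross_structure(radius_z: int) -> np.ndarray:
    """6-connected ball unit: full 3D cross if radius_z > 0, else in-plane cross."""
    s = np.zeros((3, 3, 3), dtype=bool)
    s[1, 1, 1] = s[1, 0, 1] = s[1, 2, 1] = s[1, 1, 0] = s[1, 1, 2] = True
    if radius_z > 0:
        s[0, 1, 1] = s[2, 1, 1] = True
    return s


def erode_cell_edges(
    cells: LabelVolume,
    radius_xy: int = DEFAULT_EROSION_RADIUS_XY,
    radius_z: int = DEFAULT_EROSION_RADIUS_Z,
) -> LabelVolume:
    """Erode each cell independently by a 6-connected ball.

    Anisotropy-aware: the default ball has radius 2 in-plane and 0 in z.
    Per-label erosion shrinks shared boundaries too, so labels never merge.
    A cell annihilated by erosion is dropped with a logged warning.
    """
    if radius_xy < 0 or radius_z < 0:
        raise InvalidParameterError("erosion radii must be >= 0")
    if radius_xy == 0 and radius_z == 0:
        return LabelVolume(cells.labels.copy(), kind=cells.kind)
    iters = max(radius_xy, radius_z)
    structure = _cross_structure(radius_z)
    out = np.zeros_like(cells.labels)
    objects = ndi.find_objects(cells.labels)
    pad = iters + 1
    for lab, sl in enumerate(objects, start=1):
        if sl is None:
            continue
        sl_pad = tuple(
            slice(max(s.start - pad, 0), min(s.stop + pad, dim))
            for s, dim in zip(sl, cells.shape)
        )
        region = cells.labels[sl_pad] == lab
        # interleave xy/z erosions to honor unequal radii
        n_xy, n_z = radius_xy, radius_z
        eroded = region
        for _ in range(iters):
            use_z = n_z > 0
            use_xy = n_xy > 0
            s = _cross_structure(1 if use_z else 0) if use_xy else _z_only_structure()
            eroded = ndi.binary_erosion(eroded, structure=s, border_value=1)
            n_xy = max(n_xy - 1, 0)
            n_z = max(n_z - 1, 0) if use_z else 0
        if not eroded.any():
            logger.warning("cell %d annihilated by erosion (radius xy=%d z=%d); dropped",
                           lab, radius_xy, radius_z)
            continue
        out[sl_pad][eroded] = lab
    return LabelVolume(out, kind=cells.kind)


def _z_only_structure() -> np.ndarray:
    s = np.zeros((3, 3, 3), dtype=bool)
    s[:, 1, 1] = True
    return s


def remove_border_cells(cells: LabelVolume) -> LabelVolume:
    """Drop cells with any voxel on the lateral (row/column) field boundary.

    z-boundary contact alone does not trigger removal: confocal stacks
    routinely truncate cells axially, and "edge of the field" is lateral.
    Survivors keep their labels.
    """
    lab = cells.labels
    border_ids = np.unique(
        np.concatenate([
            lab[:, 0, :].ravel(), lab[:, -1, :].ravel(),
            lab[:, :, 0].ravel(), lab[:, :, -1].ravel(),
        ])
    )
    border_ids = border_ids[border_ids > 0]
    out = lab.copy()
    if border_ids.size:
        out[np.isin(out, border_ids)] = 0
    return LabelVolume(out, kind=cells.kind)


__all__ = [
    "DEFAULT_RELATIVE_THRESHOLD", "DEFAULT_MIN_NUCLEUS_VOLUME",
    "DEFAULT_EROSION_RADIUS_XY", "DEFAULT_EROSION_RADIUS_Z",
    "relative_threshold_planes", "segment_nuclei", "segment_cells",
    "erode_cell_edges", "remove_border_cells",
]
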