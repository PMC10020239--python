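"""Cell masks from phase contrast and per-channel signal masks.

Cells are dark footprints on a bright phase-contrast background; they are
segmented by Otsu thresholding the inverted image, hole filling, and
labelling. Cells whose dilated masks touch another cell are flagged
``touching_neighbor`` (an automated stand-in for manual curation of
too-close neighbours), and cells on the frame edge ``border_clipped``.

Fluorescence channels are smoothed with a Gaussian filter, background
subtracted (median of the dim in-cell pixels) and Otsu-thresholded within
each cell; the numeric threshold is kept for the record.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import regionprops
from skimage.morphology import disk

from .config import ImagingConfig, DEFAULT_CONFIG

QC_OK = "ok"
QC_TOUCHING = "touching_neighbor"
QC_BORDER = "border_clipped"


@dataclass
class CellMask:
    """Label image of segmented cells with per-cell QC flags."""

    labels: np.ndarray  # int label image, 0 = background
    qc_flags: dict[int, str] = field(default_factory=dict)
    bounding_boxes: dict[int, tuple[int, int, int, int]] = field(default_factory=dict)

    @property
    def cell_ids(self) -> list[int]:
        return sorted(self.qc_flags)

    @property
    def n_cells(self) -> int:
        return len(self.qc_flags)

    def mask_of(self, cell_id: int) -> np.ndarray:
        if cell_id not in self.qc_flags:
            raise KeyError(f"no cell with label {cell_id}")
        return self.labels == cell_id


@dataclass
class ChannelMask:
    """Boolean signal mask for one channel within one cell."""

    mask: np.ndarray
    threshold: float
    background: float
    cell_id: int = 0
    channel: str = ""


def segment_cells(
    phase: np.ndarray,
    min_area_px: int = 50,
    touch_margin_px: int = 2,
) -> CellMask:
    """Segment cell footprints from a phase-contrast image.

    Returns one label per cell, labels contiguous from 1 in raster order.
    A blank (near-constant) image yields zero cells.
    """
    phase = np.asarray(phase, dtype=float)
    if phase.size == 0 or np.ptp(phase) < 1e-12:
        return CellMask(labels=np.zeros(phase.shape, dtype=np.int32))

    # cells are dark: threshold the inverted image
    thr = threshold_otsu(phase)
    fg = phase < thr
    fg = ndimage.binary_fill_holes(fg)
    lab, n0 = ndimage.label(fg)
    if n0:
        sizes = ndimage.sum_labels(fg, lab, index=np.arange(1, n0 + 1))
        small = np.flatnonzero(sizes < min_area_px) + 1
        fg[np.isin(lab, small)] = False
    if not fg.any():
        return CellMask(labels=np.zeros(phase.shape, dtype=np.int32))

    labels, n = ndimage.label(fg)
    # relabel contiguously in raster order of first pixel
    order = np.argsort([np.flatnonzero(labels == i + 1)[0] for i in range(n)])
    relabeled = np.zeros_like(labels)
    for new, old in enumerate(order, start=1):
        relabeled[labels == old + 1] = new
    labels = relabeled

    flags: dict[int, str] = {}
    boxes: dict[int, tuple[int, int, int, int]] = {}
    selem = disk(touch_margin_px)
    border = np.zeros(labels.shape, bool)
    border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
    for prop in regionprops(labels):
        cid = prop.label
        mask = labels == cid
        boxes[cid] = tuple(prop.bbox)
        dilated = ndimage.binary_dilation(mask, structure=selem)
        others = (labels > 0) & (labels != cid)
        if (dilated & others).any():
            flags[cid] = QC_TOUCHING
        elif (mask & border).any():
            flags[cid] = QC_BORDER
        else:
            flags[cid] = QC_OK
    return CellMask(labels=labels, qc_flags=flags, bounding_boxes=boxes)


def threshold_channel(
    image: np.ndarray,
    cells: CellMask,
    cell_id: int,
    config: ImagingConfig = DEFAULT_CONFIG,
    channel: str = "",
) -> ChannelMask:
    """Threshold one fluorescence channel within one cell.

    Gaussian smoothing (``config.smoothing_sigma_px``), background
    subtraction (median of in-cell pixels below the 25th percentile), then
    Otsu on the in-cell residual. An all-background channel yields an empty
    mask, not an error. The returned mask is always a subset of the cell
    mask.
    """
    cell = cells.mask_of(cell_id)
    smoothed = ndimage.gaussian_filter(np.asarray(image, float), config.smoothing_sigma_px)
    inside = smoothed[cell]
    if inside.size == 0:
        return ChannelMask(np.zeros_like(cell), 0.0, 0.0, cell_id, channel)

    q25 = np.percentile(inside, 25)
    dim = inside[inside <= q25]
    background = float(np.median(dim)) if dim.size else float(np.median(inside))
    residual = inside - background
    if np.ptp(residual) < 1e-12 or residual.max() <= 0:
        return ChannelMask(np.zeros_like(cell), float(residual.max()), background, cell_id, channel)
    thr = float(threshold_otsu(residual))
    mask = np.zeros_like(cell)
    mask[cell] = (smoothed[cell] - background) > thr
    return ChannelMask(mask=mask, threshold=thr, background=background, cell_id=cell_id, channel=channel)


def label_clusters(
    channel_mask: ChannelMask | np.ndarray,
    intensity: np.ndarray | None = None,
    min_area_px: int = DEFAULT_CONFIG.min_cluster_px,
):
    """8-connected components of a signal mask with areas and intensities.

    Components smaller than ``min_area_px`` are removed; their count is
    returned so callers can log the removals.

    Returns ``(label_image, clusters, n_removed)`` where ``clusters`` is a
    list of dicts with keys ``label``, ``area_px``, ``sum_intensity``,
    ``coords``.
    """
    mask = channel_mask.mask if isinstance(channel_mask, ChannelMask) else channel_mask
    structure = np.ones((3, 3), int)
    labels, n = ndimage.label(mask, structure=structure)
    clusters = []
    n_removed = 0
    keep_labels = np.zeros_like(labels)
    next_label = 1
    for i in range(1, n + 1):
        comp = labels == i
        area = int(comp.sum())
        if area < min_area_px:
            n_removed += 1
            continue
        total = float(intensity[comp].sum()) if intensity is not None else float(area)
        keep_labels[comp] = next_label
        clusters.append(
            {
                "label": next_label,
                "area_px": area,
                "sum_intensity": total,
                "coords": np.argwhere(comp),
            }
        )
        next_label += 1
    return keep_labels, clusters, n_removed
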