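"""Arm-asymmetry statistic A around the origin of replication.

The origin of replication lies between the two chromosome arms of the
toroid. An oriented central axis is drawn from the chromosome's intensity
centre of mass through the ori focus; within a circular ROI (default
diameter 20 px = 1.3 um) centred on ori, the channel intensity is summed on
each side of the axis and the asymmetricity is

    A = |sum_R - sum_L| / (sum_R + sum_L)

so A = 0 when the signal is spread equally over the two arms and A = 1 when
it all sits on one arm. Side labels are geometric (clockwise versus
anticlockwise about the oriented axis, in image coordinates with y down) —
they cannot be attributed to the genomic left/right arms from imaging
alone. Pixels whose centre falls exactly on the axis contribute half to
each side (an exclude-axis mode is available).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import ImagingConfig, DEFAULT_CONFIG


@dataclass
class AsymmetryResult:
    A: float
    sum_right: float
    sum_left: float
    roi_center: tuple[float, float]  # (row, col) of ori
    roi_diameter_px: float
    channel: str = ""
    undefined: bool = False


def center_of_mass(
    image: np.ndarray, mask: np.ndarray | None = None
) -> tuple[float, float]:
    """Intensity-weighted centroid (row, col) of a channel within a mask.

    Raises on zero total signal.
    """
    img = np.asarray(image, float)
    if mask is not None:
        img = np.where(np.asarray(mask, bool), img, 0.0)
    total = img.sum()
    if total <= 0:
        raise ValueError("zero total intensity: centre of mass undefined")
    rows = np.arange(img.shape[0])[:, None]
    cols = np.arange(img.shape[1])[None, :]
    return (float((rows * img).sum() / total), float((cols * img).sum() / total))


def central_axis(
    ori: tuple[float, float], com: tuple[float, float]
) -> tuple[float, float]:
    """Unit direction of the oriented axis com -> ori, in (row, col).

    The axis through both points defines the two half-planes used for the
    left/right split. ori == com leaves the axis undefined and raises.
    """
    d = (ori[0] - com[0], ori[1] - com[1])
    norm = float(np.hypot(*d))
    if norm < 1e-12:
        raise ValueError("ori coincides with centre of mass: axis undefined")
    return (d[0] / norm, d[1] / norm)


def side_of_axis(
    points_rc: np.ndarray, ori: tuple[float, float], direction: tuple[float, float]
) -> np.ndarray:
    """Signed side of each (row, col) point relative to the oriented axis.

    Positive = clockwise ("right") side in image coordinates (y down): with
    the axis pointing up-screen, positive is image-right. Zero = on the
    axis.
    """
    dr, dc = direction
    rows = points_rc[..., 0] - ori[0]
    cols = points_rc[..., 1] - ori[1]
    # cross product in screen coords (x=col right, y=row down):
    # s = d_col * y_rel - d_row * x_rel ... sign chosen so that for an axis
    # pointing up-screen (dr<0), points with col > ori_col get s > 0.
    return dc * rows - dr * cols


def asymmetricity(
    image: np.ndarray,
    ori: tuple[float, float],
    com: tuple[float, float],
    roi_diameter_px: float | None = None,
    channel: str = "",
    config: ImagingConfig = DEFAULT_CONFIG,
    background: float = 0.0,
    axis_mode: str = "split",
) -> AsymmetryResult:
    """Asymmetricity A of a channel about the ori axis within the ori ROI.

    ``axis_mode='split'`` (default) assigns pixels on the axis half to each
    side; ``'exclude'`` drops them. The result is undefined (NaN, flagged)
    when the ROI holds no signal.
    """
    if roi_diameter_px is None:
        roi_diameter_px = config.roi_diameter_px
    img = np.asarray(image, float) - background
    h, w = img.shape
    radius = roi_diameter_px / 2.0

    r0 = max(0, int(np.floor(ori[0] - radius)) - 1)
    r1 = min(h, int(np.ceil(ori[0] + radius)) + 2)
    c0 = max(0, int(np.floor(ori[1] - radius)) - 1)
    c1 = min(w, int(np.ceil(ori[1] + radius)) + 2)
    if r0 >= r1 or c0 >= c1:
        return AsymmetryResult(
            float("nan"), 0.0, 0.0, ori, roi_diameter_px, channel, undefined=True
        )

    rows, cols = np.mgrid[r0:r1, c0:c1]
    in_roi = (rows - ori[0]) ** 2 + (cols - ori[1]) ** 2 <= radius**2
    vals = img[r0:r1, c0:c1][in_roi]
    pts = np.stack([rows[in_roi], cols[in_roi]], axis=-1).astype(float)

    direction = central_axis(ori, com)
    s = side_of_axis(pts, ori, direction)

    eps = 1e-9
    right = vals[s > eps].sum()
    left = vals[s < -eps].sum()
    on_axis = vals[np.abs(s) <= eps].sum()
    if axis_mode == "split":
        right += 0.5 * on_axis
        left += 0.5 * on_axis
    elif axis_mode != "exclude":
        raise ValueError(f"unknown axis_mode {axis_mode!r}")

    total = right + left
    if total <= 0:
        return AsymmetryResult(
            float("nan"), float(right), float(left), ori, roi_diameter_px, channel,
            undefined=True,
        )
    A = abs(right - left) / total
    return AsymmetryResult(
        A=float(A),
        sum_right=float(right),
        sum_left=float(left),
        roi_center=ori,
        roi_diameter_px=float(roi_diameter_px),
        channel=channel,
    )
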