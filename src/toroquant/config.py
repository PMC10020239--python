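"""Imaging calibration and analysis defaults.

All physical quantities are in micrometres unless a ``_px`` suffix says
otherwise. The defaults describe widefield imaging of A22-widened
*E. coli*: 0.065 um pixels, a lateral PSF of 350 nm FWHM (800 nm axial),
and a 20-pixel (1.3 um) circular ROI used for the local arm-asymmetry
measurement around the origin of replication.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

#: full width at half maximum of a Gaussian = FWHM_FACTOR * sigma
FWHM_FACTOR: float = 2.0 * math.sqrt(2.0 * math.log(2.0))


@dataclass(frozen=True)
class ImagingConfig:
    """Calibration constants and analysis parameters.

    Attributes
    ----------
    pixel_size_um:
        Lateral pixel size of the camera, um/pixel.
    z_step_um:
        Vertical step between z-slices, um.
    roi_diameter_px:
        Diameter of the circular ROI centred on the ori focus for the
        arm-asymmetry statistic. 20 px * 0.065 um/px = 1.3 um.
    psf_fwhm_lateral_um, psf_fwhm_axial_um:
        Point-spread-function widths of the (non-deconvolved) widefield
        images.
    smoothing_sigma_px:
        Gaussian filter applied to fluorescence channels before
        thresholding.
    min_cluster_px:
        Connected components smaller than this are dropped when labelling
        signal clusters.
    spur_length_px:
        Skeleton spurs shorter than this are pruned during backbone
        extraction.
    foci_min_separation_px:
        Local maxima closer than this are merged (brighter peak kept).
    deconvolve:
        Restore fluorescence channels by Richardson-Lucy deconvolution with
        the known Gaussian PSF before quantification. The source imagery
        this pipeline models was deconvolved (maximum-likelihood) before
        measurement, and the reported widths/compaction presuppose it.
    rl_iterations:
        Richardson-Lucy iteration count.
    significance_thresholds:
        p-value cut-offs for the star convention (ns/*/**/***/****).
    """

    pixel_size_um: float = 0.065
    z_step_um: float = 0.227
    roi_diameter_px: int = 20
    psf_fwhm_lateral_um: float = 0.35
    psf_fwhm_axial_um: float = 0.80
    smoothing_sigma_px: float = 1.0
    min_cluster_px: int = 4
    spur_length_px: int = 5
    foci_min_separation_px: int = 4
    deconvolve: bool = True
    rl_iterations: int = 10
    significance_thresholds: tuple[float, ...] = (0.05, 0.01, 0.001, 0.0001)

    @property
    def psf_sigma_lateral_um(self) -> float:
        return self.psf_fwhm_lateral_um / FWHM_FACTOR

    @property
    def psf_sigma_lateral_px(self) -> float:
        return self.psf_sigma_lateral_um / self.pixel_size_um

    @property
    def roi_diameter_um(self) -> float:
        return self.roi_diameter_px * self.pixel_size_um


DEFAULT_CONFIG = ImagingConfig()
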