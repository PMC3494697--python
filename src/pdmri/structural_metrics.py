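"""Tissue-volume features from modulated segmentation maps.

Modulated gray-matter, white-matter and CSF probability maps preserve the
regional amount of tissue after spatial normalisation, so their regional
means act as volume features. This module smooths the maps with a Gaussian
kernel (10 mm FWHM by default) and averages them over atlas regions. The
maps arrive already modulated and resampled; only grid agreement with the
atlas is checked here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .fmri_metrics import MetricMap, RoiFeatureVector, metric_to_roi_features
from .volumes_io import AtlasParcellation, BrainMask

__all__ = ["TissueMap", "fwhm_to_sigma", "gaussian_smooth", "tissue_roi_features"]

TISSUE_TAGS = ("GM", "WM", "CSF")

#: FWHM = 2 * sqrt(2 ln 2) * sigma
FWHM_FACTOR = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass
class TissueMap:
    tissue_tag: str
    values: np.ndarray
    voxel_size: tuple[float, float, float]

    def __post_init__(self) -> None:
        if self.tissue_tag not in TISSUE_TAGS:
            raise ValueError(f"tissue_tag must be one of {TISSUE_TAGS}")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("tissue map must be 3-D")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("tissue map contains non-finite values")
        if (self.values < 0).any():
            raise ValueError("tissue map contains negative values")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel sizes must be positive")


def fwhm_to_sigma(fwhm_mm: float, voxel_size_mm: float) -> float:
    """Gaussian sigma in voxel units for a kernel width given as FWHM in mm."""
    return fwhm_mm / FWHM_FACTOR / voxel_size_mm


def gaussian_smooth(tissue: TissueMap, fwhm_mm: float = 10.0,
                    mode: str = "reflect") -> TissueMap:
    """Separable Gaussian smoothing with width given as FWHM in mm.

    ``mode`` sets the boundary handling ('reflect' default; 'constant'
    approximates zero-padding). Interior mass is preserved by the unit-mass
    kernel.
    """
    if fwhm_mm <= 0:
        raise ValueError("fwhm_mm must be positive")
    sigmas = [fwhm_to_sigma(fwhm_mm, v) for v in tissue.voxel_size]
    if any(fwhm_mm < 0.5 * v for v in tissue.voxel_size):
        warnings.warn("FWHM below half a voxel: near-identity kernel",
                      stacklevel=2)
    smoothed = ndimage.gaussian_filter(tissue.values, sigma=sigmas, mode=mode)
    smoothed = np.clip(smoothed, 0.0, None)
    return TissueMap(tissue_tag=tissue.tissue_tag, values=smoothed,
                     voxel_size=tissue.voxel_size)


def tissue_roi_features(tissue: TissueMap, atlas: AtlasParcellation,
                        mask: BrainMask | None = None) -> RoiFeatureVector:
    """Mean tissue value per atlas region, tagged with the tissue type."""
    metric = MetricMap(metric_tag=tissue.tissue_tag, values=tissue.values,
                       normalized=False)
    return metric_to_roi_features(metric, atlas, mask=mask)
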