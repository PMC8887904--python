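"""Gaussian smoothing and coronal slice handling.

Smoothed grey-matter maps are standard in voxel-based morphometry: smoothing
absorbs individual variability in sulcal/gyral positioning and renders the
maps approximately normally distributed.  The pipeline runs on smoothed and
unsmoothed maps alike, so both variants are first-class here.

Plane indices are 1-based throughout ("plane 113 (out of 156)" style), since
that is how coronal planes are referred to in radiological reading.
"""

from __future__ import annotations

import math
from dataclasses import replace
from typing import Union

import numpy as np
from scipy import ndimage

from .datatypes import GMSlice, GMVolume

_FWHM_TO_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))  # ≈ 2.3548


def fwhm_to_sigma(fwhm_mm: float) -> float:
    """Convert a Gaussian full-width-at-half-maximum to its standard deviation.

    sigma = FWHM / (2 * sqrt(2 * ln 2)).
    """
    if fwhm_mm < 0:
        raise ValueError("FWHM must be non-negative")
    return fwhm_mm / _FWHM_TO_SIGMA


def smooth(image: Union[GMSlice, GMVolume], fwhm_mm: float) -> Union[GMSlice, GMVolume]:
    """Gaussian-smooth a slice (2D) or volume (3D) by an isotropic FWHM in mm.

    The kernel sigma in pixels is ``fwhm_to_sigma(fwhm) / voxel_size`` per
    axis.  Reflective boundary handling preserves constant images and keeps
    total mass approximately conserved.  ``fwhm_mm = 0`` returns an identical
    copy.  The output is clipped to [0, 1] (numerically it can only leave the
    interval by rounding) and flagged as smoothed.
    """
    if fwhm_mm < 0:
        raise ValueError("FWHM must be non-negative")
    sigma_mm = fwhm_to_sigma(fwhm_mm)
    if isinstance(image, GMSlice):
        if fwhm_mm == 0:
            return image.copy()
        sigma_px = sigma_mm / image.voxel_size_mm
        out = ndimage.gaussian_filter(image.pixels, sigma_px, mode="reflect")
        return replace(image, pixels=np.clip(out, 0.0, 1.0), smoothed=True)
    if isinstance(image, GMVolume):
        if fwhm_mm == 0:
            return GMVolume(voxels=image.voxels.copy(), voxel_size_mm=image.voxel_size_mm)
        sigma_px = [sigma_mm / v for v in image.voxel_size_mm]
        out = ndimage.gaussian_filter(image.voxels, sigma_px, mode="reflect")
        return GMVolume(voxels=np.clip(out, 0.0, 1.0), voxel_size_mm=image.voxel_size_mm)
    raise TypeError(f"cannot smooth object of type {type(image).__name__}")


def extract_coronal_slice(volume: GMVolume, plane_index: int) -> GMSlice:
    """Extract the 1-based ``plane_index``-th coronal plane of a volume."""
    n = volume.n_coronal_planes
    if not 1 <= plane_index <= n:
        raise IndexError(f"plane {plane_index} out of range 1..{n}")
    pixels = volume.voxels[plane_index - 1].copy()
    return GMSlice(
        pixels=np.clip(pixels, 0.0, 1.0),
        voxel_size_mm=float(volume.voxel_size_mm[1]),
        plane_index=plane_index,
    )
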