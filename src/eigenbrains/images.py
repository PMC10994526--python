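"""Subject images and preprocessing: reference normalization and smoothing.

FDG-PET voxel intensities carry an arbitrary multiplicative global-uptake
factor (dose, scanner gain, metabolism level).  Dividing every voxel by the
mean uptake in a reference region assumed spared by disease (the pons)
removes that factor, making images comparable across subjects.  Smoothing
with an isotropic Gaussian kernel (FWHM in mm) trades resolution for noise
suppression; sigma = FWHM / (2 * sqrt(2 ln 2)) voxels.

The default pipeline order is normalize -> smooth; both operations commute
with global scaling so the order only matters near volume edges.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import nibabel as nib
import numpy as np
from scipy.ndimage import gaussian_filter

from .grid import TemplateGrid

__all__ = [
    "SubjectImage",
    "FWHM_TO_SIGMA",
    "normalize_to_reference",
    "smooth_gaussian",
    "flatten",
    "unflatten",
    "load_image",
    "save_image",
    "preprocess",
]

#: FWHM -> standard deviation conversion, 1 / (2 sqrt(2 ln 2)).
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class SubjectImage:
    subject_id: str
    values: np.ndarray  # 3-D volume on the TemplateGrid
    normalized: bool = False
    smoothed_fwhm_mm: float = 0.0

    def validate(self, grid: TemplateGrid) -> None:
        grid.check_volume(self.values)
        inside = self.values[grid.brain_mask]
        if not np.all(np.isfinite(inside)):
            raise ValueError(f"subject {self.subject_id}: non-finite values inside brain mask")


def normalize_to_reference(image: SubjectImage, grid: TemplateGrid) -> SubjectImage:
    """Divide all voxels by the reference-region mean (pons normalization).

    Scale-equivariant: normalize(c * x) == normalize(x) for c > 0, so
    per-subject global uptake differences cancel exactly.
    """
    image.validate(grid)
    ref_mean = float(np.mean(image.values[grid.reference_mask]))
    if not np.isfinite(ref_mean) or ref_mean <= 0:
        raise ValueError(
            f"subject {image.subject_id}: non-positive reference-region mean ({ref_mean})"
        )
    return replace(image, values=image.values / ref_mean, normalized=True)


def smooth_gaussian(image: SubjectImage, fwhm_mm: float, grid: TemplateGrid) -> SubjectImage:
    """Isotropic Gaussian smoothing of the full volume.

    Applied before masking, with reflective boundaries so total image mass
    is conserved.  ``fwhm_mm`` is converted to voxels via the grid's
    (isotropic) voxel size.
    """
    if fwhm_mm <= 0:
        raise ValueError("fwhm_mm must be positive")
    image.validate(grid)
    sigma = fwhm_mm * FWHM_TO_SIGMA / grid.voxel_mm
    smoothed = gaussian_filter(np.asarray(image.values, dtype=float), sigma=sigma, mode="reflect")
    return replace(image, values=smoothed, smoothed_fwhm_mm=float(fwhm_mm))


def flatten(image: SubjectImage, grid: TemplateGrid) -> np.ndarray:
    """Brain-mask voxels of the image as a vector in the fixed voxel order."""
    return grid.flatten(image.values)


def unflatten(vector: np.ndarray, grid: TemplateGrid, subject_id: str = "") -> SubjectImage:
    """Inverse of :func:`flatten`; voxels outside the mask are set to 0."""
    return SubjectImage(subject_id=subject_id, values=grid.unflatten(vector))


def preprocess(
    image: SubjectImage, grid: TemplateGrid, fwhm_mm: float = 6.0, smooth_first: bool = False
) -> SubjectImage:
    """Reference-normalize and smooth one subject image.

    Default order is normalize -> smooth; ``smooth_first`` swaps it.
    """
    steps = (
        (lambda im: smooth_gaussian(im, fwhm_mm, grid), lambda im: normalize_to_reference(im, grid))
        if smooth_first
        else (lambda im: normalize_to_reference(im, grid), lambda im: smooth_gaussian(im, fwhm_mm, grid))
    )
    for step in steps:
        image = step(image)
    return image


def load_image(path, grid: TemplateGrid, subject_id: str | None = None) -> SubjectImage:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.shape != grid.dims:
        raise_from = grid.describe_mismatch(data.shape, img.affine)
        from .grid import GridMismatchError

        raise GridMismatchError(raise_from)
    sid = subject_id if subject_id is not None else str(path)
    return SubjectImage(subject_id=sid, values=data)


def save_image(image: SubjectImage, grid: TemplateGrid, path) -> None:
    nib.save(grid.to_nifti(image.values), str(path))
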