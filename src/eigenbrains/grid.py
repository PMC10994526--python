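"""Template grid: the shared voxel lattice all images must live on.

Every stage of the pipeline (normalization, smoothing, the
participant-by-voxel matrix, Z-maps, decoding) assumes images are already
registered to a common template space.  The :class:`TemplateGrid` bundles
the lattice dimensions, the voxel size, the affine, the brain-tissue mask
that censors the analysis and the reference-region mask (a pons stand-in)
used for global-uptake normalization.  Registration itself is out of scope:
images that do not match the grid are rejected with a diff report, never
resampled.

Voxel order convention
----------------------
Masked vectors are laid out in lexicographic order with the first (x) axis
fastest, i.e. Fortran ravel order of the ``[x, y, z]`` array.  The order is
fixed so per-subject scores are bit-reproducible across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = ["TemplateGrid", "GridMismatchError", "default_grid", "load_mask", "save_volume"]


class GridMismatchError(ValueError):
    """Raised when an image does not share the template grid."""


@dataclass(frozen=True)
class TemplateGrid:
    dims: tuple[int, int, int]
    voxel_mm: float
    affine: np.ndarray
    brain_mask: np.ndarray
    reference_mask: np.ndarray
    _flat_mask: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        dims = tuple(int(d) for d in self.dims)
        if len(dims) != 3 or any(d <= 0 for d in dims):
            raise ValueError(f"dims must be 3 positive integers, got {self.dims!r}")
        object.__setattr__(self, "dims", dims)
        if self.voxel_mm <= 0:
            raise ValueError("voxel_mm must be positive")
        for name in ("brain_mask", "reference_mask"):
            m = np.asarray(getattr(self, name), dtype=bool)
            if m.shape != dims:
                raise ValueError(f"{name} shape {m.shape} does not match dims {dims}")
            if not m.any():
                raise ValueError(f"{name} has no true voxel")
            object.__setattr__(self, name, m)
        affine = np.asarray(self.affine, dtype=float)
        if affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        object.__setattr__(self, "affine", affine)
        # Fixed lexicographic voxel order: x fastest (Fortran ravel).
        object.__setattr__(self, "_flat_mask", self.brain_mask.ravel(order="F"))

    @property
    def n_voxels(self) -> int:
        """Number of voxels inside the brain mask."""
        return int(self.brain_mask.sum())

    @property
    def voxel_index(self) -> np.ndarray:
        """Flat (Fortran-order) indices of brain-mask voxels, in vector order."""
        return np.flatnonzero(self._flat_mask)

    def flatten(self, volume: np.ndarray) -> np.ndarray:
        """Extract the brain-mask voxels of a volume as a 1-D vector."""
        volume = np.asarray(volume)
        if volume.shape != self.dims:
            raise GridMismatchError(self.describe_mismatch(volume.shape))
        return volume.ravel(order="F")[self._flat_mask].astype(float)

    def unflatten(self, vector: np.ndarray) -> np.ndarray:
        """Place a masked vector back on the grid; zero outside the mask."""
        vector = np.asarray(vector, dtype=float)
        if vector.shape != (self.n_voxels,):
            raise ValueError(
                f"vector length {vector.shape} does not match mask size {self.n_voxels}"
            )
        flat = np.zeros(int(np.prod(self.dims)))
        flat[self._flat_mask] = vector
        return flat.reshape(self.dims, order="F")

    def describe_mismatch(self, other_shape, other_affine=None, other_voxel_mm=None) -> str:
        parts = [f"grid mismatch: expected dims {self.dims}, got {tuple(other_shape)}"]
        if other_affine is not None and not np.allclose(other_affine, self.affine):
            parts.append(f"affine differs:\n{self.affine}\nvs\n{np.asarray(other_affine)}")
        if other_voxel_mm is not None and other_voxel_mm != self.voxel_mm:
            parts.append(f"voxel size differs: {self.voxel_mm} vs {other_voxel_mm} mm")
        return "; ".join(parts)

    def check_volume(self, volume: np.ndarray) -> None:
        if np.asarray(volume).shape != self.dims:
            raise GridMismatchError(self.describe_mismatch(np.asarray(volume).shape))

    # --- NIfTI I/O -------------------------------------------------------
    def to_nifti(self, volume: np.ndarray) -> nib.Nifti1Image:
        self.check_volume(volume)
        return nib.Nifti1Image(np.asarray(volume, dtype=np.float32), self.affine)

    def save_masks(self, brain_path, reference_path) -> None:
        nib.save(nib.Nifti1Image(self.brain_mask.astype(np.uint8), self.affine), str(brain_path))
        nib.save(
            nib.Nifti1Image(self.reference_mask.astype(np.uint8), self.affine),
            str(reference_path),
        )


def default_grid(
    dims: tuple[int, int, int] = (18, 22, 18), voxel_mm: float = 6.0
) -> TemplateGrid:
    """Build the default analysis grid.

    The brain mask is the interior box (one-voxel margin on every face);
    the reference region is a fixed 3x3x3 block low in the volume, inside
    the brain mask, mimicking the pons: a small region relatively spared
    by neurodegeneration that anchors global-uptake normalization.
    """
    dims = tuple(int(d) for d in dims)
    brain = np.zeros(dims, dtype=bool)
    brain[1:-1, 1:-1, 1:-1] = True
    cx, cy = dims[0] // 2, dims[1] // 2
    ref = np.zeros(dims, dtype=bool)
    ref[cx - 1 : cx + 2, cy - 1 : cy + 2, 2:5] = True
    ref &= brain
    if not ref.any():  # degenerate tiny grids
        ref = brain.copy()
    affine = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
    return TemplateGrid(dims=dims, voxel_mm=voxel_mm, affine=affine,
                        brain_mask=brain, reference_mask=ref)


def load_mask(path, grid: TemplateGrid | None = None) -> np.ndarray:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj) > 0
    if grid is not None and data.shape != grid.dims:
        raise GridMismatchError(grid.describe_mismatch(data.shape, img.affine))
    return data


def save_volume(volume: np.ndarray, grid: TemplateGrid, path) -> None:
    nib.save(grid.to_nifti(volume), str(path))
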