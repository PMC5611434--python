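"""Reading subfield probability maps and thresholding them into binary masks.

Subfield segmentations (e.g. FreeSurfer hippocampal-subfield output) arrive
as NIfTI volumes whose voxel intensities encode subfield membership
probability on a 0-255 scale (255 = certain membership).  This module loads
such volumes, validates their geometry, and binarizes them at an intensity
threshold (default 127, i.e. probability >= 0.5) into an explicit voxel set
with world-space geometry.

All downstream geometry uses voxel *centers* mapped to world millimetres via
the NIfTI affine, so anisotropic or oblique acquisitions are handled
correctly even though typical inputs are 1 mm isotropic.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass

import nibabel as nib
import numpy as np

logger = logging.getLogger("subaxis")

#: Default binarization threshold: 127/255 ~ 0.498, the integer intensity at
#: which membership probability is read as "0.5 or higher".  Inclusive.
DEFAULT_THRESHOLD = 127

#: World axis (RAS convention) that points anterior.  NIfTI affines map voxel
#: indices to RAS+ world coordinates, so anterior is always world axis 1 (+Y).
ANTERIOR_WORLD_AXIS = 1


class MaskError(ValueError):
    """Raised for invalid or degenerate mask inputs."""


@dataclass(frozen=True)
class ProbabilityVolume:
    """A 3-D grid of subfield-membership intensities with voxel geometry.

    Parameters
    ----------
    intensities
        3-D integer array with values in [0, 255].
    affine
        4x4 voxel-index -> world-mm map (RAS+ world convention).
    anterior_axis
        Index of the world axis that points anterior (1 for RAS).
    """

    intensities: np.ndarray
    affine: np.ndarray
    anterior_axis: int = ANTERIOR_WORLD_AXIS

    def __post_init__(self) -> None:
        inten = np.asarray(self.intensities)
        if inten.ndim != 3:
            raise MaskError(f"intensities must be 3-D, got shape {inten.shape}")
        if inten.size and (inten.min() < 0 or inten.max() > 255):
            raise MaskError(
                "intensities outside [0, 255]: "
                f"range [{inten.min()}, {inten.max()}]"
            )
        aff = np.asarray(self.affine, dtype=float)
        if aff.shape != (4, 4):
            raise MaskError(f"affine must be 4x4, got {aff.shape}")
        if abs(np.linalg.det(aff[:3, :3])) < 1e-12:
            raise MaskError("affine is not invertible (singular 3x3 block)")
        object.__setattr__(self, "intensities", inten)
        object.__setattr__(self, "affine", aff)

    @property
    def voxel_size(self) -> tuple[float, float, float]:
        """Voxel edge lengths in mm (column norms of the affine)."""
        return tuple(np.linalg.norm(self.affine[:3, :3], axis=0))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape


@dataclass(frozen=True)
class BinaryMask:
    """A thresholded subfield: a set of in-mask voxel indices plus geometry.

    ``voxels`` is stored as an (n, 3) integer array of index triples in
    lexicographic order (set semantics with a canonical ordering).
    """

    voxels: np.ndarray
    affine: np.ndarray
    shape: tuple[int, int, int]
    anterior_axis: int = ANTERIOR_WORLD_AXIS

    def __post_init__(self) -> None:
        vox = np.asarray(self.voxels, dtype=np.int64).reshape(-1, 3)
        # canonical lexicographic order; also de-duplicates
        vox = np.unique(vox, axis=0)
        aff = np.asarray(self.affine, dtype=float)
        if abs(np.linalg.det(aff[:3, :3])) < 1e-12:
            raise MaskError("affine is not invertible (singular 3x3 block)")
        object.__setattr__(self, "voxels", vox)
        object.__setattr__(self, "affine", aff)
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))

    @property
    def n_voxels(self) -> int:
        return int(self.voxels.shape[0])

    @property
    def voxel_size(self) -> tuple[float, float, float]:
        return tuple(np.linalg.norm(self.affine[:3, :3], axis=0))

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3 (product of voxel edge lengths)."""
        return float(np.prod(self.voxel_size))

    @property
    def total_volume_mm3(self) -> float:
        return self.n_voxels * self.voxel_volume

    def world_coordinates(self, voxels: np.ndarray | None = None) -> np.ndarray:
        """World-mm coordinates of voxel centers, (n, 3)."""
        vox = self.voxels if voxels is None else np.asarray(voxels).reshape(-1, 3)
        return vox @ self.affine[:3, :3].T + self.affine[:3, 3]

    def to_grid(self) -> np.ndarray:
        """Dense boolean occupancy grid of ``shape``."""
        grid = np.zeros(self.shape, dtype=bool)
        grid[tuple(self.voxels.T)] = True
        return grid


def read_mask_volume(path: str | os.PathLike) -> ProbabilityVolume:
    """Load a 3-D subfield probability map from a NIfTI file.

    Intensities are validated to lie in [0, 255].  Inputs already binarized
    to {0, 1} are rescaled to {0, 255} with a warning.  Trailing singleton
    dimensions are squeezed; genuinely 4-D inputs are rejected.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(f"mask volume not found: {path}")
    img = nib.load(path)
    data = np.asanyarray(img.dataobj)
    if data.ndim > 3:
        extra = data.shape[3:]
        if all(s == 1 for s in extra):
            data = data.reshape(data.shape[:3])
        else:
            raise MaskError(
                f"expected a 3-D single-frame volume, got shape {data.shape}"
            )
    if data.ndim != 3:
        raise MaskError(f"expected a 3-D volume, got shape {data.shape}")
    if not np.all(np.isfinite(data)):
        raise MaskError("volume contains non-finite intensities")
    rounded = np.rint(data)
    if np.max(np.abs(data - rounded)) > 1e-6:
        raise MaskError("intensities are not integer-valued on the 0-255 scale")
    data = rounded.astype(np.int64)
    if data.min() < 0 or data.max() > 255:
        raise MaskError(
            f"intensities outside [0, 255]: range [{data.min()}, {data.max()}]"
        )
    values = np.unique(data)
    if set(values.tolist()) <= {0, 1} and 1 in values:
        logger.warning(
            "%s: volume looks already binarized to {0,1}; rescaling to {0,255}",
            path,
        )
        data = data * 255
    return ProbabilityVolume(intensities=data, affine=img.affine)


def write_mask_volume(
    vol: ProbabilityVolume | BinaryMask, path: str | os.PathLike
) -> None:
    """Write a probability volume or a binary mask (as 0/255) to NIfTI."""
    if isinstance(vol, BinaryMask):
        data = np.zeros(vol.shape, dtype=np.uint8)
        data[tuple(vol.voxels.T)] = 255
        affine = vol.affine
    else:
        data = vol.intensities.astype(np.uint8)
        affine = vol.affine
    nib.save(nib.Nifti1Image(data, affine), os.fspath(path))


def threshold_probability_map(
    vol: ProbabilityVolume, threshold: int = DEFAULT_THRESHOLD
) -> BinaryMask:
    """Binarize a probability map: keep voxels with intensity >= threshold.

    The comparison is inclusive: intensity 127 corresponds to membership
    probability ~0.5, and voxels at probability "0.5 or higher" belong to
    the subfield.

    Raises
    ------
    MaskError
        If the threshold is outside [1, 255] or no voxel reaches it.
    """
    if not (1 <= threshold <= 255):
        raise MaskError(f"threshold must be in [1, 255], got {threshold}")
    idx = np.argwhere(vol.intensities >= threshold)
    if idx.shape[0] == 0:
        raise MaskError(f"no voxels at or above threshold {threshold}")
    return BinaryMask(
        voxels=idx,
        affine=vol.affine,
        shape=vol.shape,
        anterior_axis=vol.anterior_axis,
    )
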