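"""3D image volumes with physical geometry.

The package works on a single in-memory container, :class:`ImageVolume`:
a 3D scalar grid (MR intensity in arbitrary units, or CT numbers in HU)
plus voxel spacing and origin in millimetres.  Grid axes are bound to the
anatomical axes in the fixed order

    axis 0 = RL (right-left), axis 1 = AP (anterior-posterior),
    axis 2 = CC (cranio-caudal, the slice direction).

Physical coordinates refer to voxel *centers*: voxel ``(i, j, k)`` sits at
``origin + (i, j, k) * spacing``.  Volumes are read and written as
single-file NIfTI images whose affine is diagonal in this axis order;
that keeps the axis binding deterministic and the round trip bit-exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

AXIS_LABELS = ("RL", "AP", "CC")


@dataclass
class ImageVolume:
    """A 3D scalar grid with voxel spacing and origin in mm.

    Parameters
    ----------
    values : ndarray, shape (nRL, nAP, nCC)
        Voxel values (MR intensity or HU).
    spacing : 3-sequence of float
        Voxel size in mm along RL, AP, CC. Must be positive.
    origin : 3-sequence of float
        Physical position (mm) of the center of voxel (0, 0, 0).
    """

    values: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    axis_labels: tuple[str, str, str] = AXIS_LABELS

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(
                f"ImageVolume requires a 3D array, got {self.values.ndim}D"
            )
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.spacing.shape != (3,) or self.origin.shape != (3,):
            raise ValueError("spacing and origin must be 3-vectors")
        if np.any(self.spacing <= 0):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("volume contains non-finite values")
        if tuple(self.axis_labels) != AXIS_LABELS:
            raise ValueError(f"axis labels must be {AXIS_LABELS} in order")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def voxel_to_physical(self, indices: np.ndarray) -> np.ndarray:
        """Physical center coordinates (mm) of voxel indices, shape (..., 3)."""
        return self.origin + np.asarray(indices, dtype=float) * self.spacing

    def physical_to_voxel(self, points: np.ndarray) -> np.ndarray:
        """Nearest voxel index for physical points (mm), shape (..., 3)."""
        idx = np.rint((np.asarray(points, dtype=float) - self.origin) / self.spacing)
        return idx.astype(int)

    def contains_index(self, index) -> bool:
        index = np.asarray(index)
        return bool(np.all(index >= 0) and np.all(index < self.shape))

    def copy(self) -> "ImageVolume":
        return ImageVolume(self.values.copy(), self.spacing.copy(), self.origin.copy())


def raster_order_key(indices: np.ndarray, shape) -> np.ndarray:
    """Scalar raster rank of voxel indices: CC-major, then AP, then RL.

    Used as the deterministic tie-break whenever voxels must be ordered.
    """
    idx = np.atleast_2d(np.asarray(indices))
    n_rl, n_ap, _ = shape
    return (idx[:, 2].astype(np.int64) * shape[1] + idx[:, 1]) * n_rl + idx[:, 0]


def write_volume(vol: ImageVolume, path) -> None:
    """Write a volume as single-file NIfTI with a diagonal affine."""
    affine = np.diag(np.append(vol.spacing, 1.0))
    affine[:3, 3] = vol.origin
    img = nib.Nifti1Image(vol.values, affine)
    img.header.set_zooms(tuple(vol.spacing))
    nib.save(img, str(path))


def read_volume(path) -> ImageVolume:
    """Read a single-file NIfTI volume written by :func:`write_volume`.

    Raises
    ------
    ValueError
        If the image is not 3D or the affine is missing/non-diagonal
        (axis binding would be ambiguous).
    """
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D volume, got {data.ndim}D data in {path}")
    affine = img.affine
    if affine is None:
        raise ValueError(f"volume {path} carries no affine; geometry unknown")
    rot = affine[:3, :3]
    off_diag = rot - np.diag(np.diag(rot))
    if np.max(np.abs(off_diag)) > 1e-6:
        raise ValueError(
            "non-diagonal affine: cannot bind grid axes to RL/AP/CC deterministically"
        )
    spacing = np.diag(rot).astype(float)
    origin = affine[:3, 3].astype(float)
    if np.any(spacing < 0):
        # flip negative axes back to the canonical orientation
        for ax in range(3):
            if spacing[ax] < 0:
                data = np.flip(data, axis=ax)
                origin[ax] = origin[ax] + spacing[ax] * (data.shape[ax] - 1)
                spacing[ax] = -spacing[ax]
    return ImageVolume(data, spacing, origin)
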