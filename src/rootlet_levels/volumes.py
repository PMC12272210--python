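"""3D label volumes: NIfTI I/O, canonical LPI reorientation, and resampling.

Everything downstream operates on :class:`LabelVolume`, a thin wrapper around
an integer voxel array plus its voxel-to-physical affine.  The package
canonicalizes all inputs to LPI orientation (axes increase toward the
subject's Left, Posterior and Inferior), so the third voxel axis is always
the superior-inferior axis and *rostral* means a smaller third index.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "LabelVolume",
    "PhysicalPoint",
    "read_volume",
    "write_volume",
    "to_lpi",
    "resample",
    "pmj_from_volume",
]

#: target orientation code for all internal processing
LPI_AXCODES = ("L", "P", "I")

#: labels within this distance of an integer are rounded; beyond it we refuse
INTEGER_TOLERANCE = 1e-6


@dataclass(frozen=True)
class PhysicalPoint:
    """A point in the scanner's physical space, in millimetres."""

    x: float
    y: float
    z: float

    def __post_init__(self) -> None:
        if not all(math.isfinite(v) for v in (self.x, self.y, self.z)):
            raise ValueError("physical coordinates must be finite")

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)

    @classmethod
    def from_array(cls, arr) -> "PhysicalPoint":
        a = np.asarray(arr, dtype=float).reshape(3)
        return cls(float(a[0]), float(a[1]), float(a[2]))


@dataclass
class LabelVolume:
    """A 3D integer label map with its voxel-to-physical-mm affine.

    Parameters
    ----------
    data : ndarray of int, shape (nx, ny, nz)
        Voxel labels; non-negative integers (0 = background).
    affine : ndarray, shape (4, 4)
        Voxel-index to physical-mm transform (NIfTI convention, RAS+ world).
    """

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D volume, got {self.data.ndim}D")
        if not np.issubdtype(self.data.dtype, np.integer):
            self.data = _coerce_integer(self.data)
        if self.data.size and self.data.min() < 0:
            raise ValueError("label volumes must be non-negative")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")

    # -- derived geometry ---------------------------------------------------

    @property
    def shape(self) -> tuple:
        return self.data.shape

    @property
    def spacing(self) -> np.ndarray:
        """Per-axis voxel size in mm (column norms of the affine)."""
        return nib.affines.voxel_sizes(self.affine)

    @property
    def orientation(self) -> str:
        """Three-letter axis code, e.g. ``'LPI'``."""
        return "".join(nib.aff2axcodes(self.affine))

    def labels(self, include_background: bool = False) -> np.ndarray:
        """Sorted array of label values present in the volume."""
        vals = np.unique(self.data)
        if not include_background:
            vals = vals[vals != 0]
        return vals

    def same_grid(self, other: "LabelVolume", atol: float = 1e-4) -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=atol
        )

    def voxel_to_physical(self, ijk) -> np.ndarray:
        """Map voxel indices (…, 3) to physical mm coordinates."""
        return nib.affines.apply_affine(self.affine, np.asarray(ijk, dtype=float))

    def physical_to_voxel(self, xyz) -> np.ndarray:
        """Map physical mm coordinates (…, 3) to (fractional) voxel indices."""
        inv = np.linalg.inv(self.affine)
        return nib.affines.apply_affine(inv, np.asarray(xyz, dtype=float))

    def copy(self) -> "LabelVolume":
        return LabelVolume(self.data.copy(), self.affine.copy())


def _coerce_integer(data: np.ndarray) -> np.ndarray:
    rounded = np.rint(data)
    err = np.max(np.abs(data - rounded)) if data.size else 0.0
    if err > INTEGER_TOLERANCE:
        raise ValueError(
            f"non-integer label data (max deviation {err:.3g} from integers)"
        )
    if err > 0:
        warnings.warn(
            "label data within 1e-6 of integers; rounding", stacklevel=3
        )
    return rounded.astype(np.int32)


# -- I/O ---------------------------------------------------------------------


def read_volume(path) -> LabelVolume:
    """Read a 3D NIfTI label volume.

    The volume is returned as stored on disk; no reorientation is performed
    (see :func:`to_lpi`).  Float data that is within ``1e-6`` of integers is
    rounded with a warning; anything further off raises ``ValueError``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected 3D volume, got {data.ndim}D in {path.name}")
    return LabelVolume(data, img.affine)


def write_volume(vol: LabelVolume, path) -> None:
    """Write a label volume as int16 NIfTI, affine in both sform and qform."""
    img = nib.Nifti1Image(vol.data.astype(np.int16), vol.affine)
    img.set_sform(vol.affine, code=1)
    img.set_qform(vol.affine, code=1)
    nib.save(img, str(path))


# -- reorientation -----------------------------------------------------------

_MIN_AXIS_ALIGNMENT = math.cos(math.radians(45.0)) - 1e-9


def to_lpi(vol: LabelVolume) -> LabelVolume:
    """Reorient a volume to canonical LPI axes.

    The voxel data are permuted/flipped and the affine updated so that every
    labelled voxel keeps its physical position exactly.  Raises on oblique
    affines whose axes cannot be assigned to anatomical directions within 45
    degrees.
    """
    rot = vol.affine[:3, :3]
    norms = np.linalg.norm(rot, axis=0)
    if np.any(norms == 0):
        raise ValueError("degenerate affine: zero-length axis")
    if np.any(np.max(np.abs(rot), axis=0) / norms < _MIN_AXIS_ALIGNMENT):
        raise ValueError(
            "oblique affine: voxel axes cannot be assigned to anatomical "
            "directions within 45 degrees"
        )
    current = nib.orientations.io_orientation(vol.affine)
    target = nib.orientations.axcodes2ornt(LPI_AXCODES)
    transform = nib.orientations.ornt_transform(current, target)
    identity = np.array([[0, 1], [1, 1], [2, 1]], dtype=float)
    if np.array_equal(transform, identity):
        return vol
    new_data = nib.orientations.apply_orientation(vol.data, transform)
    new_affine = vol.affine @ nib.orientations.inv_ornt_aff(transform, vol.shape)
    return LabelVolume(np.ascontiguousarray(new_data), new_affine)


# -- resampling --------------------------------------------------------------


def resample(vol: LabelVolume, new_spacing, mode: str = "nearest") -> LabelVolume:
    """Resample a volume to a new voxel spacing.

    Grid convention: the centre of the first output voxel coincides with the
    centre of the first input voxel, and the output size is
    ``ceil(extent / new_spacing)`` per axis, so the output grid covers the
    input physical extent.  ``mode='nearest'`` never introduces new label
    values and is required for multi-class label maps; ``mode='linear'`` is
    allowed only for binary masks (the interpolated values are rounded, i.e.
    thresholded at 0.5).
    """
    if mode not in ("nearest", "linear"):
        raise ValueError(f"unknown mode {mode!r}")
    new_spacing = np.broadcast_to(np.asarray(new_spacing, dtype=float), (3,)).copy()
    if np.any(new_spacing <= 0):
        raise ValueError("new_spacing must be strictly positive")
    n_labels = vol.labels(include_background=True).size
    if mode == "linear" and n_labels > 2:
        raise ValueError("labels require nearest: multi-class volume, use mode='nearest'")

    old_spacing = vol.spacing
    ratio = new_spacing / old_spacing
    extent = np.array(vol.shape) * old_spacing
    new_shape = np.ceil(extent / new_spacing).astype(int)
    new_shape = np.maximum(new_shape, 1)

    grids = np.meshgrid(
        *(np.arange(n) * r for n, r in zip(new_shape, ratio)), indexing="ij"
    )
    coords = np.stack(grids)
    order = 0 if mode == "nearest" else 1
    out = ndimage.map_coordinates(
        vol.data.astype(float), coords, order=order, mode="nearest"
    )
    out = np.rint(out).astype(vol.data.dtype)

    new_affine = vol.affine.copy()
    new_affine[:3, :3] = vol.affine[:3, :3] * ratio[np.newaxis, :]
    return LabelVolume(out, new_affine)


# -- PMJ helper --------------------------------------------------------------


def pmj_from_volume(vol: LabelVolume) -> PhysicalPoint:
    """Extract the PMJ physical coordinate from a single-voxel label volume.

    If several voxels are labelled, their centroid is used with a warning.
    """
    idx = np.argwhere(vol.data > 0)
    if idx.shape[0] == 0:
        raise ValueError("PMJ volume contains no labelled voxel")
    if idx.shape[0] > 1:
        warnings.warn(
            f"PMJ volume has {idx.shape[0]} labelled voxels; using centroid",
            stacklevel=2,
        )
    centroid = idx.mean(axis=0)
    return PhysicalPoint.from_array(vol.voxel_to_physical(centroid))
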