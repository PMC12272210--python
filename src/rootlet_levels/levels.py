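"""Spinal-level derivation from rootlet segmentations.

The pipeline: dilate the binary spinal-cord mask, intersect it with the
multi-class dorsal-rootlets segmentation to locate each level's root entry
zone, project each level's rostral/caudal intersection slices back onto the
cord to produce a semantic spinal-level volume (label v on every cord voxel
of the level's slices), then measure rostro-caudal level lengths and
distances from the pontomedullary junction (PMJ) along the cord centerline,
so that cord curvature is taken into account.

All volumes are assumed canonical LPI: the third axis is superior-inferior
and slice index increases caudally.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
from scipy import ndimage

from .volumes import LabelVolume, PhysicalPoint

__all__ = [
    "Centerline",
    "LevelSpan",
    "LevelSet",
    "dilate_mask",
    "intersect_rootlets",
    "derive_spinal_levels",
    "extract_centerline",
    "pmj_distance",
    "measure_levels",
]


@dataclass
class Centerline:
    """Ordered per-slice cord centerline with cumulative arc length.

    ``points[i]`` is the physical-mm center of mass of the cord on slice
    ``slice_indices[i]``; ``cumulative_arc_mm[i]`` is the polyline arc length
    from the first (most rostral) entry.
    """

    slice_indices: np.ndarray  # (n,) int, ascending (rostral -> caudal)
    points: np.ndarray  # (n, 3) physical mm
    cumulative_arc_mm: np.ndarray  # (n,), starts at 0, non-decreasing

    def __post_init__(self) -> None:
        self.slice_indices = np.asarray(self.slice_indices, dtype=int)
        self.points = np.asarray(self.points, dtype=float)
        self.cumulative_arc_mm = np.asarray(self.cumulative_arc_mm, dtype=float)
        if not (
            len(self.slice_indices) == len(self.points) == len(self.cumulative_arc_mm)
        ):
            raise ValueError("centerline fields must have equal length")
        if np.any(np.diff(self.cumulative_arc_mm) < 0):
            raise ValueError("cumulative arc length must be non-decreasing")

    def _entry(self, slice_index: int) -> int:
        pos = np.nonzero(self.slice_indices == slice_index)[0]
        if pos.size == 0:
            raise ValueError(f"slice {slice_index} outside centerline coverage")
        return int(pos[0])

    def arc_at(self, slice_index: int) -> float:
        return float(self.cumulative_arc_mm[self._entry(slice_index)])

    def point_at(self, slice_index: int) -> np.ndarray:
        return self.points[self._entry(slice_index)]


@dataclass
class LevelSpan:
    """One spinal level's slice extent and PMJ distances."""

    label: int
    rostral_slice: int
    caudal_slice: int
    middle_slice: int
    d_rostral: Optional[float] = None  # mm from PMJ along the centerline
    d_middle: Optional[float] = None
    d_caudal: Optional[float] = None
    length_mm: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.rostral_slice <= self.middle_slice <= self.caudal_slice:
            raise ValueError("require rostral <= middle <= caudal slice")


@dataclass
class LevelSet:
    """Semantic spinal-level volume plus per-level spans."""

    spans: List[LevelSpan]
    levels_volume: LabelVolume
    absent_labels: List[int] = field(default_factory=list)

    def span(self, label: int) -> LevelSpan:
        for s in self.spans:
            if s.label == label:
                return s
        raise KeyError(label)

    @property
    def labels(self) -> List[int]:
        return [s.label for s in self.spans]


# ---------------------------------------------------------------------------

_STRUCTURE_6 = ndimage.generate_binary_structure(3, 1)  # face-connected


def dilate_mask(cord: LabelVolume, radius_voxels: int) -> LabelVolume:
    """Morphological dilation by ``radius_voxels`` iterations of the
    face-connected (6-neighbour) structuring element."""
    if radius_voxels < 0:
        raise ValueError("radius must be >= 0")
    vals = cord.labels(include_background=True)
    if not set(vals.tolist()) <= {0, 1}:
        raise ValueError("dilate_mask expects a binary mask")
    if radius_voxels == 0:
        return cord.copy()
    out = ndimage.binary_dilation(
        cord.data > 0, structure=_STRUCTURE_6, iterations=radius_voxels
    )
    return LabelVolume(out.astype(np.int16), cord.affine.copy())


def intersect_rootlets(rootlets: LabelVolume, dilated_cord: LabelVolume) -> LabelVolume:
    """Keep each rootlets label only where the (dilated) cord is foreground."""
    if not rootlets.same_grid(dilated_cord):
        raise ValueError("rootlets and cord grids do not match")
    out = np.where(dilated_cord.data > 0, rootlets.data, 0)
    return LabelVolume(out.astype(rootlets.data.dtype), rootlets.affine.copy())


def derive_spinal_levels(
    rootlets: LabelVolume,
    cord: LabelVolume,
    dilation_radius: int = 3,
    labels: Optional[Sequence[int]] = None,
) -> LevelSet:
    """Derive the semantic spinal-level volume from rootlets + cord masks.

    For each rootlets label present in the intersection with the dilated
    cord, the rostral/caudal slices of the intersection are projected onto
    the cord: every cord voxel in those slices receives the label.  Slices
    claimed by two levels go to the more rostral (smaller) label, with a
    warning.  Slices in inter-level gaps remain 0.  Labels whose intersection
    is empty are listed in ``absent_labels``.
    """
    if not (cord.data > 0).any():
        raise ValueError("empty cord mask")
    if labels is None:
        labels = [int(v) for v in rootlets.labels()]
    labels = sorted(int(v) for v in labels)

    dilated = dilate_mask(cord, dilation_radius)
    inter = intersect_rootlets(rootlets, dilated)

    nz = cord.shape[2]
    owner = np.zeros(nz, dtype=int)  # slice -> owning label (0 = none)
    spans: List[LevelSpan] = []
    absent: List[int] = []
    for v in labels:
        zs = np.nonzero((inter.data == v).any(axis=(0, 1)))[0]
        if zs.size == 0:
            absent.append(v)
            continue
        kr, kc = int(zs.min()), int(zs.max())
        span_slices = np.arange(kr, kc + 1)
        taken = owner[span_slices] != 0
        if taken.any():
            warnings.warn(
                f"level {v} overlaps slices {span_slices[taken].tolist()} already "
                f"assigned to a more rostral level; keeping the rostral label",
                stacklevel=2,
            )
        owner[span_slices[~taken]] = v
        spans.append(
            LevelSpan(
                label=v,
                rostral_slice=kr,
                caudal_slice=kc,
                middle_slice=(kr + kc) // 2,
            )
        )

    levels_data = np.zeros(cord.shape, dtype=np.int16)
    cord_fg = cord.data > 0
    for kk in np.nonzero(owner)[0]:
        sl = levels_data[:, :, kk]
        sl[cord_fg[:, :, kk]] = owner[kk]
    return LevelSet(
        spans=spans,
        levels_volume=LabelVolume(levels_data, cord.affine.copy()),
        absent_labels=absent,
    )


# ---------------------------------------------------------------------------


def extract_centerline(
    cord: LabelVolume, smoothing_mm: Optional[float] = None
) -> Centerline:
    """Per-slice center-of-mass centerline of a binary cord mask.

    Slices with more than one connected component use the largest (with a
    warning).  Arc length is the cumulative Euclidean distance between
    consecutive slice points in physical mm.

    ``smoothing_mm`` applies an in-plane moving average over an odd window
    of approximately that rostro-caudal extent; off by default since
    center-of-mass centerlines are already smooth on clean masks.
    """
    fg = cord.data > 0
    slice_has = fg.any(axis=(0, 1))
    ks = np.nonzero(slice_has)[0]
    if ks.size < 2:
        raise ValueError("cord must span at least 2 slices")

    pts = np.empty((ks.size, 3), dtype=float)
    structure2d = ndimage.generate_binary_structure(2, 1)
    for n, kk in enumerate(ks):
        sl = fg[:, :, kk]
        labeled, n_comp = ndimage.label(sl, structure=structure2d)
        if n_comp > 1:
            warnings.warn(
                f"slice {kk}: {n_comp} cord components; using the largest",
                stacklevel=2,
            )
            sizes = ndimage.sum_labels(sl, labeled, index=np.arange(1, n_comp + 1))
            sl = labeled == (int(np.argmax(sizes)) + 1)
        ci, cj = ndimage.center_of_mass(sl)
        pts[n] = cord.voxel_to_physical([ci, cj, float(kk)])

    if smoothing_mm is not None and smoothing_mm > 0:
        sz = float(cord.spacing[2])
        w = max(1, int(round(smoothing_mm / sz)))
        if w % 2 == 0:
            w += 1
        if w > 1:
            # smooth the in-plane coordinates only; the slice (S-I) coordinate
            # stays exact so arc positions are not compressed at the ends
            kernel = np.ones(w) / w
            padded = np.pad(pts, ((w // 2, w // 2), (0, 0)), mode="edge")
            for d in range(2):
                pts[:, d] = np.convolve(padded[:, d], kernel, mode="valid")

    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    return Centerline(slice_indices=ks, points=pts, cumulative_arc_mm=arc)


def pmj_distance(centerline: Centerline, pmj: PhysicalPoint, slice_index: int) -> float:
    """Curvature-aware distance (mm) from the PMJ to a cord slice.

    The PMJ is projected to its nearest centerline point; the distance is
    the arc length between that point and the requested slice, plus the
    Euclidean offset of the PMJ from the centerline.
    """
    arc_slice = centerline.arc_at(slice_index)
    d = np.linalg.norm(centerline.points - pmj.as_array()[None, :], axis=1)
    m = int(np.argmin(d))
    return abs(arc_slice - float(centerline.cumulative_arc_mm[m])) + float(d[m])


def measure_levels(
    level_set: LevelSet, centerline: Centerline, pmj: PhysicalPoint
) -> LevelSet:
    """Fill PMJ distances and rostro-caudal lengths for every span (in place).

    ``d_rostral/d_middle/d_caudal`` are centerline distances from the PMJ to
    the span's rostral/middle/caudal slices; ``length_mm = d_caudal -
    d_rostral`` is the level's rostro-caudal (arc) length.
    """
    for s in level_set.spans:
        s.d_rostral = pmj_distance(centerline, pmj, s.rostral_slice)
        s.d_middle = pmj_distance(centerline, pmj, s.middle_slice)
        s.d_caudal = pmj_distance(centerline, pmj, s.caudal_slice)
        s.length_mm = s.d_caudal - s.d_rostral
    return level_set
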