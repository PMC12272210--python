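"""Synthetic cervical-cord phantoms with known ground truth.

The generator emulates the label volumes the pipeline consumes in practice:
a tubular spinal cord along a straight or lordotic (sagittal-sine) centerline,
one thin dorsal rootlet structure per level (labels 2-8 for C2-C8) spanning a
known superior-inferior extent, and a pontomedullary-junction (PMJ) point at
the rostral end of the cord.  Volumes are produced in canonical LPI
orientation: axis 0 increases toward Left, axis 1 toward Posterior (dorsal),
axis 2 toward Inferior (caudal), so slice index 0 is the rostral end.

:func:`simulate_raters` corrupts a ground-truth mask with per-voxel
sensitivity/specificity errors to emulate imperfect manual raters, which is
the input regime of the STAPLE consensus.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .volumes import LabelVolume, PhysicalPoint

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "RaterModel",
    "generate_phantom",
    "simulate_raters",
    "pmj_volume_from_truth",
    "random_phantom_spec",
    "DEFAULT_LEVELS",
]

# Default level spans in mm from the volume top (rostral end), C2..C8.
# Rostro-caudal lengths follow published in-vivo cervical measurements
# (roughly 6.5-11.3 mm per level) with ~1.5 mm inter-level gaps.
DEFAULT_LEVELS: Tuple[Tuple[int, float, float], ...] = (
    (2, 5.0, 12.5),
    (3, 14.0, 25.3),
    (4, 27.0, 33.5),
    (5, 35.0, 41.9),
    (6, 43.5, 52.1),
    (7, 54.0, 63.1),
    (8, 65.0, 75.0),
)


@dataclass
class PhantomSpec:
    """Geometry of a synthetic cord + rootlets phantom.

    All lengths are millimetres.  ``levels`` lists ``(label, rostral_z,
    caudal_z)`` with *z* measured from the volume top (rostral end).
    """

    shape: Tuple[int, int, int] = (48, 48, 96)
    spacing: Tuple[float, float, float] = (0.8, 0.8, 0.8)
    centerline_kind: str = "straight"  # or "sagittal_sine"
    sine_amplitude: float = 5.0
    sine_period: float = 80.0
    cord_radius: float = 4.0
    rootlet_radius: float = 0.6
    levels: Sequence[Tuple[int, float, float]] = DEFAULT_LEVELS
    pmj_offset: float = 2.0
    seed: int = 0
    allow_overlap: bool = False

    def __post_init__(self) -> None:
        if self.centerline_kind not in ("straight", "sagittal_sine"):
            raise ValueError(f"unknown centerline_kind {self.centerline_kind!r}")
        labels = [lv[0] for lv in self.levels]
        if labels != sorted(set(labels)):
            raise ValueError("level labels must be unique and sorted ascending")
        if any(not 2 <= v <= 8 for v in labels):
            raise ValueError("level labels must lie in 2..8 (C2-C8)")
        z_max = (self.shape[2] - 1) * self.spacing[2]
        for v, rz, cz in self.levels:
            if not rz < cz:
                raise ValueError(f"level {v}: rostral_z must be < caudal_z")
            if rz < 0 or cz > z_max:
                raise ValueError(
                    f"level {v}: span [{rz}, {cz}] outside cord extent [0, {z_max:.1f}]"
                )
        if not 0 <= self.pmj_offset <= z_max:
            raise ValueError("pmj_offset outside the volume's z extent")

    def slice_spans(self) -> Dict[int, Tuple[int, int]]:
        """Level spans converted to slice indices (rounded to nearest slice)."""
        sz = self.spacing[2]
        return {
            v: (int(round(rz / sz)), int(round(cz / sz)))
            for v, rz, cz in self.levels
        }


@dataclass
class PhantomTruth:
    """Ground truth recorded by the generator, used as the test oracle."""

    spans: Dict[int, Tuple[int, int]]
    centerline_points: np.ndarray  # (n_slices, 3) physical mm
    pmj: PhysicalPoint
    arc_length_table: np.ndarray  # (n_slices,) cumulative mm, 0 at slice 0

    def to_json(self) -> str:
        return json.dumps(
            {
                "spans": {str(k): list(v) for k, v in self.spans.items()},
                "centerline_points": self.centerline_points.tolist(),
                "pmj": [self.pmj.x, self.pmj.y, self.pmj.z],
                "arc_length_table": self.arc_length_table.tolist(),
            },
            indent=2,
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "PhantomTruth":
        d = json.loads(text)
        return cls(
            spans={int(k): tuple(v) for k, v in d["spans"].items()},
            centerline_points=np.array(d["centerline_points"], dtype=float),
            pmj=PhysicalPoint(*d["pmj"]),
            arc_length_table=np.array(d["arc_length_table"], dtype=float),
        )


@dataclass
class RaterModel:
    """Per-voxel error model for simulated manual raters.

    Each rater retains a true foreground voxel with probability ``sensitivity``
    and, within a bounded region of interest (the foreground bounding box
    dilated by ``roi_margin`` voxels), turns a background voxel into
    foreground with probability ``1 - specificity``.  Specificity is defined
    over the bounded ROI because over a whole volume it is trivially ~1.
    """

    n_raters: int = 4
    sensitivity: float = 0.9
    specificity: float = 0.99
    roi_margin: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_raters < 1:
            raise ValueError("need at least one rater")
        for name in ("sensitivity", "specificity"):
            p = getattr(self, name)
            if not 0.0 < p <= 1.0:
                raise ValueError(f"{name} must be in (0, 1]")


# ---------------------------------------------------------------------------


def _lpi_affine(spacing: Sequence[float]) -> np.ndarray:
    """Affine of an LPI-oriented grid: axes point toward -x, -y, -z (RAS+)."""
    aff = np.diag([-spacing[0], -spacing[1], -spacing[2], 1.0])
    return aff


def _centerline_inplane_mm(spec: PhantomSpec, k: np.ndarray):
    """In-plane centerline position (index-mm units) at slice index k."""
    sx, sy, sz = spec.spacing
    cx = (spec.shape[0] - 1) / 2.0 * sx
    cy = (spec.shape[1] - 1) / 2.0 * sy
    if spec.centerline_kind == "sagittal_sine":
        # lordotic curvature: posterior-anterior displacement along the P axis
        y = cy + spec.sine_amplitude * np.sin(2.0 * np.pi * k * sz / spec.sine_period)
    else:
        y = np.full_like(np.asarray(k, dtype=float), cy)
    x = np.full_like(np.asarray(k, dtype=float), cx)
    return x, y


def generate_phantom(spec: PhantomSpec):
    """Build (cord, rootlets, truth) volumes for a phantom spec.

    The construction is fully deterministic: geometry only, no randomness.

    Returns
    -------
    cord : LabelVolume
        Binary tube of ``cord_radius`` around the parametric centerline,
        spanning every slice.
    rootlets : LabelVolume
        Multi-class dorsal rootlet structures; label ``v`` spans exactly the
        slices of level ``v``.
    truth : PhantomTruth
        Exact slice spans, centerline, arc-length table and PMJ.
    """
    nx, ny, nz = spec.shape
    sx, sy, sz = spec.spacing
    spans = spec.slice_spans()

    # non-overlap check on slice spans
    if not spec.allow_overlap:
        ordered = sorted(spans.values())
        for (r1, c1), (r2, c2) in zip(ordered, ordered[1:]):
            if r2 <= c1:
                raise ValueError(
                    "overlapping level spans; set allow_overlap=True to permit"
                )

    k = np.arange(nz)
    cl_x, cl_y = _centerline_inplane_mm(spec, k)

    # bounds: cord + curvature must stay inside the in-plane extent
    if (
        cl_x[0] - spec.cord_radius < 0
        or cl_x[0] + spec.cord_radius > (nx - 1) * sx
        or np.min(cl_y) - spec.cord_radius < 0
        or np.max(cl_y) + spec.cord_radius > (ny - 1) * sy
    ):
        raise ValueError("cord radius (plus curvature) exceeds in-plane extent")

    ux = (np.arange(nx) * sx)[:, None, None]
    uy = (np.arange(ny) * sy)[None, :, None]
    cord_data = (
        (ux - cl_x[None, None, :]) ** 2 + (uy - cl_y[None, None, :]) ** 2
        <= spec.cord_radius**2
    ).astype(np.int16)

    # Rootlets: one thin dorsal fin per level, half-thickness rootlet_radius
    # along L, extending posteriorly from the cord surface, spanning exactly
    # the level's slices.
    rootlets_data = np.zeros(spec.shape, dtype=np.int16)
    half_x = max(spec.rootlet_radius, sx / 2.0 + 1e-9)
    fin_depth = 2.5  # mm outward from the cord surface
    for v, (kr, kc) in sorted(spans.items()):
        for kk in range(kr, kc + 1):
            x_ok = np.abs(np.arange(nx) * sx - cl_x[kk]) <= half_x
            y_lo = cl_y[kk] + spec.cord_radius - sy
            y_hi = cl_y[kk] + spec.cord_radius + fin_depth
            y_ok = (np.arange(ny) * sy >= y_lo) & (np.arange(ny) * sy <= y_hi)
            rootlets_data[np.ix_(x_ok, y_ok, [kk])] = v

    affine = _lpi_affine(spec.spacing)
    cord = LabelVolume(cord_data, affine)
    rootlets = LabelVolume(rootlets_data, affine)

    # ground-truth centerline in physical space + analytic arc length
    vox = np.stack([cl_x / sx, cl_y / sy, k.astype(float)], axis=1)
    pts = cord.voxel_to_physical(vox)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])

    k_pmj = int(round(spec.pmj_offset / sz))
    truth = PhantomTruth(
        spans=spans,
        centerline_points=pts,
        pmj=PhysicalPoint.from_array(pts[k_pmj]),
        arc_length_table=arc,
    )
    return cord, rootlets, truth


def pmj_volume_from_truth(truth: PhantomTruth, like: LabelVolume) -> LabelVolume:
    """Single-voxel PMJ label volume on the grid of ``like``."""
    ijk = np.rint(like.physical_to_voxel(truth.pmj.as_array())).astype(int)
    data = np.zeros(like.shape, dtype=np.int16)
    data[tuple(np.clip(ijk, 0, np.array(like.shape) - 1))] = 1
    return LabelVolume(data, like.affine.copy())


def random_phantom_spec(rng: np.random.Generator, **overrides) -> PhantomSpec:
    """Draw a random, valid, non-overlapping phantom spec.

    Randomizes the centerline kind, curvature, cord radius and the number,
    lengths and gaps of the level spans; used for randomized round-trip
    testing of the level-derivation pipeline.
    """
    shape = overrides.pop("shape", (40, 40, 96))
    spacing = overrides.pop("spacing", (0.8, 0.8, 0.8))
    z_max = (shape[2] - 1) * spacing[2]
    n_levels = int(rng.integers(3, 8))
    labels = sorted(rng.choice(np.arange(2, 9), size=n_levels, replace=False).tolist())
    levels = []
    z = float(rng.uniform(2.0, 5.0))
    for v in labels:
        length = float(rng.uniform(5.0, 9.0))
        if z + length > z_max - 2.0:
            break
        levels.append((int(v), round(z, 2), round(z + length, 2)))
        z += length + float(rng.uniform(1.8, 3.5))
    kind = str(rng.choice(["straight", "sagittal_sine"]))
    spec = dict(
        shape=shape,
        spacing=spacing,
        centerline_kind=kind,
        sine_amplitude=float(rng.uniform(2.0, 6.0)),
        sine_period=float(rng.uniform(60.0, 100.0)),
        cord_radius=float(rng.uniform(3.0, 4.5)),
        levels=levels,
        pmj_offset=float(rng.uniform(0.0, 2.0)),
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    spec.update(overrides)
    return PhantomSpec(**spec)


# ---------------------------------------------------------------------------


def _roi_from_mask(fg: np.ndarray, margin: int) -> np.ndarray:
    """Bounding box of the foreground, expanded by ``margin`` voxels."""
    idx = np.argwhere(fg)
    lo = np.maximum(idx.min(axis=0) - margin, 0)
    hi = np.minimum(idx.max(axis=0) + margin + 1, fg.shape)
    roi = np.zeros(fg.shape, dtype=bool)
    roi[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] = True
    return roi


def simulate_raters(truth_mask: LabelVolume, model: RaterModel) -> List[LabelVolume]:
    """Simulate imperfect raters from a ground-truth (binary or multi-class) mask.

    Foreground voxels are independently retained with probability
    ``sensitivity``; background voxels inside the ROI flip to foreground with
    probability ``1 - specificity`` and, for multi-class masks, receive the
    label of the nearest true-foreground voxel.  Voxels outside the ROI are
    untouched.  Deterministic given ``model.seed``.
    """
    data = truth_mask.data
    fg = data > 0
    if not fg.any():
        raise ValueError("empty truth mask")
    roi = _roi_from_mask(fg, model.roi_margin)
    roi_bg = roi & ~fg

    multiclass = truth_mask.labels().size > 1
    if multiclass:
        # nearest true label for false-positive voxels
        _, nearest_idx = ndimage.distance_transform_edt(~fg, return_indices=True)
        nearest_label = data[tuple(nearest_idx)]
    else:
        nearest_label = np.full_like(data, int(data.max()))

    raters = []
    for j in range(model.n_raters):
        rng = np.random.default_rng([model.seed, j])
        keep = rng.random(data.shape) < model.sensitivity
        flip = rng.random(data.shape) < (1.0 - model.specificity)
        out = np.where(fg & keep, data, 0)
        false_pos = roi_bg & flip
        out = np.where(false_pos, nearest_label, out)
        raters.append(LabelVolume(out.astype(data.dtype), truth_mask.affine.copy()))
    return raters
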