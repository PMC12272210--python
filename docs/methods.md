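# Methods

This note documents the models, conventions and design choices behind
`rootlet-levels`, in the spirit of a methods appendix: what is computed,
under which assumptions, and what the synthetic tests do and do not show.

## Coordinate conventions

All processing happens in canonical **LPI** orientation: voxel axes
increase toward the subject's Left, Posterior and Inferior. The third axis
is therefore always superior–inferior, slice 0 is the most rostral slice,
and "dorsal" is the +P (second-axis) direction. `to_lpi` permutes and flips
the voxel array while updating the affine so that every labelled voxel
keeps its physical position exactly; it refuses oblique affines whose axes
cannot be matched to anatomical directions within 45°. NIfTI-1 stores the
affine in a float32 header, so affines round-trip bit-exactly only when
their entries are float32-representable; this is a property of the file
format, not of the implementation.

Resampling uses a fixed grid convention: the centre of the first output
voxel coincides with the centre of the first input voxel and the output
size is `ceil(extent / new_spacing)`, which makes the mapping deterministic
and exactly invertible at integer spacing ratios. Label maps are resampled
with nearest-neighbour interpolation only (no new label values can appear);
linear interpolation is allowed for binary masks and is equivalent to a 0.5
threshold after rounding.

## Level derivation

The dorsal root entry zone of level *v* is the intersection of the
rootlets label *v* with the cord mask dilated by `dilation_radius`
iterations of the face-connected (6-neighbour) structuring element. The
default radius is 3 voxels; the radius is a parameter because the
appropriate physical dilation depends on voxel size and on how far the
rootlet segmentation stops short of the cord surface. The rostral and
caudal slices of the intersection are projected onto the cord: every cord
voxel in `[rostral, caudal]` receives value *v*.

Degenerate and contested cases are resolved deterministically:

- a slice claimed by two levels goes to the more rostral (smaller) label,
  with a warning — adjacent cervical levels overlap only marginally, and a
  deterministic rule keeps repeated runs identical;
- slices between levels stay unlabeled: anatomical evidence on inter-level
  gaps is mixed, and inventing an interpolation rule would manufacture
  data;
- the "middle" of a level is the floor of the slice-index midpoint
  `(rostral + caudal) // 2`, which is deterministic for even spans; using
  the centroid of intersection voxels instead would couple the level
  position to segmentation thickness.

## Centerline and PMJ distances

The centerline is the per-slice center of mass of the cord mask, mapped to
physical mm; cumulative arc length is the running sum of Euclidean
distances between consecutive slice points. On phantoms this polyline is
exact to well under a voxel, so no smoothing is applied by default; an
optional moving-average window (odd width, given in mm) smooths only the
in-plane coordinates, leaving slice positions exact. Slices whose cord
cross-section has several connected components use the largest, with a
warning.

The distance from the PMJ to a slice is the arc length between that slice
and the centerline point nearest to the PMJ, plus the PMJ's Euclidean
offset from the centerline. Measuring along the centerline rather than
along the scanner z-axis makes positions comparable across neck postures
and cord curvatures; the residual Euclidean term accounts for the PMJ
sitting slightly off the cord axis.

## STAPLE consensus

Binary STAPLE is the standard EM estimator: hidden true segmentation,
per-rater sensitivity/specificity, fixed foreground prior. Numerical
choices:

- initialization `p_j = q_j = 0.99999` (common reference practice);
- prior `f` = mean rater foreground fraction within the ROI, held fixed;
- probabilities clamped to `[1e-8, 1 − 1e-8]` to avoid 0/0 in the E-step;
- E-step computed in log space with `logaddexp` for stability;
- convergence when the max per-voxel posterior change drops below `1e-6`
  (cap 100 iterations); after convergence one final E-step is evaluated at
  the final `(p, q)` so the returned posterior and parameters are mutually
  consistent;
- the observed-data log-likelihood is recorded per iteration; EM theory
  guarantees it is non-decreasing, and the tests assert this on every run.

The analysis is restricted to an ROI (union of rater foregrounds dilated by
5 voxels) because outside it the posterior is identically 0 and background
voxels would only dilute the specificity estimates. Multi-class consensus
runs binary STAPLE per label and fuses posteriors by maximum; a voxel needs
posterior ≥ 0.5 from some label to be labelled at all, and exact ties break
toward the lowest label. Per-label fusion is used because the rater error
model of interest (missed voxels, stray voxels near the structure) is
essentially binary per level; a full multi-category confusion-matrix STAPLE
would estimate 7×7 rater matrices from very few voxels per level.

## Evaluation metrics

- **Dice** per label, `2|A∩B|/(|A|+|B|)`. A label present in only one
  volume scores 0 rather than being dropped: a prediction that misses a
  level entirely must count against the mean. A label absent from both is
  omitted.
- **COV** uses the sample standard deviation (n−1): rater and session
  counts in practice are small (4–10), where the population formula would
  bias the COV low.
- **Positional MAE** averages `|Δ d_middle|` over labels present in both
  level sets; missing labels are reported, not silently averaged.
- **Rank tests**: two-sided Wilcoxon signed-rank for paired comparisons,
  Mann-Whitney U otherwise, with the exact small-sample null when n ≤ 25
  and the data are tie-free (delegated to scipy). Identical paired samples
  return statistic 0 with p = 1 — no evidence of a difference — rather than
  an error. p-values are reported, never thresholded by the library.
- When averaging COV "across levels and sessions" the CLI reports both
  orderings (mean of per-level COVs, and the COV summary per level) since
  the two are not interchangeable.

## The phantom generator

The generator emulates the geometry the pipeline consumes, not MRI
intensities:

- **Cord**: a binary tube of radius 4 mm (default) around a parametric
  centerline — straight, or a sagittal sine (amplitude 5 mm, period 80 mm
  by default) mimicking cervical lordosis. In-plane displacement is purely
  posterior–anterior, as in neck flexion/extension.
- **Rootlets**: one thin dorsal fin per level (half-thickness 0.6 mm,
  reaching ~2.5 mm posteriorly from the cord surface), spanning exactly the
  level's slices. Individual rootlet fascicles are not modelled: the
  downstream pipeline only uses each level's rostro-caudal extent, so
  fascicle realism would add nothing testable. A fin rather than a
  sub-voxel-radius tube guarantees the structure survives voxelization at
  every grid spacing used.
- **Default spans**: C2–C8 lengths of 7.5–11.3 mm with ~1.5 mm gaps,
  matching published in-vivo cervical measurements; 0.8 mm isotropic
  voxels, the standard resolution of open-access cervical T2-weighted
  protocols.
- **PMJ**: the centerline point 2 mm below the volume top.
- **Raters**: each true foreground voxel kept with probability
  `sensitivity`; background voxels inside the foreground bounding box
  (+5 voxels margin) flip to foreground with probability
  `1 − specificity`, taking the label of the nearest true voxel.
  Specificity is defined over this bounded ROI because over a full volume
  it is trivially ≈ 1 and parameter recovery could not be tested.
  Defaults (sensitivity 0.9, specificity 0.99) represent careful manual
  raters who miss thin voxels occasionally and rarely add spurious ones.

What the phantom does **not** model: image intensities and contrast, noise
and partial-volume effects, rootlet angulation (caudal rootlets descending
obliquely before entering the cord), ventral rootlets, C1, and
level-overlapping rootlets. Consequently, passing tests demonstrate that
the geometric pipeline is correct given a segmentation, not that any
segmentation of real data is accurate. In particular, on real data the
intersection-based method inherits a caudal bias for strongly angulated
levels that the phantom's orthogonal fins cannot expose.

## Problem sizes and determinism

Tests and the acceptance script run on phantoms of about 48×48×96 voxels
at 0.8 mm (≈ 650 rootlet voxels, ≈ 7,700 cord voxels), with 20 randomized
geometries for the span-recovery property and 5 random cases for the
STAPLE brute-force cross-check — sizes at which every oracle is exact and
the full suite completes in seconds. All stochastic components (rater
simulation, randomized specs) draw from `numpy.random.default_rng` seeded
explicitly; phantom geometry itself is deterministic. CLI artifacts embed
no timestamps, so identical (inputs, config, seed) produce byte-identical
tabular outputs.

## Known limitations

- The rostral/caudal projection assumes rootlet labels are contiguous
  along the cord; a fragmented segmentation with outlier voxels far from
  the true level would stretch the projected span (no outlier rejection is
  applied).
- The centerline is per-axial-slice; for cords nearly orthogonal to the
  slice axis this is appropriate, but strongly tilted acquisitions should
  be reoriented/resampled first.
- `staple_multiclass` treats labels independently; it does not model
  inter-level confusion (a rater labelling C5 voxels as C6).
- COV requires strictly positive means, which holds for PMJ distances but
  makes the metric unsuitable for signed quantities.
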