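# rootlet-levels

Spinal-level identification from multi-class nerve-rootlet segmentations of
the cervical spinal cord, with STAPLE multi-rater consensus and
reproducibility metrics.

## The problem

Spinal levels (spinal cord segments) are defined by where each spinal
nerve's rootlets enter the cord — not by the bony vertebrae, whose
correspondence to spinal levels varies across individuals. Given a
level-specific dorsal-rootlets segmentation (voxel values 2–8 for C2–C8) and
a binary spinal-cord mask, this package derives a semantic spinal-level
volume and measures each level's position as a distance from the
pontomedullary junction (PMJ) along the cord centerline, so that cord
curvature is accounted for. It is aimed at spinal-cord MRI researchers who
need spinal-level coordinates for functional studies, inter-session
comparisons, or template labeling, and at method developers who need a
controlled test bed for such pipelines.

## The method

1. **Level derivation.** The cord mask is dilated by 3 voxels
   (face-connected element); its intersection with the rootlets segmentation
   localizes each level's dorsal root entry zone. For each label *v*, the
   rostral and caudal intersection slices are projected onto the cord: every
   cord voxel in those slices receives value *v* (2: C2 spinal level, 3: C3,
   …). Gaps between levels stay unlabeled.
2. **Curvature-aware distances.** The centerline is the per-slice center of
   mass of the cord in physical mm; the distance from the PMJ to a level's
   rostral/middle/caudal slice is measured as arc length along that
   polyline. A level's rostro-caudal length is
   `d_caudal − d_rostral`.
3. **STAPLE consensus.** Multiple raters' masks are fused by
   expectation–maximization: the hidden true segmentation *T* and per-rater
   sensitivity `p_j = P(D_ij=1 | T_i=1)` and specificity
   `q_j = P(D_ij=0 | T_i=0)` are estimated jointly,

   ```
   E-step:  W_i = f Π_j p_j^D_ij (1−p_j)^(1−D_ij)
                  / [ ·  + (1−f) Π_j (1−q_j)^D_ij q_j^(1−D_ij) ]
   M-step:  p_j = Σ_i W_i D_ij / Σ_i W_i ,   q_j = Σ_i (1−W_i)(1−D_ij) / Σ_i (1−W_i)
   ```

   Multi-class masks run binary STAPLE per label with posterior-maximum
   fusion.
4. **Evaluation metrics.** Per-label Dice `2|A∩B|/(|A|+|B|)`, coefficient of
   variation `COV = SD/mean × 100`, mean absolute error of the
   PMJ-to-level-middle distance, and two-sided Wilcoxon signed-rank /
   Mann-Whitney U comparisons.

A deterministic phantom generator (tubular cord along a straight or
lordotic sine centerline, one dorsal rootlet structure per level with known
slice spans, simulated imperfect raters) provides exact ground truth for
every stage.

## Worked example

```python
from rootlet_levels import (
    PhantomSpec, generate_phantom, simulate_raters, RaterModel,
    staple_multiclass, derive_spinal_levels, extract_centerline,
    measure_levels, dice_per_level,
)

# synthetic "subject": cord + C2-C8 rootlets with known level spans
spec = PhantomSpec(centerline_kind="sagittal_sine")
cord, rootlets, truth = generate_phantom(spec)

# four imperfect raters and their STAPLE consensus
raters = simulate_raters(rootlets, RaterModel(n_raters=4, seed=42))
consensus, per_label = staple_multiclass(raters, labels=range(2, 9))
print("consensus vs truth Dice:", round(dice_per_level(consensus, rootlets).mean, 3))

# spinal levels from the consensus, measured from the PMJ
levels = derive_spinal_levels(consensus, cord, dilation_radius=3)
measure_levels(levels, extract_centerline(cord), truth.pmj)
for s in levels.spans:
    print(f"C{s.label}: slices {s.rostral_slice}-{s.caudal_slice}, "
          f"PMJ->middle {s.d_middle:.1f} mm, length {s.length_mm:.1f} mm")
```

prints

```
consensus vs truth Dice: 0.98
C2: slices 6-16, PMJ->middle 7.7 mm, length 8.4 mm
C3: slices 18-32, PMJ->middle 19.1 mm, length 11.3 mm
C4: slices 34-42, PMJ->middle 29.6 mm, length 6.7 mm
C5: slices 44-52, PMJ->middle 38.1 mm, length 6.9 mm
C6: slices 54-65, PMJ->middle 47.5 mm, length 9.2 mm
C7: slices 68-79, PMJ->middle 59.0 mm, length 8.8 mm
C8: slices 81-94, PMJ->middle 70.3 mm, length 10.8 mm
```

The Dice of 0.98 says the four-rater consensus recovers the true rootlets
almost perfectly despite each rater missing ~10% of voxels; each level's
row gives its slice extent, its position below the PMJ along the (curved)
centerline, and its rostro-caudal length — all within a voxel of the
phantom's ground truth.

The same pipeline is available from the shell:

```bash
rootlet-levels phantom --out-dir phantom/
rootlet-levels derive --rootlets phantom/rootlets.nii.gz \
    --cord phantom/cord.nii.gz --pmj phantom/pmj.nii.gz \
    --dilation 3 --out-levels levels.nii.gz --out-spans spans.csv
rootlet-levels staple r1.nii.gz r2.nii.gz r3.nii.gz r4.nii.gz \
    --labels 2-8 --out consensus.nii.gz --report staple.json
rootlet-levels cov --spans ses1.csv --spans ses2.csv --out cov.csv
```

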