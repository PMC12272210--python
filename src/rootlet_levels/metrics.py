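"""Evaluation statistics: per-level Dice, COV, positional MAE, rank tests.

These are the reproducibility measures used to compare spinal-level
estimates across raters, sessions, sites and resolutions:

- per-label Dice overlap between two multi-class segmentations,
- coefficient of variation COV = SD / mean * 100 (sample SD, n-1),
- mean absolute error of the PMJ-to-level-middle distance between a
  reference and a test level set,
- two-sided Wilcoxon signed-rank (paired) / Mann-Whitney U (unpaired)
  comparisons, exact small-sample method where applicable.

p-values are reported, never thresholded here; interpretation is the
caller's responsibility.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .levels import LevelSet
from .volumes import LabelVolume

__all__ = [
    "DiceReport",
    "CovResult",
    "dice_per_level",
    "cov",
    "level_position_mae",
    "compare_level_positions",
]


@dataclass
class DiceReport:
    """Per-label Dice coefficients with their mean and sample SD."""

    per_label: Dict[int, float]
    mean: float
    sd: float


@dataclass
class CovResult:
    """Coefficient of variation of a set of measurements (mm)."""

    values: np.ndarray
    mean: float
    sd: float
    cov_percent: float


def dice_per_level(
    a: LabelVolume, b: LabelVolume, labels: Optional[Sequence[int]] = None
) -> DiceReport:
    """Dice = 2|A_v n B_v| / (|A_v| + |B_v|) for every label v.

    A label absent from both volumes is omitted; a label present in exactly
    one scores 0 (little-to-no overlap still counts toward the mean).
    """
    if not a.same_grid(b):
        raise ValueError("volumes must share one grid")
    if labels is None:
        labels = sorted(set(a.labels().tolist()) | set(b.labels().tolist()))
    per: Dict[int, float] = {}
    for v in labels:
        av = a.data == v
        bv = b.data == v
        na, nb = int(av.sum()), int(bv.sum())
        if na == 0 and nb == 0:
            continue
        per[int(v)] = 2.0 * int((av & bv).sum()) / (na + nb)
    vals = np.array(list(per.values()), dtype=float)
    mean = float(vals.mean()) if vals.size else math.nan
    sd = float(vals.std(ddof=1)) if vals.size > 1 else math.nan
    return DiceReport(per_label=per, mean=mean, sd=sd)


def cov(values: Sequence[float]) -> CovResult:
    """Coefficient of variation, COV = SD / mean * 100 (sample SD, n-1)."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("COV requires at least 2 values")
    mean = float(arr.mean())
    if mean <= 0:
        raise ValueError("COV requires a strictly positive mean")
    sd = float(arr.std(ddof=1))
    return CovResult(values=arr, mean=mean, sd=sd, cov_percent=sd / mean * 100.0)


def level_position_mae(ref: LevelSet, test: LevelSet) -> float:
    """Mean absolute error (mm) of the PMJ-to-level-middle distance.

    Averaged over labels present in both level sets; labels missing from
    either side are excluded and reported via a warning.
    """
    ref_d = {s.label: s.d_middle for s in ref.spans}
    test_d = {s.label: s.d_middle for s in test.spans}
    if any(d is None for d in ref_d.values()) or any(
        d is None for d in test_d.values()
    ):
        raise ValueError("level sets must be measured (d_middle filled) first")
    common = sorted(set(ref_d) & set(test_d))
    if not common:
        raise ValueError("no common labels between the level sets")
    missing = sorted(set(ref_d) ^ set(test_d))
    if missing:
        warnings.warn(
            f"labels {missing} present in only one level set; excluded from MAE",
            stacklevel=2,
        )
    return float(np.mean([abs(ref_d[v] - test_d[v]) for v in common]))


def compare_level_positions(
    x: Sequence[float], y: Sequence[float], paired: bool = False
) -> Tuple[float, float]:
    """Two-sided rank comparison of two sets of PMJ distances.

    Paired data use the Wilcoxon signed-rank test on the differences
    (identical samples return statistic 0, p = 1: no evidence of any
    difference); unpaired data use the Mann-Whitney U test.  The exact
    small-sample null distribution is used when n <= 25 and the data allow
    it (no ties/zeros), otherwise the standard approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if paired:
        if x.shape != y.shape:
            raise ValueError("paired comparison requires equal lengths")
        diff = x - y
        if np.all(diff == 0):
            return 0.0, 1.0
        n = diff[diff != 0].size
        method = "exact" if (n <= 25 and not _has_tied_magnitudes(diff)) else "auto"
        res = stats.wilcoxon(x, y, alternative="two-sided", method=method)
    else:
        exact_ok = max(x.size, y.size) <= 25 and np.unique(
            np.concatenate([x, y])
        ).size == x.size + y.size
        res = stats.mannwhitneyu(
            x, y, alternative="two-sided", method="exact" if exact_ok else "auto"
        )
    return float(res.statistic), float(res.pvalue)


def _has_tied_magnitudes(diff: np.ndarray) -> bool:
    mags = np.abs(diff[diff != 0])
    return np.unique(mags).size != mags.size or np.any(diff == 0)
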