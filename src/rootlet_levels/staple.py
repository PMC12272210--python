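"""STAPLE: Simultaneous Truth And Performance Level Estimation.

An expectation-maximization consensus over multiple raters' binary
segmentations.  The hidden variable is the true segmentation T; each rater j
is characterized by a sensitivity p_j = P(D_ij = 1 | T_i = 1) and a
specificity q_j = P(D_ij = 0 | T_i = 0).  With a fixed foreground prior f:

    E-step:  W_i = f * prod_j p_j^D_ij (1-p_j)^(1-D_ij)
                   / [ that + (1-f) * prod_j (1-q_j)^D_ij q_j^(1-D_ij) ]
    M-step:  p_j = sum_i W_i D_ij / sum_i W_i
             q_j = sum_i (1-W_i)(1-D_ij) / sum_i (1-W_i)

iterated until the largest per-voxel change in W drops below ``tol``.  The
observed-data log-likelihood is non-decreasing across EM iterations; every
run records its trajectory so callers can assert this.

The analysis is restricted to a region of interest (default: the union of
rater foregrounds dilated by 5 voxels) — outside it the posterior is 0 and
rater performance carries no information.

Multi-class consensus runs binary STAPLE per label and fuses posteriors by
maximum, breaking exact ties toward the lowest label.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .volumes import LabelVolume

__all__ = ["StapleResult", "staple_binary", "staple_multiclass", "fuse_posteriors"]

#: clamp for probabilities, avoiding degenerate 0/0 in the E-step
PROB_CLAMP = 1e-8
#: initial sensitivity/specificity (standard STAPLE practice)
INIT_PQ = 0.99999


@dataclass
class StapleResult:
    """Outcome of a binary STAPLE run."""

    posterior: np.ndarray  # full-volume W in [0, 1]
    consensus: LabelVolume  # W >= 0.5
    sensitivity: np.ndarray  # p_j per rater
    specificity: np.ndarray  # q_j per rater
    prior: float
    n_iterations: int
    converged: bool
    log_likelihood: np.ndarray = field(default_factory=lambda: np.empty(0))


def _check_grids(raters: Sequence[LabelVolume]) -> None:
    if len(raters) == 0:
        raise ValueError("need at least one rater")
    ref = raters[0]
    for r in raters[1:]:
        if not ref.same_grid(r):
            raise ValueError("rater volumes must share one grid")


def _default_roi(raters: Sequence[LabelVolume], dilate: int = 5) -> np.ndarray:
    union = np.zeros(raters[0].shape, dtype=bool)
    for r in raters:
        union |= r.data > 0
    if dilate > 0 and union.any():
        structure = ndimage.generate_binary_structure(3, 1)
        union = ndimage.binary_dilation(union, structure=structure, iterations=dilate)
    return union


def staple_binary(
    raters: Sequence[LabelVolume],
    roi: Optional[np.ndarray] = None,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> StapleResult:
    """Run binary STAPLE over the raters' foregrounds.

    Parameters
    ----------
    raters : sequence of LabelVolume
        Binary segmentations on a common grid (any nonzero value counts as
        foreground).
    roi : bool array, optional
        Restrict the analysis to these voxels; defaults to the union of
        rater foregrounds dilated by 5 voxels.
    tol : float
        Convergence threshold on max per-voxel ``|dW|``.
    max_iter : int
        Iteration cap; the result is flagged unconverged if reached.
    """
    _check_grids(raters)
    shape = raters[0].shape
    fgs = [r.data > 0 for r in raters]
    if not any(f.any() for f in fgs):
        raise ValueError("no foreground evidence: all rater masks are empty")
    if roi is None:
        roi = _default_roi(raters)
    else:
        roi = np.asarray(roi, dtype=bool)
        if roi.shape != shape:
            raise ValueError("roi shape does not match rater grids")
    if not roi.any():
        raise ValueError("empty roi")

    # decision matrix restricted to the ROI: (n_voxels, n_raters)
    D = np.stack([f[roi] for f in fgs], axis=1).astype(float)
    n_vox, n_raters = D.shape

    p = np.full(n_raters, INIT_PQ)
    q = np.full(n_raters, INIT_PQ)
    f = float(np.clip(D.mean(), PROB_CLAMP, 1.0 - PROB_CLAMP))

    W = np.full(n_vox, f)
    ll_trace: List[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        la = np.log(f) + D @ np.log(p) + (1.0 - D) @ np.log1p(-p)
        lb = np.log1p(-f) + D @ np.log1p(-q) + (1.0 - D) @ np.log(q)
        ll_trace.append(float(np.logaddexp(la, lb).sum()))
        W_new = 1.0 / (1.0 + np.exp(lb - la))

        sum_w = W_new.sum()
        sum_1mw = (1.0 - W_new).sum()
        p = np.clip((W_new @ D) / max(sum_w, PROB_CLAMP), PROB_CLAMP, 1 - PROB_CLAMP)
        q = np.clip(
            ((1.0 - W_new) @ (1.0 - D)) / max(sum_1mw, PROB_CLAMP),
            PROB_CLAMP,
            1 - PROB_CLAMP,
        )

        delta = float(np.max(np.abs(W_new - W)))
        W = W_new
        if delta < tol:
            converged = True
            break

    # final E-step so the returned posterior is consistent with the
    # returned (p, q) estimates
    la = np.log(f) + D @ np.log(p) + (1.0 - D) @ np.log1p(-p)
    lb = np.log1p(-f) + D @ np.log1p(-q) + (1.0 - D) @ np.log(q)
    ll_trace.append(float(np.logaddexp(la, lb).sum()))
    W = 1.0 / (1.0 + np.exp(lb - la))

    posterior = np.zeros(shape, dtype=float)
    posterior[roi] = W
    consensus_data = (posterior >= 0.5).astype(np.int16)
    consensus = LabelVolume(consensus_data, raters[0].affine.copy())
    return StapleResult(
        posterior=posterior,
        consensus=consensus,
        sensitivity=p,
        specificity=q,
        prior=f,
        n_iterations=it,
        converged=converged,
        log_likelihood=np.array(ll_trace),
    )


def staple_multiclass(
    raters: Sequence[LabelVolume],
    labels: Sequence[int],
    tol: float = 1e-6,
    max_iter: int = 100,
) -> Tuple[LabelVolume, Dict[int, StapleResult]]:
    """Per-label binary STAPLE with posterior-maximum fusion.

    Each label's consensus is computed independently on the ``rater == label``
    masks.  A voxel claimed by several labels (posterior >= 0.5 for more than
    one) is assigned the label with the highest posterior; exact ties break
    toward the lowest label.  Labels with no votes from any rater are
    reported absent (missing from ``per_label``), not an error.
    """
    _check_grids(raters)
    labels = sorted(int(v) for v in labels)
    present = set()
    for r in raters:
        present.update(int(v) for v in r.labels())
    extra = present - set(labels)
    if extra:
        raise ValueError(f"rater labels {sorted(extra)} outside requested {labels}")

    per_label: Dict[int, StapleResult] = {}
    for v in labels:
        if v not in present:
            continue
        masks = [
            LabelVolume((r.data == v).astype(np.int16), r.affine.copy())
            for r in raters
        ]
        per_label[v] = staple_binary(masks, tol=tol, max_iter=max_iter)
    consensus = fuse_posteriors({v: r.posterior for v, r in per_label.items()})
    return LabelVolume(consensus, raters[0].affine.copy()), per_label


def fuse_posteriors(posteriors: Dict[int, np.ndarray]) -> np.ndarray:
    """Fuse per-label posterior maps into one multi-class volume.

    A voxel gets the label whose posterior is highest among those >= 0.5;
    exact ties break toward the lowest label; voxels with no posterior
    >= 0.5 stay background.
    """
    labels = sorted(posteriors)
    shape = posteriors[labels[0]].shape
    best_w = np.zeros(shape, dtype=float)
    consensus = np.zeros(shape, dtype=np.int16)
    for v in labels:  # ascending: strict > keeps the lowest label on ties
        w = posteriors[v]
        claim = (w >= 0.5) & (w > best_w)
        consensus[claim] = v
        best_w = np.maximum(best_w, np.where(w >= 0.5, w, 0.0))
    return consensus
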