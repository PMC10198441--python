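"""Microglial dynamics: drift correction, max projections, motility index,
and surveillance index.

Both indices are computed on 2D max projections per layer.  Between
consecutive binarized projections, pixels are classified as extended
(present only at t+1), retracted (present only at t), or stable (present in
both); the per-pair motility index is (extended + retracted) / stable and an
animal's index is the mean over pairs (a pooled-counts variant is available).
The surveillance index is the union of all timepoints' mask pixels divided by
the number of valid frame pixels; regions shifted out of frame by drift
correction are excluded from both numerator and denominator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage.registration import phase_cross_correlation

__all__ = [
    "DynamicsResult",
    "drift_correct",
    "max_project",
    "motility_index",
    "surveillance_index",
    "analyze_masks",
]


@dataclass
class DynamicsResult:
    """Pixel-turnover counts and derived indices for one layer of one animal."""

    extended_px: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    retracted_px: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    stable_px: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    motility_index: float = float("nan")
    surveillance_index: float = float("nan")
    drift_vectors: np.ndarray = field(default_factory=lambda: np.zeros((0, 2), int))


def _shift2d(frame: np.ndarray, dy: int, dx: int) -> np.ndarray:
    out = np.zeros_like(frame)
    h, w = frame.shape
    out[max(dy, 0): min(h + dy, h), max(dx, 0): min(w + dx, w)] = frame[
        max(-dy, 0): min(h - dy, h), max(-dx, 0): min(w - dx, w)
    ]
    return out


def drift_correct(
    projections: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Register each 2D frame to t=0 by integer-pixel translation.

    Returns (registered frames, per-t (dy, dx) shifts of the content relative
    to t=0, valid-pixel mask).  The valid mask marks pixels that stayed in
    frame at every timepoint; featureless frames get zero shift with a
    warning.
    """
    projections = np.asarray(projections)
    if projections.ndim != 3 or projections.shape[0] < 2:
        raise ValueError("need a (t, y, x) array with >= 2 frames")
    ref = projections[0].astype(np.float64)
    n_t, h, w = projections.shape
    shifts = np.zeros((n_t, 2), dtype=int)
    registered = projections.copy()
    valid = np.ones((h, w), dtype=bool)
    for t in range(1, n_t):
        frame = projections[t].astype(np.float64)
        if frame.std() == 0 or ref.std() == 0:
            warnings.warn(f"featureless frame at t={t}; assuming zero drift")
            continue
        shift, _, _ = phase_cross_correlation(ref, frame, upsample_factor=1)
        dy, dx = int(round(shift[0])), int(round(shift[1]))
        shifts[t] = (-dy, -dx)  # content drift relative to t=0
        registered[t] = _shift2d(projections[t], dy, dx)
        vmask = _shift2d(np.ones((h, w), dtype=projections.dtype), dy, dx)
        valid &= vmask.astype(bool)
    return registered, shifts, valid


def max_project(substack: np.ndarray) -> np.ndarray:
    """Pixelwise max over z for a (z, y, x) or per-t (t, z, y, x) substack."""
    substack = np.asarray(substack)
    if substack.ndim not in (3, 4):
        raise ValueError("expected (z, y, x) or (t, z, y, x)")
    if substack.shape[-3] == 0:
        raise ValueError("empty z-range: nothing to project")
    return substack.max(axis=-3)


def _pair_counts(masks: np.ndarray, valid: np.ndarray | None):
    masks = np.asarray(masks, dtype=bool)
    if valid is not None:
        masks = masks & valid
    a, b = masks[:-1], masks[1:]
    extended = (b & ~a).sum(axis=(1, 2))
    retracted = (a & ~b).sum(axis=(1, 2))
    stable = (a & b).sum(axis=(1, 2))
    return extended, retracted, stable


def motility_index(
    masks: np.ndarray,
    valid: np.ndarray | None = None,
    aggregation: str = "mean",
) -> DynamicsResult:
    """Motility index from consecutive binarized projections.

    Pairs with zero stable pixels are excluded (with a warning); if every
    pair is excluded the index is NaN (missing), never 0.  ``aggregation``
    is ``"mean"`` (mean of per-pair ratios, default) or ``"pooled"``
    ((sum ext + sum ret) / sum stable).
    """
    masks = np.asarray(masks, dtype=bool)
    if masks.ndim != 3 or masks.shape[0] < 2:
        raise ValueError("need >= 2 binary (t, y, x) projections")
    extended, retracted, stable = _pair_counts(masks, valid)
    ok = stable > 0
    if not ok.all():
        warnings.warn(
            f"{(~ok).sum()} timepoint pair(s) with zero stable pixels excluded "
            "from the motility index"
        )
    if not ok.any():
        mi = float("nan")
    elif aggregation == "mean":
        mi = float(np.mean((extended[ok] + retracted[ok]) / stable[ok]))
    elif aggregation == "pooled":
        mi = float((extended[ok].sum() + retracted[ok].sum()) / stable[ok].sum())
    else:
        raise ValueError("aggregation must be 'mean' or 'pooled'")
    return DynamicsResult(
        extended_px=extended, retracted_px=retracted, stable_px=stable,
        motility_index=mi,
    )


def surveillance_index(
    masks: np.ndarray, valid: np.ndarray | None = None
) -> float:
    """Union of mask pixels over time divided by the valid frame pixels."""
    masks = np.asarray(masks, dtype=bool)
    if masks.ndim != 3:
        raise ValueError("need binary (t, y, x) projections")
    union = masks.any(axis=0)
    if valid is not None:
        union &= valid
        denom = int(valid.sum())
    else:
        denom = masks.shape[1] * masks.shape[2]
    return float(union.sum() / denom) if denom else float("nan")


def analyze_masks(
    mask_projections: np.ndarray,
    valid: np.ndarray | None = None,
    aggregation: str = "mean",
) -> DynamicsResult:
    """Motility + surveillance for one layer's binarized projections."""
    res = motility_index(mask_projections, valid=valid, aggregation=aggregation)
    res.surveillance_index = surveillance_index(mask_projections, valid=valid)
    return res
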