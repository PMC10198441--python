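"""Preprocessing: background subtraction, brightness-compensated
bleed-through correction, PCA denoising, and ML/PCL layer separation.

The bleed-through compensation factor is estimated per stack as a robust
(Theil-Sen) slope of green vs. red over pixels that are bright in red but
outside a dilated microglia pre-mask, then ``green <- clip(green - beta*red,
0)``.  The red channel is never modified — raw red is what the interaction
analysis consumes.

The number of principal components kept during denoising is chosen by a
cumulative-explained-variance rule (the original pipeline's component-count
criterion is not public; this stand-in is logged in the returned info).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats as sps
from skimage.filters import threshold_otsu

from gliadyn.io_blind import GREEN, RED, TwoChannelStack

logger = logging.getLogger(__name__)

__all__ = [
    "LayerAssignment",
    "subtract_background",
    "correct_bleedthrough",
    "pca_denoise",
    "separate_layers",
    "harmonize_layers",
]


@dataclass
class LayerAssignment:
    """Contiguous z-ranges for the molecular and Purkinje-cell layers.

    ML is ``[ml_lo, pcl_start_z)`` (superficial), PCL is
    ``[pcl_start_z, pcl_hi)``.  Harmonized counts are per-cohort minimum
    slice counts (set by :func:`harmonize_layers`).
    """

    pcl_start_z: int
    ml_lo: int
    pcl_hi: int
    harmonized_ml_n: int | None = None
    harmonized_pcl_n: int | None = None

    def __post_init__(self) -> None:
        if not (self.ml_lo <= self.pcl_start_z < self.pcl_hi):
            raise ValueError("layer ranges must be ordered: ml_lo <= pcl_start_z < pcl_hi")
        for n, avail in (
            (self.harmonized_ml_n, self.ml_n),
            (self.harmonized_pcl_n, self.pcl_n),
        ):
            if n is not None and n > avail:
                raise ValueError("harmonized slice count exceeds available slices")

    @property
    def ml_n(self) -> int:
        return self.pcl_start_z - self.ml_lo

    @property
    def pcl_n(self) -> int:
        return self.pcl_hi - self.pcl_start_z

    def ml_slices(self) -> slice:
        n = self.harmonized_ml_n if self.harmonized_ml_n is not None else self.ml_n
        # keep the slices nearest the boundary (deepest ML)
        return slice(self.pcl_start_z - n, self.pcl_start_z)

    def pcl_slices(self) -> slice:
        n = self.harmonized_pcl_n if self.harmonized_pcl_n is not None else self.pcl_n
        return slice(self.pcl_start_z, self.pcl_start_z + n)


def subtract_background(
    stack: TwoChannelStack, channel: int, percentile: float = 5.0
) -> TwoChannelStack:
    """Subtract a per-frame low-percentile background estimate; clip at 0."""
    if channel not in (GREEN, RED):
        raise ValueError("channel must be 0 (green) or 1 (red)")
    out = stack.copy()
    vol = out.data[..., channel].astype(np.float64)
    bg = np.percentile(vol, percentile, axis=(2, 3), keepdims=True)
    sub = np.clip(vol - bg, 0, None)
    if np.issubdtype(out.data.dtype, np.integer):
        out.data = out.data.astype(np.float64)
    out.data[..., channel] = sub
    return out


def correct_bleedthrough(
    stack: TwoChannelStack,
    red_percentile: float = 90.0,
    premask_dilate_px: int = 2,
    max_pairs: int = 2000,
    rng: np.random.Generator | None = None,
) -> tuple[TwoChannelStack, float]:
    """Subtract a brightness-compensated red channel from green.

    The compensation factor ``beta`` is the Theil-Sen slope of green vs. red
    over pixels where red exceeds its ``red_percentile`` and that lie outside
    a dilated microglia pre-mask (Otsu on green).  Returns the corrected
    stack (red untouched) and the estimated beta.
    """
    green = stack.data[..., GREEN].astype(np.float64)
    red = stack.data[..., RED].astype(np.float64)
    if not np.any(red > 0):
        warnings.warn(
            "red channel is all zero; bleed-through factor undefined, "
            "green returned unchanged"
        )
        return stack.copy(), 0.0

    thresh = np.percentile(red, red_percentile)
    sel = red >= thresh
    gpos = green[green > 0]
    if gpos.size and gpos.max() > gpos.min():
        g_thr = threshold_otsu(gpos)
        premask = green > g_thr
        if premask_dilate_px > 0:
            structure = np.ones((1, 1, 2 * premask_dilate_px + 1,
                                 2 * premask_dilate_px + 1), dtype=bool)
            premask = ndimage.binary_dilation(premask, structure=structure)
        # drop the pre-mask exclusion if it would leave (almost) nothing:
        # when green is pure bleed-through, every red-bright pixel is also
        # green-bright and the exclusion is self-defeating
        sel_wo_premask = sel & ~premask
        if sel_wo_premask.sum() >= max(10, 0.02 * sel.sum()):
            sel = sel_wo_premask
    g_sel, r_sel = green[sel], red[sel]
    if g_sel.size < 10:
        warnings.warn("too few red-dominant pixels to estimate bleed-through; beta=0")
        return stack.copy(), 0.0
    if g_sel.size > max_pairs:
        rng = rng if rng is not None else np.random.default_rng(0)
        idx = rng.choice(g_sel.size, size=max_pairs, replace=False)
        g_sel, r_sel = g_sel[idx], r_sel[idx]
    beta = float(sps.theilslopes(g_sel, r_sel).slope)
    beta = max(beta, 0.0)
    logger.info("bleed-through beta=%.4f from %d pixels", beta, g_sel.size)
    out = stack.copy()
    if np.issubdtype(out.data.dtype, np.integer):
        out.data = out.data.astype(np.float64)
    out.data[..., GREEN] = np.clip(green - beta * red, 0, None)
    return out, beta


def pca_denoise(
    stack: TwoChannelStack, channel: int, variance_keep: float = 0.95
) -> tuple[TwoChannelStack, int]:
    """Reconstruct a channel from its leading principal components.

    Each (t, z) frame, flattened, is one observation.  The smallest number of
    components whose cumulative explained variance reaches ``variance_keep``
    is retained; output is clipped at 0.  Returns (stack, k_kept).
    """
    if not (0 < variance_keep <= 1):
        raise ValueError("variance_keep must be in (0, 1]")
    vol = stack.data[..., channel].astype(np.float64)
    n_t, n_z, h, w = vol.shape
    n_frames = n_t * n_z
    if n_frames < 2:
        raise ValueError("need at least 2 frames (t*z) for PCA")
    X = vol.reshape(n_frames, h * w)
    mean = X.mean(axis=0)
    Xc = X - mean
    if not np.any(Xc):
        return stack.copy(), 0  # constant stack: nothing to denoise
    # economy SVD on frames x pixels; components are right singular vectors
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    var = s**2
    cum = np.cumsum(var) / var.sum()
    k = int(np.searchsorted(cum, variance_keep - 1e-12) + 1)
    k = min(k, len(s))
    recon = (U[:, :k] * s[:k]) @ Vt[:k] + mean
    out = stack.copy()
    if np.issubdtype(out.data.dtype, np.integer):
        out.data = out.data.astype(np.float64)
    out.data[..., channel] = np.clip(recon.reshape(vol.shape), 0, None)
    return out, k


def separate_layers(
    soma_area_per_z: np.ndarray | None = None,
    pc_soma_mask: np.ndarray | None = None,
    manual_pcl_start: int | None = None,
    n_z: int | None = None,
    area_threshold: float | None = None,
    soma_radius_um: float = 10.0,
    pixel_size_um: float = 0.4,
    min_consecutive: int = 2,
) -> LayerAssignment:
    """Locate the first Purkinje-soma slice and split the stack into ML/PCL.

    Scanning from the surface (z=0), ``pcl_start_z`` is the first slice whose
    detected soma area exceeds ``area_threshold`` on at least
    ``min_consecutive`` consecutive slices.  The default threshold is a
    quarter of one soma's equatorial cross-section at the configured radius,
    which lands within a slice or two of where somas first appear.

    Provide either a per-slice soma area profile, a 3D/4D soma mask (t=0 is
    used), or a manual override index.
    """
    if manual_pcl_start is not None:
        if n_z is None:
            if pc_soma_mask is not None:
                n_z = pc_soma_mask.shape[-3]
            elif soma_area_per_z is not None:
                n_z = len(soma_area_per_z)
            else:
                raise ValueError("n_z required with a manual override alone")
        return LayerAssignment(pcl_start_z=manual_pcl_start, ml_lo=0, pcl_hi=n_z)

    if soma_area_per_z is None:
        if pc_soma_mask is None:
            raise ValueError("need soma_area_per_z, pc_soma_mask, or manual override")
        mask = pc_soma_mask[0] if pc_soma_mask.ndim == 4 else pc_soma_mask
        soma_area_per_z = mask.sum(axis=(1, 2))
    soma_area_per_z = np.asarray(soma_area_per_z, dtype=float)
    n_z = len(soma_area_per_z)
    if area_threshold is None:
        area_threshold = 0.25 * np.pi * (soma_radius_um / pixel_size_um) ** 2
    above = soma_area_per_z >= area_threshold
    for z in range(n_z - min_consecutive + 1):
        if above[z: z + min_consecutive].all():
            if z == 0:
                raise ValueError(
                    "Purkinje somas detected at the surface slice; no molecular "
                    "layer above — check the stack or pass manual_pcl_start"
                )
            return LayerAssignment(pcl_start_z=z, ml_lo=0, pcl_hi=n_z)
    raise ValueError(
        "no Purkinje somas detected in any slice; pass manual_pcl_start "
        "to set the layer boundary explicitly"
    )


def harmonize_layers(assignments: list[LayerAssignment]) -> list[LayerAssignment]:
    """Set every animal's harmonized slice counts to the cohort minimum."""
    if not assignments:
        return []
    ml_n = min(a.ml_n for a in assignments)
    pcl_n = min(a.pcl_n for a in assignments)
    for a in assignments:
        a.harmonized_ml_n = ml_n
        a.harmonized_pcl_n = pcl_n
    return assignments
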