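"""Putative microglia-Purkinje cell interactions: 3D overlap per component
pair, normalization, time-averaging, and the interaction coverage index.

Overlap is the voxelwise AND of same-timepoint binary component volumes
(full 3D layer substacks, not projections).  Per-timepoint values are
normalized to (microglia voxels + Purkinje voxels), then averaged over
timepoints.  Coverage is the S.I.-style statistic on 2D projections of the
overlap masks: |union over t| / valid frame pixels.

Only voxel co-occupancy is measured — light microscopy cannot resolve
membrane contact, so outputs describe *putative* interactions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from gliadyn.dynamics import max_project

__all__ = [
    "InteractionRecord",
    "ML_PAIRS",
    "PCL_PAIRS",
    "overlap_3d",
    "interaction_table",
    "interaction_coverage",
    "records_to_frame",
]

# (microglia component, Purkinje component) pairs analyzed per layer
ML_PAIRS = (
    ("whole", "dendrite_whole"),
    ("process", "dendrite"),
    ("soma", "dendrite"),
    ("process", "branch"),
    ("soma", "branch"),
)
PCL_PAIRS = (
    ("whole", "soma"),
    ("process", "soma"),
    ("soma", "soma"),
)


@dataclass
class InteractionRecord:
    """Per-pair overlap counts across timepoints plus derived summaries."""

    mg_component: str
    pc_component: str
    layer: str
    overlap_px: np.ndarray
    mg_px: np.ndarray
    pc_px: np.ndarray
    normalized: np.ndarray = field(init=False)
    mean_normalized: float = field(init=False)
    coverage_index: float = float("nan")

    def __post_init__(self) -> None:
        denom = self.mg_px + self.pc_px
        with np.errstate(invalid="ignore", divide="ignore"):
            self.normalized = np.where(
                denom > 0, self.overlap_px / np.maximum(denom, 1), np.nan
            )
        self.mean_normalized = (
            float(np.nanmean(self.normalized))
            if np.any(denom > 0)
            else float("nan")
        )


def overlap_3d(
    mg_mask: np.ndarray, pc_mask: np.ndarray
) -> tuple[np.ndarray, int]:
    """Voxelwise AND of two same-shape binary volumes, with its count."""
    mg_mask = np.asarray(mg_mask, dtype=bool)
    pc_mask = np.asarray(pc_mask, dtype=bool)
    if mg_mask.shape != pc_mask.shape:
        raise ValueError(
            f"mask shapes differ: {mg_mask.shape} vs {pc_mask.shape}"
        )
    overlap = mg_mask & pc_mask
    return overlap, int(overlap.sum())


_MG_KEY = {"soma": "mg_soma", "process": "mg_process", "whole": "mg_whole"}
_PC_KEY = {
    "soma": "pc_soma",
    "dendrite": "pc_dendrite",
    "branch": "pc_branch",
    "dendrite_whole": "pc_dendrite_whole",
}


def interaction_table(
    masks: dict[str, np.ndarray],
    layer: str,
    drift_shifts: np.ndarray | None = None,
) -> list[InteractionRecord]:
    """All component-pair interaction records for one layer.

    ``masks`` maps component names (``mg_soma``, ``mg_process``, and either
    ``pc_dendrite``/``pc_branch`` for the ML or ``pc_soma`` for the PCL) to
    ``(t, z, y, x)`` boolean arrays.  Derived unions (``mg_whole``,
    ``pc_dendrite_whole``) are formed here.  Each record also carries the
    coverage index of its projected overlap masks.
    """
    if layer not in ("ML", "PCL"):
        raise ValueError("layer must be 'ML' or 'PCL'")
    pairs = ML_PAIRS if layer == "ML" else PCL_PAIRS
    work = {k: np.asarray(v, dtype=bool) for k, v in masks.items()}
    work["mg_whole"] = work["mg_soma"] | work["mg_process"]
    if layer == "ML":
        work["pc_dendrite_whole"] = work["pc_dendrite"] | work["pc_branch"]

    records = []
    for mg_name, pc_name in pairs:
        mg = work[_MG_KEY[mg_name]]
        pc = work[_PC_KEY[pc_name]]
        overlap = mg & pc
        rec = InteractionRecord(
            mg_component=mg_name,
            pc_component=pc_name,
            layer=layer,
            overlap_px=overlap.reshape(overlap.shape[0], -1).sum(axis=1),
            mg_px=mg.reshape(mg.shape[0], -1).sum(axis=1),
            pc_px=pc.reshape(pc.shape[0], -1).sum(axis=1),
        )
        rec.coverage_index = interaction_coverage(overlap, shifts=drift_shifts)
        records.append(rec)
    return records


def interaction_coverage(
    overlap_masks: np.ndarray, shifts: np.ndarray | None = None
) -> float:
    """Coverage index: |union over t of projected overlap| / valid pixels.

    ``overlap_masks`` is ``(t, z, y, x)`` (projected here) or ``(t, y, x)``.
    ``shifts`` optionally applies per-timepoint (dy, dx) drift-correction
    shifts (content drift relative to t=0, as returned by
    :func:`gliadyn.dynamics.drift_correct`); shifted-out borders are excluded
    from numerator and denominator.
    """
    overlap_masks = np.asarray(overlap_masks, dtype=bool)
    if overlap_masks.ndim == 4:
        proj = max_project(overlap_masks)
    elif overlap_masks.ndim == 3:
        proj = overlap_masks
    else:
        raise ValueError("expected (t, z, y, x) or (t, y, x) overlap masks")
    n_t, h, w = proj.shape
    valid = np.ones((h, w), dtype=bool)
    if shifts is not None:
        from gliadyn.dynamics import _shift2d

        shifts = np.asarray(shifts, dtype=int)
        corrected = np.zeros_like(proj)
        for t in range(n_t):
            dy, dx = -shifts[t, 0], -shifts[t, 1]
            corrected[t] = _shift2d(proj[t], dy, dx)
            valid &= _shift2d(np.ones((h, w), dtype=bool), dy, dx)
        proj = corrected
    union = proj.any(axis=0) & valid
    denom = int(valid.sum())
    return float(union.sum() / denom) if denom else float("nan")


def records_to_frame(
    records: list[InteractionRecord], animal_id: str | None = None
) -> pd.DataFrame:
    """Long-format table: one row per (pair, timepoint) plus summary columns."""
    rows = []
    for rec in records:
        for t in range(len(rec.overlap_px)):
            rows.append(
                {
                    "animal_id": animal_id,
                    "layer": rec.layer,
                    "mg_component": rec.mg_component,
                    "pc_component": rec.pc_component,
                    "t": t,
                    "overlap_px": int(rec.overlap_px[t]),
                    "mg_px": int(rec.mg_px[t]),
                    "pc_px": int(rec.pc_px[t]),
                    "normalized": rec.normalized[t],
                    "mean_normalized": rec.mean_normalized,
                    "coverage_index": rec.coverage_index,
                }
            )
    return pd.DataFrame(rows)
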