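"""Expression-based CNV inference: smoothed relative expression by arm.

Malignant-cell identity is verified from expression alone: each gene's
log-normalized value is centered on the mean over a reference cell set
(here, endothelial cells and astrocytes, which carry no CNVs), clipped,
and smoothed by a centered moving average along genomic position within
each chromosome arm. Arm-level gains and losses are then called from
cell-type mean scores against symmetric thresholds.

Windows never span arm boundaries; arms shorter than the window use the
whole arm. Near arm edges the window shrinks to the genes available,
keeping the average centered as far as possible.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .containers import CellAnnotation, CNVProfile, ExpressionMatrix

logger = logging.getLogger(__name__)


def _moving_average_block(block: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average over the last axis with edge shrinkage."""
    n = block.shape[-1]
    if n <= window:
        return np.repeat(block.mean(axis=-1, keepdims=True), n, axis=-1)
    half = window // 2
    csum = np.cumsum(np.concatenate(
        [np.zeros(block.shape[:-1] + (1,)), block], axis=-1), axis=-1)
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half + 1, n)
    return (csum[..., hi] - csum[..., lo]) / (hi - lo)


def infer_cnv_profile(
    e: ExpressionMatrix,
    ann: pd.DataFrame,
    reference_cells,
    window: int = 101,
    clip: float = 3.0,
) -> CNVProfile:
    """Per-cell smoothed relative-expression track ordered by position.

    Parameters
    ----------
    e
        Log-normalized expression (genes x cells).
    ann
        Gene annotation indexed by gene with ``chrom``, ``arm``,
        ``start`` columns (1-based starts).
    reference_cells
        Barcodes of CNV-free cells used for centering.
    window
        Odd number of genes in the moving-average window.
    clip
        Relative-expression values are clipped to [-clip, clip] before
        averaging.
    """
    if window % 2 == 0:
        raise ValueError("window must be odd")
    reference_cells = pd.Index(reference_cells)
    ref_mask = e.cell_ids.isin(reference_cells)
    if not ref_mask.any():
        raise ValueError("reference cell set is empty or absent from matrix")
    annotated = ann.index.intersection(e.gene_ids)
    if len(annotated) == 0:
        raise ValueError("no expressed gene carries genomic annotation")
    ann = ann.loc[annotated].sort_values(["chrom", "arm", "start"], kind="stable")
    gene_idx = e.gene_ids.get_indexer(ann.index)
    vals = e.values[gene_idx]  # genes(ordered) x cells
    ref_mean = vals[:, ref_mask].mean(axis=1, keepdims=True)
    rel = np.clip(vals - ref_mean, -clip, clip)
    arms = ann["arm"].to_numpy()
    smoothed = np.empty_like(rel)
    for arm in pd.unique(arms):
        sel = arms == arm
        n_genes_arm = int(sel.sum())
        if n_genes_arm == 0:  # pragma: no cover - defensive
            warnings.warn(f"arm {arm} has no genes; skipped")
            continue
        smoothed[sel] = _moving_average_block(rel[sel].T, window).T
    scores = smoothed.T  # cells x windows
    return CNVProfile(
        cell_ids=e.cell_ids,
        scores=scores,
        window_genes=ann.index,
        window_arms=arms,
        window=window,
        reference_cells=reference_cells,
    )


def arm_means_by_type(p: CNVProfile, annotation: CellAnnotation) -> pd.DataFrame:
    """Mean window score per (cell-type label, arm)."""
    rows = []
    labels = pd.unique(annotation.label)
    label_series = pd.Series(annotation.label, index=annotation.cell_ids)
    aligned = label_series.reindex(p.cell_ids).to_numpy()
    for label in labels:
        mask = aligned == label
        if not mask.any():
            continue
        for arm in p.arms():
            rows.append(
                {"label": label, "arm": arm, "mean_score": p.arm_score(mask, arm)}
            )
    df = pd.DataFrame(rows)
    p.arm_means = df
    return df


def call_arm_events(
    p: CNVProfile,
    annotation: CellAnnotation,
    gain_thresh: float = 0.1,
    loss_thresh: float = -0.1,
) -> pd.DataFrame:
    """Arm-level gain/loss/neutral calls per cell type.

    gain if the type's mean arm score > ``gain_thresh``; loss if
    < ``loss_thresh``; neutral otherwise.
    """
    if not (gain_thresh > 0 > loss_thresh):
        raise ValueError("need gain_thresh > 0 > loss_thresh")
    means = arm_means_by_type(p, annotation)
    calls = np.where(
        means["mean_score"] > gain_thresh,
        "gain",
        np.where(means["mean_score"] < loss_thresh, "loss", "neutral"),
    )
    out = means.assign(call=calls, gain_thresh=gain_thresh, loss_thresh=loss_thresh)
    return out
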