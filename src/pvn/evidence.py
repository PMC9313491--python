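"""Patient-evidence tiering for prioritized receptors.

For each patient tumor scRNA-seq matrix, neoplastic cells are enriched
by dropping de novo clusters marked by terminally differentiated,
immune or astrocytic genes (MBP, PLP1, CD14, AIF1, ETNPPL). Within the
remaining cells, genes expressed in at least 3 cells are kept and
normalized; the first quartile of per-gene average expression serves as
the reference, and each receptor's average expression is classified:

* ``none``     - average expression is exactly 0
* ``marginal`` - greater than 0 but not above the first quartile
* ``strong``   - strictly above the first quartile

Patients contributing fewer than a minimum number of neoplastic cells
(default 113) are excluded.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from . import qc as qc_mod
from .containers import CellAnnotation, CountMatrix

logger = logging.getLogger(__name__)

EXCLUSION_MARKERS = ("MBP", "PLP1", "CD14", "AIF1", "ETNPPL")


def enrich_neoplastic(
    e,
    clusters: CellAnnotation,
    exclusion_markers=EXCLUSION_MARKERS,
    lfc_min: float = 0.3,
    fdr_max: float = 0.05,
) -> pd.Index:
    """Cells of clusters whose marker list contains no exclusion marker.

    A cluster is removed when its one-vs-rest marker-gene list
    (|log2FC| >= ``lfc_min``, FDR <= ``fdr_max``) contains any of the
    exclusion markers with positive fold change.
    """
    present = [m for m in exclusion_markers if m in e.gene_ids]
    missing = sorted(set(exclusion_markers) - set(present))
    if missing:
        warnings.warn(f"exclusion markers absent from matrix, ignored: {missing}")
    markers = qc_mod.marker_de(e, clusters, lfc_min=lfc_min, fdr_max=fdr_max)
    drop = set()
    for cluster_id, table in markers.items():
        up = table[table["log2fc"] > 0]
        if any(m in up.index for m in present):
            drop.add(cluster_id)
    keep_mask = ~np.isin(clusters.cluster, sorted(drop))
    if not keep_mask.any():
        raise ValueError("every cluster carries an exclusion marker; no cells left")
    return clusters.cell_ids[keep_mask]


def evidence_tier(avg_expr: float, q1_reference: float) -> str:
    """Classify average receptor expression against the gene-wide Q1."""
    if avg_expr < 0 or q1_reference < 0:
        raise ValueError("expression values must be non-negative")
    if avg_expr == 0:
        return "none"
    if avg_expr <= q1_reference:
        return "marginal"
    return "strong"


def per_patient_receptor_evidence(
    matrices: dict[str, CountMatrix],
    receptors,
    min_cells: int = 113,
    min_detect_cells: int = 3,
    target_sum: float = 1e4,
) -> pd.DataFrame:
    """Evidence tier per (receptor, patient).

    Each patient matrix is expected to contain neoplastic cells only
    (apply :func:`enrich_neoplastic` upstream). Per patient: genes
    expressed in >= ``min_detect_cells`` cells are kept and
    log-normalized; q1 is the first quartile (linear interpolation) of
    per-gene average log-normalized expression; receptors are tiered by
    :func:`evidence_tier` on their average over cells.
    """
    rows = []
    for patient, m in sorted(matrices.items()):
        if m.n_cells < min_cells:
            logger.info(
                "patient %s excluded: %d < %d cells", patient, m.n_cells, min_cells
            )
            continue
        detected = (m.counts > 0).sum(axis=1) >= min_detect_cells
        sub = m.subset_genes(detected)
        e = qc_mod.normalize_log(sub, target_sum=target_sum, regress_covariates=False)
        gene_avg = e.values.mean(axis=1)
        q1 = float(np.quantile(gene_avg, 0.25))
        for receptor in receptors:
            if receptor in e.gene_ids:
                avg = float(e.values[e.gene_ids.get_loc(receptor)].mean())
                tier = evidence_tier(avg, q1)
            else:
                warnings.warn(
                    f"receptor {receptor} absent from patient {patient}; tier none"
                )
                avg, tier = 0.0, "none"
            rows.append(
                {
                    "receptor": receptor,
                    "patient": patient,
                    "avg_expr": avg,
                    "q1_reference": q1,
                    "tier": tier,
                    "n_cells": m.n_cells,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["receptor", "patient", "avg_expr", "q1_reference", "tier", "n_cells"],
    )
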