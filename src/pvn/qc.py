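"""Quality filtering, normalization, HVG selection, clustering, annotation.

The processing chain mirrors standard single-cell practice: remove
low-quality cells (too few detected genes, high mitochondrial fraction)
and rarely detected genes; library-size normalize and log1p; regress
total-UMI and mitochondrial-fraction covariates out of a scaled copy
used only for PCA; select highly variable genes; build a shared-nearest-
neighbor (SNN) graph on the top principal components and cluster it by
modularity optimization (Leiden); finally label clusters from canonical
markers (PECAM1 for endothelial cells, S100B for astrocytes, CDKN2A for
glioma stem cells).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from . import de as de_mod
from .containers import CellAnnotation, CountMatrix, ExpressionMatrix

logger = logging.getLogger(__name__)

DEFAULT_MARKERS = {"EC": "PECAM1", "astrocyte": "S100B", "GSC": "CDKN2A"}


@dataclass
class QCReport:
    n_cells_in: int
    n_genes_in: int
    n_cells_removed_min_genes: int
    n_cells_removed_mito: int
    n_genes_removed_min_cells: int

    @property
    def n_cells_out(self) -> int:
        return self.n_cells_in - self.n_cells_removed_min_genes - self.n_cells_removed_mito

    @property
    def n_genes_out(self) -> int:
        return self.n_genes_in - self.n_genes_removed_min_cells


def qc_filter(
    m: CountMatrix,
    min_cells: int = 3,
    min_genes: int = 200,
    max_mito: float = 0.18,
) -> tuple[CountMatrix, QCReport]:
    """Remove low-quality cells, then rarely detected genes.

    Cells with fewer than ``min_genes`` detected genes or with
    mitochondrial fraction strictly greater than ``max_mito`` are
    removed first; genes detected (count > 0) in fewer than ``min_cells``
    of the remaining cells are removed second, so gene prevalence is
    evaluated on the retained cell set.
    """
    detected_per_cell = (m.counts > 0).sum(axis=0)
    keep_genes_cells = detected_per_cell >= min_genes
    mito = m.mito_fraction
    keep_mito = mito <= max_mito
    keep_cells = keep_genes_cells & keep_mito
    n_min_genes = int((~keep_genes_cells).sum())
    n_mito = int((keep_genes_cells & ~keep_mito).sum())
    if not keep_cells.any():
        raise ValueError("QC removed every cell; check thresholds and input")
    filtered = m.subset_cells(keep_cells)
    cells_per_gene = (filtered.counts > 0).sum(axis=1)
    keep_genes = cells_per_gene >= min_cells
    out = filtered.subset_genes(keep_genes)
    report = QCReport(
        n_cells_in=m.n_cells,
        n_genes_in=m.n_genes,
        n_cells_removed_min_genes=n_min_genes,
        n_cells_removed_mito=n_mito,
        n_genes_removed_min_cells=int((~keep_genes).sum()),
    )
    logger.info(
        "QC: %d/%d cells kept (%d < %d genes, %d mito > %.2f); %d/%d genes kept",
        report.n_cells_out, report.n_cells_in, n_min_genes, min_genes,
        n_mito, max_mito, report.n_genes_out, report.n_genes_in,
    )
    return out, report


def normalize_log(
    m: CountMatrix,
    target_sum: float = 1e4,
    regress_covariates: bool = True,
) -> ExpressionMatrix:
    """Library-size normalize to ``target_sum`` per cell, then log1p.

    The returned ``values`` matrix (used for DE and fraction-expressing
    computations) is untouched by covariate regression. When
    ``regress_covariates`` is set, a second copy is produced in which
    each gene is linearly regressed on per-cell total UMIs and
    mitochondrial fraction and replaced by its residuals, then scaled to
    unit variance; that copy (``pca_values``) feeds PCA and clustering
    only.
    """
    totals = m.total_umis.astype(float)
    if (totals == 0).any():
        raise ValueError("zero-total cell encountered; run qc_filter first")
    norm = m.counts / totals * target_sum
    values = np.log1p(norm)
    pca_values = None
    if regress_covariates:
        X = np.column_stack(
            [np.ones(m.n_cells), totals, m.mito_fraction]
        )  # cells x 3
        # least-squares residuals for all genes at once
        beta, *_ = np.linalg.lstsq(X, values.T, rcond=None)
        resid = values - (X @ beta).T
        sd = resid.std(axis=1, ddof=1)
        sd[sd == 0] = 1.0
        pca_values = resid / sd[:, None]
    return ExpressionMatrix(
        values,
        m.gene_ids,
        m.cell_ids,
        m.cell_meta,
        provenance={"target_sum": target_sum, "regressed": regress_covariates},
        pca_values=pca_values,
    )


def select_hvg(e: ExpressionMatrix, n_top: int = 4000, n_bins: int = 20) -> ExpressionMatrix:
    """Mark the top ``n_top`` highly variable genes (dispersion-based).

    Per gene, dispersion = variance/mean of the de-logged normalized
    values; dispersions are z-scored within mean-expression bins and the
    top genes by normalized dispersion are flagged. Zero-variance genes
    are never ranked above any gene with positive variance. Deterministic
    given the input.
    """
    vals = np.expm1(e.values)
    mean = vals.mean(axis=1)
    var = vals.var(axis=1, ddof=1) if e.n_cells > 1 else np.zeros(e.n_genes)
    with np.errstate(invalid="ignore", divide="ignore"):
        disp = np.where(mean > 0, var / mean, 0.0)
    # normalize dispersion by the median of its mean-expression bin, so the
    # statistic is comparable across the mean range but robust in
    # homogeneous bins
    order = np.argsort(mean, kind="stable")
    bins = np.array_split(order, min(n_bins, e.n_genes))
    norm_disp = np.zeros(e.n_genes)
    for idx in bins:
        if len(idx) == 0:
            continue
        d = disp[idx]
        med = np.median(d)
        norm_disp[idx] = d / med if med > 0 else d
    effectively_constant = var <= 1e-12 * np.maximum(mean, 1.0) ** 2
    norm_disp = np.where(~effectively_constant, norm_disp, -np.inf)
    n_keep = min(n_top, e.n_genes)
    # stable selection: rank by (-norm_disp, -disp, gene order)
    ranked = np.lexsort((np.arange(e.n_genes), -disp, -norm_disp))
    mask = np.zeros(e.n_genes, dtype=bool)
    mask[ranked[:n_keep]] = True
    out = ExpressionMatrix(
        e.values, e.gene_ids, e.cell_ids, e.cell_meta,
        dict(e.provenance), mask, e.pca_values,
    )
    return out


def _snn_graph(pcs: np.ndarray, k_neighbors: int) -> sp.csr_matrix:
    """Shared-nearest-neighbor graph with Jaccard edge weights.

    Edges are taken from the union of directed kNN links; the weight of
    (i, j) is the Jaccard overlap of the two cells' neighbor sets
    (including self), pruned below 1/15.
    """
    nn = NearestNeighbors(n_neighbors=k_neighbors).fit(pcs)
    knn = nn.kneighbors_graph(pcs, mode="connectivity")  # includes self? no
    # include self so each cell shares at least itself with its neighbors
    knn = knn + sp.identity(pcs.shape[0], format="csr")
    knn.data[:] = 1.0
    shared = knn @ knn.T  # n x n shared-neighbor counts on kNN support
    union_mask = ((knn + knn.T) > 0).astype(float)
    shared = shared.multiply(union_mask)
    shared = shared.tocoo()
    k_eff = k_neighbors + 1
    jac = shared.data / (2 * k_eff - shared.data)
    keep = jac >= 1.0 / 15.0
    g = sp.coo_matrix(
        (jac[keep], (shared.row[keep], shared.col[keep])), shape=shared.shape
    ).tocsr()
    g.setdiag(0)
    g.eliminate_zeros()
    return g


def cluster_snn(
    e: ExpressionMatrix,
    n_pcs: int = 50,
    k_neighbors: int = 15,
    resolution: float = 1.0,
    seed: int = 0,
) -> CellAnnotation:
    """PCA -> kNN -> SNN -> Leiden modularity clustering.

    Uses the covariate-regressed scaled copy when available, restricted
    to the HVG mask. Deterministic for a fixed seed.
    """
    if e.n_cells <= k_neighbors:
        raise ValueError(
            f"need more than k_neighbors={k_neighbors} cells, got {e.n_cells}"
        )
    mat = e.pca_values if e.pca_values is not None else e.values
    if e.hvg_mask is not None:
        mat = mat[e.hvg_mask]
    X = mat.T  # cells x genes
    n_comp = min(n_pcs, X.shape[1], X.shape[0] - 1)
    pca = PCA(n_components=n_comp, svd_solver="randomized", random_state=seed)
    pcs = pca.fit_transform(X)
    g = _snn_graph(pcs, k_neighbors)
    coo = sp.triu(g, k=1).tocoo()
    graph = ig.Graph(
        n=e.n_cells,
        edges=list(zip(coo.row.tolist(), coo.col.tolist())),
        edge_attrs={"weight": coo.data.tolist()},
    )
    part = leidenalg.find_partition(
        graph,
        leidenalg.RBConfigurationVertexPartition,
        weights="weight",
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=-1,
    )
    clusters = np.asarray(part.membership)
    logger.info("SNN clustering: %d clusters on %d cells", clusters.max() + 1, len(clusters))
    return CellAnnotation(e.cell_ids, clusters)


def annotate_clusters(
    e: ExpressionMatrix,
    clusters: CellAnnotation,
    markers: dict[str, str] | None = None,
    min_marker_fraction: float = 0.5,
) -> CellAnnotation:
    """Label clusters by their dominant canonical marker.

    A cluster receives the label of the marker with the highest mean
    expression, provided that marker's mean inside the cluster exceeds
    its mean elsewhere and at least ``min_marker_fraction`` of the
    cluster's cells express it; otherwise the cluster is "unknown". When
    several clusters qualify for the same label, only the one with the
    highest marker-expressing fraction keeps it.
    """
    markers = dict(DEFAULT_MARKERS if markers is None else markers)
    for label, gene in markers.items():
        if gene not in e.gene_ids:
            raise KeyError(f"marker gene {gene!r} for {label!r} absent from matrix")
    cluster_ids = np.unique(clusters.cluster)
    # candidate (cluster -> label, fraction)
    proposal: dict[int, tuple[str, float]] = {}
    for c in cluster_ids:
        in_c = clusters.cluster == c
        best_label, best_mean = None, -np.inf
        for label, gene in markers.items():
            gv = e.gene_values(gene)
            if gv[in_c].mean() > best_mean:
                best_label, best_mean = label, gv[in_c].mean()
        gene = markers[best_label]
        gv = e.gene_values(gene)
        mean_in = gv[in_c].mean()
        mean_out = gv[~in_c].mean() if (~in_c).any() else -np.inf
        frac = float((gv[in_c] > 0).mean())
        if mean_in > mean_out and frac >= min_marker_fraction:
            proposal[int(c)] = (best_label, frac)
    # resolve label collisions: highest expressing fraction wins
    final: dict[int, str] = {}
    for label in markers:
        contenders = [(frac, c) for c, (lab, frac) in proposal.items() if lab == label]
        if contenders:
            _, winner = max(contenders)
            final[winner] = label
    labels = np.array(
        [final.get(int(c), "unknown") for c in clusters.cluster], dtype=object
    )
    return CellAnnotation(clusters.cell_ids, clusters.cluster, labels)


def marker_de(
    e: ExpressionMatrix,
    clusters: CellAnnotation,
    lfc_min: float = 0.3,
    fdr_max: float = 0.05,
) -> dict[int, pd.DataFrame]:
    """One-vs-rest marker genes per cluster (|log2FC| >= 0.3, FDR <= 0.05).

    Returns per cluster the DE table restricted to its marker genes.
    Singleton clusters are skipped with a warning.
    """
    cluster_ids = np.unique(clusters.cluster)
    if len(cluster_ids) < 2:
        raise ValueError("need at least two clusters for marker DE")
    out: dict[int, pd.DataFrame] = {}
    for c in cluster_ids:
        in_c = clusters.cluster == c
        if in_c.sum() < 2:
            warnings.warn(f"cluster {c} has <2 cells; skipped in marker DE")
            continue
        res = de_mod.differential_expression(
            e.values[:, in_c], e.values[:, ~in_c], e.gene_ids
        )
        keep = (res["log2fc"].abs() >= lfc_min) & (res["fdr"] <= fdr_max)
        out[int(c)] = res[keep]
    return out
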