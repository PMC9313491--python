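"""Two-group differential expression: Wilcoxon rank-sum + BH-FDR + log2FC.

The per-gene test is the two-sided Wilcoxon (Mann-Whitney) rank-sum
test. For small, tie-free samples (min group size <= 8) the exact null
distribution is used; otherwise the normal approximation with midrank
tie correction and continuity correction. P-values are adjusted with
the Benjamini-Hochberg step-up procedure across genes.

Fold changes are computed on the normalized (de-logged) scale: group
means of expm1(log-normalized values), log2-ratio with a small
pseudocount so that all-zero genes give log2FC = 0.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionMatrix

#: A DEResult is a DataFrame indexed by gene with columns
#: log2fc, p_raw, fdr, mean_a, mean_b, frac_expressing_a, frac_expressing_b,
#: stably sorted by (fdr, -|log2fc|, gene symbol).
DEResult = pd.DataFrame

DEFAULT_PSEUDOCOUNT = 1e-9


def wilcoxon_rank_sum(x, y) -> float:
    """Two-sided rank-sum p-value for samples ``x`` (group A) vs ``y``.

    Exact for min(|A|, |B|) <= 8 without ties; normal approximation with
    tie and continuity correction otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    if np.unique(pooled).size == 1:
        return 1.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (min(x.size, y.size) <= 8 and not has_ties) else "asymptotic"
    return float(
        stats.mannwhitneyu(
            x, y, alternative="two-sided", method=method, use_continuity=False
        ).pvalue
    )


def _rank_sum_matrix(values: np.ndarray, mask_a: np.ndarray) -> np.ndarray:
    """Vectorized two-sided rank-sum p-values, one per row of ``values``.

    Normal approximation with midrank tie correction and continuity
    correction, matching :func:`wilcoxon_rank_sum` in its asymptotic
    branch.
    """
    n_a = int(mask_a.sum())
    n_b = values.shape[1] - n_a
    if n_a == 0 or n_b == 0:
        raise ValueError("both groups must be non-empty")
    ranks = stats.rankdata(values, axis=1)
    rank_sum_a = ranks[:, mask_a].sum(axis=1)
    u_a = rank_sum_a - n_a * (n_a + 1) / 2.0
    mu = n_a * n_b / 2.0
    n = n_a + n_b
    # tie correction: sum over tied groups of (t^3 - t) per gene
    sorted_vals = np.sort(values, axis=1)
    tie_term = np.zeros(values.shape[0])
    for i in range(values.shape[0]):
        _, counts = np.unique(sorted_vals[i], return_counts=True)
        tie_term[i] = np.sum(counts.astype(float) ** 3 - counts)
    sigma2 = n_a * n_b / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    sigma = np.sqrt(np.maximum(sigma2, 0.0))
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.abs(u_a - mu) / sigma
    z = np.where(sigma > 0, z, 0.0)
    return np.minimum(2.0 * stats.norm.sf(z), 1.0)


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, returned in input order.

    q_(i) = min_{j >= i}( p_(j) * m / j ), capped at 1.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def log2_fold_change(
    mean_a: float, mean_b: float, pseudocount: float = DEFAULT_PSEUDOCOUNT
) -> float:
    """log2((mean_a + eps) / (mean_b + eps)) on the normalized scale."""
    if mean_a < 0 or mean_b < 0:
        raise ValueError("group means must be non-negative")
    return float(np.log2((mean_a + pseudocount) / (mean_b + pseudocount)))


def align_conditions(
    a: ExpressionMatrix, b: ExpressionMatrix
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Restrict two matrices to their common genes, in shared order.

    Order follows the first matrix's gene order restricted to the
    intersection.
    """
    common = a.gene_ids[a.gene_ids.isin(b.gene_ids)]
    if len(common) == 0:
        raise ValueError("no genes in common between the two matrices")
    mask_a = a.gene_ids.isin(common)
    a2 = a.subset_genes(mask_a.to_numpy() if hasattr(mask_a, "to_numpy") else mask_a)
    idx_b = b.gene_ids.get_indexer(common)
    b2 = ExpressionMatrix(
        b.values[idx_b],
        common,
        b.cell_ids,
        b.cell_meta,
        dict(b.provenance),
        None if b.hvg_mask is None else b.hvg_mask[idx_b],
        None if b.pca_values is None else b.pca_values[idx_b],
    )
    return a2, b2


def differential_expression(
    values_a: np.ndarray,
    values_b: np.ndarray,
    gene_ids: pd.Index,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> DEResult:
    """Per-gene DE between two cell groups of log-normalized values.

    ``values_a``/``values_b`` are genes x cells slices over the same
    genes. Group A is the condition of interest (e.g. triculture);
    log2FC > 0 means higher in A.
    """
    if values_a.shape[0] != values_b.shape[0]:
        raise ValueError("gene dimension mismatch")
    if values_a.shape[1] == 0 or values_b.shape[1] == 0:
        raise ValueError("both groups must be non-empty")
    mask_a = np.zeros(values_a.shape[1] + values_b.shape[1], dtype=bool)
    mask_a[: values_a.shape[1]] = True
    pooled = np.concatenate([values_a, values_b], axis=1)
    p_raw = _rank_sum_matrix(pooled, mask_a)
    fdr = bh_fdr(p_raw)
    mean_a = np.expm1(values_a).mean(axis=1)
    mean_b = np.expm1(values_b).mean(axis=1)
    lfc = np.log2((mean_a + pseudocount) / (mean_b + pseudocount))
    out = pd.DataFrame(
        {
            "log2fc": lfc,
            "p_raw": p_raw,
            "fdr": fdr,
            "mean_a": mean_a,
            "mean_b": mean_b,
            "frac_expressing_a": (values_a > 0).mean(axis=1),
            "frac_expressing_b": (values_b > 0).mean(axis=1),
        },
        index=gene_ids,
    )
    # stable sort by (fdr, -|log2fc|, symbol)
    out = out.sort_index(kind="stable")
    out["_abs"] = -out["log2fc"].abs()
    out = out.sort_values(["fdr", "_abs"], kind="stable").drop(columns="_abs")
    return out


def de_between_conditions(
    e_a: ExpressionMatrix,
    e_b: ExpressionMatrix,
    cells_a: pd.Index | None = None,
    cells_b: pd.Index | None = None,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> DEResult:
    """DE between cell subsets of two aligned expression matrices."""
    a2, b2 = align_conditions(e_a, e_b)
    va = a2.values if cells_a is None else a2.values[:, a2.cell_ids.isin(cells_a)]
    vb = b2.values if cells_b is None else b2.values[:, b2.cell_ids.isin(cells_b)]
    return differential_expression(va, vb, a2.gene_ids, pseudocount)


def upregulated_genes(
    de: DEResult, lfc_min: float, fdr_max: float = 0.05
) -> set[str]:
    """Genes with log2FC >= ``lfc_min`` and FDR <= ``fdr_max`` (inclusive)."""
    keep = (de["log2fc"] >= lfc_min) & (de["fdr"] <= fdr_max)
    return set(de.index[keep])
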