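"""In-memory containers shared across the pipeline.

The central object is :class:`CountMatrix`, a genes x cells integer count
matrix with per-cell metadata (culture condition, optional patient id).
Downstream stages operate on :class:`ExpressionMatrix` (log-normalized
values plus a covariate-regressed copy reserved for PCA/clustering) and a
handful of small record types (ligand-receptor pairs, gene sets, receptor
candidates, CNV profiles).

Genes are identified by symbol, case-sensitively, with no alias
resolution; mitochondrial genes are recognized by the "MT-" prefix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MITO_PREFIX = "MT-"

#: Allowed culture condition labels.
CONDITIONS = ("mono", "tri")


class ValidationError(ValueError):
    """Raised when a container's invariants are violated."""


def _check_unique(ids, what: str) -> pd.Index:
    idx = pd.Index(ids)
    if idx.has_duplicates:
        dups = idx[idx.duplicated()].unique().tolist()[:5]
        raise ValidationError(f"duplicate {what}: {dups}")
    return idx


@dataclass
class CountMatrix:
    """Raw integer gene x cell counts with cell-level metadata.

    Parameters
    ----------
    counts
        Non-negative integer matrix of shape (n_genes, n_cells).
    gene_ids
        Unique gene symbols, one per row.
    cell_ids
        Unique cell barcodes, one per column.
    cell_meta
        Per-cell table indexed by barcode with at least a ``condition``
        column (``mono`` or ``tri``); an optional ``patient`` column is
        carried through untouched.
    """

    counts: np.ndarray
    gene_ids: pd.Index
    cell_ids: pd.Index
    cell_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValidationError("counts must be 2-D (genes x cells)")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.allclose(self.counts, np.round(self.counts)):
                raise ValidationError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if (self.counts < 0).any():
            raise ValidationError("counts must be non-negative")
        self.gene_ids = _check_unique(self.gene_ids, "gene ids")
        self.cell_ids = _check_unique(self.cell_ids, "cell barcodes")
        if self.counts.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValidationError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        meta = self.cell_meta
        if not self.cell_ids.isin(meta.index).all():
            missing = self.cell_ids[~self.cell_ids.isin(meta.index)][:5].tolist()
            raise ValidationError(f"cell_meta missing barcodes: {missing}")
        # keep metadata aligned to the matrix column order
        self.cell_meta = meta.loc[self.cell_ids]
        if "condition" in self.cell_meta.columns:
            bad = set(self.cell_meta["condition"]) - set(CONDITIONS)
            if bad:
                raise ValidationError(f"unknown condition labels: {sorted(bad)}")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    @property
    def total_umis(self) -> np.ndarray:
        """Per-cell total UMI count."""
        return self.counts.sum(axis=0)

    @property
    def mito_fraction(self) -> np.ndarray:
        """Per-cell fraction of counts from "MT-"-prefixed genes."""
        mito = self.gene_ids.str.startswith(MITO_PREFIX)
        totals = self.total_umis.astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = self.counts[mito].sum(axis=0) / totals
        return np.where(totals > 0, frac, 0.0)

    def subset_genes(self, mask: np.ndarray) -> "CountMatrix":
        return CountMatrix(
            self.counts[mask], self.gene_ids[mask], self.cell_ids, self.cell_meta
        )

    def subset_cells(self, mask: np.ndarray) -> "CountMatrix":
        return CountMatrix(
            self.counts[:, mask],
            self.gene_ids,
            self.cell_ids[mask],
            self.cell_meta.loc[self.cell_ids[mask]],
        )

    def equals(self, other: "CountMatrix") -> bool:
        return (
            np.array_equal(self.counts, other.counts)
            and self.gene_ids.equals(other.gene_ids)
            and self.cell_ids.equals(other.cell_ids)
            and self.cell_meta.reindex(columns=other.cell_meta.columns).equals(
                other.cell_meta
            )
        )


@dataclass
class ExpressionMatrix:
    """Log-normalized expression with an optional regressed copy for PCA.

    ``values`` holds log1p(counts scaled to ``target_sum``) and is the
    matrix used for differential expression and fraction-expressing
    computations. ``pca_values``, when present, holds the same matrix
    after per-gene linear regression on total UMIs and mitochondrial
    fraction (residuals, then unit-variance scaling); it feeds PCA and
    clustering only, never DE.
    """

    values: np.ndarray
    gene_ids: pd.Index
    cell_ids: pd.Index
    cell_meta: pd.DataFrame
    provenance: dict = field(default_factory=dict)
    hvg_mask: np.ndarray | None = None
    pca_values: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = pd.Index(self.gene_ids)
        self.cell_ids = pd.Index(self.cell_ids)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def gene_values(self, gene: str) -> np.ndarray:
        if gene not in self.gene_ids:
            raise KeyError(f"gene {gene!r} not in matrix")
        return self.values[self.gene_ids.get_loc(gene)]

    def subset_genes(self, mask: np.ndarray) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values[mask],
            self.gene_ids[mask],
            self.cell_ids,
            self.cell_meta,
            dict(self.provenance),
            None if self.hvg_mask is None else self.hvg_mask[mask],
            None if self.pca_values is None else self.pca_values[mask],
        )

    def subset_cells(self, mask: np.ndarray) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values[:, mask],
            self.gene_ids,
            self.cell_ids[mask],
            self.cell_meta.loc[self.cell_ids[mask]],
            dict(self.provenance),
            self.hvg_mask,
            None if self.pca_values is None else self.pca_values[:, mask],
        )


@dataclass
class CellAnnotation:
    """Per-cell cluster assignment and cell-type label.

    Labels are drawn from {"EC", "astrocyte", "GSC", "unknown"}; clusters
    are arbitrary non-negative integers.
    """

    cell_ids: pd.Index
    cluster: np.ndarray
    label: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.cell_ids = pd.Index(self.cell_ids)
        self.cluster = np.asarray(self.cluster)
        if len(self.cluster) != len(self.cell_ids):
            raise ValidationError("cluster vector length mismatch")
        if self.label is None:
            self.label = np.array(["unknown"] * len(self.cell_ids), dtype=object)
        self.label = np.asarray(self.label, dtype=object)
        if len(self.label) != len(self.cell_ids):
            raise ValidationError("label vector length mismatch")

    def cells_of_type(self, label: str) -> pd.Index:
        return self.cell_ids[self.label == label]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"cluster": self.cluster, "label": self.label}, index=self.cell_ids
        )


class LRPairTable:
    """A set of (ligand, receptor) gene symbol pairs."""

    def __init__(self, pairs) -> None:
        self.pairs: set[tuple[str, str]] = set(map(tuple, pairs))

    def __len__(self) -> int:
        return len(self.pairs)

    def receptors(self) -> set[str]:
        return {r for _, r in self.pairs}

    def ligands(self) -> set[str]:
        return {l for l, _ in self.pairs}

    def ligands_for(self, receptor: str) -> set[str]:
        return {l for l, r in self.pairs if r == receptor}


class SecretedSet:
    """Gene symbols annotated as secreted proteins."""

    def __init__(self, genes) -> None:
        self.genes: set[str] = set(genes)

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes

    def __len__(self) -> int:
        return len(self.genes)


class GeneSetCollection:
    """Named pathway gene sets (GMT-style)."""

    def __init__(self, sets: dict[str, list[str]], source: str = "") -> None:
        for name, genes in sets.items():
            if len(genes) == 0:
                raise ValidationError(f"gene set {name!r} is empty")
        self.sets = {name: list(dict.fromkeys(genes)) for name, genes in sets.items()}
        self.source = source

    def __len__(self) -> int:
        return len(self.sets)

    def sets_containing(self, gene: str) -> dict[str, list[str]]:
        return {n: g for n, g in self.sets.items() if gene in g}


@dataclass(frozen=True)
class ReceptorCandidate:
    """One row of the prioritized-receptor table.

    A candidate is only emitted when it passed every cascade stage, so
    ``fdr`` <= 0.05, ``ligands`` is non-empty and
    ``n_enriched_pathways`` >= 1 for all emitted candidates.
    """

    receptor: str
    log2fc: float
    fdr: float
    ligands: tuple[str, ...]
    n_enriched_pathways: int


@dataclass
class CNVProfile:
    """Smoothed relative-expression track ordered by genomic position.

    ``scores`` is cells x windows (one window score per retained gene
    position, smoothed within its arm); ``window_arms`` names the arm of
    each column. ``arm_means`` is a (label, arm) -> mean score table.
    """

    cell_ids: pd.Index
    scores: np.ndarray
    window_genes: pd.Index
    window_arms: np.ndarray
    window: int
    reference_cells: pd.Index
    arm_means: pd.DataFrame | None = None

    def arms(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.window_arms:
            seen.setdefault(a, None)
        return list(seen)

    def arm_score(self, cells_mask: np.ndarray, arm: str) -> float:
        cols = self.window_arms == arm
        return float(self.scores[np.ix_(cells_mask, cols)].mean())
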