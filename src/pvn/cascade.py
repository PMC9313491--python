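"""Four-stage ligand-receptor prioritization cascade.

Starting from genes upregulated in triculture glioma stem cells (GSCs)
relative to monoculture:

1. intersect the upregulated genes with the receptor side of a
   literature ligand-receptor network;
2. keep receptors with at least one cognate *secreted* ligand expressed
   in >= 10% of triculture endothelial cells or astrocytes;
3. keep receptors for which at least one pathway containing the
   receptor is enriched (hypergeometric upper tail, raw p <= 0.05, no
   cross-pathway correction) for the strictly upregulated GSC genes
   (log2FC >= 1.0, FDR <= 0.05);
4. rank the survivors by log2 fold change and report the top k.

Also provided: per-(ligand, cell type) triculture-vs-monoculture
upregulation flags, and the sign-corrected first-principal-component
"eigengene" summary of a gene set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import de as de_mod
from .containers import (
    CellAnnotation,
    ExpressionMatrix,
    GeneSetCollection,
    LRPairTable,
    ReceptorCandidate,
    SecretedSet,
)

logger = logging.getLogger(__name__)


@dataclass
class EnrichmentResult:
    pathway: str
    k: int
    K: int
    n: int
    N: int
    p: float


@dataclass
class CascadeReport:
    """Stage-by-stage record of the receptor prioritization."""

    n_upregulated: int
    n_receptors_stage1: int
    n_stage2: int
    n_stage3: int
    candidates: list[ReceptorCandidate]
    top_k: list[ReceptorCandidate]
    ligand_fractions: pd.DataFrame | None = None
    ligand_flags: pd.DataFrame | None = None
    enrichments: dict[str, list[EnrichmentResult]] = field(default_factory=dict)

    def stage_counts(self) -> dict[str, int]:
        return {
            "n_upregulated": self.n_upregulated,
            "n_receptors_stage1": self.n_receptors_stage1,
            "n_stage2": self.n_stage2,
            "n_stage3": self.n_stage3,
            "n_top_k": len(self.top_k),
        }


def intersect_receptors(up_genes: set[str], lr: LRPairTable) -> set[str]:
    """Receptors of the network that are among the upregulated genes."""
    return lr.receptors() & set(up_genes)


def fraction_expressing(e: ExpressionMatrix, gene: str, cells) -> float:
    """Fraction of the given cells with nonzero expression of ``gene``."""
    gv = e.gene_values(gene)  # raises KeyError if absent
    mask = e.cell_ids.isin(pd.Index(cells))
    if not mask.any():
        return 0.0
    return float((gv[mask] > 0).mean())


def filter_secreted_expressed(
    receptors: set[str],
    lr: LRPairTable,
    secreted: SecretedSet,
    e_tri: ExpressionMatrix,
    ann: CellAnnotation,
    min_frac: float = 0.10,
) -> dict[str, list[str]]:
    """Stage 2: require an expressed secreted cognate ligand.

    A receptor is kept iff at least one of its cognate ligands is in the
    secreted set and is expressed in >= ``min_frac`` of triculture EC
    cells or of triculture astrocytes. Returns receptor -> sorted list
    of qualifying ligands. Ligand expression in GSCs (autocrine) does
    not satisfy the filter.
    """
    ec_cells = ann.cells_of_type("EC")
    astro_cells = ann.cells_of_type("astrocyte")
    if len(ec_cells) == 0 and len(astro_cells) == 0:
        raise ValueError("no EC or astrocyte cells in triculture annotation")
    out: dict[str, list[str]] = {}
    for receptor in sorted(receptors):
        qualifying = []
        for ligand in sorted(lr.ligands_for(receptor)):
            if ligand not in secreted or ligand not in e_tri.gene_ids:
                continue
            frac_ec = fraction_expressing(e_tri, ligand, ec_cells) if len(ec_cells) else 0.0
            frac_astro = (
                fraction_expressing(e_tri, ligand, astro_cells) if len(astro_cells) else 0.0
            )
            if frac_ec >= min_frac or frac_astro >= min_frac:
                qualifying.append(ligand)
        if qualifying:
            out[receptor] = qualifying
    return out


def hypergeometric_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n) (tail inclusive of k)."""
    if not (0 <= k <= min(K, n) <= N) or K > N or n > N:
        raise ValueError(f"inconsistent hypergeometric arguments k={k} K={K} n={n} N={N}")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def enrichment_filter(
    receptors_with_ligands: dict[str, list[str]],
    gsc_up_strict: set[str],
    sets: GeneSetCollection,
    universe: set[str],
    de_table: pd.DataFrame,
    p_max: float = 0.05,
) -> tuple[list[ReceptorCandidate], dict[str, list[EnrichmentResult]]]:
    """Stage 3: downstream pathway enrichment.

    For each receptor, pathways whose member list contains the receptor
    are tested for overlap between (pathway ∩ universe) and the strictly
    upregulated GSC gene set, with a hypergeometric upper tail on the
    shared ``universe`` (the aligned common genes). A receptor survives
    iff >= 1 pathway has raw p <= ``p_max``; raw p-values are used with
    no cross-pathway correction. ``de_table`` supplies each receptor's
    log2FC and FDR.
    """
    if len(universe) == 0:
        raise ValueError("empty gene universe")
    N = len(universe)
    query = gsc_up_strict & universe
    n = len(query)
    candidates: list[ReceptorCandidate] = []
    enrich: dict[str, list[EnrichmentResult]] = {}
    for receptor, ligands in sorted(receptors_with_ligands.items()):
        results = []
        for name, genes in sets.sets_containing(receptor).items():
            members = set(genes) & universe
            K = len(members)
            if K == 0:
                continue
            k = len(members & query)
            p = hypergeometric_tail(k, K, n, N)
            results.append(EnrichmentResult(name, k, K, n, N, p))
        significant = [r for r in results if r.p <= p_max]
        enrich[receptor] = results
        if significant:
            row = de_table.loc[receptor]
            candidates.append(
                ReceptorCandidate(
                    receptor=receptor,
                    log2fc=float(row["log2fc"]),
                    fdr=float(row["fdr"]),
                    ligands=tuple(ligands),
                    n_enriched_pathways=len(significant),
                )
            )
    return candidates, enrich


def rank_candidates(
    cands: list[ReceptorCandidate], top_k: int = 6
) -> list[ReceptorCandidate]:
    """Sort by log2FC descending (ties: lower FDR, then symbol); take top k."""
    ordered = sorted(cands, key=lambda c: (-c.log2fc, c.fdr, c.receptor))
    return ordered[:top_k]


def ligand_upregulation_flags(
    e_mono: ExpressionMatrix,
    e_tri: ExpressionMatrix,
    ann_mono: CellAnnotation,
    ann_tri: CellAnnotation,
    ligands,
    cell_types=("EC", "astrocyte", "GSC"),
    fdr_max: float = 0.05,
) -> pd.DataFrame:
    """Triculture-vs-monoculture upregulation flags per (ligand, cell type).

    For every tested ligand and cell type, a Wilcoxon rank-sum test of
    triculture vs monoculture expression within that cell type; BH-FDR
    across the whole ligand x cell-type grid; flag = (FDR <= 0.05 and
    log2FC > 0). Cell types missing from either condition are skipped.
    """
    import warnings

    e_mono, e_tri = de_mod.align_conditions(e_mono, e_tri)
    rows = []
    for ct in cell_types:
        cells_m = ann_mono.cells_of_type(ct)
        cells_t = ann_tri.cells_of_type(ct)
        if len(cells_m) == 0 or len(cells_t) == 0:
            warnings.warn(f"cell type {ct} absent in one condition; skipped")
            continue
        vm = e_mono.values[:, e_mono.cell_ids.isin(cells_m)]
        vt = e_tri.values[:, e_tri.cell_ids.isin(cells_t)]
        for ligand in ligands:
            if ligand not in e_tri.gene_ids:
                continue
            gi = e_tri.gene_ids.get_loc(ligand)
            p = de_mod.wilcoxon_rank_sum(vt[gi], vm[gi])
            lfc = de_mod.log2_fold_change(
                float(np.expm1(vt[gi]).mean()), float(np.expm1(vm[gi]).mean())
            )
            rows.append({"ligand": ligand, "cell_type": ct, "p_raw": p, "log2fc": lfc})
    df = pd.DataFrame(rows)
    if len(df):
        df["fdr"] = de_mod.bh_fdr(df["p_raw"].to_numpy())
        df["flag"] = (df["fdr"] <= fdr_max) & (df["log2fc"] > 0)
    else:
        df = pd.DataFrame(columns=["ligand", "cell_type", "p_raw", "log2fc", "fdr", "flag"])
    return df


def eigengene(e: ExpressionMatrix, gene_set) -> np.ndarray:
    """Sign-corrected first principal component of a gene set.

    Set genes present in the matrix are standardized across cells
    (zero-variance genes dropped); the per-cell score is the first
    principal component in that gene subspace, with its sign oriented so
    that the score correlates non-negatively with the per-cell mean of
    the standardized set genes.
    """
    genes = [g for g in gene_set if g in e.gene_ids]
    if not genes:
        raise ValueError("no gene of the set is present in the matrix")
    idx = e.gene_ids.get_indexer(pd.Index(genes))
    mat = e.values[idx]  # genes x cells
    mu = mat.mean(axis=1, keepdims=True)
    sd = mat.std(axis=1, ddof=0, keepdims=True)
    keep = sd[:, 0] > 0
    if not keep.any():
        raise ValueError("all set genes have zero variance")
    z = (mat[keep] - mu[keep]) / sd[keep]  # genes x cells, standardized
    # first right singular vector of the genes x cells matrix
    _, s, vt = np.linalg.svd(z, full_matrices=False)
    score = vt[0] * s[0]
    mean_profile = z.mean(axis=0)
    if np.dot(score - score.mean(), mean_profile - mean_profile.mean()) < 0:
        score = -score
    return score


def run_cascade(
    de_gsc: pd.DataFrame,
    lr: LRPairTable,
    secreted: SecretedSet,
    sets: GeneSetCollection,
    e_tri: ExpressionMatrix,
    ann_tri: CellAnnotation,
    universe: set[str],
    lfc_cascade: float = 0.3,
    lfc_strict: float = 1.0,
    fdr_max: float = 0.05,
    min_frac: float = 0.10,
    enrich_p: float = 0.05,
    top_k: int = 6,
) -> CascadeReport:
    """Run all four stages from a GSC triculture-vs-monoculture DE table."""
    up = de_mod.upregulated_genes(de_gsc, lfc_cascade, fdr_max)
    stage1 = intersect_receptors(up, lr)
    stage2 = filter_secreted_expressed(stage1, lr, secreted, e_tri, ann_tri, min_frac)
    up_strict = de_mod.upregulated_genes(de_gsc, lfc_strict, fdr_max)
    candidates, enrich = enrichment_filter(
        stage2, up_strict, sets, universe, de_gsc, enrich_p
    )
    ranked = rank_candidates(candidates, top_k)
    all_ligands = sorted({l for ls in stage2.values() for l in ls})
    report = CascadeReport(
        n_upregulated=len(up),
        n_receptors_stage1=len(stage1),
        n_stage2=len(stage2),
        n_stage3=len(candidates),
        candidates=rank_candidates(candidates, top_k=len(candidates) or 1),
        top_k=ranked,
        enrichments=enrich,
    )
    logger.info("cascade stage counts: %s", report.stage_counts())
    report.ligand_fractions = _ligand_fraction_table(e_tri, ann_tri, all_ligands)
    return report


def _ligand_fraction_table(
    e_tri: ExpressionMatrix, ann_tri: CellAnnotation, ligands
) -> pd.DataFrame:
    rows = []
    for ligand in ligands:
        if ligand not in e_tri.gene_ids:
            continue
        rows.append(
            {
                "ligand": ligand,
                "frac_EC": fraction_expressing(
                    e_tri, ligand, ann_tri.cells_of_type("EC")
                ),
                "frac_astrocyte": fraction_expressing(
                    e_tri, ligand, ann_tri.cells_of_type("astrocyte")
                ),
                "frac_GSC": fraction_expressing(
                    e_tri, ligand, ann_tri.cells_of_type("GSC")
                ),
            }
        )
    return pd.DataFrame(rows)
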