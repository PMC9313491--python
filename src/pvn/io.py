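"""Readers and writers for the external file formats.

Count matrices come in as either a 10x-style MatrixMarket triplet
(``matrix.mtx`` + ``features.tsv`` + ``barcodes.tsv``) or a dense TSV
(genes in rows, cells in columns). Ligand-receptor pairs, secreted-gene
lists, gene annotation and cell metadata are plain TSV; pathway gene
sets use the standard GMT layout.

Readers never silently drop records: deduplication and skipped rows are
reported through the module logger.
"""

from __future__ import annotations

import logging
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .containers import (
    CellAnnotation,
    CountMatrix,
    GeneSetCollection,
    LRPairTable,
    ReceptorCandidate,
    SecretedSet,
)

logger = logging.getLogger(__name__)


class ParseError(ValueError):
    """Structured parse failure naming the offending file (and line)."""


# ---------------------------------------------------------------------------
# count matrices


def _read_id_column(path: Path, what: str) -> list[str]:
    ids = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            ids.append(line.split("\t")[0])
    if len(set(ids)) != len(ids):
        raise ParseError(f"{path}: duplicate {what}")
    return ids


def read_count_matrix(
    path: str | Path,
    format: str = "mtx_triplet",
    cell_meta: pd.DataFrame | None = None,
) -> CountMatrix:
    """Read a gene x cell count matrix.

    Parameters
    ----------
    path
        For ``mtx_triplet``: a directory holding ``matrix.mtx``,
        ``features.tsv`` and ``barcodes.tsv`` (and optionally
        ``cell_meta.tsv``). For ``tsv``: a dense TSV with gene symbols in
        the first column and barcodes in the header.
    cell_meta
        Optional externally supplied per-cell metadata (indexed by
        barcode, with a ``condition`` column). If omitted for an MTX
        triplet, a ``cell_meta.tsv`` next to the matrix is used when
        present; otherwise every cell is labeled ``mono``.
    """
    path = Path(path)
    if format == "mtx_triplet":
        mtx = path / "matrix.mtx"
        feat = path / "features.tsv"
        barc = path / "barcodes.tsv"
        for f in (mtx, feat, barc):
            if not f.exists():
                raise ParseError(f"{f}: file not found")
        genes = _read_id_column(feat, "gene ids")
        cells = _read_id_column(barc, "barcodes")
        try:
            mat = scipy.io.mmread(mtx)
        except Exception as exc:  # pragma: no cover - scipy message passthrough
            raise ParseError(f"{mtx}: {exc}") from exc
        mat = np.asarray(scipy.sparse.coo_matrix(mat).todense())
        if mat.shape != (len(genes), len(cells)):
            raise ParseError(
                f"{mtx}: matrix is {mat.shape[0]} x {mat.shape[1]} but "
                f"features.tsv has {len(genes)} rows and barcodes.tsv "
                f"{len(cells)} rows"
            )
        if not np.allclose(mat, np.round(mat)):
            raise ParseError(f"{mtx}: non-integer entries")
        counts = np.round(mat).astype(np.int64)
        if cell_meta is None:
            meta_path = path / "cell_meta.tsv"
            if meta_path.exists():
                cell_meta = read_cell_meta(meta_path)
            else:
                cell_meta = pd.DataFrame({"condition": "mono"}, index=pd.Index(cells))
    elif format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        if df.index.has_duplicates:
            raise ParseError(f"{path}: duplicate gene ids")
        if df.columns.has_duplicates:
            raise ParseError(f"{path}: duplicate barcodes")
        vals = df.to_numpy()
        if not np.allclose(vals, np.round(vals)):
            raise ParseError(f"{path}: non-integer entries")
        counts = np.round(vals).astype(np.int64)
        genes = df.index.tolist()
        cells = df.columns.tolist()
        if cell_meta is None:
            cell_meta = pd.DataFrame({"condition": "mono"}, index=pd.Index(cells))
    else:
        raise ValueError(f"unknown format {format!r}")
    return CountMatrix(counts, pd.Index(genes), pd.Index(cells), cell_meta)


def write_count_matrix(m: CountMatrix, path: str | Path, format: str = "mtx_triplet"):
    """Write a count matrix as an MTX triplet directory or dense TSV."""
    path = Path(path)
    if format == "mtx_triplet":
        path.mkdir(parents=True, exist_ok=True)
        scipy.io.mmwrite(
            path / "matrix.mtx", scipy.sparse.coo_matrix(m.counts), field="integer"
        )
        (path / "features.tsv").write_text("".join(f"{g}\n" for g in m.gene_ids))
        (path / "barcodes.tsv").write_text("".join(f"{b}\n" for b in m.cell_ids))
        write_cell_meta(m.cell_meta, path / "cell_meta.tsv")
    elif format == "tsv":
        pd.DataFrame(m.counts, index=m.gene_ids, columns=m.cell_ids).to_csv(
            path, sep="\t"
        )
    else:
        raise ValueError(f"unknown format {format!r}")


def read_cell_meta(path: str | Path) -> pd.DataFrame:
    """Read per-cell metadata TSV (columns: barcode, condition[, patient])."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "barcode" not in df.columns or "condition" not in df.columns:
        raise ParseError(f"{path}: need 'barcode' and 'condition' columns")
    return df.set_index("barcode")


def write_cell_meta(meta: pd.DataFrame, path: str | Path) -> None:
    meta.rename_axis("barcode").reset_index().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# ligand-receptor pairs, secreted genes, annotation


def read_lr_pairs(path: str | Path) -> LRPairTable:
    """Read a ligand-receptor pair TSV with ``ligand``/``receptor`` columns."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("ligand", "receptor"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    pairs = list(zip(df["ligand"], df["receptor"]))
    table = LRPairTable(pairs)
    n_dup = len(pairs) - len(table)
    if len(pairs) == 0:
        logger.warning("%s: empty ligand-receptor table", path)
    if n_dup:
        logger.warning("%s: removed %d duplicate pairs", path, n_dup)
    logger.info("%s: loaded %d ligand-receptor pairs", path, len(table))
    return table


def write_lr_pairs(table: LRPairTable, path: str | Path) -> None:
    pd.DataFrame(sorted(table.pairs), columns=["ligand", "receptor"]).to_csv(
        path, sep="\t", index=False
    )


def read_secreted(path: str | Path) -> SecretedSet:
    """Read a secreted-protein gene list TSV (column: ``gene``)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "gene" not in df.columns:
        raise ParseError(f"{path}: missing column 'gene'")
    s = SecretedSet(df["gene"].dropna())
    if len(s) == 0:
        raise ParseError(f"{path}: secreted gene list is empty")
    return s


def write_secreted(s: SecretedSet, path: str | Path) -> None:
    pd.DataFrame({"gene": sorted(s.genes)}).to_csv(path, sep="\t", index=False)


def read_gene_annotation(path: str | Path) -> pd.DataFrame:
    """Read gene annotation TSV (gene, chrom, arm, start; 1-based starts).

    Returns a DataFrame indexed by gene, ordered by (chrom, arm, start).
    """
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "chrom": str, "arm": str})
    need = {"gene", "chrom", "arm", "start"}
    if not need.issubset(df.columns):
        raise ParseError(f"{path}: need columns {sorted(need)}")
    if (df["start"] <= 0).any():
        raise ParseError(f"{path}: gene starts must be positive (1-based)")
    bad = df[~df.apply(lambda r: r["arm"].startswith(str(r["chrom"])), axis=1)]
    if len(bad):
        raise ParseError(
            f"{path}: arm does not match chromosome for genes "
            f"{bad['gene'].tolist()[:5]}"
        )
    return df.set_index("gene").sort_values(["chrom", "arm", "start"], kind="stable")


def write_gene_annotation(ann: pd.DataFrame, path: str | Path) -> None:
    ann.rename_axis("gene").reset_index().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# gene sets (GMT)


def read_gene_sets(path: str | Path, source: str = "") -> GeneSetCollection:
    """Read a GMT file: name <TAB> description <TAB> gene1 <TAB> gene2 ..."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: GMT line has <3 fields")
            name, _desc, *genes = fields
            if name in sets:
                raise ParseError(f"{path}:{lineno}: duplicate gene set {name!r}")
            deduped = list(dict.fromkeys(g for g in genes if g))
            if len(deduped) < len([g for g in genes if g]):
                logger.info("%s:%d: removed duplicate genes in %s", path, lineno, name)
            sets[name] = deduped
    return GeneSetCollection(sets, source=source)


def write_gene_sets(coll: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in coll.sets.items():
            fh.write("\t".join([name, coll.source or "na", *genes]) + "\n")


# ---------------------------------------------------------------------------
# packaged fixtures


def load_table1_fixture() -> list[ReceptorCandidate]:
    """The 15 prioritized receptors with their printed statistics.

    Packaged machine-readable copy of the published receptor table
    (receptor, log2FC, BH-FDR, cognate expressed ligands, number of
    enriched downstream pathways), in printed order.
    """
    with resources.files("pvn.data").joinpath("table1.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    return [
        ReceptorCandidate(
            receptor=row.receptor,
            log2fc=float(row.log2fc),
            fdr=float(row.fdr),
            ligands=tuple(row.ligands.split(",")),
            n_enriched_pathways=int(row.n_enriched_pathways),
        )
        for row in df.itertuples()
    ]


def write_candidates(cands: list[ReceptorCandidate], path: str | Path) -> None:
    """Serialize receptor candidates with the published column layout."""
    pd.DataFrame(
        {
            "receptor": [c.receptor for c in cands],
            "log2fc": [c.log2fc for c in cands],
            "fdr": [c.fdr for c in cands],
            "ligands": [",".join(c.ligands) for c in cands],
            "n_enriched_pathways": [c.n_enriched_pathways for c in cands],
        }
    ).to_csv(path, sep="\t", index=False)


def read_candidates(path: str | Path) -> list[ReceptorCandidate]:
    df = pd.read_csv(path, sep="\t")
    return [
        ReceptorCandidate(
            r.receptor,
            float(r.log2fc),
            float(r.fdr),
            tuple(str(r.ligands).split(",")),
            int(r.n_enriched_pathways),
        )
        for r in df.itertuples()
    ]


def write_annotation(ann: CellAnnotation, path: str | Path) -> None:
    ann.to_frame().rename_axis("barcode").reset_index().to_csv(
        path, sep="\t", index=False
    )


def read_annotation(path: str | Path) -> CellAnnotation:
    df = pd.read_csv(path, sep="\t", dtype={"barcode": str, "label": str})
    return CellAnnotation(
        pd.Index(df["barcode"]), df["cluster"].to_numpy(), df["label"].to_numpy()
    )
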