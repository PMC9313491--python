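"""End-to-end orchestration: qc -> cluster/annotate -> CNV -> DE -> cascade.

The pipeline consumes a fixture-bundle directory (``mono/`` and ``tri/``
count-matrix triplets plus the ligand-receptor, secretome, pathway and
gene-annotation tables) and emits plain TSV/JSON artifacts:
``candidates.tsv`` (published-table column layout), ``stage_counts.json``,
``cnv_calls.tsv``, ``ligand_flags.tsv``, ``enrichment.tsv`` and
per-condition annotations. Individual stages can be re-run from cached
artifacts.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cascade as cascade_mod
from . import cnv as cnv_mod
from . import de as de_mod
from . import io as io_mod
from . import qc as qc_mod
from .containers import CellAnnotation, ExpressionMatrix

logger = logging.getLogger(__name__)

STAGES = ("qc", "cluster", "cnv", "de", "cascade")


class StageError(RuntimeError):
    """A pipeline stage failed or its prerequisites are missing."""


@dataclass
class PipelineConfig:
    """All tunable thresholds of the analysis, with published defaults."""

    bundle_dir: str = "."
    out_dir: str = "pvn_out"
    # QC
    min_cells: int = 3
    min_genes: int = 200
    max_mito: float = 0.18
    # normalization / clustering
    target_sum: float = 1e4
    n_hvg: int = 4000
    n_pcs: int = 50
    k_neighbors: int = 15
    resolution: float = 1.0
    # DE thresholds
    lfc_cascade: float = 0.3
    lfc_strict: float = 1.0
    fdr_max: float = 0.05
    # cascade
    min_ligand_frac: float = 0.10
    enrich_p: float = 0.05
    top_k: int = 6
    # CNV
    cnv_window: int = 101
    cnv_clip: float = 3.0
    cnv_gain_thresh: float = 0.1
    cnv_loss_thresh: float = -0.1
    target_arms: tuple = ("17q", "4q")
    # patient evidence
    evidence_min_cells: int = 113
    seed: int = 0

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["target_arms"] = list(d["target_arms"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "target_arms" in d:
            d["target_arms"] = tuple(d["target_arms"])
        return cls(**d)


@dataclass
class PipelineResult:
    report: cascade_mod.CascadeReport
    de_gsc: pd.DataFrame
    cnv_calls: pd.DataFrame
    ann_mono: CellAnnotation
    ann_tri: CellAnnotation
    e_mono: ExpressionMatrix
    e_tri: ExpressionMatrix


def _cache(cfg: PipelineConfig) -> Path:
    return Path(cfg.out_dir) / "cache"


def _process_condition(cfg: PipelineConfig, m):
    filtered, _report = qc_mod.qc_filter(
        m, min_cells=cfg.min_cells, min_genes=cfg.min_genes, max_mito=cfg.max_mito
    )
    e = qc_mod.normalize_log(filtered, target_sum=cfg.target_sum)
    e = qc_mod.select_hvg(e, n_top=cfg.n_hvg)
    clusters = qc_mod.cluster_snn(
        e,
        n_pcs=cfg.n_pcs,
        k_neighbors=cfg.k_neighbors,
        resolution=cfg.resolution,
        seed=cfg.seed,
    )
    ann = qc_mod.annotate_clusters(e, clusters)
    return filtered, e, ann


def _load_bundle(cfg: PipelineConfig):
    bundle = Path(cfg.bundle_dir)
    mono = io_mod.read_count_matrix(bundle / "mono")
    tri = io_mod.read_count_matrix(bundle / "tri")
    lr = io_mod.read_lr_pairs(bundle / "lr_pairs.tsv")
    secreted = io_mod.read_secreted(bundle / "secreted.tsv")
    gmt = io_mod.read_gene_sets(bundle / "pathways.gmt")
    gene_ann = io_mod.read_gene_annotation(bundle / "gene_annotation.tsv")
    return mono, tri, lr, secreted, gmt, gene_ann


def run_pipeline(cfg: PipelineConfig, write_outputs: bool = True) -> PipelineResult:
    """Run the full analysis on an on-disk fixture bundle."""
    try:
        inputs = _load_bundle(cfg)
    except Exception as exc:
        raise StageError(f"input: {exc}") from exc
    result = run_pipeline_objects(cfg, *inputs)
    if write_outputs:
        _write_outputs(cfg, result)
    return result


def run_pipeline_objects(
    cfg: PipelineConfig, mono, tri, lr, secreted, gmt, gene_ann
) -> PipelineResult:
    """Run the full analysis on in-memory inputs (no file I/O)."""
    try:
        mono_f, e_mono, ann_mono = _process_condition(cfg, mono)
        tri_f, e_tri, ann_tri = _process_condition(cfg, tri)
    except Exception as exc:
        raise StageError(f"qc/cluster: {exc}") from exc

    # CNV verification on the triculture condition (reference: EC + astrocyte)
    try:
        ref_cells = ann_tri.cell_ids[
            np.isin(ann_tri.label, ["EC", "astrocyte"])
        ]
        profile = cnv_mod.infer_cnv_profile(
            e_tri, gene_ann, ref_cells, window=cfg.cnv_window, clip=cfg.cnv_clip
        )
        cnv_calls = cnv_mod.call_arm_events(
            profile, ann_tri, cfg.cnv_gain_thresh, cfg.cnv_loss_thresh
        )
    except Exception as exc:
        raise StageError(f"cnv: {exc}") from exc

    try:
        a_tri, a_mono = de_mod.align_conditions(e_tri, e_mono)
        gsc_tri = ann_tri.cells_of_type("GSC")
        gsc_mono = ann_mono.cells_of_type("GSC")
        if len(gsc_tri) == 0 or len(gsc_mono) == 0:
            raise ValueError("no GSC cluster identified in one of the conditions")
        de_gsc = de_mod.differential_expression(
            a_tri.values[:, a_tri.cell_ids.isin(gsc_tri)],
            a_mono.values[:, a_mono.cell_ids.isin(gsc_mono)],
            a_tri.gene_ids,
        )
    except StageError:
        raise
    except Exception as exc:
        raise StageError(f"de: {exc}") from exc

    try:
        universe = set(a_tri.gene_ids)
        report = cascade_mod.run_cascade(
            de_gsc, lr, secreted, gmt, e_tri, ann_tri, universe,
            lfc_cascade=cfg.lfc_cascade, lfc_strict=cfg.lfc_strict,
            fdr_max=cfg.fdr_max, min_frac=cfg.min_ligand_frac,
            enrich_p=cfg.enrich_p, top_k=cfg.top_k,
        )
        tested_ligands = sorted({l for c in report.candidates for l in c.ligands})
        report.ligand_flags = cascade_mod.ligand_upregulation_flags(
            e_mono, e_tri, ann_mono, ann_tri, tested_ligands, fdr_max=cfg.fdr_max
        )
    except Exception as exc:
        raise StageError(f"cascade: {exc}") from exc

    return PipelineResult(report, de_gsc, cnv_calls, ann_mono, ann_tri, e_mono, e_tri)


def _write_outputs(cfg: PipelineConfig, res: PipelineResult) -> None:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    io_mod.write_candidates(res.report.candidates, out / "candidates.tsv")
    (out / "stage_counts.json").write_text(
        json.dumps(res.report.stage_counts(), indent=2)
    )
    res.cnv_calls.to_csv(out / "cnv_calls.tsv", sep="\t", index=False)
    if res.report.ligand_flags is not None:
        res.report.ligand_flags.to_csv(out / "ligand_flags.tsv", sep="\t", index=False)
    enrich_rows = [
        {"receptor": r, "pathway": e.pathway, "k": e.k, "K": e.K,
         "n": e.n, "N": e.N, "p": e.p}
        for r, results in res.report.enrichments.items()
        for e in results
    ]
    pd.DataFrame(
        enrich_rows, columns=["receptor", "pathway", "k", "K", "n", "N", "p"]
    ).to_csv(out / "enrichment.tsv", sep="\t", index=False)
    io_mod.write_annotation(res.ann_mono, out / "annotation_mono.tsv")
    io_mod.write_annotation(res.ann_tri, out / "annotation_tri.tsv")
    res.de_gsc.rename_axis("gene").reset_index().to_csv(
        out / "de_gsc.tsv", sep="\t", index=False
    )
    params = dataclasses.asdict(cfg)
    params["target_arms"] = list(params["target_arms"])
    (out / "params.json").write_text(json.dumps(params, indent=2))


# ---------------------------------------------------------------------------
# stage-wise execution with on-disk caching


def _require(path: Path, producer: str) -> Path:
    if not path.exists():
        raise StageError(
            f"missing artifact {path.name}; run stage {producer!r} first"
        )
    return path


def run_stage(name: str, cfg: PipelineConfig):
    """Run one pipeline stage from cached upstream artifacts."""
    if name not in STAGES:
        raise StageError(f"unknown stage {name!r}; choose from {STAGES}")
    cache = _cache(cfg)
    cache.mkdir(parents=True, exist_ok=True)

    if name == "qc":
        mono, tri, *_ = _load_bundle(cfg)
        for cond, m in (("mono", mono), ("tri", tri)):
            filtered, _ = qc_mod.qc_filter(
                m, cfg.min_cells, cfg.min_genes, cfg.max_mito
            )
            io_mod.write_count_matrix(filtered, cache / f"qc_{cond}")
        return cache

    if name == "cluster":
        anns = {}
        for cond in ("mono", "tri"):
            m = io_mod.read_count_matrix(_require(cache / f"qc_{cond}", "qc"))
            e = qc_mod.normalize_log(m, target_sum=cfg.target_sum)
            e = qc_mod.select_hvg(e, n_top=cfg.n_hvg)
            clusters = qc_mod.cluster_snn(
                e, cfg.n_pcs, cfg.k_neighbors, cfg.resolution, cfg.seed
            )
            ann = qc_mod.annotate_clusters(e, clusters)
            io_mod.write_annotation(ann, cache / f"annotation_{cond}.tsv")
            anns[cond] = ann
        return anns

    if name == "cnv":
        *_, gene_ann = _load_bundle(cfg)
        m = io_mod.read_count_matrix(_require(cache / "qc_tri", "qc"))
        ann = io_mod.read_annotation(_require(cache / "annotation_tri.tsv", "cluster"))
        e = qc_mod.normalize_log(m, target_sum=cfg.target_sum)
        ref = ann.cell_ids[np.isin(ann.label, ["EC", "astrocyte"])]
        profile = cnv_mod.infer_cnv_profile(
            e, gene_ann, ref, window=cfg.cnv_window, clip=cfg.cnv_clip
        )
        calls = cnv_mod.call_arm_events(
            profile, ann, cfg.cnv_gain_thresh, cfg.cnv_loss_thresh
        )
        calls.to_csv(cache / "cnv_calls.tsv", sep="\t", index=False)
        return calls

    if name == "de":
        mats, anns = {}, {}
        for cond in ("mono", "tri"):
            m = io_mod.read_count_matrix(_require(cache / f"qc_{cond}", "qc"))
            mats[cond] = qc_mod.normalize_log(m, target_sum=cfg.target_sum)
            anns[cond] = io_mod.read_annotation(
                _require(cache / f"annotation_{cond}.tsv", "cluster")
            )
        a_tri, a_mono = de_mod.align_conditions(mats["tri"], mats["mono"])
        de_gsc = de_mod.differential_expression(
            a_tri.values[:, a_tri.cell_ids.isin(anns["tri"].cells_of_type("GSC"))],
            a_mono.values[:, a_mono.cell_ids.isin(anns["mono"].cells_of_type("GSC"))],
            a_tri.gene_ids,
        )
        de_gsc.rename_axis("gene").reset_index().to_csv(
            cache / "de_gsc.tsv", sep="\t", index=False
        )
        return de_gsc

    # cascade
    bundle = Path(cfg.bundle_dir)
    lr = io_mod.read_lr_pairs(bundle / "lr_pairs.tsv")
    secreted = io_mod.read_secreted(bundle / "secreted.tsv")
    gmt = io_mod.read_gene_sets(bundle / "pathways.gmt")
    m_tri = io_mod.read_count_matrix(_require(cache / "qc_tri", "qc"))
    m_mono = io_mod.read_count_matrix(_require(cache / "qc_mono", "qc"))
    ann_tri = io_mod.read_annotation(_require(cache / "annotation_tri.tsv", "cluster"))
    de_path = _require(cache / "de_gsc.tsv", "de")
    de_gsc = pd.read_csv(de_path, sep="\t", index_col="gene")
    e_tri = qc_mod.normalize_log(m_tri, target_sum=cfg.target_sum)
    e_mono = qc_mod.normalize_log(m_mono, target_sum=cfg.target_sum)
    universe = set(e_tri.gene_ids) & set(e_mono.gene_ids)
    report = cascade_mod.run_cascade(
        de_gsc, lr, secreted, gmt, e_tri, ann_tri, universe,
        lfc_cascade=cfg.lfc_cascade, lfc_strict=cfg.lfc_strict,
        fdr_max=cfg.fdr_max, min_frac=cfg.min_ligand_frac,
        enrich_p=cfg.enrich_p, top_k=cfg.top_k,
    )
    io_mod.write_candidates(report.candidates, cache / "candidates.tsv")
    return report
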