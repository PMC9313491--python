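"""Synthetic monoculture/triculture experiments with known ground truth.

The generator emulates the study design the pipeline targets: three cell
types (endothelial cells, astrocytes, glioma stem cells) profiled in a
pooled monoculture and a triculture condition, with

* canonical marker genes (PECAM1 -> EC, S100B -> astrocyte,
  CDKN2A -> GSC) boosted in their own type,
* per-type background signature programs so the types are separable by
  clustering,
* a GSC-specific chromosome 17q gain and 4q loss applied in both
  conditions (the cell line's constitutive CNVs),
* planted ligand-receptor effects: each planted receptor's GSC mean is
  raised in triculture to a configured log2 fold change (together with a
  downstream response program of co-upregulated genes), and its ligand
  is expressed in a configured fraction of the source cell type's
  triculture cells only.

Counts are negative binomial: for cell j and gene g,
mean = library_size_j * weight(g, type, condition) / sum_g weight, with
a dispersion shared across genes (var = mu + mu^2 / dispersion).
Library sizes are log-normal. Everything is driven by one seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as io_mod
from .containers import (
    CountMatrix,
    GeneSetCollection,
    LRPairTable,
    SecretedSet,
)

MARKERS = {"EC": "PECAM1", "astrocyte": "S100B", "GSC": "CDKN2A"}
MITO_GENES = ("MT-CO1", "MT-CO2", "MT-ND1", "MT-ND2", "MT-CYB")
ARM_NAMES = ("1p", "1q", "2p", "2q", "3p", "3q", "4q", "5p", "5q", "17q")
CELL_TYPES = ("EC", "astrocyte", "GSC")


@dataclass(frozen=True)
class PlantedPair:
    """One planted ligand-receptor interaction.

    ``receptor_log2fc`` is the targeted triculture-vs-monoculture log2
    fold change of the receptor in GSCs; ``ligand_fraction`` the
    fraction of triculture source-type cells expressing the ligand.
    Each nonzero planted receptor also drags along ``n_response_genes``
    downstream genes upregulated at ``response_log2fc`` in triculture
    GSCs, emulating pathway activation.
    """

    ligand: str
    receptor: str
    source: str  # "EC" or "astrocyte"
    receptor_log2fc: float
    ligand_fraction: float
    n_response_genes: int = 15
    response_log2fc: float = 1.5


DEFAULT_PAIRS = (
    PlantedPair("PDGFA", "PDGFRA", "astrocyte", 2.5, 0.50),
    PlantedPair("SAA1", "FPR1", "EC", 2.0, 0.40),
    PlantedPair("RSPO3", "LGR6", "astrocyte", 2.2, 0.30),
    PlantedPair("IL6", "IL6R", "astrocyte", 1.6, 0.35),
    PlantedPair("APOE", "LDLR", "EC", 1.3, 0.45),
)

#: extra network pairs whose receptors receive no planted effect
DECOY_PAIRS = (
    ("FGF5", "FGFR4"),
    ("TFPI", "F3"),
    ("PSAP", "CELSR1"),
    ("GNAS", "VIPR1"),
    ("THBS1", "SCARB1"),
)


@dataclass
class SimConfig:
    """Study-condition parameters for the synthetic experiment."""

    n_cells_tri: dict = field(
        default_factory=lambda: {"EC": 1221, "astrocyte": 477, "GSC": 217}
    )
    n_cells_mono: dict = field(
        default_factory=lambda: {"EC": 1345, "astrocyte": 281, "GSC": 483}
    )
    n_genes: int = 2000
    lib_log_mean: float = float(np.log(2500.0))
    lib_log_sigma: float = 0.35
    nb_dispersion: float = 10.0
    marker_boost: float = 8.0
    signature_boost: float = 3.0
    n_signature_genes: int = 60
    cnv_gain: float = 1.5  # 17q in GSC
    cnv_loss: float = 0.5  # 4q in GSC
    ligand_weight: float = 10.0
    mito_weight: float = 25.0
    planted_pairs: tuple = DEFAULT_PAIRS
    seed: int = 0

    def __post_init__(self) -> None:
        for f in (self.marker_boost, self.signature_boost, self.cnv_gain,
                  self.cnv_loss, self.nb_dispersion, self.ligand_weight):
            if f <= 0:
                raise ValueError("all factors must be > 0")
        for p in self.planted_pairs:
            if not 0.0 <= p.ligand_fraction <= 1.0:
                raise ValueError("ligand fractions must lie in [0, 1]")
            if p.source not in ("EC", "astrocyte"):
                raise ValueError(f"planted ligand source must be EC or astrocyte, got {p.source}")


def null_config(seed: int = 0, **kwargs) -> SimConfig:
    """A configuration with all planted ligand-receptor effects zeroed."""
    pairs = tuple(
        PlantedPair(p.ligand, p.receptor, p.source, 0.0, p.ligand_fraction,
                    p.n_response_genes, 0.0)
        for p in DEFAULT_PAIRS
    )
    return SimConfig(planted_pairs=pairs, seed=seed, **kwargs)


@dataclass
class GroundTruth:
    """Generating parameters needed to score downstream recovery."""

    cell_types_mono: np.ndarray
    cell_types_tri: np.ndarray
    gene_ids: pd.Index
    annotation: pd.DataFrame  # gene -> chrom, arm, start
    weights: dict  # (condition, type) -> per-gene weight vector
    planted_pairs: tuple
    response_genes: dict  # receptor -> list of response gene names
    cnv_arms: dict  # arm -> factor applied to GSC
    signature_genes: dict  # type -> list of signature gene names

    def proportions(self, condition: str) -> dict:
        arr = self.cell_types_tri if condition == "tri" else self.cell_types_mono
        vals, counts = np.unique(arr, return_counts=True)
        return dict(zip(vals.tolist(), counts.tolist()))


def _build_gene_universe(cfg: SimConfig, rng: np.random.Generator):
    """Gene names, genomic annotation and per-(type, condition) weights."""
    special: list[str] = list(MARKERS.values())
    response_genes: dict[str, list[str]] = {}
    for p in cfg.planted_pairs:
        special.extend([p.ligand, p.receptor])
        response_genes[p.receptor] = [
            f"RESP-{p.receptor}-{i + 1:02d}" for i in range(p.n_response_genes)
        ]
        special.extend(response_genes[p.receptor])
    special.extend(l for l, r in DECOY_PAIRS)
    special.extend(r for l, r in DECOY_PAIRS)
    special = list(dict.fromkeys(special))
    n_filler = cfg.n_genes - len(special) - len(MITO_GENES)
    if n_filler < 0:
        raise ValueError("n_genes too small for the planted gene set")
    filler = [f"G{i + 1:04d}" for i in range(n_filler)]
    nuclear = special + filler

    # contiguous arm blocks; special genes kept off the CNV arms so planted
    # DE effects and CNV dosage never overlap
    n_nuclear = len(nuclear)
    block = n_nuclear // len(ARM_NAMES)
    sizes = [block] * len(ARM_NAMES)
    sizes[-1] += n_nuclear - block * len(ARM_NAMES)
    cnv_free_arms = [a for a in ARM_NAMES if a not in ("17q", "4q")]
    order: list[str] = []
    pool = list(filler)
    rng.shuffle(pool)
    placements: dict[str, list[str]] = {a: [] for a in ARM_NAMES}
    # round-robin the special genes over CNV-free arms
    for i, g in enumerate(special):
        placements[cnv_free_arms[i % len(cnv_free_arms)]].append(g)
    for arm, size in zip(ARM_NAMES, sizes):
        need = size - len(placements[arm])
        placements[arm].extend(pool[:need])
        pool = pool[need:]
    rows = []
    for arm, size in zip(ARM_NAMES, sizes):
        genes_on_arm = placements[arm]
        chrom = arm.rstrip("pq")
        for j, g in enumerate(genes_on_arm):
            rows.append({"gene": g, "chrom": chrom, "arm": arm,
                         "start": (j + 1) * 10_000})
            order.append(g)
    for j, g in enumerate(MITO_GENES):
        rows.append({"gene": g, "chrom": "MT", "arm": "MT",
                     "start": (j + 1) * 1_000})
        order.append(g)
    ann = pd.DataFrame(rows).set_index("gene")
    gene_ids = pd.Index(order)
    return gene_ids, ann, response_genes


def _base_weights(cfg: SimConfig, gene_ids: pd.Index, rng: np.random.Generator):
    w = rng.gamma(shape=2.0, scale=0.5, size=len(gene_ids))  # mean 1.0
    w = np.maximum(w, 0.02)
    s = pd.Series(w, index=gene_ids)
    for g in MITO_GENES:
        s[g] = cfg.mito_weight
    for marker in MARKERS.values():
        s[marker] = 0.25
    for p in cfg.planted_pairs:
        s[p.ligand] = 0.0  # expressed only where planted
        s[p.receptor] = 1.0
    for l, _r in DECOY_PAIRS:
        s[l] = 0.0
    return s


def _type_weights(cfg: SimConfig, base: pd.Series, gt_signatures: dict,
                  condition: str, response_genes: dict) -> dict:
    """Per-gene weight vector for every cell type in one condition."""
    out = {}
    for ct in CELL_TYPES:
        w = base.copy()
        w[MARKERS[ct]] *= cfg.marker_boost
        for g in gt_signatures[ct]:
            w[g] *= cfg.signature_boost
        out[ct] = w
    if condition == "tri":
        for p in cfg.planted_pairs:
            if p.receptor_log2fc != 0.0:
                out["GSC"][p.receptor] *= 2.0 ** p.receptor_log2fc
            if p.response_log2fc != 0.0:
                for g in response_genes[p.receptor]:
                    out["GSC"][g] *= 2.0 ** p.response_log2fc
    return out


def _sample_block(
    rng: np.random.Generator,
    weights: np.ndarray,
    lib_sizes: np.ndarray,
    dispersion: float,
    ligand_indicator: dict[int, np.ndarray] | None = None,
) -> np.ndarray:
    """NB counts for one (type, condition) block: genes x cells."""
    mu = np.outer(weights / weights.sum(), lib_sizes)
    if ligand_indicator:
        for row, indicator in ligand_indicator.items():
            mu[row] = mu[row] * indicator
    theta = dispersion
    p = theta / (theta + mu)
    return rng.negative_binomial(theta, p)


def generate_experiment(cfg: SimConfig) -> tuple[CountMatrix, CountMatrix, GroundTruth]:
    """Generate (monoculture, triculture, ground truth) for one seed."""
    rng = np.random.default_rng(cfg.seed)
    gene_ids, ann, response_genes = _build_gene_universe(cfg, rng)
    base = _base_weights(cfg, gene_ids, rng)

    # Per-type signature programs drawn from filler genes in genomic order,
    # interleaved EC/astrocyte/GSC at adjacent positions so that type-specific
    # expression differences largely cancel inside CNV smoothing windows.
    filler = [g for g in gene_ids if g.startswith("G")]
    sig: dict[str, list[str]] = {ct: [] for ct in CELL_TYPES}
    stride = max(len(filler) // max(cfg.n_signature_genes, 1), 3)
    for j in range(cfg.n_signature_genes):
        loc = j * stride
        if loc + len(CELL_TYPES) > len(filler):
            break
        for k, ct in enumerate(CELL_TYPES):
            sig[ct].append(filler[loc + k])

    cnv_arms = {"17q": cfg.cnv_gain, "4q": cfg.cnv_loss}
    arm_of = ann["arm"].reindex(gene_ids)
    cnv_factor = np.ones(len(gene_ids))
    for arm, factor in cnv_arms.items():
        cnv_factor[(arm_of == arm).to_numpy()] = factor

    weights_store: dict = {}
    matrices: dict[str, CountMatrix] = {}
    truths: dict[str, np.ndarray] = {}
    for condition, counts_per_type in (
        ("mono", cfg.n_cells_mono),
        ("tri", cfg.n_cells_tri),
    ):
        tw = _type_weights(cfg, base, sig, condition, response_genes)
        blocks, types, barcodes = [], [], []
        for ct in CELL_TYPES:
            n = int(counts_per_type.get(ct, 0))
            if n == 0:
                continue
            w = tw[ct].to_numpy().copy()
            if ct == "GSC":
                w = w * cnv_factor
            lib = rng.lognormal(cfg.lib_log_mean, cfg.lib_log_sigma, size=n)
            ligand_indicator = None
            if condition == "tri":
                ligand_indicator = {}
                for p in cfg.planted_pairs:
                    if p.source == ct and p.ligand_fraction > 0:
                        row = gene_ids.get_loc(p.ligand)
                        w[row] = cfg.ligand_weight
                        ligand_indicator[row] = (
                            rng.random(n) < p.ligand_fraction
                        ).astype(float)
            blocks.append(
                _sample_block(rng, w, lib, cfg.nb_dispersion, ligand_indicator)
            )
            types.extend([ct] * n)
            barcodes.extend(
                f"{condition}-{ct}-{i + 1:04d}" for i in range(n)
            )
            weights_store[(condition, ct)] = w
        counts = np.concatenate(blocks, axis=1).astype(np.int64)
        meta = pd.DataFrame({"condition": condition}, index=pd.Index(barcodes))
        matrices[condition] = CountMatrix(counts, gene_ids, pd.Index(barcodes), meta)
        truths[condition] = np.array(types, dtype=object)

    gt = GroundTruth(
        cell_types_mono=truths["mono"],
        cell_types_tri=truths["tri"],
        gene_ids=gene_ids,
        annotation=ann,
        weights=weights_store,
        planted_pairs=cfg.planted_pairs,
        response_genes=response_genes,
        cnv_arms=cnv_arms,
        signature_genes=sig,
    )
    return matrices["mono"], matrices["tri"], gt


# ---------------------------------------------------------------------------
# fixture bundle


def reference_tables(cfg: SimConfig, gt: GroundTruth):
    """The ligand-receptor network, secretome and pathway fixtures that
    accompany a simulated experiment."""
    pairs = [(p.ligand, p.receptor) for p in cfg.planted_pairs] + list(DECOY_PAIRS)
    lr = LRPairTable(pairs)
    secreted = SecretedSet(
        [p.ligand for p in cfg.planted_pairs] + [l for l, _ in DECOY_PAIRS]
    )
    rng = np.random.default_rng(cfg.seed + 1)
    filler = [g for g in gt.gene_ids if g.startswith("G")]
    sets: dict[str, list[str]] = {}
    for p in cfg.planted_pairs:
        downstream = gt.response_genes[p.receptor]
        extra = list(rng.choice(filler, size=5, replace=False))
        sets[f"PW_{p.receptor}_RESPONSE"] = [p.receptor] + downstream + extra
        decoy_members = [p.receptor] + list(rng.choice(filler, size=20, replace=False))
        sets[f"PW_{p.receptor}_HOUSEKEEPING"] = decoy_members
    for i in range(5):
        sets[f"PW_BACKGROUND_{i + 1}"] = list(
            rng.choice(filler, size=25, replace=False)
        )
    gmt = GeneSetCollection(sets, source="SYNTH")
    return lr, secreted, gmt


def write_fixture_bundle(out_dir: str | Path, cfg: SimConfig) -> dict:
    """Generate an experiment and write every input file the pipeline needs.

    Layout: ``mono/`` and ``tri/`` MTX triplets (+ cell_meta.tsv),
    ``lr_pairs.tsv``, ``secreted.tsv``, ``pathways.gmt``,
    ``gene_annotation.tsv`` and ``manifest.json`` recording ground truth.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    mono, tri, gt = generate_experiment(cfg)
    lr, secreted, gmt = reference_tables(cfg, gt)
    io_mod.write_count_matrix(mono, out_dir / "mono")
    io_mod.write_count_matrix(tri, out_dir / "tri")
    io_mod.write_lr_pairs(lr, out_dir / "lr_pairs.tsv")
    io_mod.write_secreted(secreted, out_dir / "secreted.tsv")
    io_mod.write_gene_sets(gmt, out_dir / "pathways.gmt")
    io_mod.write_gene_annotation(gt.annotation, out_dir / "gene_annotation.tsv")
    pd.DataFrame(
        {"barcode": list(mono.cell_ids) + list(tri.cell_ids),
         "true_type": list(gt.cell_types_mono) + list(gt.cell_types_tri)}
    ).to_csv(out_dir / "true_types.tsv", sep="\t", index=False)
    manifest = {
        "seed": cfg.seed,
        "n_genes": cfg.n_genes,
        "n_pairs": len(lr),
        "files": {
            "mono": "mono",
            "tri": "tri",
            "lr_pairs": "lr_pairs.tsv",
            "secreted": "secreted.tsv",
            "pathways": "pathways.gmt",
            "gene_annotation": "gene_annotation.tsv",
            "true_types": "true_types.tsv",
        },
        "planted_pairs": [asdict(p) for p in cfg.planted_pairs],
        "cnv_arms": gt.cnv_arms,
        "cell_counts": {"mono": gt.proportions("mono"), "tri": gt.proportions("tri")},
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


# ---------------------------------------------------------------------------
# synthetic patient tumors


def generate_patient_tumor(
    seed: int,
    receptors: dict[str, float],
    n_neoplastic: int = 300,
    n_immune: int = 80,
    n_genes: int = 400,
    dispersion: float = 10.0,
) -> CountMatrix:
    """A synthetic patient tumor with a neoplastic and an immune cluster.

    ``receptors`` maps receptor symbols to relative weights in the
    neoplastic cells (0 = not expressed); immune cells overexpress CD14
    and AIF1 eight-fold, so the neoplastic-enrichment step can remove
    them. Gene universe: the receptors, the exclusion markers, and
    filler genes.
    """
    rng = np.random.default_rng(seed)
    exclusion = ["MBP", "PLP1", "CD14", "AIF1", "ETNPPL"]
    filler = [f"PG{i + 1:04d}" for i in range(n_genes - len(receptors) - len(exclusion))]
    gene_ids = pd.Index(list(receptors) + exclusion + filler)
    base = np.maximum(rng.gamma(2.0, 0.5, size=len(gene_ids)), 0.02)
    w_neo = base.copy()
    w_imm = base.copy()
    for i, (r, weight) in enumerate(receptors.items()):
        w_neo[i] = weight
        w_imm[i] = 0.0
    for marker in ("CD14", "AIF1"):
        w_imm[gene_ids.get_loc(marker)] *= 8.0
        w_neo[gene_ids.get_loc(marker)] *= 0.05
    blocks, barcodes = [], []
    for name, w, n in (("neo", w_neo, n_neoplastic), ("imm", w_imm, n_immune)):
        if n == 0:
            continue
        lib = rng.lognormal(np.log(1500.0), 0.3, size=n)
        blocks.append(_sample_block(rng, w, lib, dispersion))
        barcodes.extend(f"{name}-{i + 1:04d}" for i in range(n))
    counts = np.concatenate(blocks, axis=1).astype(np.int64)
    meta = pd.DataFrame({"condition": "mono"}, index=pd.Index(barcodes))
    return CountMatrix(counts, gene_ids, pd.Index(barcodes), meta)
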