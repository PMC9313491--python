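# Methods

This note documents the models, defaults and design choices behind
`pvn`, and what the synthetic experiments do and do not establish.

## Data model

Counts are held as dense genes × cells integer matrices
(`CountMatrix`) with per-cell condition labels (`mono`/`tri`). Gene
identity is by symbol, case-sensitive, with no alias resolution: alias
maps are database-version-dependent, and every rule in the pipeline
(markers, ligand–receptor pairs, pathway membership) is stated on
symbols. Mitochondrial genes are recognized by the `MT-` prefix.
Genomic annotation is 1-based gene starts with chromosome-arm labels;
genes are ordered by (chromosome, arm, start).

## Quality control and normalization

Cells are filtered before genes: a cell needs ≥ 200 detected genes and
≤ 18 % mitochondrial counts (strictly greater than 18 % is removed);
genes must then be detected in ≥ 3 of the *retained* cells, since gene
prevalence depends on the surviving cell set. The filter is idempotent.

Normalization scales each cell to a common target sum (default 10⁴)
and applies log1p. Two copies then exist:

* the **analysis matrix** (plain log-normalized values) used for
  differential expression and fraction-expressing computations;
* a **PCA matrix** in which each gene is linearly regressed on per-cell
  total UMIs and mitochondrial fraction and replaced by unit-variance
  residuals. Rank-based tests and expression-fraction filters need
  untransformed values, so the regressed copy never feeds them.

## Highly variable genes

Per gene, dispersion = variance/mean of the de-logged normalized
values; dispersions are normalized by the median of their
mean-expression bin (20 equal-count bins) and the top 4000 genes are
kept. A bin-median ratio was chosen over within-bin z-scoring because
z-scores explode when a bin is nearly homogeneous (tiny standard
deviation amplifies noise); the ratio preserves ranking by excess
dispersion and is deterministic. Genes with (numerically) zero variance
are never selected ahead of any variable gene.

## Clustering and annotation

PCA (50 components, randomized SVD with fixed seed) on the HVG subset
of the regressed matrix; k-nearest-neighbor graph (k = 15, Euclidean);
shared-nearest-neighbor edge weights by Jaccard overlap of (self-
inclusive) neighbor sets, pruned below 1/15; Leiden modularity
optimization at resolution 1.0. All stochastic steps take one seed, so
labels are reproducible.

Clusters are labeled by canonical markers (PECAM1 → EC, S100B →
astrocyte, CDKN2A → GSC): a cluster takes the label of the marker with
the highest mean expression provided that marker's in-cluster mean
exceeds its mean elsewhere *and* ≥ 50 % of the cluster's cells express
it; otherwise the cluster is `unknown`. When several clusters qualify
for one label, the cluster with the highest expressing fraction keeps
it and the rest become `unknown`. At resolution 1.0 Leiden sometimes
splits the large EC population into two pure sub-clusters; the
one-cluster-per-label rule then sends the smaller one to `unknown`, and
overall cell-type recovery on synthetic data ranges from ~94 % to 100 %
across seeds (≥ 95 % at the default seed). Down-weighting resolution
removes the effect but 1.0 is kept as the conventional default;
`unknown` cells are excluded downstream, which is also how the small
unassignable cluster in real data is handled.

## Copy-number scoring

Malignant identity is verified from expression alone, in the style of
reference-anchored CNV inference: per gene, relative expression =
log-normalized value minus the mean over reference cells (cells
annotated EC or astrocyte, which carry no CNVs); values are clipped to
±3 and smoothed by a centered moving average over 101 genes within each
arm (never across arm boundaries; arms shorter than the window use the
whole arm, and edge windows shrink). Arm calls per cell type use the
mean window score: gain above +0.1, loss below −0.1. The defaults
(window 101, clip 3, thresholds ±0.1) are conventional desk-scale
choices; all are configurable. Scores are invariant to adding a
constant to a gene (centering removes it), and wider windows strictly
reduce null-score variance.

## Differential expression

The per-gene test is the two-sided Wilcoxon rank-sum. For small
tie-free samples (min group size ≤ 8) the exact permutation null is
used; otherwise the normal approximation with midrank tie correction
and no continuity correction, so identical samples give exactly p = 1.
The gene-wise vectorized path implements the same asymptotic formula.
BH-FDR is the step-up q(i) = min over j ≥ i of p(j)·m/j, capped at 1.

log2 fold change is computed on de-logged normalized group means with a
pseudocount of 1e-9 (configurable); the pseudocount only affects genes
whose means are both near zero, and makes the all-zero case exactly 0.
Two gene lists feed the cascade: the entry list at log2FC ≥ 0.3 and the
enrichment list at log2FC ≥ 1.0, both at FDR ≤ 0.05, all thresholds
inclusive.

## The cascade

Stage 2 requires a cognate ligand that is (a) in the secreted-protein
list and (b) expressed (value > 0) in ≥ 10 % of triculture EC cells or
of triculture astrocytes. Autocrine expression (the ligand in GSCs
themselves) never satisfies the filter, though fractions are reported.

Stage 3 operationalizes "pathways downstream of the receptor" as
pathways whose member list contains the receptor symbol. Each such
pathway is tested by the hypergeometric upper tail P(X ≥ k) on the
overlap between (pathway ∩ universe) and the strict upregulated list,
where the universe is the set of genes common to both conditions after
alignment — not the whole genome — matching how the DE gene space is
defined. Raw p ≤ 0.05 per pathway with **no** cross-pathway correction
is deliberately permissive; it mirrors the screening intent of the
procedure and is flagged as such.

Stage 4 sorts by log2FC descending, ties broken by lower FDR then
symbol. The eigengene (per-cell score = sign-corrected first principal
component of the standardized set genes, oriented to correlate
non-negatively with the set mean) is exposed for pathway summarization
but is not a cascade filter.

## Patient evidence

Per patient: genes expressed in ≥ 3 cells are kept and log-normalized;
the reference is the first quartile (linear interpolation) of per-gene
average expression; a receptor is `none` at average 0, `marginal` up to
and including the quartile, `strong` strictly above it. Averages are on
log-normalized values (the de-logged alternative changes no tier in the
synthetic checks but is available by normalizing differently). Patients
with < 113 neoplastic cells are excluded. Neoplastic enrichment drops
clusters whose one-vs-rest marker list (|log2FC| ≥ 0.3, FDR ≤ 0.05,
positive fold change) contains any of MBP, PLP1, CD14, AIF1, ETNPPL.

## Synthetic data

The generator reproduces the study design: triculture with
EC = 1221 / astrocyte = 477 / GSC = 217 cells and pooled monoculture
with 1345 / 281 / 483, over 2000 genes. Counts are negative binomial
with mean = library size × normalized gene weight and dispersion 10
shared across genes (var = μ + μ²/10); library sizes are log-normal
(mean log 2500, σ 0.35), creating the UMI covariate structure the
normalization stage must handle. Sequencing depth is a free parameter
(the study reports reads, not UMIs).

Structure planted on top of Gamma(2, 0.5) baseline weights:

* markers at base weight 0.25, boosted 8× in their own type — high
  enough that ≥ 80 % of own-type cells express the marker;
* 60 signature genes per type boosted 3×, placed as adjacent
  EC/astrocyte/GSC triples at evenly spaced genomic positions so
  type-specific expression differences cancel inside CNV smoothing
  windows instead of mimicking arm events;
* GSC weights ×1.5 on 17q and ×0.5 on 4q in both conditions (the cell
  line's constitutive CNVs); ~190 genes per arm give the 101-gene
  window full support;
* five planted ligand–receptor pairs named after the study's headline
  axes (PDGFA→PDGFRA, SAA1→FPR1, RSPO3→LGR6, IL6→IL6R, APOE→LDLR) with
  receptor log2FCs 1.3–2.5 and ligand expressing fractions 0.3–0.5 in
  their source type (triculture only; ligands are Bernoulli-expressed
  per cell at weight 10, so expressing cells are virtually always
  detected); each active receptor carries 15 downstream response genes
  at log2FC 1.5, emulating pathway activation so the enrichment stage
  has genuine signal; decoy network pairs and decoy pathways provide
  negative controls;
* five `MT-` genes at weight 25 give ~6 % mitochondrial fractions.

Not simulated: doublets, ambient RNA, batch effects, cell-cycle or
continuous within-type heterogeneity, and UMI saturation. Passing tests
therefore show that the pipeline recovers planted structure under a
clean negative-binomial world, not that it is robust to those real-data
artifacts.

## Problem sizes and determinism

Acceptance-level checks run the full pipeline at the study scale
(~2000 × 2000 per condition): 20 seeds for planted-pair and CNV
recovery plus 10 null seeds in the test suite, and 10 + 5 seeds in
`scripts/acceptance.py`; unit tests use a scaled-down design (600
genes, ~320–330 cells per condition). A fixed seed drives generation,
PCA and Leiden, and pipeline outputs are byte-identical across reruns.

## Known limitations

* The rank-sum normal approximation is used for all gene-wise tests;
  at very small cluster sizes (a few cells) its p-values are coarse.
* Pathway enrichment without cross-pathway correction inflates the
  per-receptor "enriched pathway" count when many pathways contain the
  receptor; it is a screening statistic, not an inference.
* CNV calls are arm-level means only — no segmentation, breakpoints or
  subclonal structure.
* The ligand–receptor network, secretome and pathway fixtures shipped
  for testing are miniatures; real analyses should supply the
  full-scale resources through the same TSV/GMT readers.
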