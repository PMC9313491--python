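"""Cascade stages, hypergeometric oracle, ranking, flags, eigengene."""

import math

import numpy as np
import pandas as pd
import pytest

from pvn import io as io_mod
from pvn import qc as qc_mod
from pvn.cascade import (
    eigengene,
    enrichment_filter,
    filter_secreted_expressed,
    fraction_expressing,
    hypergeometric_tail,
    intersect_receptors,
    ligand_upregulation_flags,
    rank_candidates,
    run_cascade,
)
from pvn.containers import (
    CellAnnotation,
    ExpressionMatrix,
    GeneSetCollection,
    LRPairTable,
    SecretedSet,
)


def _expr(values, genes, labels=None):
    values = np.asarray(values, dtype=float)
    cells = [f"c{j}" for j in range(values.shape[1])]
    meta = pd.DataFrame({"condition": "tri"}, index=pd.Index(cells))
    e = ExpressionMatrix(values, pd.Index(genes), pd.Index(cells), meta)
    ann = None
    if labels is not None:
        ann = CellAnnotation(e.cell_ids, np.zeros(len(cells), dtype=int),
                             np.asarray(labels, dtype=object))
    return e, ann


class TestIntersectReceptors:
    def test_set_logic(self):
        lr = LRPairTable([("L1", "R1"), ("L2", "R2")])
        assert intersect_receptors({"R1", "G9"}, lr) == {"R1"}

    def test_empty_query(self):
        lr = LRPairTable([("L1", "R1")])
        assert intersect_receptors(set(), lr) == set()


class TestFractionExpressing:
    def test_all_zero(self):
        e, _ = _expr(np.zeros((1, 10)), ["g"])
        assert fraction_expressing(e, "g", e.cell_ids) == 0.0

    def test_one_in_ten(self):
        vals = np.zeros((1, 10))
        vals[0, 3] = 1.0
        e, _ = _expr(vals, ["g"])
        assert fraction_expressing(e, "g", e.cell_ids) == pytest.approx(0.1)

    def test_absent_gene_raises(self):
        e, _ = _expr(np.zeros((1, 5)), ["g"])
        with pytest.raises(KeyError):
            fraction_expressing(e, "nope", e.cell_ids)

    def test_simulated_fraction_recovered(self, small_experiment):
        gt, cfg = small_experiment["gt"], small_experiment["cfg"]
        e = qc_mod.normalize_log(small_experiment["tri"], regress_covariates=False)
        for pair in cfg.planted_pairs:
            cells = e.cell_ids[gt.cell_types_tri == pair.source]
            frac = fraction_expressing(e, pair.ligand, cells)
            tol = 0.05 + 1.5 * np.sqrt(pair.ligand_fraction * 0.5 / len(cells))
            assert abs(frac - pair.ligand_fraction) <= tol


class TestSecretedFilter:
    def _setup(self, frac_ec, frac_astro):
        n = 50
        vals = np.zeros((2, 2 * n))
        rng = np.random.default_rng(0)
        vals[0, :n] = (np.arange(n) < frac_ec * n).astype(float)
        vals[0, n:] = (np.arange(n) < frac_astro * n).astype(float)
        labels = ["EC"] * n + ["astrocyte"] * n
        e, ann = _expr(vals, ["LIG", "REC"], labels)
        lr = LRPairTable([("LIG", "REC")])
        return e, ann, lr

    def test_low_fraction_everywhere_drops_receptor(self):
        e, ann, lr = self._setup(0.05, 0.05)
        out = filter_secreted_expressed({"REC"}, lr, SecretedSet({"LIG"}), e, ann)
        assert out == {}

    def test_astro_fraction_alone_keeps_receptor(self):
        e, ann, lr = self._setup(0.05, 0.12)
        out = filter_secreted_expressed({"REC"}, lr, SecretedSet({"LIG"}), e, ann)
        assert out == {"REC": ["LIG"]}

    def test_non_secreted_ligand_never_qualifies(self):
        e, ann, lr = self._setup(1.0, 1.0)
        out = filter_secreted_expressed({"REC"}, lr, SecretedSet({"OTHER"}), e, ann)
        assert out == {}

    def test_missing_stroma_raises(self):
        vals = np.ones((2, 10))
        e, ann = _expr(vals, ["LIG", "REC"], ["GSC"] * 10)
        lr = LRPairTable([("LIG", "REC")])
        with pytest.raises(ValueError, match="EC or astrocyte"):
            filter_secreted_expressed({"REC"}, lr, SecretedSet({"LIG"}), e, ann)


def hypergeom_tail_oracle(k, K, n, N):
    """P(X >= k) by direct combinatorial enumeration."""
    total = math.comb(N, n)
    acc = 0
    for x in range(k, min(K, n) + 1):
        acc += math.comb(K, x) * math.comb(N - K, n - x)
    return acc / total


class TestHypergeometricTail:
    def test_zero_overlap_gives_one(self):
        assert hypergeometric_tail(0, 5, 4, 10) == 1.0

    def test_hand_enumerated_case(self):
        assert hypergeometric_tail(4, 5, 4, 10) == pytest.approx(5 / 210)

    def test_saturated_urn(self):
        assert hypergeometric_tail(3, 10, 3, 10) == pytest.approx(1.0)

    def test_inconsistent_arguments_raise(self):
        with pytest.raises(ValueError):
            hypergeometric_tail(5, 4, 4, 10)

    def test_matches_enumeration_all_small_cases(self):
        for N in range(1, 13):
            for K in range(0, N + 1):
                for n in range(0, N + 1):
                    for k in range(0, min(K, n) + 1):
                        assert hypergeometric_tail(k, K, n, N) == pytest.approx(
                            hypergeom_tail_oracle(k, K, n, N), abs=1e-12
                        )


class TestEnrichmentFilter:
    def _de(self, receptors):
        return pd.DataFrame(
            {"log2fc": [1.5] * len(receptors), "fdr": [0.01] * len(receptors)},
            index=receptors,
        )

    def test_receptor_in_no_pathway_dropped(self):
        sets = GeneSetCollection({"P1": ["A", "B"]})
        cands, _ = enrichment_filter(
            {"REC": ["LIG"]}, {"A"}, sets, {"A", "B", "REC"}, self._de(["REC"])
        )
        assert cands == []

    def test_constructed_significant_overlap_kept(self):
        # pathway of 5 genes (incl. receptor) overlapping the 4-gene query
        # by 4 inside a 10-gene universe: p = 5/210 ~ 0.024
        universe = {f"g{i}" for i in range(9)} | {"REC"}
        pathway = ["REC", "g0", "g1", "g2", "g3"]
        query = {"g0", "g1", "g2", "REC"}
        sets = GeneSetCollection({"PW": pathway})
        cands, enrich = enrichment_filter(
            {"REC": ["LIG"]}, query, sets, universe, self._de(["REC"])
        )
        assert len(cands) == 1
        assert cands[0].n_enriched_pathways == 1
        assert enrich["REC"][0].p == pytest.approx(5 / 210)

    def test_empty_strict_query_drops_everything(self):
        sets = GeneSetCollection({"PW": ["REC", "g0"]})
        cands, _ = enrichment_filter(
            {"REC": ["LIG"]}, set(), sets, {"REC", "g0", "g1"}, self._de(["REC"])
        )
        assert cands == []

    def test_invariant_to_pathway_and_gene_order(self):
        universe = {f"g{i}" for i in range(9)} | {"REC"}
        query = {"g0", "g1", "g2", "REC"}
        sets_a = GeneSetCollection(
            {"PW1": ["REC", "g0", "g1", "g2", "g3"], "PW2": ["g4", "REC", "g5"]}
        )
        sets_b = GeneSetCollection(
            {"PW2": ["g5", "g4", "REC"], "PW1": ["g3", "g2", "g1", "g0", "REC"]}
        )
        out_a, _ = enrichment_filter({"REC": ["LIG"]}, query, sets_a, universe,
                                     self._de(["REC"]))
        out_b, _ = enrichment_filter({"REC": ["LIG"]}, query, sets_b, universe,
                                     self._de(["REC"]))
        assert out_a == out_b

    def test_empty_universe_raises(self):
        sets = GeneSetCollection({"PW": ["REC"]})
        with pytest.raises(ValueError, match="universe"):
            enrichment_filter({"REC": ["L"]}, set(), sets, set(), self._de(["REC"]))


class TestRankCandidates:
    def test_published_table_top_six(self):
        cands = io_mod.load_table1_fixture()
        top = rank_candidates(cands, top_k=6)
        assert [c.receptor for c in top] == [
            "PDGFRA", "LGR6", "FPR1", "FGFR4", "LPR8", "F3"
        ]

    def test_published_table_top_log2fc(self):
        top = rank_candidates(io_mod.load_table1_fixture(), top_k=1)
        assert top[0].log2fc == pytest.approx(2.68)

    def test_top_k_clamps(self):
        cands = io_mod.load_table1_fixture()
        assert len(rank_candidates(cands, top_k=100)) == 15


class TestLigandFlags:
    def _cond(self, tri_shift=0.0):
        rng = np.random.default_rng(5)
        n = 40
        base = rng.lognormal(0, 0.3, size=(2, 2 * n))
        vals = np.log1p(base)
        labels = ["EC"] * n + ["astrocyte"] * n
        return vals, labels

    def test_identical_conditions_not_flagged(self):
        vals, labels = self._cond()
        e_a, ann_a = _expr(vals, ["LIG", "X"], labels)
        e_b, ann_b = _expr(vals, ["LIG", "X"], labels)
        flags = ligand_upregulation_flags(e_a, e_b, ann_a, ann_b, ["LIG"])
        assert not flags["flag"].any()

    def test_downregulation_not_flagged(self):
        vals, labels = self._cond()
        e_mono, ann_mono = _expr(vals + 2.0, ["LIG", "X"], labels)
        e_tri, ann_tri = _expr(vals, ["LIG", "X"], labels)
        flags = ligand_upregulation_flags(e_mono, e_tri, ann_mono, ann_tri, ["LIG"])
        assert (flags["fdr"] <= 0.05).any()  # strong signal, wrong sign
        assert not flags["flag"].any()

    def test_planted_ligand_flagged_in_source_type(self, small_experiment):
        gt = small_experiment["gt"]
        cfg = small_experiment["cfg"]
        e_mono = qc_mod.normalize_log(small_experiment["mono"],
                                      regress_covariates=False)
        e_tri = qc_mod.normalize_log(small_experiment["tri"],
                                     regress_covariates=False)
        ann_mono = CellAnnotation(e_mono.cell_ids,
                                  np.zeros(e_mono.n_cells, dtype=int),
                                  gt.cell_types_mono.copy())
        ann_tri = CellAnnotation(e_tri.cell_ids,
                                 np.zeros(e_tri.n_cells, dtype=int),
                                 gt.cell_types_tri.copy())
        pair = cfg.planted_pairs[0]
        flags = ligand_upregulation_flags(
            e_mono, e_tri, ann_mono, ann_tri, [pair.ligand]
        )
        row = flags[(flags["ligand"] == pair.ligand)
                    & (flags["cell_type"] == pair.source)]
        assert bool(row["flag"].iloc[0])


class TestEigengene:
    def test_single_gene_set_is_standardized_gene(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(2, 1, size=(3, 60))
        e, _ = _expr(vals, ["A", "B", "C"])
        score = eigengene(e, ["B"])
        z = (vals[1] - vals[1].mean()) / vals[1].std()
        assert abs(np.corrcoef(score, z)[0, 1]) == pytest.approx(1.0)
        assert np.corrcoef(score, vals[1])[0, 1] > 0

    def test_perfectly_correlated_pair(self):
        rng = np.random.default_rng(1)
        g = rng.normal(size=80)
        vals = np.vstack([g, 2 * g + 3])
        e, _ = _expr(vals, ["A", "B"])
        score = eigengene(e, ["A", "B"])
        assert np.corrcoef(score, g)[0, 1] == pytest.approx(1.0)

    def test_orientation_follows_set_mean(self):
        rng = np.random.default_rng(2)
        vals = rng.normal(size=(6, 100))
        e, _ = _expr(vals, [f"g{i}" for i in range(6)])
        score = eigengene(e, [f"g{i}" for i in range(6)])
        z = (vals - vals.mean(axis=1, keepdims=True)) / vals.std(axis=1, keepdims=True)
        assert np.corrcoef(score, z.mean(axis=0))[0, 1] >= 0

    def test_absent_set_raises(self):
        e, _ = _expr(np.ones((2, 10)), ["A", "B"])
        with pytest.raises(ValueError):
            eigengene(e, ["ZZZ"])


def test_stage_counts_monotone_on_simulated_bundle(small_experiment):
    gt = small_experiment["gt"]
    e_mono = qc_mod.normalize_log(small_experiment["mono"], regress_covariates=False)
    e_tri = qc_mod.normalize_log(small_experiment["tri"], regress_covariates=False)
    ann_tri = CellAnnotation(e_tri.cell_ids, np.zeros(e_tri.n_cells, dtype=int),
                             gt.cell_types_tri.copy())
    from pvn import de as de_mod

    a_tri, a_mono = de_mod.align_conditions(e_tri, e_mono)
    de_gsc = de_mod.differential_expression(
        a_tri.values[:, gt.cell_types_tri == "GSC"],
        a_mono.values[:, gt.cell_types_mono == "GSC"],
        a_tri.gene_ids,
    )
    report = run_cascade(
        de_gsc, small_experiment["lr"], small_experiment["secreted"],
        small_experiment["gmt"], e_tri, ann_tri, set(a_tri.gene_ids),
    )
    c = report.stage_counts()
    assert (c["n_upregulated"] >= c["n_receptors_stage1"] >= c["n_stage2"]
            >= c["n_stage3"] >= c["n_top_k"])
    # every candidate satisfies the emitted-row invariants
    for cand in report.candidates:
        assert cand.fdr <= 0.05
        assert cand.ligands
        assert cand.n_enriched_pathways >= 1
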