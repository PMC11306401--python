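import anndata as ad
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from magicrv import (
    CarrierMatrix,
    candidate_gene_celltype_profile,
    celltype_burden_enrichment,
    celltype_marker_genes,
    per_cell_burden_score,
    per_cell_gene_sets,
    run_scpbs,
    rvtrs_score,
    tpm_and_specificity,
    trait_relevant_genes,
)
from magicrv.scpbs import ensure_lognorm


def make_adata(counts, types, genes=None):
    counts = np.asarray(counts)
    genes = genes or [f"g{i}" for i in range(counts.shape[1])]
    adata = ad.AnnData(
        X=counts.astype(np.int64),
        obs=pd.DataFrame({"cell_type": list(types)},
                         index=[f"c{i}" for i in range(counts.shape[0])]),
        var=pd.DataFrame(index=pd.Index(genes, name="gene")),
    )
    return ensure_lognorm(adata)


class TestSpecificity:
    def test_single_type_gene_and_uniform_gene(self):
        # 4 cells, 2 types; g0 only in type A, g1 uniform, g2 silent
        counts = [[10, 5, 0], [10, 5, 0], [0, 5, 0], [0, 5, 0]]
        adata = make_adata(counts, ["A", "A", "B", "B"])
        s = tpm_and_specificity(adata)
        assert s.loc["g0", "A"] == 1.0 and s.loc["g0", "B"] == 0.0
        assert (s.loc["g2"] == 0.0).all()

    def test_tpm_ratio(self):
        # type A TPM for g0 is half of type B's -> specificity 0.5 vs 1.0
        counts = [[30, 70], [60, 40]]
        adata = make_adata(counts, ["A", "B"])
        s = tpm_and_specificity(adata)
        tpm_a = 30 / 100 * 1e6
        tpm_b = 60 / 100 * 1e6
        assert s.loc["g0", "A"] == pytest.approx(tpm_a / tpm_b)
        assert s.loc["g0", "B"] == 1.0

    def test_bounds_and_argmax_property(self):
        rng = np.random.default_rng(0)
        adata = make_adata(rng.poisson(3, (30, 50)) + (rng.random((30, 50)) < 0.2),
                           ["A"] * 10 + ["B"] * 10 + ["C"] * 10)
        s = tpm_and_specificity(adata)
        v = s.to_numpy()
        assert (v >= 0).all() and (v <= 1).all()
        expressed = np.ravel(np.asarray(adata.X.sum(axis=0))) > 0
        assert np.allclose(v[expressed].max(axis=1), 1.0)

    def test_zero_count_type_rejected(self):
        adata = make_adata([[1, 1], [0, 0]], ["A", "B"])
        with pytest.raises(ValueError):
            tpm_and_specificity(adata)


class TestMarkers:
    def make(self, seed=0):
        rng = np.random.default_rng(seed)
        counts = rng.poisson(2, (60, 40))
        counts[:20, 0] += 12  # g0 planted marker of type A
        return make_adata(counts, ["A"] * 20 + ["B"] * 20 + ["C"] * 20)

    def test_planted_marker_ranked_first(self):
        markers = celltype_marker_genes(self.make())
        assert markers["A"][0] == "g0"

    def test_min_pct_excludes_rare_detection(self):
        rng = np.random.default_rng(1)
        counts = np.zeros((60, 5), dtype=int)
        counts[:, 1:] = rng.poisson(3, (60, 4))
        counts[0, 0] = 50  # detected in 1/20 cells of type A: below min.pct
        adata = make_adata(counts, ["A"] * 20 + ["B"] * 20 + ["C"] * 20)
        markers = celltype_marker_genes(adata)
        assert all("g0" not in m for m in markers.values())

    def test_identical_expression_gives_no_markers(self):
        counts = np.tile(np.arange(1, 9), (30, 1))
        adata = make_adata(counts, ["A"] * 15 + ["B"] * 15)
        markers = celltype_marker_genes(adata)
        assert markers == {"A": [], "B": []}


class TestPerCellGeneSets:
    def test_identical_cells_identical_sets_and_sizes(self):
        rng = np.random.default_rng(2)
        row = rng.poisson(4, 50)
        row[:5] = 0
        counts = np.tile(row, (8, 1))
        adata = make_adata(counts, ["A"] * 4 + ["B"] * 4)
        spec = tpm_and_specificity(adata)
        sets = per_cell_gene_sets(adata, spec)
        assert np.array_equal(sets["c0"], sets["c1"])
        n_expressed = int((row > 0).sum())
        assert len(sets["c0"]) == int(np.ceil(0.10 * n_expressed))
        # zero-expression genes never selected
        assert set(sets["c0"]).isdisjoint(set(np.where(row == 0)[0]))

    def test_sparse_cells_skipped(self):
        counts = np.zeros((4, 30), dtype=int)
        counts[0, :3] = 5  # fewer than 10 expressed genes
        counts[1:, :] = 4
        adata = make_adata(counts, ["A", "A", "B", "B"])
        sets = per_cell_gene_sets(adata, tpm_and_specificity(adata))
        assert "c0" not in sets and "c1" in sets


class TestPerCellBurden:
    def design(self, n=120, seed=3):
        rng = np.random.default_rng(seed)
        idx = [f"s{i}" for i in range(n)]
        d = pd.DataFrame({"status": [1] * (n // 2) + [0] * (n // 2),
                          "sex": rng.integers(0, 2, n)}, index=idx)
        return d

    def test_no_carriers_scores_zero_with_flag(self):
        design = self.design()
        carriers = np.zeros((10, len(design)), dtype=bool)
        out = per_cell_burden_score({"c0": np.array([0, 1])}, carriers,
                                    pd.Index(range(10)), design, covariates=["sex"])
        assert out.loc["c0", "scpbs"] == 0.0 and bool(out.loc["c0", "null_flag"])

    def test_enriched_carriage_scores_positive(self):
        design = self.design()
        rng = np.random.default_rng(4)
        carriers = np.zeros((4, len(design)), dtype=bool)
        y = design["status"].to_numpy()
        carriers[0, (y == 1) & (rng.random(len(design)) < 0.4)] = True
        carriers[0, (y == 0) & (rng.random(len(design)) < 0.05)] = True
        out = per_cell_burden_score({"c0": np.array([0])}, carriers,
                                    pd.Index(range(4)), design, covariates=["sex"])
        assert out.loc["c0", "scpbs"] > 0

    def test_sample_order_invariance(self):
        design = self.design()
        rng = np.random.default_rng(5)
        carriers = rng.random((3, len(design))) < 0.1
        sets = {"c0": np.array([0, 2])}
        out1 = per_cell_burden_score(sets, carriers, pd.Index(range(3)), design,
                                     covariates=["sex"])
        perm = rng.permutation(len(design))
        out2 = per_cell_burden_score(sets, carriers[:, perm], pd.Index(range(3)),
                                     design.iloc[perm], covariates=["sex"])
        assert out1.loc["c0", "scpbs"] == pytest.approx(out2.loc["c0", "scpbs"], abs=1e-8)


class TestTraitGenesAndRvtrs:
    def scored_adata(self, seed=6):
        rng = np.random.default_rng(seed)
        counts = rng.poisson(3, (40, 60))
        adata = make_adata(counts, ["A"] * 20 + ["B"] * 20)
        s = rng.standard_normal(40)
        scpbs = pd.DataFrame({"scpbs": s, "null_flag": False}, index=adata.obs_names)
        return adata, scpbs

    def test_perfectly_correlated_gene_ranks_first(self):
        adata, scpbs = self.scored_adata()
        lognorm = adata.layers["lognorm"].copy()
        lognorm[:, 7] = 2.0 * scpbs["scpbs"].to_numpy() + 5.0
        adata.layers["lognorm"] = lognorm
        pcc, trait = trait_relevant_genes(scpbs, adata)
        assert pcc["g7"] == pytest.approx(1.0)
        assert trait[0] == "g7"

    def test_constant_gene_excluded_and_sign_flip_reverses(self):
        adata, scpbs = self.scored_adata()
        lognorm = adata.layers["lognorm"].copy()
        lognorm[:, 3] = 1.0
        adata.layers["lognorm"] = lognorm
        pcc, _ = trait_relevant_genes(scpbs, adata)
        assert "g3" not in pcc.index
        flipped = scpbs.assign(scpbs=-scpbs["scpbs"])
        pcc2, _ = trait_relevant_genes(flipped, adata)
        assert np.allclose(pcc2.loc[pcc.index], -pcc)

    def test_constant_expression_rvtrs_zero(self):
        counts = np.full((20, 40), 5)
        adata = make_adata(counts, ["A"] * 10 + ["B"] * 10)
        score = rvtrs_score(adata, ["g0", "g1"], n_bins=5, n_ctrl=10, seed=1)
        assert np.allclose(score.to_numpy(), 0.0, atol=1e-5)

    def test_random_trait_draws_center_on_zero(self):
        rng = np.random.default_rng(7)
        counts = rng.poisson(4, (50, 80))
        adata = make_adata(counts, ["A"] * 25 + ["B"] * 25)
        means = []
        genes = np.asarray(adata.var_names)
        for k in range(200):
            draw = rng.choice(genes, size=8, replace=False)
            means.append(rvtrs_score(adata, list(draw), n_bins=10, n_ctrl=20,
                                     seed=int(k)).mean())
        m = np.array(means)
        assert abs(m.mean()) < 3 * m.std(ddof=1) / np.sqrt(len(m)) + 0.01

    def test_cell_relabeling_invariance(self):
        rng = np.random.default_rng(8)
        counts = rng.poisson(4, (30, 40))
        adata1 = make_adata(counts, ["A"] * 15 + ["B"] * 15)
        adata2 = adata1.copy()
        adata2.obs_names = [f"zz{i}" for i in range(30)]
        s1 = rvtrs_score(adata1, ["g0", "g5"], seed=2, n_bins=5, n_ctrl=10)
        s2 = rvtrs_score(adata2, ["g0", "g5"], seed=2, n_bins=5, n_ctrl=10)
        assert np.allclose(s1.to_numpy(), s2.to_numpy())

    def test_missing_trait_gene_rejected(self):
        adata = make_adata(np.full((6, 12), 3), ["A"] * 3 + ["B"] * 3)
        with pytest.raises(KeyError):
            rvtrs_score(adata, ["nope"], seed=0)


class TestCandidateProfile:
    def test_marker_gene_peaks_in_home_type(self):
        counts = np.zeros((30, 4), dtype=int)
        counts[:, 1:] = 3
        counts[:10, 0] = 20  # expressed only in fibroblast-labeled cells
        adata = make_adata(counts, ["fibroblast"] * 10 + ["neuron"] * 10 + ["glia"] * 10)
        prof = candidate_gene_celltype_profile(adata, "g0")
        assert prof.idxmax() == "fibroblast"
        assert prof.mean() == pytest.approx(0.0, abs=1e-12)
        assert prof.std(ddof=1) == pytest.approx(1.0)

    def test_uniform_gene_all_zero(self):
        adata = make_adata(np.full((20, 3), 4), ["A"] * 10 + ["B"] * 10)
        prof = candidate_gene_celltype_profile(adata, "g1")
        assert np.allclose(prof.to_numpy(), 0.0)

    def test_absent_gene_rejected(self):
        adata = make_adata(np.full((4, 3), 2), ["A", "A", "B", "B"])
        with pytest.raises(KeyError):
            candidate_gene_celltype_profile(adata, "nope")


class TestEndToEnd:
    def test_recovery_and_determinism_on_linked_fixture(self, small_linked):
        ds = small_linked
        res1 = run_scpbs(ds.adata, ds.cohort.gene_carriers, ds.cohort.design, seed=5)
        res2 = run_scpbs(ds.adata.copy(), ds.cohort.gene_carriers, ds.cohort.design, seed=5)
        # same seed -> bit-identical output
        pd.testing.assert_frame_equal(res1.per_cell, res2.per_cell)
        # the causal type has the top median rvTRS and separates by rank test
        assert res1.per_type.index[0] == ds.causal_type
        causal = res1.per_cell.loc[res1.per_cell["cell_type"] == ds.causal_type, "rvtrs"]
        rest = res1.per_cell.loc[res1.per_cell["cell_type"] != ds.causal_type, "rvtrs"]
        p = stats.mannwhitneyu(causal, rest, alternative="greater").pvalue
        assert p < 0.01
        # causal-type cells' mean scPBS exceeds the others'
        sc = res1.per_cell.loc[~res1.per_cell["scpbs_null"]]
        mean_causal = sc.loc[sc["cell_type"] == ds.causal_type, "scpbs"].mean()
        mean_rest = sc.loc[sc["cell_type"] != ds.causal_type, "scpbs"].mean()
        assert mean_causal > mean_rest

    def test_permuted_phenotype_centers_scpbs_on_zero(self, small_linked):
        ds = small_linked
        rng = np.random.default_rng(13)
        design = ds.cohort.design.copy()
        design["status"] = rng.permutation(design["status"].to_numpy())
        res = run_scpbs(ds.adata, ds.cohort.gene_carriers, design, seed=5)
        sc = res.scpbs.loc[~res.scpbs["null_flag"], "scpbs"]
        se = sc.std(ddof=1) / np.sqrt(len(sc))
        # cells are heavily correlated, so allow the dispersion of the scores
        # themselves rather than the naive SE of the mean
        assert abs(sc.mean()) < max(2 * se, 2 * sc.std(ddof=1))

    def test_celltype_enrichment_recovers_causal_type(self, small_linked):
        ds = small_linked
        markers = celltype_marker_genes(ds.adata)
        res = celltype_burden_enrichment(
            markers, ds.cohort.gene_carriers, ds.cohort.design, test="FET"
        )
        ptv = res[res["class"] == "PTV"].set_index("cell_type")
        assert ptv["p"].idxmin() == ds.causal_type
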