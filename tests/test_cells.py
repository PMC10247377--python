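"""Single-cell stage: QC, expression-CNA inference, LSI projection with kNN
label transfer, Wilcoxon DE and KS enrichment."""

import anndata as ad
import numpy as np
import pandas as pd
import pytest
from scipy import sparse

from preneo.cells import (
    deg_wilcoxon,
    fit_reference,
    gsea_ks,
    infer_cell_cna,
    intersect_degs,
    knn_type_frequencies,
    link_barcode_cna,
    project_cells,
    qc_filter,
)
from preneo.sim import (
    SimulationConfig,
    sample_cells_from_program,
    sample_diploid_reference,
    sample_scrna,
    sample_typed_reference,
    simulate_evolution,
)


def _adata(X, gene_names=None, **obs_cols):
    X = np.asarray(X)
    n, g = X.shape
    obs = pd.DataFrame(obs_cols, index=[f"c{i}" for i in range(n)])
    var = pd.DataFrame(index=gene_names or [f"g{j}" for j in range(g)])
    return ad.AnnData(X=sparse.csr_matrix(X), obs=obs, var=var)


@pytest.fixture(scope="module")
def trisomy_history(genome):
    """Half the population carries a 7q gain (no other events)."""
    cfg = SimulationConfig(
        genome=genome, n_founder=400,
        founder_clones=[((), 200), (("7q+",), 200)],
        fitness_table={}, contingency_table={},
        missegregation_rate=0.0, focal_deletion_rate=0.0,
        barcoding_day=0, split_day=7, n_replicates=1, n_days=21, seed=0,
    )
    return simulate_evolution(cfg)


class TestQC:
    def test_zero_thresholds_identity(self):
        adata = _adata(np.ones((5, 30)))
        out, report = qc_filter(adata, min_counts=0, min_genes=0, max_mito_fraction=1.0)
        assert out.n_obs == 5 and report["n_removed"] == 0

    def test_single_low_count_cell_removed(self):
        X = np.ones((4, 30)) * 10
        X[2] = 0.0
        X[2, 0] = 1
        adata = _adata(X)
        out, report = qc_filter(adata, min_counts=30, min_genes=0, max_mito_fraction=1.0)
        assert list(out.obs_names) == ["c0", "c1", "c3"]
        assert report["removed_low_counts"] == 1

    def test_mito_fraction_filter(self):
        X = np.ones((3, 4)) * 10
        X[1, 3] = 200  # 83% mitochondrial
        adata = _adata(X, gene_names=["g1", "g2", "g3", "MT-0"])
        out, report = qc_filter(adata, min_counts=0, min_genes=0, max_mito_fraction=0.5)
        assert "c1" not in out.obs_names and report["removed_high_mito"] == 1

    def test_injected_low_quality_fraction_recovered(self, genome, trisomy_history):
        adata = sample_scrna(
            trisomy_history, 14, n_cells=600, seed=0, low_quality_fraction=0.1,
            replicate=0,
        )
        depth = np.asarray(adata.X.sum(axis=1)).ravel()
        out, report = qc_filter(adata, min_counts=int(np.median(depth) * 0.2),
                                min_genes=0, max_mito_fraction=1.0)
        removed = report["n_removed"] / adata.n_obs
        # binomial 99% CI around 0.10 with n=600: +-0.032
        assert abs(removed - 0.10) < 0.04
        assert set(out.obs_names) <= set(adata.obs_names[~adata.obs["low_quality"]])

    def test_all_cells_removed_is_error(self):
        adata = _adata(np.ones((3, 5)))
        with pytest.raises(ValueError, match="every cell"):
            qc_filter(adata, min_counts=100, min_genes=0, max_mito_fraction=1.0)


class TestInferCellCNA:
    @pytest.fixture(scope="class")
    def called(self, genome, trisomy_history):
        adata = sample_scrna(trisomy_history, 14, n_cells=400, genes_per_arm=40,
                             replicate=0, seed=0)
        reference = sample_diploid_reference(genome, n_cells=150, genes_per_arm=40,
                                             seed=0)
        cc = infer_cell_cna(adata, reference, genome, window_genes=21,
                            arm_threshold=0.1, min_cells=10)
        return adata, cc, trisomy_history

    def test_reference_like_cells_mostly_uncalled(self, genome):
        """Generative null at realistic gene density: diploid query cells get
        no arm calls in >= 95% of cells."""
        kw = dict(genes_per_arm=200, baseline_scale=10.0, dispersion=50.0, seed=0)
        reference = sample_diploid_reference(genome, n_cells=200, **kw)
        query = sample_diploid_reference(genome, n_cells=100, stream="diploid-query", **kw)
        query.obs_names = [f"q{i}" for i in range(query.n_obs)]
        cc = infer_cell_cna(query, reference, genome, window_genes=101, arm_threshold=0.1)
        fully_neutral = (cc.arm_calls.fillna(0.0) == 0).all(axis=1).mean()
        assert fully_neutral >= 0.95

    def test_trisomy_arm_gain_called_in_most_carrier_cells(self, called):
        adata, cc, h = called
        carriers = adata.obs["clone_id"].map(
            lambda cid: "7q+" in h.clones[int(cid)].events
        ).to_numpy()
        assert carriers.sum() >= 100
        calls = cc.arm_calls.loc[adata.obs_names[carriers], "7q"]
        assert (calls == 1).mean() >= 0.9
        # dosage scale: arm mean ~ log2(3/2) for carriers before any thresholding
        means = cc.arm_means.loc[adata.obs_names[carriers], "7q"]
        assert abs(means.mean() - np.log2(1.5)) < 0.2

    def test_consensus_requires_min_cells(self, called):
        adata, cc, _ = called
        counts = adata.obs["barcode_id"].value_counts()
        small = [int(b) for b, n in counts.items() if n < 10]
        assert set(cc.consensus.index).isdisjoint(small)
        large = [int(b) for b, n in counts.items() if n >= 10]
        assert set(cc.consensus.index) == set(large)

    def test_depth_scaling_invariance(self, genome, called):
        adata, cc, _ = called
        scaled = adata.copy()
        X = scaled.X.toarray()
        X[0] *= 3
        scaled.X = sparse.csr_matrix(X)
        reference = sample_diploid_reference(genome, n_cells=150, genes_per_arm=40, seed=0)
        cc2 = infer_cell_cna(scaled, reference, genome, window_genes=21,
                             arm_threshold=0.1, min_cells=10)
        pd.testing.assert_series_equal(
            cc.arm_calls.iloc[0], cc2.arm_calls.iloc[0], atol=1e-12
        )

    def test_too_few_reference_cells_rejected(self, genome, trisomy_history):
        adata = sample_scrna(trisomy_history, 14, n_cells=20, replicate=0, seed=0)
        reference = sample_diploid_reference(genome, n_cells=10, seed=0)
        with pytest.raises(ValueError, match="50 reference"):
            infer_cell_cna(adata, reference, genome)

    def test_sparse_arm_marked_uncallable(self, genome, trisomy_history):
        adata = sample_scrna(trisomy_history, 14, n_cells=60, genes_per_arm=8,
                             replicate=0, seed=0)
        reference = sample_diploid_reference(genome, n_cells=100, genes_per_arm=8, seed=0)
        cc = infer_cell_cna(adata, reference, genome, window_genes=21, arm_threshold=0.1)
        # 8 genes per arm < 21/2: every arm uncallable
        assert cc.arm_calls.isna().all().all()


class TestLinkBarcodeCNA:
    def _cc(self, genome, calls: dict):
        from preneo.cells import CellCNAMatrix

        arms = list(calls)
        df = pd.DataFrame([calls] * 20, index=[f"c{i}" for i in range(20)])
        return CellCNAMatrix(
            smoothed=pd.DataFrame(), arm_means=df.astype(float), arm_calls=df.astype(float),
            consensus=pd.DataFrame(), cell_barcodes=pd.Series(0, index=df.index),
            arm_threshold=0.1,
        )

    def _bulk(self, genome, events: set):
        from preneo.cna import ArmEventCall, CopyNumberProfile

        arm_events = [
            ArmEventCall(e[:-1], "gain" if e[-1] == "+" else "loss", 1.0, True)
            for e in events
        ]
        return CopyNumberProfile(
            sample_id="bulk", day=0, genome=genome,
            log_ratios=np.zeros(genome.n_bins),
            imputed=np.zeros(genome.n_bins, bool),
            segments=pd.DataFrame(columns=["chrom", "start", "end", "start_bin",
                                           "end_bin", "n_bins", "mean"]),
            arm_events=arm_events,
        )

    def test_identical_call_sets_jaccard_one(self, genome):
        cc = self._cc(genome, {"7q": 1.0, "9p": -1.0, "3p": 0.0})
        bulk = self._bulk(genome, {"7q+", "9p-"})
        assert link_barcode_cna(cc, bulk)["jaccard"] == 1.0

    def test_disjoint_call_sets_jaccard_zero(self, genome):
        cc = self._cc(genome, {"7q": 1.0, "9p": 0.0})
        bulk = self._bulk(genome, {"9p-"})
        assert link_barcode_cna(cc, bulk)["jaccard"] == 0.0

    def test_end_to_end_concordance(self, genome, trisomy_history):
        from preneo.cna import call_profile
        from preneo.sim import sample_swgs

        adata = sample_scrna(trisomy_history, 14, n_cells=300, genes_per_arm=40,
                             replicate=0, seed=0)
        reference = sample_diploid_reference(genome, n_cells=150, genes_per_arm=40,
                                             seed=0)
        cc = infer_cell_cna(adata, reference, genome, window_genes=21)
        bulk = call_profile(
            sample_swgs(trisomy_history, 14, mean_coverage=5.0, replicate=0, seed=0),
            genome,
        )
        out = link_barcode_cna(cc, bulk)
        assert out["jaccard"] >= 0.8


class TestLSIProjection:
    @pytest.fixture(scope="class")
    def atlas(self, genome):
        adata, programs = sample_typed_reference(
            genome, n_cells=300, n_types=3, genes_per_arm=20, seed=1
        )
        model = fit_reference(adata, adata.obs["cell_type"], n_dims=10, n_top_genes=400)
        return adata, programs, model

    def test_reference_projection_idempotent(self, atlas):
        adata, _, model = atlas
        coords, shared = project_cells(model, adata)
        assert shared == 1.0
        assert np.allclose(coords, model.coordinates, atol=1e-8)

    def test_projection_invariant_to_gene_order(self, atlas):
        adata, _, model = atlas
        perm = np.random.default_rng(0).permutation(adata.n_vars)
        shuffled = adata[:, perm].copy()
        coords, _ = project_cells(model, shuffled)
        assert np.allclose(coords, model.coordinates, atol=1e-8)

    def test_clusters_separated_in_embedding(self, atlas):
        from sklearn.metrics import silhouette_score

        adata, _, model = atlas
        assert silhouette_score(model.coordinates, model.labels) > 0.5

    def test_query_cells_land_in_their_cluster(self, genome, atlas):
        adata, programs, model = atlas
        query = sample_cells_from_program(programs[1], adata.var, n_cells=80, seed=2)
        coords, _ = project_cells(model, query)
        freq = knn_type_frequencies(coords, model, k=25)
        assert freq.loc["all", "type_1"] >= 0.95

    def test_knn_equals_brute_force_on_200_cells(self, genome):
        adata, programs = sample_typed_reference(
            genome, n_cells=200, n_types=2, genes_per_arm=20, seed=3
        )
        model = fit_reference(adata, adata.obs["cell_type"], n_dims=8, n_top_genes=300)
        query = sample_cells_from_program(programs[0], adata.var, n_cells=40, seed=4)
        coords, _ = project_cells(model, query)
        k = 25
        freq = knn_type_frequencies(coords, model, k=k)
        types = sorted(set(model.labels))
        brute = np.zeros((len(coords), len(types)))
        for i, c in enumerate(coords):
            d = np.linalg.norm(model.coordinates - c, axis=1)
            idx = np.argsort(d, kind="stable")[:k]
            for t_i, t in enumerate(types):
                brute[i, t_i] = (model.labels[idx] == t).mean()
        assert np.allclose(freq.loc["all"].to_numpy(), brute.mean(axis=0))

    def test_rows_sum_to_one_per_sample(self, genome, atlas):
        adata, programs, model = atlas
        query = sample_cells_from_program(programs[0], adata.var, n_cells=30, seed=5)
        coords, _ = project_cells(model, query)
        samples = pd.Series(["s1"] * 15 + ["s2"] * 15)
        freq = knn_type_frequencies(coords, model, k=25, samples=samples)
        assert np.allclose(freq.sum(axis=1), 1.0)

    def test_zero_shared_genes_rejected(self, atlas):
        adata, _, model = atlas
        query = _adata(np.ones((3, 4)), gene_names=["x1", "x2", "x3", "x4"])
        with pytest.raises(ValueError, match="shares no genes"):
            project_cells(model, query)

    def test_single_type_degenerate_reference(self, genome):
        adata, programs = sample_typed_reference(
            genome, n_cells=120, n_types=1, genes_per_arm=15, seed=6
        )
        with pytest.warns(UserWarning, match="single cell type"):
            model = fit_reference(adata, adata.obs["cell_type"], n_dims=5,
                                  n_top_genes=200)
        query = sample_cells_from_program(programs[0], adata.var, n_cells=10, seed=7)
        coords, _ = project_cells(model, query)
        freq = knn_type_frequencies(coords, model, k=25)
        assert freq.loc["all", "type_0"] == 1.0


class TestWilcoxonDE:
    def test_identical_groups_nothing_significant(self):
        X = np.random.default_rng(0).poisson(5, size=(20, 50))
        a, b = _adata(X[:10]), _adata(X[10:])
        out = deg_wilcoxon(a, b)
        assert not out["significant"].any()

    def test_exact_3v3_separation_p_is_0p1(self):
        # gene 0 carries values 1,2,3 vs 4,5,6; gene 1 equalizes library depth
        # so normalization preserves them; exact two-sided p = 2/C(6,3) = 0.1
        a = _adata(np.array([[1.0, 9.0], [2.0, 8.0], [3.0, 7.0]]))
        b = _adata(np.array([[4.0, 6.0], [5.0, 5.0], [6.0, 4.0]]))
        out = deg_wilcoxon(a, b)
        assert out["p"].iloc[0] == pytest.approx(0.1)
        assert out["direction"].iloc[0] == -1

    def test_constant_gene_p_one(self):
        a = _adata(np.full((5, 2), 7.0))
        b = _adata(np.full((5, 2), 7.0))
        out = deg_wilcoxon(a, b)
        assert (out["p"] == 1.0).all()

    def test_bonferroni_scales_with_gene_count(self):
        rng = np.random.default_rng(1)
        X = rng.poisson(5, size=(40, 100)).astype(float)
        a, b = _adata(X[:20]), _adata(X[20:])
        out = deg_wilcoxon(a, b)
        assert np.allclose(out["p_bonferroni"], np.minimum(out["p"] * 100, 1.0))

    def test_shifted_genes_detected_with_controlled_fp(self):
        rng = np.random.default_rng(2)
        n_genes, n_shift, n_cells = 500, 25, 100
        base = rng.gamma(2.0, 2.0, n_genes)
        mu = np.tile(base, (2 * n_cells, 1))
        mu[n_cells:, :n_shift] *= 2.0  # 2x shift in group B
        X = rng.poisson(mu * 5)
        a, b = _adata(X[:n_cells]), _adata(X[n_cells:])
        out = deg_wilcoxon(a, b)
        sens = out["significant"][:n_shift].mean()
        fp = int(out["significant"][n_shift:].sum())
        assert sens >= 0.9
        assert fp <= max(3, 0.05 * (n_genes - n_shift))

    def test_too_few_cells_rejected(self):
        a, b = _adata(np.ones((2, 5))), _adata(np.ones((5, 5)))
        with pytest.raises(ValueError, match="three cells"):
            deg_wilcoxon(a, b)


class TestIntersections:
    def _table(self, genes, sig_up=(), sig_down=()):
        return pd.DataFrame(
            {
                "direction": [1 if g in sig_up else -1 for g in genes],
                "p": 0.001,
                "p_bonferroni": [
                    0.01 if (g in sig_up or g in sig_down) else 1.0 for g in genes
                ],
                "significant": [g in sig_up or g in sig_down for g in genes],
            },
            index=pd.Index(genes, name="gene"),
        )

    def test_identical_sets_intersection_is_set(self):
        genes = ["g1", "g2", "g3"]
        per = {c: self._table(genes, sig_up=("g1", "g2")) for c in ("c1", "c2", "c3")}
        out = intersect_degs(per)
        assert out["shared_up"] == {"g1", "g2"} and out["shared_down"] == set()

    def test_disjoint_sets_empty_intersection(self):
        genes = ["g1", "g2"]
        per = {
            "c1": self._table(genes, sig_up=("g1",)),
            "c2": self._table(genes, sig_up=("g2",)),
        }
        out = intersect_degs(per)
        assert out["shared_up"] == set()
        assert set(out["upset"].index) == {"g1", "g2"}

    def test_constructed_three_way_overlap(self):
        genes = [f"g{i}" for i in range(6)]
        per = {
            "c1": self._table(genes, sig_up=("g1", "g2", "g3")),
            "c2": self._table(genes, sig_up=("g1", "g2", "g4")),
            "c3": self._table(genes, sig_up=("g1", "g2", "g5")),
        }
        assert intersect_degs(per)["shared_up"] == {"g1", "g2"}


class TestGseaKS:
    def test_set_spanning_ranking_is_null(self):
        scores = pd.Series(np.arange(50), index=[f"g{i}" for i in range(50)])
        out = gsea_ks(scores, {"everything": list(scores.index)})
        assert out.loc["everything", "score"] == 0.0
        assert out.loc["everything", "p"] == 1.0

    def test_top_block_fully_separated(self):
        scores = pd.Series(np.arange(100), index=[f"g{i}" for i in range(100)])
        top10 = list(scores.sort_values(ascending=False).index[:10])
        out = gsea_ks(scores, {"top": top10})
        assert out.loc["top", "score"] == pytest.approx(1.0)
        assert out.loc["top", "direction"] == "up"
        assert out.loc["top", "p"] < 1e-6

    def test_small_sets_skipped_with_warning(self):
        scores = pd.Series(np.arange(30), index=[f"g{i}" for i in range(30)])
        with pytest.warns(UserWarning, match="skipped"):
            out = gsea_ks(scores, {"tiny": ["g0", "g1"], "ok": [f"g{i}" for i in range(8)]})
        assert list(out.index) == ["ok"]

    def test_bh_adjustment_monotone(self):
        rng = np.random.default_rng(3)
        genes = [f"g{i}" for i in range(200)]
        scores = pd.Series(rng.normal(size=200), index=genes)
        sets = {f"s{j}": list(rng.choice(genes, 15, replace=False)) for j in range(10)}
        sets["signal"] = list(scores.sort_values().index[:15])
        out = gsea_ks(scores, sets)
        assert (out["p_bh"] >= out["p"] - 1e-12).all()
        assert out.loc["signal", "p_bh"] < 0.05
        assert out.loc["signal", "direction"] == "down"
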