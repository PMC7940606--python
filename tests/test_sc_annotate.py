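"""DE ranking, preranked GSEA, cell-cycle scoring and the three-layer annotation."""

import numpy as np
import pandas as pd
import pytest

from brmtme.sc import (
    AnnotationEvidence,
    annotate_clusters,
    compare_cluster_cycle,
    doublet_coexpression_fraction,
    gsea_preranked,
    marker_fractions,
    normalize_log1p,
    rank_markers,
    score_cell_cycle,
)
from tests.conftest import make_adata


def planted_marker_adata(seed=0, n_per=100, n_genes=200, logfc=3.0):
    rng = np.random.default_rng(seed)
    base = rng.gamma(2.0, 1.0, size=n_genes)
    mA = base.copy()
    mA[0] *= 2.0**logfc  # g0 is the planted marker of cluster A
    counts = np.vstack(
        [rng.poisson(np.tile(m, (n_per, 1))) for m in (mA, base)]
    ).astype(float)
    a = make_adata(counts)
    normalize_log1p(a)
    clusters = pd.Series(["A"] * n_per + ["B"] * n_per, index=a.obs_names)
    return a, clusters


class TestRankMarkers:
    def test_planted_marker_top_ranked_and_significant(self):
        a, clusters = planted_marker_adata()
        de = rank_markers(a, clusters)
        top = de[de["cluster"] == "A"].iloc[0]
        assert top["gene"] == "g0"
        assert top["p_adj"] < 0.05

    def test_null_calibration_of_pvalues(self):
        fracs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            a = make_adata(rng.poisson(3.0, size=(120, 150)).astype(float))
            normalize_log1p(a)
            clusters = pd.Series(
                rng.permutation(["A"] * 60 + ["B"] * 60), index=a.obs_names
            )
            de = rank_markers(a, clusters)
            fracs.append((de[de["cluster"] == "A"]["p"] < 0.05).mean())
        assert np.mean(fracs) == pytest.approx(0.05, abs=0.02)

    def test_identical_expression_zero_log_fc(self):
        counts = np.tile(np.arange(1.0, 11.0), (40, 1))
        a = make_adata(counts)
        normalize_log1p(a)
        clusters = pd.Series(["A"] * 20 + ["B"] * 20, index=a.obs_names)
        de = rank_markers(a, clusters)
        np.testing.assert_allclose(de["log_fc"], 0.0, atol=1e-12)

    def test_singleton_cluster_skipped(self):
        a, clusters = planted_marker_adata(n_per=30)
        clusters.iloc[0] = "lonely"
        with pytest.warns(UserWarning, match="fewer"):
            de = rank_markers(a, clusters)
        assert "lonely" not in set(de["cluster"])

    def test_bh_adjustment_is_monotone(self):
        a, clusters = planted_marker_adata(seed=2)
        de = rank_markers(a, clusters)
        sub = de[de["cluster"] == "A"].sort_values("p")
        assert sub["p_adj"].is_monotonic_increasing


class TestGseaPreranked:
    @staticmethod
    def _ranking(n=500, seed=0):
        rng = np.random.default_rng(seed)
        return pd.Series(rng.normal(size=n), index=[f"g{i}" for i in range(n)])

    def test_extremal_top_k_set_beats_random_sets(self):
        ranking = self._ranking()
        top = ranking.sort_values(ascending=False).head(20).index.tolist()
        res = gsea_preranked(ranking, {"top": top}, n_perm=200, seed=1)
        es_top = res.loc[0, "es"]
        assert es_top > 0
        rng = np.random.default_rng(2)
        from brmtme.sc.annotate import _es

        order = ranking.sort_values(ascending=False)
        scores = order.to_numpy()
        rand_es = [
            _es(scores, np.sort(rng.choice(len(ranking), 20, replace=False)),
                len(ranking), 1.0)
            for _ in range(1000)
        ]
        assert es_top >= max(rand_es)
        assert res.loc[0, "enriched"]

    def test_reversed_ranking_negates_extremal_es(self):
        ranking = self._ranking(seed=3)
        top = ranking.sort_values(ascending=False).head(25).index.tolist()
        es_fwd = gsea_preranked(ranking, {"s": top}, n_perm=50, seed=0).loc[0, "es"]
        es_rev = gsea_preranked(-ranking, {"s": top}, n_perm=50, seed=0).loc[0, "es"]
        assert es_rev == pytest.approx(-es_fwd, rel=1e-9)

    def test_random_sets_fdr_calibrated(self):
        # null gene sets should rarely clear the NES > 0, FDR < 0.25 gate
        flagged = 0
        n_rep = 200
        for seed in range(n_rep):
            rng = np.random.default_rng(1000 + seed)
            ranking = pd.Series(rng.normal(size=300),
                                index=[f"g{i}" for i in range(300)])
            genes = [f"g{i}" for i in rng.choice(300, 15, replace=False)]
            res = gsea_preranked(ranking, {"s": genes}, n_perm=100, seed=seed)
            flagged += int(res.loc[0, "enriched"])
        assert flagged / n_rep <= 0.30

    def test_empty_intersection_errors(self):
        ranking = self._ranking(n=50)
        with pytest.raises(ValueError, match="empty intersection"):
            gsea_preranked(ranking, {"s": ["absent1", "absent2"]}, n_perm=10, seed=0)

    def test_es_matches_independent_implementation(self):
        """Enrichment scores agree with gseapy's prerank on the same input."""
        import gseapy

        rng = np.random.default_rng(0)
        ranking = pd.Series(
            rng.normal(size=200), index=[f"g{i}" for i in range(200)]
        )
        sets = {
            f"s{k}": [f"g{i}" for i in rng.choice(200, 15, replace=False)]
            for k in range(3)
        }
        ours = gsea_preranked(ranking, sets, n_perm=10, seed=0).set_index("gene_set")
        ref = gseapy.prerank(
            rnk=ranking.sort_values(ascending=False).reset_index(),
            gene_sets=sets, permutation_num=10, outdir=None, seed=0,
            no_plot=True, min_size=1, max_size=500,
        ).res2d.set_index("Term")
        for s in sets:
            assert ours.loc[s, "es"] == pytest.approx(float(ref.loc[s, "ES"]), abs=1e-9)


class TestCellCycle:
    def test_identical_cells_score_zero(self):
        counts = np.tile(np.arange(1.0, 7.0), (20, 1))
        a = make_adata(counts, genes=["MCM5", "PCNA", "CDK1", "MKI67", "x", "y"])
        normalize_log1p(a)
        s = score_cell_cycle(a, ["MCM5", "PCNA"], ["CDK1", "MKI67"])
        np.testing.assert_allclose(s.to_numpy(), 0.0, atol=1e-12)

    def test_planted_proliferating_population_separates(self):
        import scipy.sparse as sp

        diffs = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            n = 200
            vals = rng.normal(1.0, 0.5, size=(n, 50))
            # last 50 cells: cycle genes (columns 0..9) shifted by +2 gene sd
            vals[150:, :10] += 2 * vals[:150, :10].std(axis=0)
            genes = [f"cc{i}" for i in range(10)] + [f"g{i}" for i in range(40)]
            a = make_adata(np.ones_like(vals), genes=genes)
            a.layers["lognorm"] = sp.csr_matrix(vals)
            s = score_cell_cycle(a, genes[:5], genes[5:10])
            diffs.append(s.iloc[150:].mean().mean() - s.iloc[:150].mean().mean())
        assert min(diffs) > 1.0

    def test_affine_invariance_via_zscoring(self):
        rng = np.random.default_rng(5)
        counts = rng.poisson(4.0, size=(30, 6)).astype(float) + 1
        a = make_adata(counts)
        a.layers["lognorm"] = a.X.copy()
        s1 = score_cell_cycle(a, ["g0", "g1"], ["g2"])
        b = make_adata(counts)
        import scipy.sparse as sp

        scaled = np.asarray(counts)
        scaled[:, 0] = scaled[:, 0] * 7.0 + 3.0
        b.layers["lognorm"] = sp.csr_matrix(scaled)
        s2 = score_cell_cycle(b, ["g0", "g1"], ["g2"])
        np.testing.assert_allclose(s1.to_numpy(), s2.to_numpy(), atol=1e-12)

    def test_missing_set_genes_error(self):
        a = make_adata(np.ones((5, 3)))
        normalize_log1p(a)
        with pytest.raises(ValueError, match="g1s"):
            score_cell_cycle(a, ["absent"], ["g0"])


class TestCompareClusterCycle:
    def test_fold_change_gate_blocks_significant_small_difference(self):
        rng = np.random.default_rng(0)
        n = 4000
        scores = pd.DataFrame({"g1s": np.concatenate([
            rng.normal(0.05, 0.1, n), rng.normal(0.0, 0.1, n)])})
        clusters = pd.Series(["A"] * n + ["B"] * n)
        out = compare_cluster_cycle(scores, clusters)
        row = out[(out["cluster"] == "A")].iloc[0]
        assert row["p"] < 1e-6 and 0 < row["mean_diff"] < 0.1
        assert not row["flagged"]

    def test_identical_distributions_not_flagged(self):
        scores = pd.DataFrame({"g1s": np.tile([0.1, 0.2, 0.3], 4)})
        clusters = pd.Series(["A"] * 6 + ["B"] * 6)
        out = compare_cluster_cycle(scores, clusters)
        assert not out["flagged"].any()

    def test_large_difference_flagged(self):
        rng = np.random.default_rng(1)
        scores = pd.DataFrame({"g2m": np.concatenate([
            rng.normal(1.0, 0.2, 50), rng.normal(0.0, 0.2, 50)])})
        clusters = pd.Series(["A"] * 50 + ["B"] * 50)
        out = compare_cluster_cycle(scores, clusters)
        assert out[out["cluster"] == "A"].iloc[0]["flagged"]


class TestAnnotateClusters:
    @staticmethod
    def _evidence(marker_ct="TAM", de_genes=("CD68", "LYZ"), gsea_ct="TAM"):
        mf = pd.DataFrame(
            [{"cluster": "c0", "cell_type": "TAM", "marker": "CD68",
              "fraction": 0.9 if marker_ct == "TAM" else 0.1},
             {"cluster": "c0", "cell_type": "B", "marker": "MS4A1",
              "fraction": 0.9 if marker_ct == "B" else 0.1}]
        )
        de = pd.DataFrame(
            {"cluster": "c0", "gene": list(de_genes) + ["x", "y"],
             "log_fc": [3.0, 2.5, 1.0, 0.5], "p": [1e-5] * 4, "p_adj": [1e-4] * 4}
        )
        gs = pd.DataFrame(
            [{"cluster": "c0", "gene_set": gsea_ct, "es": 0.8, "nes": 2.0,
              "p": 0.001, "fdr": 0.01, "enriched": True}]
        )
        return AnnotationEvidence(marker_fractions=mf, de_table=de, gsea_table=gs)

    CURATED = {"TAM": ["CD68", "LYZ"], "B": ["MS4A1", "CD79A"], "T": ["CD3D", "CD3E"]}

    def test_unanimous_vote(self):
        ann = annotate_clusters(self._evidence(), self.CURATED)
        assert ann.loc[0, "label"] == "TAM"

    def test_split_vote_unassigned(self):
        ev = self._evidence(marker_ct="B", de_genes=("CD3D", "CD3E"), gsea_ct="TAM")
        ann = annotate_clusters(ev, self.CURATED)
        assert ann.loc[0, "label"] == "unassigned"

    def test_doublet_flagging(self):
        ann = annotate_clusters(
            self._evidence(), self.CURATED,
            doublet_fractions=pd.Series({"c0": 0.4}),
        )
        assert bool(ann.loc[0, "suspected_doublet"])

    def test_missing_layer_errors(self):
        ev = self._evidence()
        ev.gsea_table = pd.DataFrame()
        with pytest.raises(ValueError, match="layers"):
            annotate_clusters(ev, self.CURATED)

    def test_bh_invariant_enforced(self):
        de = pd.DataFrame({"cluster": ["c0"], "gene": ["g"], "log_fc": [1.0],
                           "p": [0.5], "p_adj": [0.01]})
        with pytest.raises(ValueError, match="BH"):
            AnnotationEvidence(
                marker_fractions=pd.DataFrame({"cluster": []}),
                de_table=de, gsea_table=pd.DataFrame(),
            )


class TestEndToEndAnnotation:
    def test_planted_cytotoxic_cluster_labeled(self, small_config):
        """With truth clusters, the 3-layer vote names the cytotoxic T cluster."""
        from brmtme.io import read_markers_yaml
        from brmtme.simulate import simulate_sc_dataset

        curated = read_markers_yaml()
        hits = 0
        n_seeds = 10
        for seed in range(n_seeds):
            cfg = small_config.with_(seed=seed, n_cells_per_sample={"tumor": 500, "csf": 200})
            a, truth = simulate_sc_dataset(cfg, "tumor")
            ok = (truth.cell_meta["qc_class"] == "ok").to_numpy()
            sub = a[ok].copy()
            normalize_log1p(sub)
            clusters = truth.cell_meta.loc[sub.obs_names, "cell_type"].rename("cluster")
            de = rank_markers(sub, clusters)
            mf = marker_fractions(sub, clusters, curated)
            gs = []
            for c in sorted(clusters.unique()):
                g = gsea_preranked(
                    de[de["cluster"] == c].set_index("gene")["log_fc"],
                    curated, n_perm=100, seed=seed,
                )
                g.insert(0, "cluster", c)
                gs.append(g)
            ev = AnnotationEvidence(mf, de, pd.concat(gs, ignore_index=True))
            ann = annotate_clusters(ev, curated).set_index("cluster")
            hits += ann.loc["cytotoxic T", "label"] == "cytotoxic T"
        assert hits >= 9
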