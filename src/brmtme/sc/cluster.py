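"""Normalization, variable-gene selection and graph community clustering.

The clustering follows the standard scRNA-seq recipe: library-size
normalization and log transform, variance-stabilized variable-gene ranking,
z-scaling, PCA with a dimension rule based on component standard deviation
(components with sd >= 2 on z-scaled data), a k-nearest-neighbor graph with
Jaccard edge weights, and modularity-based community detection at a fixed
resolution and seed.
"""

from __future__ import annotations

import logging

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

logger = logging.getLogger("brmtme")


def normalize_log1p(adata: ad.AnnData, scale: float = 1e4) -> ad.AnnData:
    """Store ln(1 + scale * count / cell_total) in ``adata.layers['lognorm']``."""
    X = adata.X.tocsr() if sp.issparse(adata.X) else sp.csr_matrix(adata.X)
    totals = np.asarray(X.sum(axis=1)).ravel()
    if (totals == 0).any():
        bad = adata.obs_names[totals == 0].tolist()
        raise ValueError(f"cells with zero total count (should have failed QC): {bad[:5]}")
    norm = X.multiply(scale / totals[:, None]).tocsr()
    norm.data = np.log1p(norm.data)
    adata.layers["lognorm"] = norm
    return adata


def select_variable_genes(adata: ad.AnnData, n_top: int = 2000) -> list[str]:
    """Rank genes by variance residual against a polynomial mean-variance trend.

    The trend is a degree-2 polynomial of log10 variance on log10 mean, fitted
    over expressed genes; genes are ranked by their residual (observed minus
    trend) and the top ``n_top`` returned. Constant genes are never selected.
    """
    if adata.n_obs < 2:
        raise ValueError("variable-gene selection needs at least 2 cells")
    X = adata.layers.get("lognorm", adata.X)
    X = X.tocsc() if sp.issparse(X) else sp.csc_matrix(X)
    n = X.shape[0]
    mean = np.asarray(X.mean(axis=0)).ravel()
    sq = np.asarray(X.multiply(X).mean(axis=0)).ravel()
    var = (sq - mean**2) * n / (n - 1)
    ok = (mean > 0) & (var > 0)
    lm, lv = np.log10(mean[ok]), np.log10(var[ok])
    coef = np.polyfit(lm, lv, deg=2)
    resid = np.full(X.shape[1], -np.inf)
    resid[ok] = lv - np.polyval(coef, lm)
    order = np.argsort(resid)[::-1]
    keep = [i for i in order if resid[i] > -np.inf][:n_top]
    return adata.var_names[keep].tolist()


def _pca_embed(Z: np.ndarray, pc_sd_min: float, seed: int, max_pcs: int = 50) -> np.ndarray:
    from sklearn.decomposition import PCA

    k = min(max_pcs, Z.shape[0] - 1, Z.shape[1])
    pca = PCA(n_components=k, svd_solver="randomized", random_state=seed)
    emb = pca.fit_transform(Z)
    sd = emb.std(axis=0, ddof=1)
    n_keep = max(2, int((sd >= pc_sd_min).sum()))
    logger.info("PCA: keeping %d/%d components (sd >= %.2f)", n_keep, k, pc_sd_min)
    return emb[:, :n_keep]


def _knn_jaccard_graph(emb: np.ndarray, k_neighbors: int):
    import igraph
    from sklearn.neighbors import NearestNeighbors

    n = emb.shape[0]
    nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(emb)
    _, idx = nn.kneighbors(emb)
    neigh = [set(row[1:]) for row in idx]
    edges, weights = [], []
    seen = set()
    for i in range(n):
        for j in idx[i][1:]:
            j = int(j)
            key = (i, j) if i < j else (j, i)
            if key in seen:
                continue
            seen.add(key)
            inter = len(neigh[i] & neigh[j])
            union = len(neigh[i] | neigh[j])
            w = inter / union if union else 0.0
            edges.append(key)
            weights.append(max(w, 1e-6))
    g = igraph.Graph(n=n, edges=edges)
    g.es["weight"] = weights
    return g


def cluster_cells(
    adata: ad.AnnData,
    variable_genes: list[str],
    pc_sd_min: float = 2.0,
    resolution: float = 0.4,
    k_neighbors: int = 20,
    seed: int = 0,
) -> pd.Series:
    """Community labels on the kNN graph of the PCA embedding (deterministic)."""
    import leidenalg

    if adata.n_obs < k_neighbors + 1:
        raise ValueError(f"need more than {k_neighbors} cells")
    genes = [g for g in variable_genes if g in set(adata.var_names)]
    X = adata.layers.get("lognorm", adata.X)
    sub = X[:, adata.var_names.get_indexer(genes)]
    Z = np.asarray(sub.todense()) if sp.issparse(sub) else np.asarray(sub)
    mu = Z.mean(axis=0)
    sd = Z.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    Z = (Z - mu) / sd
    emb = _pca_embed(Z, pc_sd_min=pc_sd_min, seed=seed)
    g = _knn_jaccard_graph(emb, k_neighbors)
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        weights="weight",
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=2,
    )
    labels = pd.Series(
        [str(m) for m in part.membership], index=adata.obs_names, name="cluster"
    )
    logger.info("clustering: %d communities at resolution %.2f", labels.nunique(), resolution)
    return labels


def recluster_t_cells(
    adata: ad.AnnData,
    clusters: pd.Series,
    t_genes: tuple[str, str] = ("CD3D", "CD3E"),
    frac_threshold: float = 0.10,
    cycle_flags: dict[str, bool] | None = None,
    **cluster_kw,
) -> pd.Series:
    """Pool clusters with > 10% CD3-positive cells and re-cluster them.

    A cell is CD3-positive when its mean normalized CD3D/CD3E expression is
    > 0. Clusters flagged as cell-cycle-driven are re-clustered alone (no
    cycle adjustment) rather than pooled; other labels pass through unchanged.
    """
    present = [g for g in t_genes if g in set(adata.var_names)]
    if len(present) < len(t_genes):
        raise ValueError(f"T marker genes missing from panel: {set(t_genes) - set(present)}")
    X = adata.layers.get("lognorm", adata.X)
    sub = X[:, adata.var_names.get_indexer(list(t_genes))]
    expr = np.asarray(sub.todense()) if sp.issparse(sub) else np.asarray(sub)
    cd3_pos = expr.mean(axis=1) > 0
    cd3 = pd.Series(cd3_pos, index=adata.obs_names)

    cycle_flags = cycle_flags or {}
    t_clusters = [
        c for c, frac in cd3.groupby(clusters, observed=True).mean().items()
        if frac > frac_threshold and not cycle_flags.get(c, False)
    ]
    out = clusters.copy().astype(object)
    if t_clusters:
        mask = clusters.isin(t_clusters)
        sub_ad = adata[mask.to_numpy()]
        sub_labels = cluster_cells(sub_ad, **_sub_kw(adata, cluster_kw, sub_ad))
        out[mask] = "T" + sub_labels.astype(str)
    for c in (c for c, f in cycle_flags.items() if f):
        mask = clusters == c
        if not mask.any():
            continue
        sub_ad = adata[mask.to_numpy()]
        sub_labels = cluster_cells(sub_ad, **_sub_kw(adata, cluster_kw, sub_ad))
        out[mask] = f"{c}cyc" + sub_labels.astype(str)
    return out.rename("cluster")


def _sub_kw(adata, cluster_kw, sub_ad) -> dict:
    # re-clustering runs on small subsets: cap the feature count by cell count
    # so the PCA dimension rule is not swamped by sampling-noise components
    kw = dict(cluster_kw)
    n_top = min(2000, max(200, sub_ad.n_obs // 2))
    kw.setdefault("variable_genes", select_variable_genes(sub_ad, n_top=n_top))
    kw.setdefault("k_neighbors", min(20, sub_ad.n_obs - 1))
    return kw
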