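"""Three-evidence cluster annotation: curated markers, one-vs-rest DE, preranked GSEA.

Each evidence layer casts one vote per cluster — the cell type with the
highest curated-marker expressing fraction, the type with most of its markers
among the top-20 DE genes, and the type whose gene set is the strongest
positive GSEA enrichment (FDR < 0.25). The majority label wins; clusters
without a majority stay "unassigned", and clusters co-expressing T and
myeloid markers in more than 25% of cells are flagged as suspected doublets.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.stats as ss

from .._utils import benjamini_hochberg

logger = logging.getLogger("brmtme")


@dataclass
class AnnotationEvidence:
    marker_fractions: pd.DataFrame  # cluster x (cell_type, marker) fraction expressing
    de_table: pd.DataFrame  # cluster, gene, log_fc, p, p_adj
    gsea_table: pd.DataFrame  # cluster, gene_set, es, nes, p, fdr, enriched
    notes: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.de_table.empty:
            if (self.de_table["p_adj"] + 1e-12 < self.de_table["p"]).any():
                raise ValueError("BH-adjusted p below raw p")


def _dense(X) -> np.ndarray:
    return np.asarray(X.todense()) if sp.issparse(X) else np.asarray(X)


def rank_markers(
    adata: ad.AnnData, clusters: pd.Series, min_cells: int = 3, pseudo: float = 1e-9
) -> pd.DataFrame:
    """One-vs-rest Wilcoxon rank-sum DE per cluster on normalized expression.

    Returns one row per (cluster, gene) with the log2 fold change of means
    (pseudocount ``pseudo``) and BH-adjusted p within cluster, sorted by
    descending log fold change.
    """
    if clusters.nunique() < 2:
        raise ValueError("DE needs at least 2 clusters")
    X = _dense(adata.layers.get("lognorm", adata.X))
    rows = []
    for c in sorted(clusters.unique()):
        mask = (clusters == c).to_numpy()
        if mask.sum() < min_cells:
            warnings.warn(f"cluster {c!r} has fewer than {min_cells} cells; skipped")
            continue
        inside, outside = X[mask], X[~mask]
        with np.errstate(invalid="ignore"):
            stat, p = ss.mannwhitneyu(
                inside, outside, alternative="two-sided", axis=0, method="asymptotic"
            )
        p = np.nan_to_num(p, nan=1.0)
        log_fc = np.log2((inside.mean(axis=0) + pseudo) / (outside.mean(axis=0) + pseudo))
        padj = benjamini_hochberg(p)
        sub = pd.DataFrame(
            {"cluster": c, "gene": adata.var_names, "log_fc": log_fc, "p": p, "p_adj": padj}
        )
        rows.append(sub.sort_values("log_fc", ascending=False))
    return pd.concat(rows, ignore_index=True)


def gsea_preranked(
    ranking: pd.Series,
    gene_sets: dict[str, list[str]],
    n_perm: int = 1000,
    seed: int = 0,
    fdr_max: float = 0.25,
    weight: float = 1.0,
) -> pd.DataFrame:
    """Preranked GSEA: weighted KS enrichment score with permutation NES/FDR.

    The running sum increments by |r|^weight / NR at member genes and
    decrements by 1/(N - k) elsewhere; ES is the extremum of the running sum.
    The null is gene-label permutation (random same-size sets); NES divides ES
    by the mean same-sign null ES, and FDR uses the standard positive/negative
    pooled ratio. Sets with NES > 0 and FDR < ``fdr_max`` are flagged enriched.
    """
    ranking = ranking.sort_values(ascending=False)
    order = ranking.index.to_numpy()
    scores = ranking.to_numpy(dtype=float)
    N = len(order)
    pos_of = {g: i for i, g in enumerate(order)}
    rng = np.random.default_rng(seed)

    results = []
    null_nes_all = []
    obs = []
    for name, genes in gene_sets.items():
        hit_idx = np.array(sorted(pos_of[g] for g in genes if g in pos_of))
        if hit_idx.size == 0:
            raise ValueError(f"gene set {name!r} has empty intersection with ranking")
        es = _es(scores, hit_idx, N, weight)
        null = np.empty(n_perm)
        k = hit_idx.size
        for b in range(n_perm):
            null[b] = _es(scores, rng.choice(N, size=k, replace=False), N, weight)
        same = null[null * es > 0] if es != 0 else null
        denom = np.abs(same).mean() if same.size else np.abs(null).mean() or 1.0
        nes = es / denom
        null_nes = null / np.where(
            null > 0,
            np.abs(null[null > 0]).mean() if (null > 0).any() else 1.0,
            np.abs(null[null < 0]).mean() if (null < 0).any() else 1.0,
        )
        p = float(((np.abs(same) >= abs(es)).sum() + 1) / (same.size + 1)) if same.size else 1.0
        obs.append({"gene_set": name, "es": float(es), "nes": float(nes), "p": p, "n_genes": k})
        null_nes_all.append(null_nes)

    null_nes_all = np.concatenate(null_nes_all)
    obs_nes = np.array([o["nes"] for o in obs])
    for o in obs:
        nes = o["nes"]
        if nes >= 0:
            num = (null_nes_all >= nes).mean() / max((null_nes_all >= 0).mean(), 1e-12)
            den = max((obs_nes >= nes).mean() / max((obs_nes >= 0).mean(), 1e-12), 1e-12)
        else:
            num = (null_nes_all <= nes).mean() / max((null_nes_all <= 0).mean(), 1e-12)
            den = max((obs_nes <= nes).mean() / max((obs_nes <= 0).mean(), 1e-12), 1e-12)
        fdr = float(min(1.0, num / den))
        o["fdr"] = fdr
        o["enriched"] = bool(nes > 0 and fdr < fdr_max)
        results.append(o)
    return pd.DataFrame(results)


def _es(scores: np.ndarray, hit_idx: np.ndarray, N: int, weight: float) -> float:
    """Weighted KS running-sum extremum for a hit-position set."""
    w = np.abs(scores[hit_idx]) ** weight
    nr = w.sum()
    if nr == 0:
        nr = 1.0
    k = hit_idx.size
    miss = 1.0 / (N - k) if N > k else 0.0
    delta = np.full(N, -miss)
    delta[hit_idx] = w / nr
    run = np.cumsum(delta)
    return float(run[np.argmax(np.abs(run))])


def score_cell_cycle(
    adata: ad.AnnData, g1s_genes: list[str], g2m_genes: list[str]
) -> pd.DataFrame:
    """Per-cell G1/S and G2/M scores: mean z-scored normalized expression."""
    out = {}
    for name, genes in (("g1s", g1s_genes), ("g2m", g2m_genes)):
        present = [g for g in genes if g in set(adata.var_names)]
        if not present:
            raise ValueError(f"no {name} genes present in panel")
        X = _dense(adata.layers.get("lognorm", adata.X)[:, adata.var_names.get_indexer(present)])
        mu = X.mean(axis=0)
        sd = X.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        out[name] = ((X - mu) / sd).mean(axis=1)
    return pd.DataFrame(out, index=adata.obs_names)


def compare_cluster_cycle(
    scores: pd.DataFrame,
    clusters: pd.Series,
    p_max: float = 0.05,
    fc_min: float = 0.1,
) -> pd.DataFrame:
    """One-vs-rest Mann-Whitney per cluster on each cycle score.

    A cluster is flagged only when p < 0.05 AND the score difference
    (cluster mean minus rest mean) exceeds 0.1 — significance alone is not
    enough.
    """
    if clusters.nunique() < 2:
        raise ValueError("need at least 2 clusters")
    rows = []
    for col in scores.columns:
        s = scores[col]
        for c in sorted(clusters.unique()):
            mask = clusters == c
            if mask.sum() == 0:
                continue
            inside, outside = s[mask.to_numpy()], s[~mask.to_numpy()]
            _, p = ss.mannwhitneyu(inside, outside, alternative="two-sided")
            diff = float(inside.mean() - outside.mean())
            rows.append(
                {
                    "score": col,
                    "cluster": c,
                    "mean_diff": diff,
                    "p": float(p),
                    "flagged": bool(p < p_max and diff > fc_min),
                }
            )
    return pd.DataFrame(rows)


def marker_fractions(
    adata: ad.AnnData, clusters: pd.Series, curated: dict[str, list[str]]
) -> pd.DataFrame:
    """Fraction of cells per cluster expressing each curated marker (> 0)."""
    X = adata.layers.get("lognorm", adata.X)
    rows = []
    for ct, genes in curated.items():
        present = [g for g in genes if g in set(adata.var_names)]
        for g in present:
            expr = _dense(X[:, adata.var_names.get_indexer([g])]).ravel() > 0
            frac = pd.Series(expr, index=adata.obs_names).groupby(clusters, observed=True).mean()
            for c, f in frac.items():
                rows.append({"cluster": c, "cell_type": ct, "marker": g, "fraction": float(f)})
    return pd.DataFrame(rows)


def annotate_clusters(
    evidence: AnnotationEvidence,
    curated: dict[str, list[str]],
    doublet_fractions: pd.Series | None = None,
    doublet_max: float = 0.25,
    top_n_de: int = 20,
) -> pd.DataFrame:
    """Majority vote of the three evidence layers per cluster.

    Returns a table with the per-layer votes, the final label ("unassigned"
    when no majority) and the suspected-doublet flag (fraction of cells
    co-expressing T and myeloid markers above ``doublet_max``).
    """
    if evidence.marker_fractions.empty or evidence.de_table.empty or evidence.gsea_table.empty:
        raise ValueError("all three evidence layers are required")
    mf, de, gs = evidence.marker_fractions, evidence.de_table, evidence.gsea_table
    clusters = sorted(set(mf["cluster"]) | set(de["cluster"]))
    marker_sets = {ct: set(genes) for ct, genes in curated.items()}
    rows = []
    for c in clusters:
        votes = {}
        sub = mf[mf["cluster"] == c]
        if not sub.empty:
            support = sub.groupby("cell_type")["fraction"].mean()
            votes["markers"] = support.idxmax()
        top = de[de["cluster"] == c].nlargest(top_n_de, "log_fc")["gene"]
        overlap = {ct: len(set(top) & s) for ct, s in marker_sets.items()}
        best = max(overlap.values(), default=0)
        if best > 0:
            cands = [ct for ct, k in overlap.items() if k == best]
            votes["de"] = cands[0] if len(cands) == 1 else None
        gsub = gs[(gs["cluster"] == c) & gs["enriched"]] if "cluster" in gs else gs[gs["enriched"]]
        if not gsub.empty:
            gsub = gsub.sort_values(["fdr", "nes"], ascending=[True, False])
            votes["gsea"] = gsub.iloc[0]["gene_set"]
        cast = [v for v in votes.values() if v is not None]
        counts = pd.Series(cast).value_counts() if cast else pd.Series(dtype=int)
        label = counts.index[0] if (not counts.empty and counts.iloc[0] >= 2) else "unassigned"
        doublet = bool(
            doublet_fractions is not None and doublet_fractions.get(c, 0.0) > doublet_max
        )
        rows.append(
            {
                "cluster": c,
                "vote_markers": votes.get("markers"),
                "vote_de": votes.get("de"),
                "vote_gsea": votes.get("gsea"),
                "label": label,
                "suspected_doublet": doublet,
            }
        )
    return pd.DataFrame(rows)


def doublet_coexpression_fraction(
    adata: ad.AnnData,
    clusters: pd.Series,
    t_genes: tuple[str, ...] = ("CD3D", "CD3E"),
    myeloid_genes: tuple[str, ...] = ("CD68",),
) -> pd.Series:
    """Per cluster, fraction of cells expressing both a T and a myeloid marker."""
    X = adata.layers.get("lognorm", adata.X)

    def any_pos(genes):
        present = [g for g in genes if g in set(adata.var_names)]
        if not present:
            raise ValueError(f"markers absent from panel: {genes}")
        sub = _dense(X[:, adata.var_names.get_indexer(present)])
        return (sub > 0).any(axis=1)

    both = any_pos(t_genes) & any_pos(myeloid_genes)
    return pd.Series(both, index=adata.obs_names).groupby(clusters, observed=True).mean()
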